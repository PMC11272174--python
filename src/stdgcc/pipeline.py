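"""End-to-end convenience: raw data -> features -> graph -> training ->
PCA + k-means -> (optional) evaluation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .clustering_eval import ClusterResult, ari, cluster_embedding, nmi
from .data_io import RawDataset, preprocess
from .graph import build_spatial_graph
from .training import TrainConfig, TrainResult, train


@dataclass
class PipelineResult:
    train_result: TrainResult
    cluster_result: ClusterResult
    ari: Optional[float] = None
    nmi: Optional[float] = None


def run_pipeline(raw: RawDataset, k: int, cfg: TrainConfig = None,
                 min_spots: int = 5) -> PipelineResult:
    """Run the full method on one section and score against labels if present.

    ``k`` is the number of spatial domains to extract (for annotated data,
    the number of annotated regions).  The number of principal components
    fed to k-means is capped by the latent width.
    """
    cfg = cfg or TrainConfig()
    fm = preprocess(raw, min_spots=min_spots, hvg_t=cfg.hvg_t)
    graph = build_spatial_graph(raw.coords, delta=cfg.delta, lam=cfg.lam)
    tr = train(fm, graph, cfg)
    n_pcs = min(cfg.n_pcs, cfg.latent_dim, raw.n_spots)
    cr = cluster_embedding(tr.final_embedding, k=k, seed=cfg.seed,
                           n_components=n_pcs)
    res = PipelineResult(train_result=tr, cluster_result=cr)
    if raw.labels is not None:
        res.ari = ari(cr.labels_pred, raw.labels)
        res.nmi = nmi(cr.labels_pred, raw.labels)
    return res
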