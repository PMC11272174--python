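"""Reading spot-level expression data and preprocessing it into features.

Supported on-disk layouts:

* ``mtx-dir`` — a directory holding ``matrix.mtx`` (genes x spots, the 10x
  convention), ``barcodes.tsv`` and ``features.tsv`` (or ``genes.tsv``),
  with coordinates in a separate CSV.
* ``10x-h5`` — a 10x Genomics HDF5 feature-barcode matrix (read via scanpy),
  coordinates in a separate CSV.
* ``dense`` — a CSV/TSV table with one row per spot (index = barcode) and one
  column per gene; coordinates may be embedded as ``x``/``y`` columns and
  ground-truth annotations as a ``label`` column.

Coordinate CSVs follow the tissue-positions style: columns
``barcode, x, y`` (header optional for exactly-3-column files).

The preprocessing chain is: gene filter -> per-spot library-size
normalization to the median library -> log1p -> per-gene standardization ->
highly-variable-gene selection.  Gene variability is ranked on the
log-normalized (pre-standardization) matrix, since standardization equalizes
variances by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import AlignmentError, EmptyResultError, ParameterError, ValidationError

SCALE_CLIP = 10.0  # optional clip bound for standardized values (off by default)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RawDataset:
    """One tissue section: counts, spot coordinates and optional annotations.

    counts is an N x G dense array of non-negative integers; coords is N x 2
    in platform units (the same units as the neighbor-graph distance
    threshold delta); labels, when present, hold one integer domain
    annotation per spot.
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_names: np.ndarray
    labels: Optional[np.ndarray] = None
    barcodes: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-D (spots x genes)")
        if np.any(self.counts < 0):
            raise ValidationError("counts contain negative entries")
        if self.coords.shape != (self.counts.shape[0], 2):
            raise AlignmentError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.counts.shape[0]} spots"
            )
        if self.gene_names.shape[0] != self.counts.shape[1]:
            raise ValidationError("gene_names length does not match gene count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.counts.shape[0]:
                raise AlignmentError("labels length does not match spot count")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class FeatureMatrix:
    """Preprocessed N x F feature matrix with provenance.

    ``hvg_scores``, when set, carries the per-gene variance of the
    log-normalized matrix used to rank highly variable genes.
    """

    X: np.ndarray
    gene_subset: np.ndarray
    preprocessing_log: list = field(default_factory=list)
    hvg_scores: Optional[np.ndarray] = None

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_coords(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "barcode" in cols and "x" in cols and "y" in cols:
        df.columns = cols
    elif df.shape[1] == 3:
        df.columns = ["barcode", "x", "y"]
    else:
        raise ValidationError(
            f"coordinate table {path!r} needs columns barcode, x, y"
        )
    return df[["barcode", "x", "y"]].astype({"barcode": str})


def _read_labels(path: str) -> pd.Series:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"label table {path!r} needs barcode + label columns")
    df.columns = ["barcode", "label"] + list(df.columns[2:])
    return df.set_index(df["barcode"].astype(str))["label"]


def _align(counts, barcodes, gene_names, coords_df, labels=None) -> RawDataset:
    coords_df = coords_df.set_index("barcode")
    missing = [b for b in barcodes if b not in coords_df.index]
    if missing:
        raise AlignmentError(
            f"no coordinates for {len(missing)} spot(s): {missing[:10]}"
        )
    coords = coords_df.loc[list(barcodes), ["x", "y"]].to_numpy(dtype=float)
    lab = None
    if labels is not None:
        missing = [b for b in barcodes if b not in labels.index]
        if missing:
            raise AlignmentError(
                f"no labels for {len(missing)} spot(s): {missing[:10]}"
            )
        lab = labels.loc[list(barcodes)].to_numpy()
    return RawDataset(counts=counts, coords=coords, gene_names=gene_names,
                      labels=lab, barcodes=np.asarray(barcodes, dtype=object))


def load_dataset(path: str, format: str = "mtx-dir",
                 coords_source: Optional[str] = None,
                 labels_source: Optional[str] = None) -> RawDataset:
    """Load counts + coordinates (+ labels) into an aligned :class:`RawDataset`.

    ``format`` is one of ``mtx-dir`` (matrix-market directory), ``10x-h5``,
    ``dense`` (spots-as-rows table).  ``coords_source`` is required unless the
    dense table embeds ``x``/``y`` columns.
    """
    fmt = format.lower().replace("matrix-market-dir", "mtx-dir").replace(
        "dense-table", "dense")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if fmt == "mtx-dir":
        mat = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
        counts = np.asarray(sp.csr_matrix(mat).T.todense())  # genes x spots on disk
        barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t",
                               header=None)[0].astype(str).tolist()
        feat_path = os.path.join(path, "features.tsv")
        if not os.path.exists(feat_path):
            feat_path = os.path.join(path, "genes.tsv")
        gene_names = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(
            str).to_numpy(dtype=object)
        if coords_source is None:
            coords_source = os.path.join(path, "coords.csv")
        if labels_source is None:
            cand = os.path.join(path, "labels.csv")
            labels_source = cand if os.path.exists(cand) else None
    elif fmt == "10x-h5":
        import scanpy as sc
        adata = sc.read_10x_h5(path)
        counts = np.asarray(
            adata.X.todense() if sp.issparse(adata.X) else adata.X)
        barcodes = adata.obs_names.astype(str).tolist()
        gene_names = adata.var_names.to_numpy(dtype=object)
        if coords_source is None:
            raise ValidationError("10x-h5 input requires coords_source")
    elif fmt == "dense":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        labels = None
        embedded_coords = None
        lower = {c.lower(): c for c in df.columns}
        if "label" in lower:
            labels = df[lower["label"]].copy()
            df = df.drop(columns=[lower["label"]])
        if "x" in lower and "y" in lower:
            embedded_coords = pd.DataFrame({
                "barcode": df.index,
                "x": df[lower["x"]].to_numpy(dtype=float),
                "y": df[lower["y"]].to_numpy(dtype=float)})
            df = df.drop(columns=[lower["x"], lower["y"]])
        counts = df.to_numpy()
        barcodes = df.index.tolist()
        gene_names = df.columns.to_numpy(dtype=object)
        coords_df = (_read_coords(coords_source) if coords_source is not None
                     else embedded_coords)
        if coords_df is None:
            raise ValidationError("dense input has no x/y columns and no coords_source")
        if labels_source is not None:
            labels = _read_labels(labels_source)
        return _align(counts, barcodes, gene_names, coords_df, labels)
    else:
        raise ParameterError(f"unknown format {format!r}")

    if np.any(counts < 0):
        raise ValidationError("counts contain negative entries")
    coords_df = _read_coords(coords_source)
    labels = _read_labels(labels_source) if labels_source else None
    return _align(counts, barcodes, gene_names, coords_df, labels)


def save_dataset(raw: RawDataset, outdir: str) -> None:
    """Write a dataset in the matrix-market directory layout this module reads."""
    os.makedirs(outdir, exist_ok=True)
    barcodes = (raw.barcodes if raw.barcodes is not None
                else np.array([f"spot{i:05d}" for i in range(raw.n_spots)],
                              dtype=object))
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"),
                     sp.csr_matrix(raw.counts.T))  # genes x spots on disk
    pd.Series(barcodes).to_csv(os.path.join(outdir, "barcodes.tsv"),
                               sep="\t", index=False, header=False)
    pd.Series(raw.gene_names).to_csv(os.path.join(outdir, "features.tsv"),
                                     sep="\t", index=False, header=False)
    pd.DataFrame({"barcode": barcodes,
                  "x": raw.coords[:, 0],
                  "y": raw.coords[:, 1]}).to_csv(
        os.path.join(outdir, "coords.csv"), index=False)
    if raw.labels is not None:
        pd.DataFrame({"barcode": barcodes, "label": raw.labels}).to_csv(
            os.path.join(outdir, "labels.csv"), index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_genes(raw: RawDataset, min_spots: int = 5) -> RawDataset:
    """Drop genes with nonzero counts in fewer than ``min_spots`` spots."""
    if min_spots < 1:
        raise ParameterError("min_spots must be >= 1")
    keep = (raw.counts > 0).sum(axis=0) >= min_spots
    if not keep.any():
        raise EmptyResultError(
            f"all {raw.n_genes} genes removed at min_spots={min_spots}")
    return RawDataset(counts=raw.counts[:, keep],
                      coords=raw.coords,
                      gene_names=raw.gene_names[keep],
                      labels=raw.labels,
                      barcodes=raw.barcodes)


def normalize_log_scale(raw: RawDataset, clip: bool = False) -> FeatureMatrix:
    """Library-size normalize, log1p, then standardize each gene column.

    Per-spot counts are scaled so every spot has the median library size,
    then log(1+x) is applied, then each gene is centered and divided by its
    (population) standard deviation.  Constant genes map to all-zero columns.
    With ``clip=True`` standardized values are clamped to +-10.
    """
    counts = raw.counts.astype(np.float64)
    lib = counts.sum(axis=1)
    if np.any(lib == 0):
        raise ValidationError(
            f"{int((lib == 0).sum())} spot(s) have zero total counts")
    target = float(np.median(lib))
    log_steps = [f"normalize_total(target={target:g})", "log1p"]
    X = counts * (target / lib)[:, None]
    X = np.log1p(X)
    log_var = X.var(axis=0, ddof=1)  # HVG ranking statistic (pre-scaling)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    X = (X - mu) / sd_safe
    X[:, zero] = 0.0
    log_steps.append("scale(zero_mean,unit_variance)")
    if zero.any():
        log_steps.append(f"constant_genes_zeroed(n={int(zero.sum())})")
    if clip:
        X = np.clip(X, -SCALE_CLIP, SCALE_CLIP)
        log_steps.append(f"clip(+-{SCALE_CLIP:g})")
    return FeatureMatrix(X=X, gene_subset=raw.gene_names.copy(),
                         preprocessing_log=log_steps, hvg_scores=log_var)


def select_hvgs(fm: FeatureMatrix, t: int = 3000) -> FeatureMatrix:
    """Restrict to the ``t`` most variable genes.

    Genes are ranked by the variance of the log-normalized matrix (carried on
    ``fm.hvg_scores``; falls back to column variance of ``fm.X``), descending,
    ties broken by gene name for determinism.
    """
    if t < 1:
        raise ParameterError("t must be >= 1")
    if t > fm.n_features:
        raise ParameterError(
            f"t={t} exceeds available gene count F={fm.n_features}")
    scores = (fm.hvg_scores if fm.hvg_scores is not None
              else fm.X.var(axis=0, ddof=1))
    order = sorted(range(fm.n_features),
                   key=lambda j: (-scores[j], str(fm.gene_subset[j])))
    idx = order[:t]
    return FeatureMatrix(
        X=fm.X[:, idx],
        gene_subset=fm.gene_subset[idx],
        preprocessing_log=fm.preprocessing_log + [f"select_hvgs(t={t})"],
        hvg_scores=scores[idx] if fm.hvg_scores is not None else None)


def preprocess(raw: RawDataset, min_spots: int = 5, hvg_t: int = 3000,
               clip: bool = False) -> FeatureMatrix:
    """Full chain: filter -> normalize -> log1p -> scale -> HVG select.

    ``hvg_t`` is clamped to the number of genes surviving the filter.
    """
    filtered = filter_genes(raw, min_spots=min_spots)
    fm = normalize_log_scale(filtered, clip=clip)
    return select_hvgs(fm, t=min(hvg_t, fm.n_features))


def save_features(fm: FeatureMatrix, path: str) -> None:
    """Write the processed matrix to HDF5 (.h5) or CSV, with the log attached."""
    if path.endswith(".h5") or path.endswith(".hdf5"):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=fm.X)
            f.create_dataset("genes",
                             data=np.asarray(fm.gene_subset, dtype="S"))
            f.attrs["preprocessing_log"] = "\n".join(fm.preprocessing_log)
    else:
        df = pd.DataFrame(fm.X, columns=list(fm.gene_subset))
        with open(path, "w") as fh:
            for step in fm.preprocessing_log:
                fh.write(f"# {step}\n")
            df.to_csv(fh, index=False)
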