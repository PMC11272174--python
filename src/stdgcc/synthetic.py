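"""Synthetic spatial transcriptomics with known domain structure.

The generator lays spots on a regular lattice, partitions them into K
spatially contiguous domains (horizontal strips mimicking cortical layers,
concentric rings, or a Voronoi tessellation of random seed points), and
draws counts from a negative-binomial model with domain marker programs:
each domain owns ``markers_per_domain`` genes whose mean is
``base_mean * fold_change`` inside the domain and ``base_mean`` elsewhere;
non-marker genes sit at ``base_mean`` everywhere.  Independent dropout then
zeroes each entry with probability ``dropout_rate``, reproducing the
overdispersion and sparsity typical of spot-level data.

Defaults give a 30 x 30 lattice (900 spots, lattice spacing 100 units,
the scale on which a distance threshold of 1.5 spacings connects the
4-neighborhood), 150 genes with 10 markers per domain, base mean 2,
fold change 4, dispersion 2 and 20% dropout — a compact fixture with a
clearly recoverable but noisy domain signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .data_io import RawDataset
from .errors import ParameterError

LAYOUTS = ("strips", "rings", "voronoi")


@dataclass
class SyntheticSpec:
    """Generative settings for one synthetic tissue section."""

    layout: str = "strips"
    K: int = 5
    grid: Tuple[int, int] = (30, 30)
    spacing: float = 100.0
    genes: int = 150
    markers_per_domain: int = 10
    base_mean: float = 2.0
    fold_change: float = 4.0
    dispersion: float = 2.0
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.layout not in LAYOUTS:
            raise ParameterError(f"layout must be one of {LAYOUTS}")
        if self.K < 2:
            raise ParameterError("K must be >= 2")
        if self.markers_per_domain * self.K > self.genes:
            raise ParameterError("markers_per_domain * K exceeds gene count")
        if self.fold_change <= 0 or self.base_mean <= 0 or self.dispersion <= 0:
            raise ParameterError("base_mean, fold_change, dispersion must be > 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must lie in [0, 1)")
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ParameterError("grid dims must be positive")
        if self.K > self.grid[0] * self.grid[1]:
            raise ParameterError("more domains than spots")


@dataclass
class SyntheticDataset:
    """Generated section plus its generative spec and true marker map."""

    dataset: RawDataset
    spec: SyntheticSpec
    marker_map: Dict[str, int] = field(default_factory=dict)


def generate_layout(spec: SyntheticSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Lattice coordinates and contiguous domain labels (values 1..K)."""
    rows, cols = spec.grid
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r, c = r.ravel(), c.ravel()
    coords = np.column_stack([c, r]).astype(float) * spec.spacing
    if spec.layout == "strips":
        # K horizontal bands, as equal as possible
        edges = np.linspace(0, rows, spec.K + 1)
        labels = np.searchsorted(edges, r, side="right")
        labels = np.clip(labels, 1, spec.K)
    elif spec.layout == "rings":
        center = coords.mean(axis=0)
        radius = np.linalg.norm(coords - center, axis=1)
        qs = np.quantile(radius, np.linspace(0, 1, spec.K + 1)[1:-1])
        labels = np.searchsorted(qs, radius, side="right") + 1
    else:  # voronoi
        rng = np.random.default_rng(spec.seed)
        seeds = coords[rng.choice(coords.shape[0], size=spec.K, replace=False)]
        d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
        labels = d.argmin(axis=1) + 1
    return coords, labels.astype(np.int64)


def marker_assignment(spec: SyntheticSpec) -> Tuple[np.ndarray, Dict[str, int]]:
    """Gene names and the gene -> domain map for marker genes.

    The first ``markers_per_domain * K`` genes are markers, grouped by
    domain; the rest are background.
    """
    gene_names = np.array([f"G{j:04d}" for j in range(spec.genes)], dtype=object)
    marker_map = {
        str(gene_names[d * spec.markers_per_domain + m]): d + 1
        for d in range(spec.K) for m in range(spec.markers_per_domain)}
    return gene_names, marker_map


def generate_counts(coords: np.ndarray, labels: np.ndarray,
                    spec: SyntheticSpec) -> np.ndarray:
    """Negative-binomial counts with marker programs and dropout."""
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > spec.K:
        raise ParameterError("labels must take values in 1..K")
    n = coords.shape[0]
    rng = np.random.default_rng(spec.seed + 1)
    _, marker_map = marker_assignment(spec)
    mean = np.full((n, spec.genes), spec.base_mean)
    for d in range(spec.K):
        in_domain = labels == d + 1
        lo = d * spec.markers_per_domain
        hi = lo + spec.markers_per_domain
        mean[np.ix_(in_domain, np.arange(lo, hi))] = (
            spec.base_mean * spec.fold_change)
    # NB with shape theta: variance = mu + mu^2 / theta
    theta = spec.dispersion
    p = theta / (theta + mean)
    counts = rng.negative_binomial(theta, p)
    if spec.dropout_rate > 0:
        counts = np.where(rng.random(counts.shape) < spec.dropout_rate,
                          0, counts)
    return counts.astype(np.int64)


def generate_dataset(spec: SyntheticSpec = None, **kwargs) -> SyntheticDataset:
    """Full fixture: layout + counts + names, validated as a RawDataset."""
    if spec is None:
        spec = SyntheticSpec(**kwargs)
    coords, labels = generate_layout(spec)
    counts = generate_counts(coords, labels, spec)
    gene_names, marker_map = marker_assignment(spec)
    barcodes = np.array([f"spot{i:05d}" for i in range(coords.shape[0])],
                        dtype=object)
    raw = RawDataset(counts=counts, coords=coords, gene_names=gene_names,
                     labels=labels, barcodes=barcodes)
    return SyntheticDataset(dataset=raw, spec=spec, marker_map=marker_map)
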