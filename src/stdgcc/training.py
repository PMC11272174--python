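"""End-to-end joint optimization over the full spot graph.

Each epoch performs one forward pass on the clean view (X, Anorm) and one on
a freshly resampled corrupted view (row-shuffled X, same Anorm), evaluates
the weighted joint objective, and takes one Adam step over all parameters.
The corruption permutation and the reparameterization noise are redrawn
every epoch.  After training, the final embedding is produced by a
noise-free (mean) forward pass so downstream clustering is deterministic.

Ablation modes mirror the model's component analysis:

* ``no_vgcn`` — the variational head is bypassed (Z = mu, a plain GCN
  embedding); loss = reconstruction + contrastive.
* ``no_decoder`` — the decoder branch is skipped; loss = KL + contrastive.
* ``no_contrastive`` — the discriminator/corruption branch is skipped;
  loss = reconstruction + KL.

Masked branches are skipped in the forward pass, so their parameters receive
no gradient and remain at initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from . import _autograd as ag
from ._autograd import Adam
from .data_io import FeatureMatrix
from .errors import NumericalInstabilityError, ParameterError
from .graph import SpatialGraph, corrupt_features
from .network import (ENCODER_WIDTHS, LATENT_DIM, ModelParams, decode,
                      encode, init_params, readout)
from .objectives import (ALPHA_DEFAULT, BETA_DEFAULT, GAMMA_DEFAULT,
                         LossBundle, contrastive_loss, kl_loss_from_logsigma,
                         reconstruction_loss, total_loss)

ABLATION_MODES = ("full", "no_vgcn", "no_decoder", "no_contrastive")


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the reference configuration."""

    lam: float = 0.8
    delta: float = 250.0
    hvg_t: int = 3000
    alpha: float = ALPHA_DEFAULT
    beta: float = BETA_DEFAULT
    gamma: float = GAMMA_DEFAULT
    lr: float = 1e-5
    epochs: int = 2500
    widths: Sequence[int] = ENCODER_WIDTHS
    latent_dim: int = LATENT_DIM
    seed: int = 0
    ablation: str = "full"
    hidden_activation: str = "prelu"
    grad_clip: Optional[float] = None
    n_pcs: int = 30

    def __post_init__(self):
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.lr <= 0:
            raise ParameterError("lr must be positive")
        if self.ablation not in ABLATION_MODES:
            raise ParameterError(
                f"ablation must be one of {ABLATION_MODES}, got {self.ablation!r}")

    @classmethod
    def fast_profile(cls, **overrides) -> "TrainConfig":
        """Scaled-down profile for CI-sized fixtures: widths 64/32, latent 16,
        300 epochs, lr 5e-4 (not the reference settings; see docs/methods.md
        for how the rate was calibrated)."""
        base = dict(widths=(64, 32), latent_dim=16, epochs=300, lr=5e-4)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainResult:
    params: ModelParams
    history: List[LossBundle]
    final_embedding: np.ndarray
    config: TrainConfig = None


def ablate(cfg: TrainConfig, mode: str) -> TrainConfig:
    """Return a copy of ``cfg`` with the given ablation mode."""
    if mode not in ABLATION_MODES:
        raise ParameterError(f"unknown ablation mode {mode!r}")
    return replace(cfg, ablation=mode)


def _forward_losses(X, Anorm, params, cfg: TrainConfig, rng: np.random.Generator):
    """One epoch's forward pass; returns (total Tensor, LossBundle)."""
    n, m = X.shape[0], cfg.latent_dim
    variational = cfg.ablation != "no_vgcn"
    noise = rng.standard_normal((n, m)) if variational else None

    state = encode(X, Anorm, params, noise=noise,
                   hidden_activation=cfg.hidden_activation,
                   variational=variational)

    zero = 0.0
    L_kl = zero
    if variational:
        L_kl = kl_loss_from_logsigma(state.mu, ag.log(state.sigma))

    L_r = zero
    if cfg.ablation != "no_decoder":
        X_tilde = decode(state.H, params,
                         hidden_activation=cfg.hidden_activation)
        L_r = reconstruction_loss(X, X_tilde)

    L_pos = L_neg = L_cos = L_c = zero
    if cfg.ablation != "no_contrastive":
        view = corrupt_features(X, seed=int(rng.integers(2**31)))
        # the corrupted view reuses the epoch's noise draw so the contrast
        # between the two views isolates the corruption itself rather than
        # being confounded with an independent reparameterization draw
        state_bar = encode(view.X_bar, Anorm, params, noise=noise,
                           hidden_activation=cfg.hidden_activation,
                           variational=variational)
        s = readout(state.H)
        L_pos, L_neg, L_cos, L_c = contrastive_loss(
            state.H, state_bar.H, s, params.disc_bilinear)

    # weights enter the total exactly as the joint objective prescribes;
    # masked terms are identically zero
    alpha = cfg.alpha if cfg.ablation != "no_contrastive" else 0.0
    beta = cfg.beta if cfg.ablation != "no_decoder" else 0.0
    gamma = cfg.gamma if cfg.ablation != "no_vgcn" else 0.0
    L = total_loss(L_c, L_r, L_kl, alpha=alpha, beta=beta, gamma=gamma)

    bundle = LossBundle(
        L_pos=float(ag.value(L_pos)), L_neg=float(ag.value(L_neg)),
        L_cos=float(ag.value(L_cos)), L_c=float(ag.value(L_c)),
        L_r=float(ag.value(L_r)), L_KL=float(ag.value(L_kl)),
        L_total=float(ag.value(L)), weights=(alpha, beta, gamma))
    return L, bundle


def train(fm: FeatureMatrix, graph: SpatialGraph, cfg: TrainConfig) -> TrainResult:
    """Jointly optimize all branches; returns parameters, loss history and the
    noise-free final embedding."""
    X = np.asarray(fm.X, dtype=np.float64)
    if graph.n_spots != X.shape[0]:
        raise ParameterError(
            f"graph has {graph.n_spots} spots but features have {X.shape[0]}")
    master = np.random.default_rng(cfg.seed)
    init_seed = int(master.integers(2**31))
    params = init_params(X.shape[1], widths=cfg.widths,
                         latent_dim=cfg.latent_dim, seed=init_seed)
    opt = Adam(params.all_params(), lr=cfg.lr)
    history: List[LossBundle] = []

    # wrap once; Adam updates .data in place
    Xc = X
    Anorm = graph.Anorm

    for epoch in range(cfg.epochs):
        opt.zero_grad()
        L, bundle = _forward_losses(Xc, Anorm, params, cfg, master)
        if not np.isfinite(bundle.L_total):
            raise NumericalInstabilityError(
                f"non-finite loss at epoch {epoch}: {bundle}")
        L.backward()
        if cfg.grad_clip is not None:
            for p in opt.params:
                if p.grad is not None:
                    np.clip(p.grad, -cfg.grad_clip, cfg.grad_clip, out=p.grad)
        opt.step()
        history.append(bundle)

    final_state = encode(X, Anorm, params, noise=None,
                         hidden_activation=cfg.hidden_activation,
                         variational=cfg.ablation != "no_vgcn")
    final_embedding = np.asarray(ag.value(final_state.H), dtype=np.float64)
    return TrainResult(params=params, history=history,
                       final_embedding=final_embedding, config=cfg)


def loss_history_frame(history: List[LossBundle]):
    """Loss history as a pandas DataFrame (one row per epoch)."""
    import pandas as pd
    return pd.DataFrame(
        [{"epoch": i, "L_pos": b.L_pos, "L_neg": b.L_neg, "L_cos": b.L_cos,
          "L_c": b.L_c, "L_r": b.L_r, "L_KL": b.L_KL, "L_total": b.L_total}
         for i, b in enumerate(history)])
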