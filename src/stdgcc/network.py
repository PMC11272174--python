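"""Forward computation of the variational graph-convolutional model.

Architecture (defaults in parentheses):

* a stack of graph-convolutional layers, widths F -> 1024 -> 512 -> 256,
  each computing ``Anorm @ E @ W + b`` with a shared learnable PReLU between
  hidden layers;
* a variational head: two parallel graph-convolutional layers map the last
  hidden representation to mu and log(sigma) (width 256 -> 128); sampling
  uses the reparameterization Z = mu + sigma * eps with eps ~ N(0, I), and
  the embedding is H = PReLU(Z);
* a fully-connected decoder symmetric to the encoder
  (128 -> 256 -> 512 -> 1024 -> F) reconstructing the feature matrix
  row-wise (no graph mixing);
* a global mean readout s and a bilinear discriminator
  D(h, s) = logistic(h^T W_D s) scoring node-vs-summary pairs.

log(sigma) rather than sigma is produced by the variational head so sigma is
positive by construction, and the discriminator's bilinear form is squashed
through a logistic so the contrastive log-losses are well defined.

All operations accept plain ndarrays (returning ndarrays) or autodiff
Tensors (extending the tape), so the same code serves training and
plain-array checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from . import _autograd as ag
from ._autograd import Tensor
from .errors import NumericalInstabilityError, ParameterError

ENCODER_WIDTHS = (1024, 512, 256)
LATENT_DIM = 128
PRELU_INIT = 0.25


@dataclass
class ModelParams:
    """All trainable parameters.

    Weight matrices use Glorot-uniform initialization, biases start at zero,
    the shared PReLU slope at 0.25.  ``params_of(branch)`` exposes the
    parameters exclusive to one branch (used to verify that ablated branches
    receive no updates).
    """

    gcn_weights: list          # [(W, b)] for the hidden GCN stack
    mu_head: tuple             # (W, b)
    logsigma_head: tuple       # (W, b)
    decoder_layers: list       # [(W, b)] widths latent -> ... -> F
    disc_bilinear: Tensor      # M x M
    prelu_slope: Tensor        # scalar, shared
    widths: tuple = ()
    latent_dim: int = LATENT_DIM
    n_features: int = 0

    def all_params(self) -> list:
        out = []
        for W, b in self.gcn_weights:
            out += [W, b]
        out += [*self.mu_head, *self.logsigma_head]
        for W, b in self.decoder_layers:
            out += [W, b]
        out += [self.disc_bilinear, self.prelu_slope]
        return out

    def params_of(self, branch: str) -> list:
        if branch == "sigma":
            return list(self.logsigma_head)
        if branch == "decoder":
            return [p for Wb in self.decoder_layers for p in Wb]
        if branch == "discriminator":
            return [self.disc_bilinear]
        raise ParameterError(f"unknown branch {branch!r}")


@dataclass
class LatentState:
    """Per-spot latent quantities from one encoder pass.

    ``sigma`` is None in the non-variational (plain GCN head) ablation, where
    Z = mu deterministically.
    """

    mu: object
    sigma: Optional[object]
    Z: object
    H: object
    H_bar: Optional[object] = None
    s: Optional[object] = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor.param(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


def init_params(n_features: int, widths: Sequence[int] = ENCODER_WIDTHS,
                latent_dim: int = LATENT_DIM, seed: int = 0) -> ModelParams:
    """Glorot-uniform weights, zero biases, PReLU slope 0.25."""
    rng = np.random.default_rng(seed)
    dims = [n_features, *widths]
    gcn = [( _glorot(rng, dims[k], dims[k + 1]),
             Tensor.param(np.zeros(dims[k + 1])) )
           for k in range(len(widths))]
    mu_head = (_glorot(rng, dims[-1], latent_dim),
               Tensor.param(np.zeros(latent_dim)))
    logsig_head = (_glorot(rng, dims[-1], latent_dim),
                   Tensor.param(np.zeros(latent_dim)))
    dec_dims = [latent_dim, *reversed(widths), n_features]
    dec = [( _glorot(rng, dec_dims[k], dec_dims[k + 1]),
             Tensor.param(np.zeros(dec_dims[k + 1])) )
           for k in range(len(dec_dims) - 1)]
    W_D = _glorot(rng, latent_dim, latent_dim)
    return ModelParams(gcn_weights=gcn, mu_head=mu_head,
                       logsigma_head=logsig_head, decoder_layers=dec,
                       disc_bilinear=W_D,
                       prelu_slope=Tensor.param(PRELU_INIT),
                       widths=tuple(widths), latent_dim=latent_dim,
                       n_features=n_features)


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------

def gcn_layer(E, Anorm, W, b):
    """One graph convolution: Anorm @ E @ W + b (no activation)."""
    d_in = ag.value(E).shape[1]
    if ag.value(W).shape[0] != d_in:
        raise ParameterError(
            f"gcn_layer: input width {d_in} does not match W rows "
            f"{ag.value(W).shape[0]}")
    AE = ag.spmm(sp.csr_matrix(Anorm), E) if sp.issparse(Anorm) else ag.matmul(Anorm, E)
    return ag.matmul(AE, W) + b


def encode(X, Anorm, params: ModelParams, noise=None,
           hidden_activation: str = "prelu",
           variational: bool = True) -> LatentState:
    """Encoder pass: GCN stack -> (mu, sigma) heads -> Z -> H = PReLU(Z).

    ``noise`` is an N x M array of standard-normal draws (or None for zeros,
    the deterministic mean pass).  With ``variational=False`` the sigma head
    is bypassed and Z = mu exactly.
    """
    E = X
    for k, (W, b) in enumerate(params.gcn_weights):
        E = gcn_layer(E, Anorm, W, b)
        if hidden_activation == "prelu":
            E = ag.prelu(E, params.prelu_slope)
        if not np.all(np.isfinite(ag.value(E))):
            raise NumericalInstabilityError(f"non-finite activations at GCN layer {k}")
    mu = gcn_layer(E, Anorm, *params.mu_head)
    if variational:
        logsig = gcn_layer(E, Anorm, *params.logsigma_head)
        sigma = ag.exp(logsig)
        if noise is None:
            Z = mu
        else:
            Z = mu + sigma * np.asarray(noise, dtype=float)
    else:
        sigma, Z = None, mu
    H = ag.prelu(Z, params.prelu_slope)
    return LatentState(mu=mu, sigma=sigma, Z=Z, H=H)


def decode(H, params: ModelParams, hidden_activation: str = "prelu"):
    """Row-wise fully-connected decoder reconstructing the feature matrix."""
    if ag.value(H).shape[1] != params.latent_dim:
        raise ParameterError(
            f"decode: embedding width {ag.value(H).shape[1]} != latent dim "
            f"{params.latent_dim}")
    E = H
    last = len(params.decoder_layers) - 1
    for k, (W, b) in enumerate(params.decoder_layers):
        E = ag.matmul(E, W) + b
        if k < last and hidden_activation == "prelu":
            E = ag.prelu(E, params.prelu_slope)
    return E


def readout(H):
    """Global summary s: the column-wise mean of the node embeddings."""
    return ag.mean(H, axis=0, keepdims=True)


def discriminate(h, s, W_D):
    """Bilinear pair score logistic(h^T W_D s), strictly inside (0, 1).

    For single plain vectors returns a float; for an N x M matrix of
    embeddings returns one score per row.
    """
    scalar = (not isinstance(h, Tensor)) and np.asarray(h).ndim == 1
    out = ag.sigmoid(discriminate_logits(h, s, W_D))
    return float(ag.value(out)[0]) if scalar else out


def discriminate_logits(H, s, W_D):
    """Bilinear form h_i^T W_D s for each row of H (pre-logistic)."""
    if not isinstance(H, Tensor) and np.asarray(H).ndim == 1:
        H = np.asarray(H, dtype=float).reshape(1, -1)
    Hm = ag.matmul(H, W_D)
    s_row = s if isinstance(s, Tensor) else np.asarray(s, dtype=float).reshape(1, -1)
    return ag.sum_(Hm * s_row, axis=1)
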