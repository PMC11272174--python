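"""Loss terms: KL regularizer, reconstruction, contrastive, weighted total.

* KL loss pulls the variational posterior N(mu_i, diag(sigma_i^2)) toward the
  standard-normal prior:
  L_KL = (1/N) * (1/2) * sum_ij (-log sigma_ij^2 + mu_ij^2 + sigma_ij^2 - 1).
* Reconstruction loss L_r = (1/N) * sum_ij (X_ij - Xtilde_ij)^2.
* Contrastive loss (Deep-Graph-Infomax style):
  L_pos = -(1/N) sum_i log D(h_i, s),
  L_neg = -(1/N) sum_i log(1 - D(hbar_i, s)),
  L_cos = -(1/N) sum_i log(1 - cos(h_i, hbar_i)),
  L_c   = L_pos + L_neg + L_cos.
  The cosine term, minimized as cos -> -1, pushes each corrupted embedding
  away from its clean counterpart; cos is clamped to <= 1 - 1e-7 before the
  log so identical pairs yield a large finite penalty, and zero-norm vectors
  define cos = 0.
* Total: L = alpha * L_c + beta * L_r + gamma * L_KL
  with defaults (alpha, beta, gamma) = (2.0, 0.05, 0.005).

The positive/negative log-discriminator terms are evaluated from the
bilinear logits via stable log-sigmoid forms (identical values, no underflow
at extreme logits).

All functions follow the dispatch convention of :mod:`stdgcc._autograd`:
plain arrays in, floats out; Tensors in, tape-extending Tensor out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .errors import ParameterError, ValidationError
from .network import discriminate_logits

COS_CLAMP = 1.0 - 1e-7
_NORM_EPS = 1e-12

ALPHA_DEFAULT = 2.0
BETA_DEFAULT = 0.05
GAMMA_DEFAULT = 0.005


@dataclass
class LossBundle:
    """All loss components of one training step, as plain floats."""

    L_pos: float
    L_neg: float
    L_cos: float
    L_c: float
    L_r: float
    L_KL: float
    L_total: float
    weights: Tuple[float, float, float] = (ALPHA_DEFAULT, BETA_DEFAULT,
                                           GAMMA_DEFAULT)


def _maybe_float(x):
    return float(ag.value(x)) if not isinstance(x, Tensor) else x


def kl_loss(mu, sigma):
    """KL divergence of N(mu, diag(sigma^2)) from N(0, I), averaged over spots."""
    sig_val = ag.value(sigma)
    if np.any(sig_val <= 0):
        raise ValidationError("sigma must be strictly positive")
    n = ag.value(mu).shape[0]
    term = -ag.log(sigma * sigma) + mu * mu + sigma * sigma - 1.0
    return _maybe_float(ag.sum_(term) * (0.5 / n))


def kl_loss_from_logsigma(mu, logsigma):
    """KL loss parameterized by log(sigma); avoids exp/log round trips."""
    n = ag.value(mu).shape[0]
    term = -2.0 * logsigma + mu * mu + ag.exp(2.0 * logsigma) - 1.0
    return _maybe_float(ag.sum_(term) * (0.5 / n))


def reconstruction_loss(X, X_tilde):
    """Mean-per-spot squared reconstruction error (1/N) * ||X - Xtilde||_F^2."""
    if ag.value(X).shape != ag.value(X_tilde).shape:
        raise ValidationError(
            f"shape mismatch {ag.value(X).shape} vs {ag.value(X_tilde).shape}")
    n = ag.value(X).shape[0]
    diff = X - X_tilde
    return _maybe_float(ag.sum_(diff * diff) * (1.0 / n))


def _row_cosine(H, H_bar):
    dot = ag.sum_(H * H_bar, axis=1)
    nh = ag.sqrt(ag.sum_(H * H, axis=1))
    nb = ag.sqrt(ag.sum_(H_bar * H_bar, axis=1))
    if isinstance(dot, Tensor):
        return dot / (nh * nb + _NORM_EPS)
    denom = nh * nb
    out = np.zeros_like(dot)
    nz = denom > 0
    out[nz] = dot[nz] / denom[nz]
    return out


def contrastive_loss(H, H_bar, s, W_D):
    """Positive, negative and cosine-separation terms and their sum L_c."""
    n = ag.value(H).shape[0]
    pos_logits = discriminate_logits(H, s, W_D)
    neg_logits = discriminate_logits(H_bar, s, W_D)
    L_pos = -ag.mean(ag.log_sigmoid(pos_logits))
    L_neg = -ag.mean(ag.log1m_sigmoid(neg_logits))
    cos = ag.clip_max(_row_cosine(H, H_bar), COS_CLAMP)
    L_cos = -ag.mean(ag.log(1.0 - cos))
    L_c = L_pos + L_neg + L_cos
    return (_maybe_float(L_pos), _maybe_float(L_neg),
            _maybe_float(L_cos), _maybe_float(L_c))


def total_loss(L_c, L_r, L_KL, alpha: float = ALPHA_DEFAULT,
               beta: float = BETA_DEFAULT, gamma: float = GAMMA_DEFAULT):
    """Weighted joint objective alpha*L_c + beta*L_r + gamma*L_KL."""
    if alpha < 0 or beta < 0 or gamma < 0:
        raise ParameterError("loss weights must be non-negative")
    return _maybe_float(alpha * L_c + beta * L_r + gamma * L_KL)
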