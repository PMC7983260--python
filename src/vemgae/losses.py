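"""Loss terms for the dual-autoencoder objective.

All losses are summed (not averaged), following the Frobenius-norm /
elementwise-sum forms of the objective; the learning rate absorbs scale.
Each function accepts NumPy arrays or autodiff tensors and returns a
scalar tensor (use ``float(...)`` for the value); gradients flow through
tensor inputs.

The label/feature cross-entropies are full binary cross-entropies: a
positive-term-only form would be globally minimised by the trivial
all-ones output, so the (1 - X) log(1 - X') term is required for a
well-posed objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor

__all__ = [
    "LossWeights",
    "gaussian_recon_loss",
    "bernoulli_recon_loss",
    "kl_loss",
    "manifold_loss",
    "cotrain_loss",
    "total_q_loss",
    "total_p_loss",
]

_CLAMP = 1e-10  # guards logs against exact 0/1 decoder outputs


@dataclass(frozen=True)
class LossWeights:
    """alpha balances the two spaces; beta and gamma weight the couplings."""

    alpha: float = 0.5
    beta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be nonnegative")


def _pair(x, y, name: str) -> tuple[Tensor, Tensor]:
    xt, yt = T.as_tensor(x), T.as_tensor(y)
    if xt.shape != yt.shape:
        raise ValueError(f"{name}: shape mismatch {xt.shape} vs {yt.shape}")
    return xt, yt


def gaussian_recon_loss(X, X_prime) -> Tensor:
    """Squared-error reconstruction: (1/2) ||X - X'||_F^2."""
    xt, yt = _pair(X, X_prime, "gaussian_recon_loss")
    return 0.5 * T.tsum(T.square(xt - yt))


def bernoulli_recon_loss(X, X_prime) -> Tensor:
    """Full binary cross-entropy between binary X and X' in (0, 1)."""
    xt, yt = _pair(X, X_prime, "bernoulli_recon_loss")
    if not np.isin(xt.data, (0.0, 1.0)).all():
        raise ValueError("bernoulli_recon_loss: X must be binary")
    if ((yt.data < 0) | (yt.data > 1)).any():
        raise ValueError("bernoulli_recon_loss: X' must lie in [0, 1]")
    p = T.clip(yt, _CLAMP, 1.0 - _CLAMP)
    ones = Tensor(np.ones(xt.shape))
    return -T.tsum(T.mul(xt, T.log(p)) + T.mul(ones - xt, T.log(ones - p)))


def kl_loss(mu, sigma) -> Tensor:
    """KL divergence of N(mu, sigma^2) from N(0, 1), summed elementwise.

    -(1/2) sum(1 + 2 log sigma - mu^2 - sigma^2).
    """
    mt, st = _pair(mu, sigma, "kl_loss")
    if (st.data <= 0).any():
        raise ValueError("kl_loss: sigma must be positive")
    ones = Tensor(np.ones(mt.shape))
    inner = ones + 2.0 * T.log(st) - T.square(mt) - T.square(st)
    return -0.5 * T.tsum(inner)


def manifold_loss(Z, Z_prime) -> Tensor:
    """Representation agreement between the two autoencoders:
    (1/2) ||Z - Z'||_F^2."""
    zt, zp = _pair(Z, Z_prime, "manifold_loss")
    return 0.5 * T.tsum(T.square(zt - zp))


def cotrain_loss(Z_l, Z_d, Y) -> Tensor:
    """Cross-space coupling through the labels: (1/2) ||Z_l Z_d^T - Y||_F^2."""
    zl, zd = T.as_tensor(Z_l), T.as_tensor(Z_d)
    yt = T.as_tensor(Y.values if hasattr(Y, "values") else Y)
    if zl.shape[1] != zd.shape[1]:
        raise ValueError("cotrain_loss: representation widths differ")
    if (zl.shape[0], zd.shape[0]) != yt.shape:
        raise ValueError("cotrain_loss: product shape does not match Y")
    return 0.5 * T.tsum(T.square(zl @ zd.T - yt))


def total_q_loss(loss_ql, loss_qd, L_c, weights: LossWeights) -> Tensor:
    """alpha * L_ql + (1 - alpha) * L_qd + beta * L_c."""
    return (
        weights.alpha * T.as_tensor(loss_ql)
        + (1.0 - weights.alpha) * T.as_tensor(loss_qd)
        + weights.beta * T.as_tensor(L_c)
    )


def total_p_loss(loss_pl, loss_pd, weights: LossWeights) -> Tensor:
    """alpha * L_pl + (1 - alpha) * L_pd."""
    return weights.alpha * T.as_tensor(loss_pl) + (1.0 - weights.alpha) * T.as_tensor(loss_pd)
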