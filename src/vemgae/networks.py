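"""The two graph autoencoders.

``GnnQ`` is a variational graph autoencoder: a shared graph-convolutional
encoder feeds parallel mu / log-sigma heads, a node representation Z is
sampled with the reparameterization trick, and a two-layer decoder
reconstructs the feature matrix through a sigmoid (features live in the
unit interval).

``GnnP`` is a plain graph autoencoder that takes the label matrix as node
features and emits a sigmoid-bounded prediction of the same shape, so it
acts as a trainable label-propagation operator on the same graph.

Every layer is a graph convolution H' = rho(A_hat H W) where A_hat is the
symmetrically normalised adjacency with self-loops.  Hidden width is 256
throughout; dropout 0.5 is applied to hidden activations during training
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .graph import KnnGraph

__all__ = ["GcnLayer", "EncoderOutput", "GnnQ", "GnnP", "reparameterize",
           "gcn_forward", "gnnq_forward", "gnnp_forward"]

_ACTIVATIONS = ("relu", "sigmoid", "linear")


def glorot_uniform(rng: np.random.Generator, d_in: int, d_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return Tensor(rng.uniform(-limit, limit, size=(d_in, d_out)), requires_grad=True)


@dataclass
class GcnLayer:
    """One graph-convolutional layer: rho(A_hat @ H @ weight)."""

    weight: Tensor
    activation: str = "relu"

    def __post_init__(self):
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def d_in(self) -> int:
        return self.weight.shape[0]

    @property
    def d_out(self) -> int:
        return self.weight.shape[1]


def gcn_forward(layer: GcnLayer, normalized_adjacency, H_prev) -> Tensor:
    """Apply one graph convolution; accepts ndarrays or Tensors."""
    A = T.as_tensor(normalized_adjacency)
    H = T.as_tensor(H_prev)
    if H.shape[1] != layer.d_in:
        raise ValueError(
            f"layer expects {layer.d_in} input features, got {H.shape[1]}"
        )
    if A.shape[1] != H.shape[0]:
        raise ValueError("adjacency and feature row counts disagree")
    out = (A @ H) @ layer.weight
    if layer.activation == "relu":
        return T.relu(out)
    if layer.activation == "sigmoid":
        return T.sigmoid(out)
    return out


@dataclass
class EncoderOutput:
    """Variational encoder output: posterior mean, sd and sampled Z."""

    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        if not (self.mu.shape == self.sigma.shape == self.z.shape):
            raise ValueError("mu, sigma, z shapes must agree")
        if (np.asarray(self.sigma) <= 0).any():
            raise ValueError("sigma must be positive")


def reparameterize(mu, sigma, rng: np.random.Generator | None):
    """Z = mu + sigma * eps with eps ~ N(0, I); eps = 0 when rng is None."""
    mu_t, sig_t = T.as_tensor(mu), T.as_tensor(sigma)
    if mu_t.shape != sig_t.shape:
        raise ValueError("mu and sigma shapes must agree")
    if (sig_t.data <= 0).any():
        raise ValueError("sigma must be positive")
    if rng is None:
        return mu_t
    eps = Tensor(rng.standard_normal(mu_t.shape))
    return mu_t + T.mul(sig_t, eps)


class GnnQ:
    """Variational graph autoencoder for feature inference."""

    def __init__(self, d_in: int, hidden_dim: int = 256, dropout: float = 0.5,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.hidden_dim = hidden_dim
        self.dropout = dropout
        self.encoder = GcnLayer(glorot_uniform(rng, d_in, hidden_dim), "relu")
        self.mu_head = GcnLayer(glorot_uniform(rng, hidden_dim, hidden_dim), "linear")
        self.logsigma_head = GcnLayer(glorot_uniform(rng, hidden_dim, hidden_dim), "linear")
        self.decoder1 = GcnLayer(glorot_uniform(rng, hidden_dim, hidden_dim), "relu")
        self.decoder2 = GcnLayer(glorot_uniform(rng, hidden_dim, d_in), "sigmoid")

    def parameters(self) -> list[Tensor]:
        return [l.weight for l in
                (self.encoder, self.mu_head, self.logsigma_head, self.decoder1, self.decoder2)]


class GnnP:
    """Plain graph autoencoder for label propagation."""

    def __init__(self, n_labels: int, hidden_dim: int = 256, dropout: float = 0.5,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.hidden_dim = hidden_dim
        self.dropout = dropout
        self.encoder = GcnLayer(glorot_uniform(rng, n_labels, hidden_dim), "relu")
        self.decoder = GcnLayer(glorot_uniform(rng, hidden_dim, n_labels), "sigmoid")

    def parameters(self) -> list[Tensor]:
        return [self.encoder.weight, self.decoder.weight]


def gnnq_forward(model: GnnQ, graph: KnnGraph, X, rng: np.random.Generator | None,
                 return_tensors: bool = False):
    """Forward pass of the variational autoencoder.

    ``rng`` drives both the reparameterization noise and dropout; passing
    None selects eval mode (eps = 0, dropout off), which is deterministic.
    """
    X_t = T.as_tensor(X.values if hasattr(X, "values") else X)
    A = graph.normalized_adjacency
    if X_t.shape[0] != A.shape[0]:
        raise ValueError(
            f"feature rows ({X_t.shape[0]}) do not match graph nodes ({A.shape[0]})"
        )
    h = gcn_forward(model.encoder, A, X_t)
    h = T.dropout(h, model.dropout, rng)
    mu = gcn_forward(model.mu_head, A, h)
    logsigma = gcn_forward(model.logsigma_head, A, h)
    sigma = T.exp(logsigma)
    z = reparameterize(mu, sigma, rng)
    d = gcn_forward(model.decoder1, A, z)
    d = T.dropout(d, model.dropout, rng)
    x_prime = gcn_forward(model.decoder2, A, d)
    if return_tensors:
        return mu, sigma, z, x_prime
    return EncoderOutput(mu.data, sigma.data, z.data), x_prime.data


def gnnp_forward(model: GnnP, graph: KnnGraph, Y_in, rng: np.random.Generator | None = None,
                 return_tensors: bool = False):
    """Forward pass of the label-propagation autoencoder.

    ``Y_in`` is the label matrix seen from this graph's side (Y for the
    lncRNA graph, Y^T for the disease graph).
    """
    Y_t = T.as_tensor(Y_in.values if hasattr(Y_in, "values") else Y_in)
    A = graph.normalized_adjacency
    if Y_t.shape[0] != A.shape[0]:
        raise ValueError(
            f"label rows ({Y_t.shape[0]}) do not match graph nodes ({A.shape[0]})"
        )
    z_prime = gcn_forward(model.encoder, A, Y_t)
    z_prime = T.dropout(z_prime, model.dropout, rng)
    f = gcn_forward(model.decoder, A, z_prime)
    if return_tensors:
        return z_prime, f
    return z_prime.data, f.data
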