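"""Alternating variational-EM training of the two autoencoder pairs.

Each epoch runs one E-step and one M-step:

* E-step — the label networks are frozen; the two variational
  autoencoders (lncRNA space and disease space) take a joint Adam step on
  reconstruction + KL + the co-training coupling through the labels.
* M-step — the variational networks are frozen; the two label-propagation
  autoencoders take a joint Adam step on label cross-entropy + the
  manifold coupling to the (deterministic, posterior-mean) representations
  of the just-updated variational networks.

The coupling weights ramp linearly, beta = gamma = e / e_n, so early
epochs let each network find its own footing before the couplings bind
them together.  After e_n epochs the two per-space predictions are fused,
F = alpha * F_l + (1 - alpha) * F_d^T, and min-max rescaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _tensor as T
from ._optim import Adam
from .data_io import AssociationMatrix, FeatureMatrix, rescale_features_unit_interval
from .graph import KnnGraph, build_knn_graph
from .losses import (
    LossWeights,
    bernoulli_recon_loss,
    cotrain_loss,
    gaussian_recon_loss,
    kl_loss,
    manifold_loss,
    total_p_loss,
    total_q_loss,
)
from .networks import GnnP, GnnQ, gnnp_forward, gnnq_forward

__all__ = ["TrainConfig", "ScoreMatrix", "EmFitResult", "schedule_beta_gamma",
           "em_fit", "fuse_and_rescale"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the alternating training run (defaults are the
    reference settings: alpha 0.5, 500 epochs, Adam lr 0.01 with weight
    decay 1e-5, dropout 0.5, hidden width 256, 10-NN graphs)."""

    alpha: float = 0.5
    epochs: int = 500
    learning_rate: float = 0.01
    weight_decay: float = 1e-5
    dropout: float = 0.5
    hidden_dim: int = 256
    knn_k: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if min(self.epochs, self.hidden_dim, self.knn_k) < 1:
            raise ValueError("epochs, hidden_dim and knn_k must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimizer settings")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScoreMatrix:
    """A prediction matrix with its provenance (which space produced it)."""

    values: np.ndarray
    provenance: str = "fused"  # lncrna_space | disease_space | fused


def schedule_beta_gamma(e: int, e_n: int) -> tuple[float, float]:
    """Coupling-weight ramp: beta = gamma = e / e_n at epoch e (1-based)."""
    if not 1 <= e <= e_n:
        raise ValueError(f"epoch {e} outside 1..{e_n}")
    w = e / e_n
    return w, w


def fuse_and_rescale(F_l, F_d, alpha: float) -> ScoreMatrix:
    """F = alpha * F_l + (1 - alpha) * F_d^T, then min-max rescaled to [0, 1].

    Both per-space predictions are low-rank (each passed through a narrow
    autoencoder bottleneck), and by the rank-sum inequality so is their
    combination.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    Fl = F_l.values if isinstance(F_l, ScoreMatrix) else np.asarray(F_l, float)
    Fd = F_d.values if isinstance(F_d, ScoreMatrix) else np.asarray(F_d, float)
    if Fl.shape != Fd.T.shape:
        raise ValueError(f"incompatible shapes {Fl.shape} and {Fd.shape}")
    fused = alpha * Fl + (1.0 - alpha) * Fd.T
    lo, hi = fused.min(), fused.max()
    if hi == lo:
        warnings.warn("constant fused score matrix; rescaled to all zeros")
        return ScoreMatrix(np.zeros_like(fused), "fused")
    return ScoreMatrix((fused - lo) / (hi - lo), "fused")


@dataclass
class EmFitResult:
    gnnq_l: GnnQ
    gnnq_d: GnnQ
    gnnp_l: GnnP
    gnnp_d: GnnP
    graph_l: KnnGraph
    graph_d: KnnGraph
    scores: ScoreMatrix           # fused, rescaled
    scores_l: ScoreMatrix         # raw lncRNA-space prediction (m x n)
    scores_d: ScoreMatrix         # raw disease-space prediction (n x m)
    fused_pre_rescale: np.ndarray
    log: list[dict] = field(default_factory=list)


def _encode_mu(model: GnnQ, graph: KnnGraph, X: np.ndarray) -> np.ndarray:
    """Posterior mean of the variational encoder in eval mode (plain NumPy)."""
    A = graph.normalized_adjacency
    h = np.maximum(A @ (X @ model.encoder.weight.data), 0.0)
    return A @ (h @ model.mu_head.weight.data)


def _prepare_features(X_l: FeatureMatrix, X_d: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    if X_l.noise_family != "gaussian":
        raise ValueError("row-entity features must be gaussian (continuous)")
    if X_d.noise_family != "bernoulli":
        raise ValueError("column-entity features must be bernoulli (binary)")
    X_l = rescale_features_unit_interval(X_l)
    return X_l.values, X_d.values


def em_fit(
    Y: AssociationMatrix,
    X_l: FeatureMatrix,
    X_d: FeatureMatrix,
    config: TrainConfig = TrainConfig(),
    beta_gamma_override: float | None = None,
    spaces: tuple[str, ...] = ("l", "d"),
    on_step=None,
) -> EmFitResult:
    """Train the four networks by alternating E and M steps.

    ``beta_gamma_override`` pins both coupling weights to a constant
    (0 decouples the spaces entirely); ``spaces`` restricts training to
    one side for diagnostic runs; ``on_step(stage, epoch, models)`` is
    called after every E- and M-step with stage "E" or "M" and the four
    networks, for inspection.  Deterministic given ``config.seed``.
    """
    m, n = Y.shape
    if X_l.shape[0] != m or X_d.shape[0] != n:
        raise ValueError(
            f"feature node counts ({X_l.shape[0]}, {X_d.shape[0]}) "
            f"do not match Y shape {Y.shape}"
        )
    use_l, use_d = "l" in spaces, "d" in spaces
    if not (use_l or use_d):
        raise ValueError("at least one space must be trained")
    both = use_l and use_d

    Xl_vals, Xd_vals = _prepare_features(X_l, X_d)
    graph_l = build_knn_graph(Xl_vals, config.knn_k)
    graph_d = build_knn_graph(Xd_vals, config.knn_k)
    Y_vals = Y.values
    Yt_vals = Y_vals.T

    # independent, reproducible streams per network so that the two spaces
    # consume randomness independently (decoupled runs replay exactly)
    ss = np.random.SeedSequence(config.seed)
    keys = ["init_ql", "init_qd", "init_pl", "init_pd",
            "train_ql", "train_qd", "train_pl", "train_pd"]
    streams = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))

    kw = dict(hidden_dim=config.hidden_dim, dropout=config.dropout)
    gnnq_l = GnnQ(Xl_vals.shape[1], rng=streams["init_ql"], **kw)
    gnnq_d = GnnQ(Xd_vals.shape[1], rng=streams["init_qd"], **kw)
    gnnp_l = GnnP(n, rng=streams["init_pl"], **kw)
    gnnp_d = GnnP(m, rng=streams["init_pd"], **kw)

    q_params = (gnnq_l.parameters() if use_l else []) + (gnnq_d.parameters() if use_d else [])
    p_params = (gnnp_l.parameters() if use_l else []) + (gnnp_d.parameters() if use_d else [])
    opt_q = Adam(q_params, lr=config.learning_rate, weight_decay=config.weight_decay)
    opt_p = Adam(p_params, lr=config.learning_rate, weight_decay=config.weight_decay)

    log: list[dict] = []
    zero = T.Tensor(0.0)
    for e in range(1, config.epochs + 1):
        if beta_gamma_override is None:
            beta, gamma = schedule_beta_gamma(e, config.epochs)
        else:
            beta = gamma = float(beta_gamma_override)
        weights = LossWeights(config.alpha, beta, gamma)

        # ---- E-step: update variational nets, label nets untouched ----
        opt_q.zero_grad()
        L_ql = L_qd = zero
        z_l = z_d = None
        if use_l:
            mu, sig, z_l, xp = gnnq_forward(gnnq_l, graph_l, Xl_vals,
                                            streams["train_ql"], return_tensors=True)
            L_ql = gaussian_recon_loss(Xl_vals, xp) + kl_loss(mu, sig)
        if use_d:
            mu, sig, z_d, xp = gnnq_forward(gnnq_d, graph_d, Xd_vals,
                                            streams["train_qd"], return_tensors=True)
            L_qd = bernoulli_recon_loss(Xd_vals, xp) + kl_loss(mu, sig)
        L_c = cotrain_loss(z_l, z_d, Y_vals) if both and beta > 0 else zero
        L_q = total_q_loss(L_ql, L_qd, L_c, weights)
        if not np.isfinite(float(L_q)):
            raise FloatingPointError(f"non-finite E-step loss at epoch {e}")
        L_q.backward()
        opt_q.step()
        if on_step is not None:
            on_step("E", e, (gnnq_l, gnnq_d, gnnp_l, gnnp_d))

        # ---- M-step: update label nets against frozen posterior means ----
        opt_p.zero_grad()
        L_pl = L_pd = zero
        if use_l:
            z_target = _encode_mu(gnnq_l, graph_l, Xl_vals)
            zp, f = gnnp_forward(gnnp_l, graph_l, Y_vals,
                                 streams["train_pl"], return_tensors=True)
            L_pl = bernoulli_recon_loss(Y_vals, f) + gamma * manifold_loss(z_target, zp)
        if use_d:
            z_target = _encode_mu(gnnq_d, graph_d, Xd_vals)
            zp, f = gnnp_forward(gnnp_d, graph_d, Yt_vals,
                                 streams["train_pd"], return_tensors=True)
            L_pd = bernoulli_recon_loss(Yt_vals, f) + gamma * manifold_loss(z_target, zp)
        L_p = total_p_loss(L_pl, L_pd, weights)
        if not np.isfinite(float(L_p)):
            raise FloatingPointError(f"non-finite M-step loss at epoch {e}")
        L_p.backward()
        opt_p.step()
        if on_step is not None:
            on_step("M", e, (gnnq_l, gnnq_d, gnnp_l, gnnp_d))

        log.append({"epoch": e, "L_ql": float(L_ql), "L_qd": float(L_qd),
                    "L_c": float(L_c), "L_pl": float(L_pl), "L_pd": float(L_pd),
                    "beta": beta, "gamma": gamma})

    # final predictions in eval mode
    _, F_l = gnnp_forward(gnnp_l, graph_l, Y_vals, rng=None)
    _, F_d = gnnp_forward(gnnp_d, graph_d, Yt_vals, rng=None)
    fused_pre = config.alpha * F_l + (1.0 - config.alpha) * F_d.T
    fused = fuse_and_rescale(F_l, F_d, config.alpha)
    return EmFitResult(
        gnnq_l, gnnq_d, gnnp_l, gnnp_d, graph_l, graph_d,
        fused, ScoreMatrix(F_l, "lncrna_space"), ScoreMatrix(F_d, "disease_space"),
        fused_pre, log,
    )


def write_training_log(log: list[dict], path) -> None:
    cols = ["epoch", "L_ql", "L_qd", "L_c", "L_pl", "L_pd", "beta", "gamma"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in log:
            fh.write("\t".join(f"{row[c]:.6g}" if c != "epoch" else str(row[c])
                               for c in cols) + "\n")
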