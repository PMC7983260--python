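"""Mutual k-nearest-neighbour graphs over feature vectors.

Node similarity only needs to be estimated roughly for label propagation
to work, so the graph is a plain Euclidean k-NN selection made symmetric
by the mutual rule: an edge exists iff each node selects the other.
Self-loops are added and the adjacency is symmetrically degree-normalised
for use inside graph-convolutional layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import DataValidationError, FeatureMatrix

__all__ = ["KnnGraph", "knn_selection", "mutual_adjacency", "normalize_adjacency", "build_knn_graph"]


@dataclass
class KnnGraph:
    """Adjacency-with-self-loops and its symmetric normalisation."""

    adjacency_with_self_loops: np.ndarray  # A~ = C^T o C + I
    normalized_adjacency: np.ndarray       # D~^{-1/2} A~ D~^{-1/2}
    k: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency_with_self_loops.shape[0]


def knn_selection(features: FeatureMatrix | np.ndarray, k: int = 10) -> np.ndarray:
    """Selection matrix C: C[i, j] = 1 iff j is among i's k nearest nodes.

    Euclidean metric on feature rows; self is excluded by index; distance
    ties are broken by ascending node index for reproducibility.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    p = X.shape[0]
    if not 1 <= k < p:
        raise DataValidationError(f"need 1 <= k < n_nodes, got k={k}, n_nodes={p}")
    C = np.zeros((p, p))
    for i in range(p):
        # squared distances: sqrt is monotone so the selection is the same,
        # and exact ties stay exact for a stable index tie-break
        d2 = ((X - X[i]) ** 2).sum(axis=1)
        d2[i] = np.inf
        nearest = np.argsort(d2, kind="stable")[:k]
        C[i, nearest] = 1.0
    return C


def mutual_adjacency(C: np.ndarray) -> np.ndarray:
    """A~ = C^T o C + I: edge iff mutually selected, plus self-loops."""
    C = np.asarray(C, dtype=np.float64)
    if np.diagonal(C).any():
        raise DataValidationError("selection matrix must have zero diagonal")
    return C.T * C + np.eye(C.shape[0])


def normalize_adjacency(A_tilde: np.ndarray) -> np.ndarray:
    """Symmetric normalisation D~^{-1/2} A~ D~^{-1/2}."""
    A_tilde = np.asarray(A_tilde, dtype=np.float64)
    if (A_tilde < 0).any():
        raise DataValidationError("adjacency must be nonnegative")
    deg = A_tilde.sum(axis=1)
    if (deg <= 0).any():
        raise DataValidationError("zero row-sum in adjacency (missing self-loop?)")
    d = 1.0 / np.sqrt(deg)
    return A_tilde * d[:, None] * d[None, :]


def build_knn_graph(features: FeatureMatrix | np.ndarray, k: int = 10) -> KnnGraph:
    """Full pipeline: k-NN selection -> mutual adjacency -> normalisation."""
    C = knn_selection(features, k)
    A = mutual_adjacency(C)
    return KnnGraph(A, normalize_adjacency(A), k)


def export_edge_list(graph: KnnGraph, path) -> None:
    """Write non-self-loop edges (i < j) as a two-column TSV."""
    A = graph.adjacency_with_self_loops
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\n")
        for i, j in zip(*np.nonzero(np.triu(A, 1))):
            fh.write(f"{i}\t{j}\n")
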