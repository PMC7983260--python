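"""Skip-gram embeddings of k-mer tokens with negative sampling.

A compact word2vec-style trainer specialised to the tiny vocabularies of
nucleotide k-mers (4^k tokens).  Training is fully deterministic given
the seed; the corpus is canonicalised (sequences sorted) so the learned
vectors do not depend on input record order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["clean_kmers", "train_kmer_skipgram"]

_VALID = frozenset("ACGT")


def clean_kmers(sequence: str, k: int) -> list[str]:
    """Overlapping k-mers (stride 1) after uppercasing and U->T mapping.

    k-mers containing any character outside ACGT are dropped.
    """
    s = sequence.upper().replace("U", "T")
    out = []
    for i in range(len(s) - k + 1):
        km = s[i : i + k]
        if set(km) <= _VALID:
            out.append(km)
    return out


def train_kmer_skipgram(
    kmer_lists: list[list[str]],
    dim: int = 300,
    window: int = 5,
    seed: int = 0,
    epochs: int = 5,
    negatives: int = 5,
    lr: float = 0.025,
) -> dict[str, np.ndarray]:
    """Train skip-gram vectors over a corpus of k-mer token lists.

    Returns a mapping k-mer -> dim-vector (the input embeddings).  The
    corpus is sorted before training so the SGD trajectory, and hence
    the vectors, are independent of the order of ``kmer_lists``.
    """
    corpus = sorted(kmer_lists)
    vocab = sorted({km for kmers in corpus for km in kmers})
    index = {km: i for i, km in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(seed)

    w_in = (rng.random((V, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))

    # unigram^0.75 negative-sampling table
    counts = np.zeros(V)
    for kmers in corpus:
        for km in kmers:
            counts[index[km]] += 1
    noise = counts ** 0.75
    noise /= noise.sum()

    # collect (center, context) pairs once; windows are symmetric
    centers, contexts = [], []
    for kmers in corpus:
        idx = np.array([index[km] for km in kmers])
        L = len(idx)
        for pos in range(L):
            lo, hi = max(0, pos - window), min(L, pos + window + 1)
            for cpos in range(lo, hi):
                if cpos != pos:
                    centers.append(idx[pos])
                    contexts.append(idx[cpos])
    centers = np.array(centers, dtype=np.int64)
    contexts = np.array(contexts, dtype=np.int64)
    n_pairs = len(centers)
    if n_pairs == 0:  # single k-mer corpus: nothing to contrast
        return {km: w_in[index[km]].copy() for km in vocab}

    total_steps = epochs * n_pairs
    step = 0
    batch = 512
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            sel = order[start : start + batch]
            b = len(sel)
            cur_lr = max(lr * (1.0 - step / total_steps), lr * 1e-3)
            step += b
            c_idx = centers[sel]
            # targets: 1 positive + `negatives` noise draws per pair
            neg = rng.choice(V, size=(b, negatives), p=noise)
            t_idx = np.concatenate([contexts[sel][:, None], neg], axis=1)
            labels = np.zeros((b, 1 + negatives))
            labels[:, 0] = 1.0
            vc = w_in[c_idx]                          # b x dim
            vt = w_out[t_idx]                         # b x (1+neg) x dim
            logits = np.einsum("bd,bnd->bn", vc, vt)
            p = 1.0 / (1.0 + np.exp(-logits))
            g = (p - labels) * cur_lr                 # b x (1+neg)
            grad_c = np.einsum("bn,bnd->bd", g, vt)
            grad_t = g[:, :, None] * vc[:, None, :]
            np.add.at(w_in, c_idx, -grad_c)
            np.add.at(w_out, t_idx.ravel(), -grad_t.reshape(-1, vt.shape[-1]))

    return {km: w_in[index[km]].copy() for km in vocab}
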