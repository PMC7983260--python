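"""Readers, writers and feature construction for association-prediction inputs.

Three kinds of input are supported: a binary lncRNA x disease association
table, continuous lncRNA features (either a precomputed numeric table or
k-mer embeddings computed from FASTA sequences), and binary disease x gene
feature tables.  Tables are TSV or CSV with one header row of column ids
and a leading column of row ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AssociationMatrix",
    "FeatureMatrix",
    "SequenceRecord",
    "read_association_matrix",
    "write_association_matrix",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_fasta",
    "embed_sequences",
    "read_gene_feature_table",
    "drop_empty_gene_columns",
    "rescale_features_unit_interval",
    "write_predictions",
]


class DataValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class AssociationMatrix:
    """Binary association matrix Y with row (lncRNA) and column (disease) ids.

    ``values[i, j] == 1`` records a known association between row entity i
    and column entity j; 0 means unknown, not negative.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataValidationError("association matrix must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise DataValidationError("id lists do not match matrix shape")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise DataValidationError("association entries must be 0 or 1")
        if self.values.sum() == 0:
            raise DataValidationError("no known associations (matrix is all zeros)")
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def positives(self) -> np.ndarray:
        """Index pairs (i, j) of the known associations, row-major order."""
        return np.argwhere(self.values == 1.0)

    def copy_with(self, values: np.ndarray) -> "AssociationMatrix":
        return AssociationMatrix(values, list(self.row_ids), list(self.col_ids))


@dataclass
class FeatureMatrix:
    """Per-node numeric features with a declared noise family.

    ``noise_family`` selects the reconstruction likelihood downstream:
    gaussian features use squared error, bernoulli features use cross
    entropy.
    """

    values: np.ndarray
    ids: list[str]
    noise_family: str = "gaussian"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataValidationError("feature matrix must be 2-D")
        if len(self.ids) != self.values.shape[0]:
            raise DataValidationError("id list does not match row count")
        if self.noise_family not in ("gaussian", "bernoulli"):
            raise DataValidationError(f"unknown noise family {self.noise_family!r}")
        if self.noise_family == "bernoulli":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise DataValidationError("bernoulli features must be 0/1")
        elif not np.isfinite(self.values).all():
            raise DataValidationError("gaussian features must be finite")
        _check_unique(self.ids, "feature row")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SequenceRecord:
    """A nucleotide sequence destined for k-mer embedding."""

    id: str
    sequence: str


def _read_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        # auto-detect limited to tab vs comma
        head = path.read_text().splitlines()[:1]
        if head and "\t" in head[0]:
            sep = "\t"
        elif head and "," in head[0]:
            sep = ","
    else:
        sep = {"tab": "\t", "comma": ","}.get(dialect, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise DataValidationError(f"{path}: no data rows")
    return df


def _parse_binary(df: pd.DataFrame, path) -> np.ndarray:
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col].to_numpy()):
            s = str(cell).strip()
            if s not in ("0", "1"):
                raise DataValidationError(
                    f"{path}: cell at row {df.index[i]!r}, column {col!r} "
                    f"is {cell!r}, expected 0 or 1"
                )
            values[i, j] = float(s)
    return values


def read_association_matrix(path: str | Path, dialect: str | None = None) -> AssociationMatrix:
    """Read a binary association table (rows: lncRNAs, columns: diseases)."""
    df = _read_table(path, dialect)
    values = _parse_binary(df, path)
    return AssociationMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_association_matrix(Y: AssociationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(Y.values.astype(int), index=Y.row_ids, columns=Y.col_ids)
    df.to_csv(path, sep="\t")


def read_feature_matrix(
    path: str | Path, noise_family: str = "gaussian", dialect: str | None = None
) -> FeatureMatrix:
    """Read a numeric feature table; rows are nodes, columns are features."""
    df = _read_table(path, dialect)
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as e:
        raise DataValidationError(f"{path}: non-numeric cell ({e})") from None
    return FeatureMatrix(values, [str(i) for i in df.index], noise_family)


def write_feature_matrix(X: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        X.values.astype(int) if X.noise_family == "bernoulli" else X.values,
        index=X.ids,
        columns=[f"f{j}" for j in range(X.values.shape[1])],
    )
    df.to_csv(path, sep="\t")


def read_gene_feature_table(path: str | Path, dialect: str | None = None) -> FeatureMatrix:
    """Read a binary disease x gene table as bernoulli features."""
    df = _read_table(path, dialect)
    values = _parse_binary(df, path)
    return FeatureMatrix(values, [str(i) for i in df.index], "bernoulli")


def drop_empty_gene_columns(features: FeatureMatrix) -> FeatureMatrix:
    """Remove gene columns that are associated with no disease.

    Column order of the retained genes is preserved; idempotent.
    """
    if features.noise_family != "bernoulli":
        raise DataValidationError("drop_empty_gene_columns expects bernoulli features")
    keep = features.values.sum(axis=0) > 0
    if not keep.any():
        raise DataValidationError("all gene columns are empty")
    return FeatureMatrix(features.values[:, keep], list(features.ids), "bernoulli")


def rescale_features_unit_interval(features: FeatureMatrix) -> FeatureMatrix:
    """Affine global min-max map onto [0, 1]; a constant matrix maps to zeros.

    Required because decoder outputs are sigmoid-bounded, so continuous
    features must live in the unit interval to be reconstructable.
    """
    if features.noise_family != "gaussian":
        raise DataValidationError("rescaling applies to gaussian features")
    v = features.values
    if not np.isfinite(v).all():
        raise DataValidationError("non-finite feature entries")
    lo, hi = v.min(), v.max()
    scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    return FeatureMatrix(scaled, list(features.ids), "gaussian")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise DataValidationError(f"{path}: no FASTA records")
    return records


def embed_sequences(
    records: Iterable[SequenceRecord],
    k: int = 3,
    dim: int = 300,
    window: int = 5,
    seed: int = 0,
    epochs: int = 5,
) -> FeatureMatrix:
    """Embed nucleotide sequences as sums of trained k-mer vectors.

    Sequences are uppercased with U mapped to T; overlapping k-mers
    (stride 1) containing characters outside ACGT are dropped.  A
    skip-gram model with negative sampling is trained on the corpus of
    all sequences, and each sequence's feature row is the sum of its
    k-mer vectors.  Deterministic given the seed and invariant to the
    order of the input records.
    """
    from .embedding import clean_kmers, train_kmer_skipgram

    records = list(records)
    if k < 1 or dim < 1:
        raise DataValidationError("k and dim must be >= 1")
    kmer_lists: list[list[str]] = []
    for rec in records:
        kmers = clean_kmers(rec.sequence, k)
        if not kmers:
            raise DataValidationError(
                f"sequence {rec.id!r} yields no valid {k}-mers (too short or non-ACGTU)"
            )
        kmer_lists.append(kmers)
    vectors = train_kmer_skipgram(kmer_lists, dim=dim, window=window, seed=seed, epochs=epochs)
    rows = np.stack([sum(vectors[km] for km in kmers) for kmers in kmer_lists])
    return FeatureMatrix(rows, [r.id for r in records], "gaussian")


def write_predictions(
    scores: np.ndarray,
    Y: AssociationMatrix,
    path: str | Path,
) -> None:
    """Write one row per (lncRNA, disease) pair: id pair, score, known flag."""
    m, n = Y.shape
    if scores.shape != (m, n):
        raise DataValidationError("score matrix shape does not match Y")
    with open(path, "w") as fh:
        fh.write("lncRNA_id\tdisease_id\tscore\tknown_flag\n")
        for i in range(m):
            for j in range(n):
                fh.write(
                    f"{Y.row_ids[i]}\t{Y.col_ids[j]}\t{scores[i, j]:.10g}\t{int(Y.values[i, j])}\n"
                )
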