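"""Reading, writing and validation of interaction and similarity matrices.

The on-disk dialect is the one used by the public drug-target benchmark
distributions: a tab-delimited UTF-8 text matrix whose first row holds
column identifiers and whose first column holds row identifiers. The public
files store *targets in rows*; the library's canonical in-memory orientation
is drugs x targets, so loading applies a transpose controlled by an explicit
``orientation`` flag (default ``"targets-in-rows"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ValidationError

ORIENTATIONS = ("drugs-in-rows", "targets-in-rows")

__all__ = [
    "InteractionData",
    "SimilarityMatrix",
    "read_matrix_file",
    "write_matrix_file",
    "load_interactions",
    "load_similarity",
    "normalized_sw_score",
    "sparseness",
    "write_predictions",
]


@dataclass
class InteractionData:
    """A binary drug x target interaction matrix with identifiers.

    Attributes
    ----------
    drug_ids, target_ids:
        Ordered, unique identifier lists for the two axes.
    Z:
        ``(n_drugs, n_targets)`` array with entries exactly 0 or 1.
    omega:
        Frozen set of ``(i, j)`` index pairs where ``Z[i, j] == 1`` — the
        known interactions. Derived from ``Z`` on construction.
    """

    drug_ids: list[str]
    target_ids: list[str]
    Z: np.ndarray
    omega: frozenset[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        n, m = len(self.drug_ids), len(self.target_ids)
        if self.Z.shape != (n, m):
            raise ValidationError(
                f"interaction matrix shape {self.Z.shape} does not match "
                f"{n} drug ids x {m} target ids")
        if n < 2 or m < 2:
            raise ValidationError("need at least 2 drugs and 2 targets")
        if len(set(self.drug_ids)) != n:
            raise ValidationError("duplicate drug identifiers")
        if len(set(self.target_ids)) != m:
            raise ValidationError("duplicate target identifiers")
        if not np.isin(self.Z, (0.0, 1.0)).all():
            raise ValidationError("interaction matrix entries must be 0 or 1")
        self.omega = frozenset(zip(*np.nonzero(self.Z == 1.0)))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def omega_mask(self) -> np.ndarray:
        """Boolean mask of known interactions, same shape as ``Z``."""
        return self.Z == 1.0


@dataclass
class SimilarityMatrix:
    """A square symmetric similarity matrix with values in [0, 1].

    The diagonal is expected to be 1 (self-similarity); a deviating diagonal
    triggers a warning rather than an error because some distributed files
    round it.
    """

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        d = len(self.ids)
        if self.S.shape != (d, d):
            raise ValidationError(
                f"similarity matrix shape {self.S.shape} does not match "
                f"{d} identifiers")
        if len(set(self.ids)) != d:
            raise ValidationError("duplicate identifiers in similarity matrix")
        if not np.allclose(self.S, self.S.T, atol=1e-8):
            raise ValidationError("similarity matrix is not symmetric (atol=1e-8)")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValidationError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-8):
            warnings.warn("similarity matrix diagonal deviates from 1",
                          stacklevel=2)

    @property
    def dim(self) -> int:
        return len(self.ids)


def read_matrix_file(path, orientation: str = "targets-in-rows",
                     delimiter: str = "\t"):
    """Read a labelled matrix file and return ``(row_ids, col_ids, matrix)``.

    ``orientation`` states what the *file* stores in rows. The returned
    triple is always in drugs-x-targets order: when the file stores targets
    in rows the matrix is transposed and the identifier lists swapped, so
    ``row_ids`` are drugs and ``col_ids`` are targets for interaction
    matrices. For square similarity matrices the flag is irrelevant in
    practice (the matrix is symmetric) but still honoured.
    """
    if orientation not in ORIENTATIONS:
        raise DomainError(f"orientation must be one of {ORIENTATIONS}")
    with open(path, encoding="utf-8") as fh:
        header_cells = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header_cells)) != len(header_cells):
        # pandas silently renames duplicate headers, so check them raw
        raise ValidationError(f"{path}: duplicate identifiers")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0,
                         dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed matrix file: {exc}") from exc
    if df.isin([""]).any().any():
        raise FormatError(f"{path}: ragged rows or empty cells")
    try:
        values = df.to_numpy(dtype=str).astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    if len(set(row_ids)) != len(row_ids) or len(set(col_ids)) != len(col_ids):
        raise ValidationError(f"{path}: duplicate identifiers")
    if orientation == "targets-in-rows":
        return col_ids, row_ids, values.T.copy()
    return row_ids, col_ids, values


def write_matrix_file(path, row_ids, col_ids, matrix,
                      delimiter: str = "\t") -> None:
    """Write a labelled matrix in the same dialect ``read_matrix_file`` reads.

    Values are written with shortest round-trip float formatting so a
    read-write-read cycle is bit-exact.
    """
    matrix = np.asarray(matrix)
    df = pd.DataFrame(matrix, index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep=delimiter)


def load_interactions(path, orientation: str = "targets-in-rows",
                      delimiter: str = "\t") -> InteractionData:
    """Load and validate a binary interaction matrix into drugs x targets."""
    drug_ids, target_ids, Z = read_matrix_file(path, orientation, delimiter)
    return InteractionData(drug_ids, target_ids, Z)


def load_similarity(path, delimiter: str = "\t") -> SimilarityMatrix:
    """Load and validate a square similarity matrix."""
    ids, col_ids, S = read_matrix_file(path, "drugs-in-rows", delimiter)
    if ids != col_ids:
        raise ValidationError(f"{path}: row and column identifiers differ")
    return SimilarityMatrix(ids, S)


def normalized_sw_score(sw_12: float, sw_11: float, sw_22: float) -> float:
    """Normalize a raw Smith-Waterman alignment score.

    Protein sequence similarity is the cross alignment score divided by the
    geometric mean of the two self-alignment scores::

        score = sw_12 / (sqrt(sw_11) * sqrt(sw_22))

    Raw alignment scores are inputs; this function never runs an alignment.
    """
    if sw_11 <= 0 or sw_22 <= 0:
        raise DomainError("self-alignment scores must be positive")
    if sw_12 < 0:
        raise DomainError("cross-alignment score must be non-negative")
    return sw_12 / (np.sqrt(sw_11) * np.sqrt(sw_22))


def sparseness(data: InteractionData) -> float:
    """Percentage of drug-target pairs with no known interaction.

    ``100 * (1 - |omega| / (n * m))`` rounded to two decimals, the figure
    benchmark datasets are conventionally summarised by.
    """
    n, m = data.n_drugs, data.n_targets
    return round(100.0 * (1.0 - len(data.omega) / (n * m)), 2)


def write_predictions(path, rows, delimiter: str = "\t") -> None:
    """Write ``(drug_id, target_id, score)`` rows sorted by descending score.

    ``rows`` is an iterable of triples; sorting is stable so equal scores
    keep their input order (drug-major pair order as produced by the CLI).
    """
    rows = list(rows)
    order = np.argsort(-np.array([r[2] for r in rows], dtype=float),
                       kind="stable")
    df = pd.DataFrame([rows[i] for i in order],
                      columns=["drug_id", "target_id", "score"])
    df.to_csv(path, sep=delimiter, index=False)
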