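"""Labeled distance matrices: reading, validation, writing, bundled example.

Supports a relaxed PHYLIP distance-matrix dialect (square or
lower-triangular, whitespace-delimited labels of any length) and delimited
text (CSV/TSV) with a header row.  All readers return a validated,
exactly symmetric :class:`DistanceMatrix`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

from .errors import MatrixParseError, MatrixValidationError

__all__ = [
    "DistanceMatrix",
    "read_phylip_distances",
    "read_delimited_distances",
    "write_phylip_distances",
    "bear_fixture",
    "BEAR_LABELS",
]

#: Relative asymmetry tolerated on read before a square matrix is rejected.
ASYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class DistanceMatrix:
    """A labeled symmetric matrix of pairwise distances.

    Parameters
    ----------
    labels:
        Ordered, unique, non-empty taxon names.  Order is preserved exactly
        as read; it is semantically meaningful for tie-break reproduction.
    values:
        Square array of non-negative reals with zero diagonal, indexed
        consistently with ``labels``.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        n = len(labels)
        if n < 2:
            raise MatrixValidationError("a distance matrix needs at least 2 taxa")
        if any(not l for l in labels):
            raise MatrixValidationError("empty taxon label")
        if len(set(labels)) != n:
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise MatrixValidationError(f"duplicate labels: {dupes}")
        if values.shape != (n, n):
            raise MatrixValidationError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(values)):
            raise MatrixValidationError("non-finite distance value")
        if np.any(np.diag(values) != 0.0):
            raise MatrixValidationError("non-zero diagonal entry")
        if np.any(values < 0.0):
            i, j = np.argwhere(values < 0.0)[0]
            raise MatrixValidationError(
                f"negative distance between {labels[i]!r} and {labels[j]!r}"
            )
        scale = max(float(np.abs(values).max()), 1.0)
        if float(np.abs(values - values.T).max()) > ASYMMETRY_RTOL * scale:
            raise MatrixValidationError("matrix is not symmetric")
        # Symmetrize by averaging so downstream arithmetic sees an exactly
        # symmetric matrix even if the input was only symmetric to tolerance.
        sym = (values + values.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        sym.setflags(write=False)
        object.__setattr__(self, "values", sym)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        """Distance between two taxa by label."""
        return float(self.values[self.index(a), self.index(b)])

    def permuted(self, order: Sequence[int]) -> "DistanceMatrix":
        """Return a copy with rows/columns reordered by ``order``."""
        idx = np.asarray(order, dtype=int)
        if sorted(idx.tolist()) != list(range(len(self))):
            raise ValueError("order must be a permutation of all indices")
        return DistanceMatrix(
            tuple(self.labels[i] for i in idx), self.values[np.ix_(idx, idx)]
        )

    def equals(self, other: "DistanceMatrix", atol: float = 1e-12) -> bool:
        return self.labels == other.labels and bool(
            np.allclose(self.values, other.values, rtol=0.0, atol=atol)
        )


def _tokens(source: IO[str] | str) -> list[list[str]]:
    text = source if isinstance(source, str) else source.read()
    return [line.split() for line in text.splitlines() if line.strip()]


def read_phylip_distances(source: IO[str] | str) -> DistanceMatrix:
    """Read a PHYLIP-style distance matrix (square or lower-triangular).

    The first non-blank line holds the taxon count; each following line is a
    label followed by that row's values.  Lower-triangular rows (row ``i``
    with ``i-1`` values, implied zero diagonal) are mirrored to square.
    Labels are whitespace-delimited tokens of any length.
    """
    rows = _tokens(source)
    if not rows:
        raise MatrixParseError("empty input")
    try:
        n = int(rows[0][0])
    except ValueError as exc:
        raise MatrixParseError(f"expected a taxon count, got {rows[0][0]!r}") from exc
    body = rows[1:]
    if len(body) != n:
        raise MatrixParseError(f"declared {n} taxa but found {len(body)} rows")

    labels: list[str] = []
    parsed: list[list[float]] = []
    for r, row in enumerate(body):
        labels.append(row[0])
        try:
            parsed.append([float(tok) for tok in row[1:]])
        except ValueError as exc:
            raise MatrixParseError(f"non-numeric value in row {row[0]!r}") from exc

    counts = [len(p) for p in parsed]
    values = np.zeros((n, n))
    if counts == [n] * n:
        values = np.array(parsed)
    elif counts == list(range(n)):
        for i, vals in enumerate(parsed):
            for j, v in enumerate(vals):
                values[i, j] = values[j, i] = v
    else:
        for i, c in enumerate(counts):
            if c not in (n, i):
                raise MatrixParseError(
                    f"row {labels[i]!r} has {c} values; expected {n} (square) "
                    f"or {i} (lower-triangular)"
                )
        raise MatrixParseError("inconsistent mixture of square and triangular rows")
    return DistanceMatrix(tuple(labels), values)


def read_delimited_distances(source: IO[str] | str, delimiter: str = ",") -> DistanceMatrix:
    """Read a delimited matrix with a header row of labels.

    Each body row starts with its label followed by a full row of values;
    row-label order must match the header order.
    """
    text = source if isinstance(source, str) else source.read()
    lines = [line for line in text.splitlines() if line.strip()]
    if len(lines) < 2:
        raise MatrixParseError("need a header row and at least one body row")
    header = [tok.strip() for tok in lines[0].split(delimiter)]
    labels = header[1:] if header and header[0] == "" else header
    n = len(labels)
    if len(lines) - 1 != n:
        raise MatrixParseError(f"header names {n} taxa but found {len(lines) - 1} rows")
    values = np.zeros((n, n))
    for i, line in enumerate(lines[1:]):
        cells = [tok.strip() for tok in line.split(delimiter)]
        if cells[0] != labels[i]:
            raise MatrixParseError(
                f"row label {cells[0]!r} does not match header label {labels[i]!r}"
            )
        if len(cells) - 1 != n:
            raise MatrixParseError(
                f"row {cells[0]!r} has {len(cells) - 1} values; expected {n}"
            )
        try:
            values[i] = [float(tok) for tok in cells[1:]]
        except ValueError as exc:
            raise MatrixParseError(f"non-numeric value in row {cells[0]!r}") from exc
    return DistanceMatrix(tuple(labels), values)


def write_phylip_distances(dm: DistanceMatrix, sink: IO[str]) -> None:
    """Write ``dm`` in the square PHYLIP dialect (round-trips on read)."""
    sink.write(f"{len(dm)}\n")
    for label, row in zip(dm.labels, dm.values):
        # 17 significant digits: exact float round-trip
        cells = " ".join(format(v, ".17g") for v in row)
        sink.write(f"{label} {cells}\n")


def to_phylip_text(dm: DistanceMatrix) -> str:
    buf = io.StringIO()
    write_phylip_distances(dm, buf)
    return buf.getvalue()


def write_delimited_distances(
    dm: DistanceMatrix, sink: IO[str], delimiter: str = ","
) -> None:
    """Write ``dm`` as delimited text with a header row."""
    sink.write(delimiter + delimiter.join(dm.labels) + "\n")
    for label, row in zip(dm.labels, dm.values):
        cells = delimiter.join(format(v, ".17g") for v in row)
        sink.write(f"{label}{delimiter}{cells}\n")


BEAR_LABELS = (
    "Abruzzo",
    "Pyrenees",
    "Kodiak",
    "Captive-3",
    "Captive-4",
    "Captive-5",
    "Grizzly",
    "Polar-2",
    "Black",
)

# Pairwise percentage differences among mitochondrial DNA sequences of nine
# brown bears; lower-triangular rows in input order.
_BEAR_LOWER = """
Pyrenees  1.3
Kodiak    4.3 4.3
Captive-3 4.3 4.3 0.7
Captive-4 2.7 2.3 5.0 5.0
Captive-5 3.0 3.0 1.3 1.3 3.7
Grizzly   1.7 1.7 2.7 2.7 2.3 2.0
Polar-2   2.0 2.0 3.0 3.0 2.7 2.3 0.3
Black     8.7 8.0 10.0 10.0 10.0 8.7 9.0 9.4
"""


def bear_fixture() -> DistanceMatrix:
    """The packaged nine-bear distance matrix (percent sequence difference)."""
    text = f"9\n{BEAR_LABELS[0]}\n" + _BEAR_LOWER.strip() + "\n"
    dm = read_phylip_distances(text)
    assert dm.labels == BEAR_LABELS
    return dm
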