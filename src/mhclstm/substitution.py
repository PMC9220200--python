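"""Amino-acid substitution matrices in the package's canonical ordering.

BLOSUM-style matrices serve as the evolutionary prior that initializes the
learnable kernel bank.  Biopython supplies the published matrices and the
standard NCBI square-matrix text format; here they are reindexed to the
canonical 20-letter ordering (see :mod:`mhclstm.alphabet`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AMINO_ACIDS, N_AMINO_ACIDS


class MatrixFormatError(ValueError):
    """A substitution-matrix file does not cover the 20 canonical residues."""


@dataclasses.dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20x20 substitution matrix, rows/columns in canonical ordering."""

    values: np.ndarray
    name: str
    ordering: str = AMINO_ACIDS

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_AMINO_ACIDS, N_AMINO_ACIDS):
            raise MatrixFormatError(
                f"substitution matrix must be 20x20, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise MatrixFormatError("substitution matrix has non-finite entries")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.ordering.index(a), self.ordering.index(b)])


def _reindex(array, alphabet: str, name: str) -> SubstitutionMatrix:
    missing = [aa for aa in AMINO_ACIDS if aa not in alphabet]
    if missing:
        raise MatrixFormatError(
            f"matrix {name!r} is missing amino acid(s) {''.join(missing)}"
        )
    idx = [alphabet.index(aa) for aa in AMINO_ACIDS]
    values = np.asarray(array, dtype=float)[np.ix_(idx, idx)]
    return SubstitutionMatrix(values=values, name=name)


def load_substitution_matrix(path_or_name: str | Path = "BLOSUM62") -> SubstitutionMatrix:
    """Load a substitution matrix by built-in name or from an NCBI-format file.

    Built-in names are those shipped with Biopython (``BLOSUM62``,
    ``BLOSUM50``, ``PAM250``, ...).  Files must use the standard square
    layout with a header row/column of amino-acid letters and must cover
    all 20 canonical residues.
    """
    name = str(path_or_name)
    if Path(name).exists():
        try:
            mat = substitution_matrices.read(name)
        except Exception as exc:  # malformed layout
            raise MatrixFormatError(f"cannot parse matrix file {name}: {exc}") from exc
        return _reindex(np.asarray(mat), "".join(mat.alphabet), Path(name).name)
    try:
        mat = substitution_matrices.load(name.upper())
    except FileNotFoundError:
        raise MatrixFormatError(
            f"{name!r} is neither an existing file nor a built-in matrix name"
        ) from None
    return _reindex(np.asarray(mat), "".join(mat.alphabet), name.upper())


def write_substitution_matrix(matrix: SubstitutionMatrix, path: str | Path) -> None:
    """Write in the standard square text layout (letter header row/column)."""
    with open(path, "w") as fh:
        fh.write("# " + matrix.name + "\n")
        fh.write("   " + "  ".join(AMINO_ACIDS) + "\n")
        for i, aa in enumerate(AMINO_ACIDS):
            row = " ".join(f"{matrix.values[i, j]:.6g}" for j in range(N_AMINO_ACIDS))
            fh.write(f"{aa} {row}\n")


def read_substitution_matrix(path: str | Path) -> SubstitutionMatrix:
    """Read a matrix written by :func:`write_substitution_matrix`."""
    letters: list[str] = []
    rows: list[list[float]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if header is None:
                header = parts
                continue
            letters.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if header is None or not rows:
        raise MatrixFormatError(f"no matrix found in {path}")
    if len(rows) != len(header) or any(len(r) != len(header) for r in rows):
        raise MatrixFormatError(f"matrix in {path} is not square")
    return _reindex(np.asarray(rows), "".join(letters), Path(str(path)).name)
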