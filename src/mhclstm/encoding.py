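"""One-hot peptide encoding and the learnable evolutionary feature layer.

A peptide of length L is first one-hot encoded as a 20xL binary matrix X
(rows = amino acids in the canonical ordering, columns = positions).  A
bank of twenty learnable 1x20 convolution kernels — jointly a 20x20 matrix
W initialized from a BLOSUM substitution matrix — then maps it to an Lx20
feature matrix::

    Evo(X)[i, k] = sum_n W[k, n] * X[n, i]

i.e. a position-wise linear map over the 20 amino-acid channels (window
size 1).  With one-hot input, row i of Evo(X) is simply the W column of the
residue at position i, so before any training the features are exactly the
BLOSUM similarity profile of each residue.  Because the kernels are updated
during training, the trained bank can be read back out as a data-adapted
("novel") substitution matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AMINO_ACIDS, validate_sequence
from .substitution import SubstitutionMatrix


@dataclasses.dataclass
class OneHotMatrix:
    """20xL binary matrix; each column has exactly one 1."""

    values: np.ndarray

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class EvoKernelBank:
    """Twenty 1x20 kernels (rows of ``weights``), window size 1.

    ``weights[k]`` is kernel k; at initialization it equals row k of the
    initializing substitution matrix.
    """

    weights: np.ndarray  # (20, 20), float64
    init_name: str = "BLOSUM62"
    trainable: bool = True

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_AMINO_ACIDS, N_AMINO_ACIDS):
            raise ValueError(f"kernel bank must be 20x20, got {w.shape}")
        self.weights = w

    @classmethod
    def from_substitution_matrix(cls, matrix: SubstitutionMatrix) -> "EvoKernelBank":
        return cls(weights=matrix.values.copy(), init_name=matrix.name)


def one_hot_encode(sequence: str) -> OneHotMatrix:
    """Encode a peptide as a 20xL one-hot matrix (canonical row ordering)."""
    validate_sequence(sequence)
    L = len(sequence)
    values = np.zeros((N_AMINO_ACIDS, L))
    for j, aa in enumerate(sequence):
        values[AA_INDEX[aa], j] = 1.0
    return OneHotMatrix(values=values)


def evo_transform(x: OneHotMatrix | np.ndarray, bank: EvoKernelBank) -> np.ndarray:
    """Apply the kernel bank: returns the Lx20 evolutionary feature matrix."""
    X = x.values if isinstance(x, OneHotMatrix) else np.asarray(x, dtype=float)
    if X.shape[0] != N_AMINO_ACIDS:
        raise ValueError(f"input must have 20 rows, got {X.shape}")
    # Evo[i, k] = sum_n W[k, n] X[n, i]  ==  X^T W^T
    return X.T @ bank.weights.T


def extract_learned_matrix(bank: EvoKernelBank, name: str | None = None) -> SubstitutionMatrix:
    """Stack the 20 kernels into a substitution matrix (canonical ordering).

    Before training this equals the initializer exactly; after training it
    is the data-adapted substitution matrix learned by the model.
    """
    return SubstitutionMatrix(
        values=bank.weights.copy(),
        name=name or f"learned_from_{bank.init_name}",
        ordering=AMINO_ACIDS,
    )
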