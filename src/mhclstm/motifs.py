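"""Position-frequency matrices and binder/non-binder motif comparison.

A PFM holds per-position residue frequencies over a set of equal-length
peptides — the data behind a sequence logo.  Binder and non-binder PFMs
are compared position-by-position with the Jensen-Shannon divergence
(symmetric, non-negative, bounded by log 2 nats): well-separated alleles
show large divergence concentrated at the anchor positions, while
non-differential alleles stay near zero everywhere.

Variable-length peptide sets must be stratified by length before PFM
computation; column alignment across different lengths is otherwise
ill-defined.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AMINO_ACIDS, validate_sequence

LOG2_NATS = float(np.log(2.0))


@dataclasses.dataclass(frozen=True)
class PositionFrequencyMatrix:
    """L x 20 per-position residue frequencies (rows sum to 1)."""

    values: np.ndarray
    n_sequences: int
    pseudocount: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != N_AMINO_ACIDS:
            raise ValueError(f"PFM must be Lx20, got {v.shape}")
        if self.n_sequences > 0 and not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PFM rows must sum to 1")
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def modal_residue(self, position: int) -> str:
        """Most frequent residue at a 0-based position."""
        return AMINO_ACIDS[int(np.argmax(self.values[position]))]


def compute_pfm(
    sequences: Sequence[str], pseudocount: float = 0.0
) -> PositionFrequencyMatrix:
    """Per-position residue frequencies with an additive pseudocount.

    frequency(a, i) = (count(a, i) + pseudocount) / (n + 20 * pseudocount)

    All sequences must share one length; stratify variable-length sets by
    length first.
    """
    if not sequences:
        raise ValueError("cannot compute a PFM from zero sequences")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(
            f"mixed peptide lengths {sorted(lengths)}: stratify by length "
            "before computing a PFM"
        )
    L = lengths.pop()
    counts = np.zeros((L, N_AMINO_ACIDS))
    for seq in sequences:
        validate_sequence(seq)
        for i, aa in enumerate(seq):
            counts[i, AA_INDEX[aa]] += 1.0
    n = len(sequences)
    values = (counts + pseudocount) / (n + N_AMINO_ACIDS * pseudocount)
    return PositionFrequencyMatrix(values=values, n_sequences=n, pseudocount=pseudocount)


def pfm_divergence(
    binders: PositionFrequencyMatrix, nonbinders: PositionFrequencyMatrix
) -> tuple[np.ndarray, float]:
    """Per-position Jensen-Shannon divergence (nats) and its mean.

    JSD(p, q) = 0.5 KL(p||m) + 0.5 KL(q||m),  m = (p + q) / 2

    Symmetric, zero iff the PFMs agree, bounded above by log 2.  Use a
    positive pseudocount on both PFMs so the divergence is well-defined
    with unobserved residues.
    """
    if binders.length != nonbinders.length:
        raise ValueError(
            f"PFM lengths differ: {binders.length} vs {nonbinders.length}"
        )
    per_position = np.empty(binders.length)
    for i in range(binders.length):
        p, q = binders.values[i], nonbinders.values[i]
        m = 0.5 * (p + q)
        per_position[i] = 0.5 * entropy(p, m) + 0.5 * entropy(q, m)
    return per_position, float(per_position.mean())


def export_logo_table(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """Write a position x residue frequency table (TSV) for logo tools.

    The layout (positions as rows, residues as columns in the canonical
    ordering) is directly consumable by logo-rendering packages.
    """
    df = pd.DataFrame(pfm.values, columns=list(AMINO_ACIDS))
    df.insert(0, "position", np.arange(1, pfm.length + 1))
    df.to_csv(path, sep="\t", index=False)


def read_logo_table(path: str | Path) -> PositionFrequencyMatrix:
    """Read back a table written by :func:`export_logo_table`."""
    df = pd.read_csv(path, sep="\t")
    values = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    return PositionFrequencyMatrix(values=values, n_sequences=-1)
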