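"""Sliding-window screening of whole protein sequences.

A protein is dissected into all equal-sized windows at a configurable
step, each window is scored by a trained per-allele model, and the
results are reported with 1-based inclusive coordinates (so
``protein[start-1:end]`` reproduces the peptide).  Because the predictor
is independent of peptide length, several window lengths (e.g. 8-11 for
class I) can be screened in a single pass.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .trainer import TrainedModel


@dataclasses.dataclass(frozen=True)
class ScanResult:
    protein_id: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    peptide: str
    probability: float
    is_binder: bool

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError("scan coordinates do not match peptide length")


def scan_protein(
    protein_id: str,
    sequence: str,
    model: TrainedModel,
    window: int,
    step: int = 1,
) -> list[ScanResult]:
    """Score every length-``window`` segment of a protein at ``step``."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > len(sequence):
        raise ValueError(
            f"window {window} longer than protein {protein_id!r} ({len(sequence)} aa)"
        )
    starts = list(range(0, len(sequence) - window + 1, step))
    peptides = [sequence[s : s + window] for s in starts]
    probs = model.predict(peptides)
    return [
        ScanResult(
            protein_id=protein_id,
            start=s + 1,
            end=s + window,
            peptide=pep,
            probability=float(p),
            is_binder=bool(p >= model.threshold),
        )
        for s, pep, p in zip(starts, peptides, probs)
    ]


def scan_fasta(
    path: str | Path,
    model: TrainedModel,
    windows: Sequence[int],
    step: int = 1,
) -> list[ScanResult]:
    """Scan every record of a FASTA file at each requested window length."""
    results: list[ScanResult] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        for window in windows:
            results.extend(scan_protein(record.id, seq, model, window, step))
    return results


def write_scan_results(results: Iterable[ScanResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tstart\tend\tpeptide\tprobability\tbinder\n")
        for r in results:
            fh.write(
                f"{r.protein_id}\t{r.start}\t{r.end}\t{r.peptide}\t"
                f"{r.probability:.6f}\t{int(r.is_binder)}\n"
            )
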