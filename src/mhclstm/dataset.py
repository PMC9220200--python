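"""Peptide binding datasets: ingestion, curation, labelling, fold splitting.

A record pairs a peptide sequence with an MHC allele and a measured IC50
affinity (nM, competitive binding assay).  Records are dichotomized at the
conventional 500 nM cutoff (IC50 < 500 nM = binder) and affinities are
standardized to [0, 1] via ``1 - log(ic50)/log(50000)``, so 1 nM maps to 1
and 50,000 nM maps to 0.

Curation resolves repeated measurements within an allele:

1. identical (allele, sequence) rows with the *same* IC50 collapse to one;
2. identical (allele, sequence) rows with *different* IC50s are all dropped
   as irreconcilable;
3. the same sequence under *different* alleles is always kept, because a
   separate predictor is trained per allele.

Records containing non-canonical residues (X, B, Z, U, ...) are dropped with
a logged count: the 20-letter one-hot encoding has no column for them.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .alphabet import is_canonical

IC50_BINDER_THRESHOLD_NM = 500.0
IC50_STANDARDIZATION_MAX_NM = 50_000.0

SPECIES = ("human", "mouse", "rat", "macaque", "chimpanzee")
MHC_CLASSES = ("I", "II")

REQUIRED_COLUMNS = ("sequence", "allele", "ic50_nM")
OPTIONAL_COLUMNS = ("species", "mhc_class")


class DatasetFormatError(ValueError):
    """The dataset file is missing required columns or is unreadable."""


@dataclasses.dataclass
class PeptideRecord:
    """One peptide-allele affinity measurement with derived fields."""

    sequence: str
    allele: str
    ic50_nM: float
    species: str = "human"
    mhc_class: str = "I"
    label: int | None = None          # 1 = binder (IC50 < 500 nM)
    std_affinity: float | None = None  # 1 - log(ic50)/log(50000), clamped

    def with_derived(self) -> "PeptideRecord":
        """Return a copy with label and standardized affinity filled in."""
        return dataclasses.replace(
            self,
            label=dichotomize(self.ic50_nM),
            std_affinity=standardize_affinity(self.ic50_nM),
        )


@dataclasses.dataclass
class CurationReport:
    n_input: int = 0
    n_kept: int = 0
    n_removed_duplicate_same_ic50: int = 0
    n_removed_conflicting_ic50: int = 0
    n_removed_invalid_residues: int = 0

    def __post_init__(self):
        removed = (
            self.n_removed_duplicate_same_ic50
            + self.n_removed_conflicting_ic50
            + self.n_removed_invalid_residues
        )
        if self.n_input != self.n_kept + removed:
            raise ValueError("curation counts do not partition the input")

    def to_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_text(self) -> str:
        return "".join(f"{k}\t{v}\n" for k, v in self.to_dict().items())


@dataclasses.dataclass
class ReadReport:
    """Row-level problems found while reading a dataset file."""

    n_rows: int = 0
    n_parsed: int = 0
    bad_rows: list[tuple[int, str]] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class FoldAssignment:
    fold_index: np.ndarray  # one integer in {0..k-1} per record
    k: int
    seed: int

    def fold(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == i)


def normalize_allele(raw: str) -> str:
    """Canonicalize an allele identifier: strip whitespace, uppercase.

    IEDB-style names appear in several dialects (``hla-a*02:01``,
    ``HLA-A*02:01``); the ``*`` and ``:`` separators are retained.
    """
    return "".join(str(raw).split()).upper()


def standardize_affinity(ic50_nM: float) -> float:
    """Map IC50 (nM) to [0, 1] via ``1 - log(ic50)/log(50000)``.

    The log ratio is base-independent.  Values outside [1, 50000] nM are
    clamped so training targets stay in the valid range for cross-entropy.
    """
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    value = 1.0 - math.log(ic50_nM) / math.log(IC50_STANDARDIZATION_MAX_NM)
    return min(1.0, max(0.0, value))


def unstandardize_affinity(std: float) -> float:
    """Inverse of the un-clamped standardization (std in [0, 1] → nM)."""
    return math.exp((1.0 - std) * math.log(IC50_STANDARDIZATION_MAX_NM))


def dichotomize(ic50_nM: float) -> int:
    """1 if binder (IC50 < 500 nM), 0 otherwise; 500 nM itself is negative."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return int(ic50_nM < IC50_BINDER_THRESHOLD_NM)


def read_dataset(
    path: str | Path, fmt: str = "auto"
) -> tuple[list[PeptideRecord], ReadReport]:
    """Read a delimited peptide dataset (columns sequence, allele, ic50_nM).

    ``fmt`` is ``"tsv"``, ``"csv"`` or ``"auto"`` (sniff from the header
    line).  Malformed rows (unparseable or non-positive IC50) are collected
    in the returned :class:`ReadReport`, not silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        header = path.open().readline()
        fmt = "tsv" if "\t" in header else "csv"
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise DatasetFormatError(f"unknown format {fmt!r}")
    df = pd.read_csv(path, sep=sep, dtype=str).rename(
        columns=lambda c: c.strip().lower().replace("ic50_nm", "ic50_nM")
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required column(s) {missing}")

    records: list[PeptideRecord] = []
    report = ReadReport(n_rows=len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ic50 = float(getattr(row, "ic50_nM"))
            if not math.isfinite(ic50) or ic50 <= 0:
                raise ValueError(f"IC50 out of domain: {ic50}")
        except (TypeError, ValueError):
            report.bad_rows.append(
                (i + 2, f"unparseable IC50 {getattr(row, 'ic50_nM')!r}")
            )
            continue
        records.append(
            PeptideRecord(
                sequence=str(row.sequence).strip().upper(),
                allele=normalize_allele(row.allele),
                ic50_nM=ic50,
                species=str(getattr(row, "species", "human") or "human").lower(),
                mhc_class=str(getattr(row, "mhc_class", "I") or "I").upper(),
            )
        )
    report.n_parsed = len(records)
    return records, report


def write_dataset(records: Iterable[PeptideRecord], path: str | Path, fmt: str = "tsv") -> None:
    """Write records (plus derived label/std_affinity columns) as text."""
    sep = {"tsv": "\t", "csv": ","}[fmt]
    rows = [dataclasses.asdict(r.with_derived() if r.label is None else r) for r in records]
    df = pd.DataFrame(
        rows,
        columns=["sequence", "allele", "species", "mhc_class", "ic50_nM", "label", "std_affinity"],
    )
    df.to_csv(path, sep=sep, index=False)


def curate(records: Sequence[PeptideRecord]) -> tuple[list[PeptideRecord], CurationReport]:
    """Apply the three filtration rules; returns curated records + report.

    Idempotent: curating curated output changes nothing.  Duplicate
    resolution happens within an (allele, sequence) group only; the same
    sequence under different alleles is untouched.  Derived fields (label,
    standardized affinity) are filled in on the kept records.
    """
    n_input = len(records)
    valid: list[PeptideRecord] = []
    n_invalid = 0
    for rec in records:
        if is_canonical(rec.sequence):
            valid.append(rec)
        else:
            n_invalid += 1

    groups: dict[tuple[str, str], list[PeptideRecord]] = defaultdict(list)
    for rec in valid:
        groups[(rec.allele, rec.sequence)].append(rec)

    kept: list[PeptideRecord] = []
    n_dup = 0
    n_conflict = 0
    seen_order: set[tuple[str, str]] = set()
    for rec in valid:  # preserve first-seen input order
        key = (rec.allele, rec.sequence)
        if key in seen_order:
            continue
        seen_order.add(key)
        group = groups[key]
        ic50s = {r.ic50_nM for r in group}
        if len(ic50s) == 1:
            kept.append(group[0].with_derived())
            n_dup += len(group) - 1
        else:
            n_conflict += len(group)

    report = CurationReport(
        n_input=n_input,
        n_kept=len(kept),
        n_removed_duplicate_same_ic50=n_dup,
        n_removed_conflicting_ic50=n_conflict,
        n_removed_invalid_residues=n_invalid,
    )
    return kept, report


def make_folds(records: Sequence[PeptideRecord], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Label-stratified k-fold partition, reproducible under ``seed``.

    Within each label stratum fold sizes differ by at most one.  Strata
    smaller than ``k`` trigger a warning (some folds then lack that label).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.array(
        [r.label if r.label is not None else dichotomize(r.ic50_nM) for r in records]
    )
    if len(records) < k:
        raise ValueError(f"cannot split {len(records)} records into {k} folds")
    degenerate = any(np.sum(labels == lab) < k for lab in np.unique(labels))
    fold_index = np.empty(len(records), dtype=int)
    if degenerate:
        warnings.warn(
            f"a label stratum has fewer than {k} records; "
            "some folds will miss this class",
            stacklevel=2,
        )
        # round-robin within each shuffled stratum, cursor shared across
        # strata so total fold sizes stay within one of each other
        rng = np.random.default_rng(seed)
        cursor = 0
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            rng.shuffle(idx)
            for j in idx:
                fold_index[j] = cursor % k
                cursor += 1
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        X = np.zeros((len(records), 1))
        for i, (_, test_idx) in enumerate(skf.split(X, labels)):
            fold_index[test_idx] = i
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)
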