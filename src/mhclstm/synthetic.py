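"""Synthetic allele-like peptide datasets with planted anchor motifs.

Real MHC ligands bind through a handful of anchor residues that occupy
pockets of the MHC groove (classically position 2 and the C-terminus for
class I), while the remaining positions are close to background.  The
generator emulates exactly that structure:

* peptide lengths are drawn from a class-appropriate distribution
  (8-11-mers for class I, 13-20-mers for class II);
* binder peptides carry preferred residues at the anchor positions with a
  probability that grows with the motif strength (strength 0 = background,
  large strength = always planted);
* IC50 values are lognormal around ``500 * exp(-+(0.5 + strength * n_matched))``
  nM — binders fall below the 500 nM cutoff in expectation, non-binders
  above it — so labels derived by dichotomization carry realistic noise;
* exact duplicates and conflicting-IC50 pairs can be injected at configured
  rates to exercise the curation rules.

Anchor positions are 1-based from the N-terminus; negative values count
from the C-terminus (-1 = last residue), so one motif applies across all
generated lengths.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .dataset import PeptideRecord

CLASS_I_LENGTHS = {8: 0.10, 9: 0.60, 10: 0.20, 11: 0.10}
CLASS_II_LENGTHS = {13: 0.10, 14: 0.10, 15: 0.40, 16: 0.15,
                    17: 0.10, 18: 0.05, 19: 0.05, 20: 0.05}

STRENGTH_NULL = 0.0
STRENGTH_WEAK = 1.0
STRENGTH_STRONG = 3.0


@dataclasses.dataclass(frozen=True)
class MotifSpec:
    """Anchor positions and their preferred residues.

    ``anchors`` maps a 1-based position (negative = from C-terminus) to a
    dict of preferred residues with weights.  ``strength`` is the
    log-affinity shift contributed by each matched anchor; it also sets
    the planting probability ``1 - exp(-strength)`` for binders.
    """

    anchors: dict[int, dict[str, float]] = dataclasses.field(
        default_factory=lambda: {2: {"L": 0.7, "M": 0.3}, -1: {"V": 0.6, "L": 0.4}}
    )
    strength: float = STRENGTH_STRONG

    def __post_init__(self):
        if self.strength < 0:
            raise ValueError("motif strength must be >= 0")
        for pos, prefs in self.anchors.items():
            if pos == 0:
                raise ValueError("anchor positions are 1-based; 0 is invalid")
            if not prefs or any(aa not in AA_INDEX for aa in prefs):
                raise ValueError(f"bad residue preferences at anchor {pos}")

    def resolve(self, length: int) -> dict[int, dict[str, float]]:
        """Map anchors to 0-based indices for a concrete peptide length."""
        out = {}
        for pos, prefs in self.anchors.items():
            idx = pos - 1 if pos > 0 else length + pos
            if not 0 <= idx < length:
                raise ValueError(f"anchor {pos} outside a length-{length} peptide")
            out[idx] = prefs
        return out

    @property
    def plant_probability(self) -> float:
        return 1.0 - math.exp(-self.strength)


@dataclasses.dataclass(frozen=True)
class SyntheticDatasetConfig:
    n_peptides: int = 2000
    mhc_class: str = "I"
    allele: str = "HLA-A*99:01"
    species: str = "human"
    length_distribution: dict[int, float] | None = None
    background: np.ndarray | None = None  # 20-vector summing to 1; uniform default
    ic50_noise_scale: float = 0.5         # sd of lognormal noise, log-units
    class_offset: float = 0.5             # baseline log-shift away from 500 nM
    positive_fraction: float = 0.5
    duplicate_rate: float = 0.0
    conflict_rate: float = 0.0
    seed: int = 0

    def lengths(self) -> tuple[np.ndarray, np.ndarray]:
        dist = self.length_distribution or (
            CLASS_I_LENGTHS if self.mhc_class == "I" else CLASS_II_LENGTHS
        )
        lengths = np.array(sorted(dist))
        probs = np.array([dist[l] for l in lengths], dtype=float)
        if self.n_peptides <= 0:
            raise ValueError("n_peptides must be positive")
        if not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("length distribution must sum to 1")
        return lengths, probs

    def background_freqs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("background must be a 20-vector summing to 1")
        return bg


def sample_peptide(
    config: SyntheticDatasetConfig,
    motif: MotifSpec,
    binder: bool,
    rng: np.random.Generator,
) -> PeptideRecord:
    """Draw one peptide record; binders carry the motif and low IC50."""
    lengths, probs = config.lengths()
    bg = config.background_freqs()
    aa = np.array(list(AMINO_ACIDS))
    for _ in range(100):
        length = int(rng.choice(lengths, p=probs))
        try:
            anchors = motif.resolve(length)
            break
        except ValueError:
            continue  # anchor impossible at this length: resample
    else:
        raise ValueError("motif anchors fit no generated length")

    residues = list(rng.choice(aa, size=length, p=bg))
    n_matched = 0
    if binder:
        for idx, prefs in anchors.items():
            if rng.random() < motif.plant_probability:
                choices = list(prefs)
                w = np.array([prefs[c] for c in choices], dtype=float)
                residues[idx] = str(rng.choice(choices, p=w / w.sum()))
                n_matched += 1
    sequence = "".join(residues)

    shift = config.class_offset + motif.strength * n_matched
    direction = -1.0 if binder else 1.0
    log_ic50 = math.log(500.0) + direction * shift + config.ic50_noise_scale * rng.normal()
    ic50 = float(np.clip(math.exp(log_ic50), 1e-3, 1e8))
    return PeptideRecord(
        sequence=sequence,
        allele=config.allele,
        ic50_nM=ic50,
        species=config.species,
        mhc_class=config.mhc_class,
    ).with_derived()


def generate_dataset(
    config: SyntheticDatasetConfig, motif: MotifSpec | None = None
) -> list[PeptideRecord]:
    """Generate a labelled allele dataset, optionally with injected repeats.

    Duplicates (same sequence + IC50) and conflicting pairs (same sequence,
    different IC50) are appended after the base draw with per-record
    Bernoulli rates, so their counts are binomial around
    ``rate * n_peptides``.
    """
    motif = motif if motif is not None else MotifSpec()
    rng = np.random.default_rng(config.seed)
    records: list[PeptideRecord] = []
    n_pos = int(round(config.positive_fraction * config.n_peptides))
    flags = np.array([True] * n_pos + [False] * (config.n_peptides - n_pos))
    rng.shuffle(flags)
    for binder in flags:
        records.append(sample_peptide(config, motif, bool(binder), rng))

    extras: list[PeptideRecord] = []
    for rec in records:
        r = rng.random()
        if r < config.duplicate_rate:
            extras.append(dataclasses.replace(rec))
        elif r < config.duplicate_rate + config.conflict_rate:
            extras.append(
                dataclasses.replace(rec, ic50_nM=rec.ic50_nM * 10.0).with_derived()
            )
    records.extend(extras)
    return records


def null_dataset(config: SyntheticDatasetConfig) -> list[PeptideRecord]:
    """Labels independent of sequence: the motif strength is forced to 0."""
    return generate_dataset(config, MotifSpec(strength=STRENGTH_NULL))
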