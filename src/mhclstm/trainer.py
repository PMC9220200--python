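"""Per-allele model training, five-fold cross-validation, persistence.

One model is trained per MHC allele.  The loss is binary cross-entropy at
learning rate 1e-4 (Adam), either against hard dichotomized labels
(default) or against the standardized affinity in [0, 1] as a soft target.
An internal validation split drives early stopping.  Cross-validation is
label-stratified five-fold: each record is scored exactly once
out-of-fold, and pooled scores are additionally stratified by peptide
length (8-11 + "Others" for class I, 13-20 + "Other" for class II).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import (
    IC50_BINDER_THRESHOLD_NM,
    FoldAssignment,
    PeptideRecord,
    make_folds,
    standardize_affinity,
)
from .alphabet import AMINO_ACIDS
from .metrics import MetricsReport, ScoredLabels, auc as _auc, metrics_report
from .network import BiLSTMNetwork, NetworkConfig
from .substitution import load_substitution_matrix

MODEL_FORMAT_VERSION = 1

#: sigmoid-scale alternative threshold: the 500 nM cutoff after affinity
#: standardization, for models trained in soft-target mode
SOFT_TARGET_THRESHOLD = standardize_affinity(IC50_BINDER_THRESHOLD_NM)


class ModelFileError(ValueError):
    """A model file is missing, corrupted, or from an incompatible version."""


@dataclasses.dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    loss: str = "bce"
    target_mode: str = "binary"        # "binary" | "affinity" (soft targets)
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    early_stop_patience: int = 10
    val_fraction: float = 0.1
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "bce":
            raise ValueError("only binary cross-entropy is supported")
        if self.target_mode not in ("binary", "affinity"):
            raise ValueError(f"unknown target mode {self.target_mode!r}")

    @property
    def default_threshold(self) -> float:
        return 0.5 if self.target_mode == "binary" else SOFT_TARGET_THRESHOLD

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def bce_loss(predicted: float, target: float, eps: float = 1e-12) -> float:
    """Binary cross-entropy for one prediction; supports soft targets.

    Predictions of exactly 0 or 1 are epsilon-clamped so the loss stays
    finite.
    """
    if not 0.0 <= predicted <= 1.0:
        raise ValueError("predicted probability must lie in [0, 1]")
    if not 0.0 <= target <= 1.0:
        raise ValueError("target must lie in [0, 1]")
    p = min(max(predicted, eps), 1.0 - eps)
    return -(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))


@dataclasses.dataclass
class TrainedModel:
    allele: str
    species: str
    mhc_class: str
    network: BiLSTMNetwork
    config: TrainingConfig
    threshold: float
    degenerate: bool = False           # trained on a single-class dataset
    training_log: list[dict] = dataclasses.field(default_factory=list)

    def predict(self, peptides: Sequence[str]) -> np.ndarray:
        return self.network.predict_proba(peptides)

    def predict_one(self, peptide: str) -> float:
        return self.network.forward(peptide)

    def classify(self, peptides: Sequence[str]) -> np.ndarray:
        return (self.predict(peptides) >= self.threshold).astype(int)

    def warn_if_mismatch(self, allele: str | None = None, mhc_class: str | None = None) -> None:
        if allele is not None and allele != self.allele:
            warnings.warn(
                f"model was trained for {self.allele}, queried for {allele}",
                stacklevel=2,
            )
        if mhc_class is not None and mhc_class != self.mhc_class:
            warnings.warn(
                f"model is MHC class {self.mhc_class}, query is class {mhc_class}",
                stacklevel=2,
            )

    def write_training_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\tval_auc\n")
            for row in self.training_log:
                val_auc = row.get("val_auc")
                fh.write(
                    f"{row['epoch']}\t{row['train_loss']:.6f}\t"
                    f"{row['val_loss']:.6f}\t"
                    f"{'NA' if val_auc is None else f'{val_auc:.4f}'}\n"
                )


class Adam:
    """Adaptive moment optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _targets(records: Sequence[PeptideRecord], mode: str) -> np.ndarray:
    if mode == "binary":
        return np.array([float(r.label) for r in records])
    return np.array([float(r.std_affinity) for r in records])


def train_model(
    records: Sequence[PeptideRecord], config: TrainingConfig | None = None
) -> TrainedModel:
    """Train one per-allele model; reproducible under ``config.seed``.

    Records must be curated (derived fields present) and belong to a single
    allele.  A warning is emitted (and the model flagged degenerate) when
    only one class is present.
    """
    config = config or TrainingConfig()
    if len(records) < 2:
        raise ValueError("need at least 2 records to train")
    alleles = {r.allele for r in records}
    if len(alleles) > 1:
        raise ValueError(f"train_model expects a single allele, got {sorted(alleles)}")
    records = [r.with_derived() if r.label is None else r for r in records]

    labels = np.array([r.label for r in records])
    degenerate = len(np.unique(labels)) < 2
    if degenerate:
        warnings.warn("training set contains a single class; model is degenerate",
                      stacklevel=2)

    rng = np.random.default_rng(config.seed)
    substitution = load_substitution_matrix(config.network.substitution_matrix)
    net = BiLSTMNetwork.initialize(config.network, substitution, rng)

    sequences = np.array([r.sequence for r in records], dtype=object)
    targets = _targets(records, config.target_mode)

    # internal validation split for early stopping
    n = len(records)
    n_val = int(round(config.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) < 2 or degenerate:
        val_idx = np.array([], dtype=int)
        train_idx = perm

    optimizer = Adam(net.parameters(), lr=config.learning_rate)
    log: list[dict] = []
    best_val = np.inf
    best_arrays: dict[str, np.ndarray] | None = None
    stall = 0

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grads = net.loss_and_gradients(
                list(sequences[batch]), targets[batch], rng=rng, train=True
            )
            optimizer.step(grads)
            losses.append(loss)
        train_loss = float(np.mean(losses))

        if len(val_idx):
            val_p = net.predict_proba(list(sequences[val_idx]))
            val_t = targets[val_idx]
            val_loss = float(np.mean([bce_loss(p, t) for p, t in zip(val_p, val_t)]))
            val_labels = labels[val_idx]
            val_auc = None
            if len(np.unique(val_labels)) == 2:
                val_auc = _auc(ScoredLabels(val_p, val_labels))
            log.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "val_auc": val_auc})
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_arrays = {k: v.copy() for k, v in net.parameters().items()}
                stall = 0
            else:
                stall += 1
                if stall >= config.early_stop_patience:
                    break
        else:
            log.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": train_loss, "val_auc": None})

    if best_arrays is not None:
        net.set_parameters(best_arrays)

    return TrainedModel(
        allele=records[0].allele,
        species=records[0].species,
        mhc_class=records[0].mhc_class,
        network=net,
        config=config,
        threshold=config.default_threshold,
        degenerate=degenerate,
        training_log=log,
    )


# --- cross-validation ----------------------------------------------------

CLASS_I_STRATA: tuple = (8, 9, 10, 11, "Others")
CLASS_II_STRATA: tuple = (13, 14, 15, 16, 17, 18, 19, 20, "Other")


@dataclasses.dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    per_length: dict[str, MetricsReport]
    folds: FoldAssignment

    def to_table(self) -> str:
        header = ("stratum\taccuracy\tsensitivity\tspecificity\tf1\tmcc\t"
                  "precision\tauc\taupr\tn_positive\tn_negative\n")
        lines = ["overall\t" + _row(self.pooled)]
        for name, rep in self.per_length.items():
            lines.append(f"{name}\t" + _row(rep))
        return header + "\n".join(lines) + "\n"


def _row(rep: MetricsReport) -> str:
    def fmt(v):
        return "NA" if v is None else f"{v:.3f}"
    vals = [fmt(getattr(rep, f)) for f in MetricsReport.FIELDS]
    return "\t".join(vals) + f"\t{rep.n_positive}\t{rep.n_negative}"


def cross_validate(
    records: Sequence[PeptideRecord],
    config: TrainingConfig | None = None,
    k: int = 5,
    seed: int | None = None,
) -> CVResult:
    """k-fold cross-validation of one allele's dataset.

    Trains k models, each on k-1 folds, and scores the held-out fold;
    every record receives exactly one out-of-fold score.  A fold whose
    test split has a single class gets NA for AUC/AUPR in its per-fold
    report (the pooled report is unaffected).
    """
    config = config or TrainingConfig()
    seed = config.seed if seed is None else seed
    records = [r.with_derived() if r.label is None else r for r in records]
    folds = make_folds(records, k=k, seed=seed)

    n = len(records)
    scores = np.full(n, np.nan)
    labels = np.array([r.label for r in records])
    fold_reports: list[MetricsReport] = []

    for i in range(k):
        test_idx = folds.fold(i)
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        fold_config = dataclasses.replace(config, seed=seed + i)
        model = train_model([records[j] for j in train_idx], fold_config)
        fold_scores = model.predict([records[j].sequence for j in test_idx])
        scores[test_idx] = fold_scores
        fold_reports.append(
            metrics_report(
                ScoredLabels(fold_scores, labels[test_idx]), model.threshold
            )
        )

    assert not np.any(np.isnan(scores)), "out-of-fold coverage violated"
    threshold = config.default_threshold
    pooled = metrics_report(ScoredLabels(scores, labels), threshold)

    strata = CLASS_I_STRATA if records[0].mhc_class == "I" else CLASS_II_STRATA
    named = {int(s): str(s) for s in strata if isinstance(s, int)}
    other_name = [s for s in strata if isinstance(s, str)][0]
    per_length: dict[str, MetricsReport] = {}
    lengths = np.array([len(r.sequence) for r in records])
    for stratum in strata:
        if isinstance(stratum, int):
            sel = lengths == stratum
            name = named[stratum]
        else:
            sel = ~np.isin(lengths, [s for s in strata if isinstance(s, int)])
            name = other_name
        if np.any(sel):
            per_length[name] = metrics_report(
                ScoredLabels(scores[sel], labels[sel]), threshold
            )
    return CVResult(
        fold_reports=fold_reports,
        pooled=pooled,
        pooled_scores=scores,
        pooled_labels=labels,
        per_length=per_length,
        folds=folds,
    )


# --- persistence ---------------------------------------------------------

def _checksum(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arrays[key]).tobytes())
    return h.hexdigest()


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file archive: parameter arrays + JSON metadata block."""
    arrays = model.network.parameters()
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "allele": model.allele,
        "species": model.species,
        "mhc_class": model.mhc_class,
        "threshold": model.threshold,
        "degenerate": model.degenerate,
        "aa_ordering": AMINO_ACIDS,
        "substitution_matrix": model.network.evo.init_name,
        "config": model.config.to_dict(),
        "checksum": _checksum(arrays),
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    """Load a saved model; validates version, ordering and checksum."""
    path = Path(path)
    if not path.exists():
        raise ModelFileError(f"no model file at {path}")
    with np.load(path, allow_pickle=False) as data:
        if "__meta__" not in data:
            raise ModelFileError(f"{path} is not a model archive")
        meta = json.loads(str(data["__meta__"]))
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFileError(
            f"unsupported model format version {meta.get('format_version')}"
        )
    if meta.get("aa_ordering") != AMINO_ACIDS:
        raise ModelFileError("model uses a different amino-acid ordering")
    if _checksum(arrays) != meta.get("checksum"):
        raise ModelFileError(f"{path}: checksum mismatch (corrupted file?)")

    cfg_dict = dict(meta["config"])
    net_cfg = NetworkConfig(**cfg_dict.pop("network"))
    config = TrainingConfig(network=net_cfg, **cfg_dict)
    net = BiLSTMNetwork.zeros(net_cfg)
    net.set_parameters(arrays)
    net.evo.init_name = meta["substitution_matrix"]
    return TrainedModel(
        allele=meta["allele"],
        species=meta["species"],
        mhc_class=meta["mhc_class"],
        network=net,
        config=config,
        threshold=float(meta["threshold"]),
        degenerate=bool(meta["degenerate"]),
    )
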