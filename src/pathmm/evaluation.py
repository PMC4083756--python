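"""Classifier evaluation: normalized confusion-matrix statistics, ROC/AUC,
cross-validation, and benchmark tables.

The six summary statistics (accuracy, precision, sensitivity, specificity,
NPV, MCC) are reported on *class-normalized* confusion matrices: each
class is rescaled to unit mass (tp' = sensitivity, fn' = 1 - sensitivity,
fp' = false-positive rate, tn' = 1 - fpr) before the standard formulas are
applied.  Sensitivity and specificity are unchanged by this; accuracy
becomes balanced accuracy and precision/NPV/MCC become independent of the
class imbalance of the benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .profiles import BackgroundComposition, ProfileSet
from .scoring import DEFAULT_THRESHOLD, classify, naive_score, score_dataset
from .variants import DiseaseConcept, MutationDataset, MutationRecord, concept_split
from .weighting import WeightScheme


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion-matrix counts must be non-negative")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_predictions(
        cls, truth: Sequence[bool], predicted: Sequence[bool]
    ) -> "ConfusionMatrix":
        truth = np.asarray(truth, dtype=bool)
        predicted = np.asarray(predicted, dtype=bool)
        if truth.shape != predicted.shape:
            raise EvaluationError("truth/prediction length mismatch")
        return cls(
            tp=int(np.sum(truth & predicted)),
            fp=int(np.sum(~truth & predicted)),
            tn=int(np.sum(~truth & ~predicted)),
            fn=int(np.sum(truth & ~predicted)),
        )


@dataclass(frozen=True)
class PerformanceReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    npv: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "npv": self.npv,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding, matching printed-report conventions."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _six_statistics(tp: float, fp: float, tn: float, fn: float, auc=None) -> PerformanceReport:
    """The standard six formulas applied to (possibly rescaled) cells."""
    denom = math.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    return PerformanceReport(
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        precision=tp / (tp + fp) if tp + fp > 0 else 0.0,
        sensitivity=tp / (tp + fn),
        specificity=tn / (fp + tn),
        npv=tn / (tn + fn) if tn + fn > 0 else 0.0,
        mcc=(tp * tn - fn * fp) / denom if denom > 0 else 0.0,
        auc=auc,
    )


def _require_both_classes(cm: ConfusionMatrix) -> None:
    if cm.tp + cm.fn <= 0:
        raise EvaluationError("no positive examples in confusion matrix")
    if cm.fp + cm.tn <= 0:
        raise EvaluationError("no negative examples in confusion matrix")


def normalized_stats(cm: ConfusionMatrix, auc: float | None = None) -> PerformanceReport:
    """Six statistics on the class-normalized matrix (each class unit mass)."""
    _require_both_classes(cm)
    s = cm.tp / (cm.tp + cm.fn)  # sensitivity
    f = cm.fp / (cm.fp + cm.tn)  # false-positive rate
    return _six_statistics(tp=s, fn=1.0 - s, fp=f, tn=1.0 - f, auc=auc)


def raw_stats(cm: ConfusionMatrix, auc: float | None = None) -> PerformanceReport:
    """Six statistics on the raw counts (class-imbalance sensitive)."""
    _require_both_classes(cm)
    return _six_statistics(cm.tp, cm.fp, cm.tn, cm.fn, auc=auc)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    *,
    lower_is_positive: bool = True,
) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoidal AUC.

    ``labels`` are True for positives.  With ``lower_is_positive`` (the
    default, matching a score where more negative means more damaging),
    the sweep treats smaller scores as stronger positive calls.  Tied
    scores collapse into a single ROC step, so the AUC equals the
    Mann-Whitney concordance probability with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not np.all(np.isfinite(scores)):
        raise EvaluationError("non-finite scores")
    if labels.all() or not labels.any():
        raise EvaluationError("ROC needs both positive and negative examples")
    decision = -scores if lower_is_positive else scores
    fpr, tpr, thresholds = _roc_curve(labels, decision, drop_intermediate=False)
    value = float(_trapezoid_auc(fpr, tpr))
    points = pd.DataFrame(
        {
            "threshold": -thresholds if lower_is_positive else thresholds,
            "fpr": fpr,
            "tpr": tpr,
        }
    )
    return points, value


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_reports: list[PerformanceReport]
    pooled: PerformanceReport
    pooled_cm: ConfusionMatrix
    fold_of_protein: dict[str, int]


def _truth_fn(scheme: WeightScheme) -> Callable[[MutationRecord], bool]:
    """Ground-truth positives under a scheme: concept-tagged records for
    disease-specific runs, all disease records for the inherited scheme."""
    return scheme.is_pathogenic_side


def kfold_cv(
    dataset: MutationDataset,
    profiles: ProfileSet,
    scheme: WeightScheme,
    *,
    background: BackgroundComposition,
    k: int = 20,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    fold_unit: str = "variant",
) -> CVResult:
    """k-fold cross-validation; per fold, weights are recomputed from the
    training folds only, held-out variants are scored with them, and the
    per-fold confusion matrices use class-normalized statistics.

    ``fold_unit`` selects what the seeded shuffle partitions:

    * ``"variant"`` (default) — held-out variants keep weight support from
      the other variants of the same protein, the k-fold generalization of
      leave-one-out.  Because pathogenicity weights are attached to a
      protein's own models, this is the only folding under which weights
      exist for held-out variants at all.
    * ``"protein"`` — whole proteins are held out; their models then carry
      no training counts and their variants are scored on conservation
      alone.  Useful to measure how much of the performance is weights.
    """
    if k < 2:
        raise EvaluationError("k must be at least 2")
    if fold_unit not in ("variant", "protein"):
        raise EvaluationError(f"unknown fold_unit {fold_unit!r}")
    rng = np.random.default_rng(seed)
    if fold_unit == "protein":
        proteins = dataset.protein_ids()
        if k > len(proteins):
            raise EvaluationError(f"k={k} exceeds the {len(proteins)} proteins available")
        order = rng.permutation(len(proteins))
        fold_of_protein = {
            proteins[idx]: fold
            for fold, chunk in enumerate(np.array_split(order, k))
            for idx in chunk
        }
        fold_of = lambda r: fold_of_protein[r.protein_id]  # noqa: E731
    else:
        if k > len(dataset):
            raise EvaluationError(f"k={k} exceeds the {len(dataset)} variants available")
        order = rng.permutation(len(dataset))
        fold_of_key = {
            dataset.records[idx].key: fold
            for fold, chunk in enumerate(np.array_split(order, k))
            for idx in chunk
        }
        fold_of_protein = {}
        fold_of = lambda r: fold_of_key[r.key]  # noqa: E731
    truth = _truth_fn(scheme)

    fold_reports: list[PerformanceReport] = []
    pooled_cm = ConfusionMatrix(0, 0, 0, 0)
    pooled_scores: list[float] = []
    pooled_truth: list[bool] = []
    for fold in range(k):
        test = dataset.subset(lambda r: fold_of(r) == fold)
        train = dataset.subset(lambda r: fold_of(r) != fold)
        scored = score_dataset(
            test,
            profiles,
            scheme,
            background=background,
            training=train,
            loo=False,
            threshold=threshold,
        )
        y = [truth(sv.record) for sv in scored]
        pred = [sv.prediction == "damaging" for sv in scored]
        cm = ConfusionMatrix.from_predictions(y, pred)
        pooled_cm = pooled_cm + cm
        pooled_scores.extend(sv.score for sv in scored)
        pooled_truth.extend(y)
        if cm.tp + cm.fn > 0 and cm.fp + cm.tn > 0:
            fold_reports.append(normalized_stats(cm))
    _, pooled_auc = roc_auc(pooled_scores, pooled_truth)
    return CVResult(
        fold_reports=fold_reports,
        pooled=normalized_stats(pooled_cm, auc=pooled_auc),
        pooled_cm=pooled_cm,
        fold_of_protein=fold_of_protein,
    )


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

BENCHMARK_COLUMNS = [
    "algorithm",
    "tp",
    "fp",
    "tn",
    "fn",
    "accuracy",
    "precision",
    "specificity",
    "sensitivity",
    "npv",
    "mcc",
    "auc",
]


def benchmark(
    dataset: MutationDataset,
    profiles: ProfileSet,
    concept: DiseaseConcept,
    *,
    background: BackgroundComposition,
    threshold: float = DEFAULT_THRESHOLD,
    loo: bool = True,
    external_scores: dict[str, dict[tuple, float]] | None = None,
) -> pd.DataFrame:
    """Concept-vs-rest benchmark of the weighted score and the naive
    weights-only baseline, one row per method.

    Positives are records tagged with ``concept``; negatives are all other
    records (other diseases' variants count as neutral).  Rows carry raw
    confusion counts at ``threshold`` plus normalized statistics and AUC.
    ``external_scores`` adds rows for precomputed per-variant scores keyed
    by ``record.key`` (lower = more damaging).
    """
    positives, _ = concept_split(dataset, concept)
    if not positives:
        raise EvaluationError(f"no variants tagged {concept.value}")
    scheme = WeightScheme.disease_specific(concept)
    scored = score_dataset(
        dataset, profiles, scheme, background=background, loo=loo, threshold=threshold
    )
    truth = [concept in sv.record.concepts for sv in scored]

    methods: dict[str, list[float]] = {
        "weighted": [sv.score for sv in scored],
        "naive": [naive_score(sv.inputs.wd, sv.inputs.wn) for sv in scored],
    }
    for name, table in (external_scores or {}).items():
        try:
            methods[name] = [table[sv.record.key] for sv in scored]
        except KeyError as exc:
            raise EvaluationError(f"external method {name!r} misses variant {exc}") from exc

    rows = []
    for name, scores in methods.items():
        pred = [classify(s, threshold) == "damaging" for s in scores]
        cm = ConfusionMatrix.from_predictions(truth, pred)
        _, method_auc = roc_auc(scores, truth)
        stats = normalized_stats(cm, auc=method_auc)
        rows.append(
            {
                "algorithm": name,
                "tp": int(cm.tp),
                "fp": int(cm.fp),
                "tn": int(cm.tn),
                "fn": int(cm.fn),
                **{k: round_half_up(v) for k, v in stats.as_dict().items()},
            }
        )
    return pd.DataFrame(rows, columns=BENCHMARK_COLUMNS)


# ---------------------------------------------------------------------------
# Published benchmark fixtures
# ---------------------------------------------------------------------------

_PUBLISHED = "table1_confusion.tsv"


def load_published_benchmarks() -> pd.DataFrame:
    """The packaged published benchmark: 16 confusion matrices (four disease
    concepts x four methods) with the printed normalized statistics."""
    with resources.files("pathmm.data").joinpath(_PUBLISHED).open() as fh:
        return pd.read_csv(fh, sep="\t")


STAT_NAMES = ["accuracy", "precision", "specificity", "sensitivity", "npv", "mcc"]


def recompute_published_stats(published: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute the six normalized statistics for every packaged confusion
    matrix and compare with the printed values at two decimal places.

    Returns the fixture with ``<stat>_recomputed`` columns and a boolean
    ``all_match`` per row.  AUC is not recomputable from counts alone and
    is carried through untouched.
    """
    df = (published if published is not None else load_published_benchmarks()).copy()
    recomputed = []
    for row in df.itertuples(index=False):
        cm = ConfusionMatrix(tp=row.tp, fp=row.fp, tn=row.tn, fn=row.fn)
        stats = normalized_stats(cm)
        recomputed.append({f"{k}_recomputed": round_half_up(v) for k, v in stats.as_dict().items()})
    rec = pd.DataFrame(recomputed)
    out = pd.concat([df.reset_index(drop=True), rec], axis=1)
    out["all_match"] = np.all(
        [out[f"{s}_recomputed"] == out[s] for s in STAT_NAMES], axis=0
    )
    return out
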