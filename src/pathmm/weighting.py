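"""Pathogenicity weights: per-model relative frequencies of pathogenic-
versus neutral-side training substitutions.

Each profile model (a protein's ab initio HMM or one of its domains)
accumulates two counts from the training variants mapping onto it: d, the
pathogenic side, and n, the neutral side.  Which side a variant lands on
depends on the weighting scheme:

* ``inherited`` — every disease-labelled variant is pathogenic-side,
  every neutral polymorphism neutral-side;
* ``disease_specific`` — only variants tagged with the chosen concept are
  pathogenic-side; other diseases' variants join the neutral side.

Weights are the in-model relative frequencies Wd = d/(d+n), Wn = n/(d+n);
they enter the score through (W + 1) factors, so a model with no training
data (Wd = Wn = 0) degrades the score to pure conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Callable, Mapping, Sequence

import pandas as pd

from .variants import DiseaseConcept, MutationDataset, MutationRecord


class WeightingError(ValueError):
    pass


class UnresolvableVariantError(WeightingError):
    """Training variants that map onto no model."""

    def __init__(self, records: list[MutationRecord]):
        self.records = records
        listing = ", ".join(f"{r.protein_id} {r.substitution}" for r in records[:10])
        more = "" if len(records) <= 10 else f" (+{len(records) - 10} more)"
        super().__init__(f"{len(records)} variant(s) map onto no model: {listing}{more}")


@dataclass(frozen=True)
class WeightScheme:
    """Inherited-disease or disease-specific weighting."""

    kind: str  # "inherited" | "disease_specific"
    concept: DiseaseConcept | None = None

    def __post_init__(self):
        if self.kind not in ("inherited", "disease_specific"):
            raise WeightingError(f"unknown scheme kind {self.kind!r}")
        if (self.kind == "disease_specific") != (self.concept is not None):
            raise WeightingError("concept is required exactly for disease_specific schemes")

    @classmethod
    def inherited(cls) -> "WeightScheme":
        return cls("inherited")

    @classmethod
    def disease_specific(cls, concept: DiseaseConcept | str) -> "WeightScheme":
        if isinstance(concept, str):
            concept = DiseaseConcept.parse(concept)
        return cls("disease_specific", concept)

    def is_pathogenic_side(self, record: MutationRecord) -> bool:
        """Whether a record increments the d (pathogenic) count."""
        if self.kind == "inherited":
            return record.is_disease
        return self.concept in record.concepts

    def __str__(self) -> str:
        if self.kind == "inherited":
            return "inherited"
        return f"disease_specific({self.concept.value})"


@dataclass(frozen=True)
class ModelCounts:
    model_id: str
    d_count: int = 0
    n_count: int = 0

    def __post_init__(self):
        if self.d_count < 0 or self.n_count < 0:
            raise WeightingError(f"negative count for model {self.model_id}")

    @property
    def total(self) -> int:
        return self.d_count + self.n_count


@dataclass(frozen=True)
class PathogenicityWeights:
    """Per-model (Wd, Wn); both zero when the model has no training data."""

    model_id: str
    wd: float
    wn: float

    def __post_init__(self):
        if not (0.0 <= self.wd <= 1.0 and 0.0 <= self.wn <= 1.0):
            raise WeightingError(f"weights outside [0, 1] for model {self.model_id}")


ModelIndex = Callable[[MutationRecord], Sequence[str]]


def count_mappings(
    dataset: MutationDataset,
    scheme: WeightScheme,
    model_index: ModelIndex | Mapping[tuple[str, object], Sequence[str]],
) -> dict[str, ModelCounts]:
    """Accumulate per-model (d, n) counts for a training dataset.

    ``model_index`` resolves a record to every model id covering its
    position (a callable, or a mapping keyed by ``record.key``).  A variant
    increments the counts of each covering model.
    """
    if not callable(model_index):
        mapping = model_index
        model_index = lambda rec: mapping.get(rec.key, ())  # noqa: E731
    d: dict[str, int] = {}
    n: dict[str, int] = {}
    unresolved: list[MutationRecord] = []
    for rec in dataset:
        model_ids = list(model_index(rec))
        if not model_ids:
            unresolved.append(rec)
            continue
        side = d if scheme.is_pathogenic_side(rec) else n
        for mid in model_ids:
            side[mid] = side.get(mid, 0) + 1
    if unresolved:
        raise UnresolvableVariantError(unresolved)
    return {
        mid: ModelCounts(mid, d.get(mid, 0), n.get(mid, 0))
        for mid in sorted(set(d) | set(n))
    }


def weights_from_counts(counts: ModelCounts) -> PathogenicityWeights:
    """Wd = d/(d+n), Wn = n/(d+n); (0, 0) when the model saw no variants."""
    if counts.total == 0:
        return PathogenicityWeights(counts.model_id, 0.0, 0.0)
    return PathogenicityWeights(
        counts.model_id,
        counts.d_count / counts.total,
        counts.n_count / counts.total,
    )


def loo_adjust(
    counts: ModelCounts, record: MutationRecord, scheme: WeightScheme
) -> ModelCounts:
    """Remove a training variant's own unit contribution from the counts.

    Used when scoring a variant that is part of the training set, so its
    own label does not inform its weights (leave-one-out).
    """
    if scheme.is_pathogenic_side(record):
        if counts.d_count < 1:
            raise WeightingError(
                f"cannot remove {record.protein_id} {record.substitution} from "
                f"model {counts.model_id}: d_count is 0"
            )
        return replace(counts, d_count=counts.d_count - 1)
    if counts.n_count < 1:
        raise WeightingError(
            f"cannot remove {record.protein_id} {record.substitution} from "
            f"model {counts.model_id}: n_count is 0"
        )
    return replace(counts, n_count=counts.n_count - 1)


WEIGHTS_COLUMNS = ["model_id", "source", "d_count", "n_count", "Wd", "Wn"]


def write_weights_table(
    counts: Mapping[str, ModelCounts],
    stream: IO[str] | str | Path,
    sources: Mapping[str, str] | None = None,
) -> None:
    """Serialize counts and derived weights as TSV, model_id ascending."""
    rows = []
    for mid in sorted(counts):
        c = counts[mid]
        w = weights_from_counts(c)
        rows.append(
            {
                "model_id": mid,
                "source": (sources or {}).get(mid, ""),
                "d_count": c.d_count,
                "n_count": c.n_count,
                "Wd": f"{w.wd:.6g}",
                "Wn": f"{w.wn:.6g}",
            }
        )
    pd.DataFrame(rows, columns=WEIGHTS_COLUMNS).to_csv(stream, sep="\t", index=False)


def read_weights_table(stream: IO[str] | str | Path) -> dict[str, ModelCounts]:
    df = pd.read_csv(stream, sep="\t", dtype={"model_id": str})
    missing = [c for c in ("model_id", "d_count", "n_count") if c not in df.columns]
    if missing:
        raise WeightingError(f"weights table missing columns: {missing}")
    return {
        row.model_id: ModelCounts(row.model_id, int(row.d_count), int(row.n_count))
        for row in df.itertuples(index=False)
    }
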