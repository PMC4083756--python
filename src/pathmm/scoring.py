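"""The weighted conservation score and the per-variant scoring pipeline.

The score of a substitution is

    score = ln[ ((1 - Pw) * (Wn + 1)) / ((1 - Pm) * (Wd + 1)) ]

where Pw and Pm are the probabilities of the wild-type and mutant residues
at the match state of the most informative model covering the position,
and (Wd, Wn) are that model's pathogenicity weights.  High wild-type
conservation (Pw near 1) and a high pathogenic weight both push the score
down; scores below the threshold (default 0) are predicted damaging.

The naive baseline ln((Wn + 1)/(Wd + 1)) drops conservation entirely:
every variant on a model shares one score, so models dominated by
pathogenic-side training variants predict all their variants as damaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd

from .profiles import (
    BackgroundComposition,
    EMISSION_FLOOR,
    ModelSource,
    ProfileSet,
    kl_divergence,
    select_informative_model,
)
from .variants import MutationDataset, MutationRecord
from .weighting import (
    ModelCounts,
    WeightScheme,
    count_mappings,
    loo_adjust,
    weights_from_counts,
)

#: Floor for (1 - P) factors so the log ratio is finite even at P = 1.
SURVIVAL_FLOOR = 1e-9

#: Default decision threshold: the natural sign boundary of the log ratio.
DEFAULT_THRESHOLD = 0.0

DAMAGING = "damaging"
TOLERATED = "tolerated"


@dataclass(frozen=True)
class ScoringInputs:
    """The four quantities entering the weighted score."""

    pw: float
    pm: float
    wd: float
    wn: float

    def __post_init__(self):
        for name, p in (("pw", self.pw), ("pm", self.pm)):
            if not (EMISSION_FLOOR <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [{EMISSION_FLOOR}, 1]")
        for name, w in (("wd", self.wd), ("wn", self.wn)):
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"{name}={w} outside [0, 1]")


def weighted_score(pw: float, pm: float, wd: float = 0.0, wn: float = 0.0) -> float:
    """ln(((1-Pw)(Wn+1)) / ((1-Pm)(Wd+1))), with (1-P) floored at 1e-9."""
    num = max(1.0 - pw, SURVIVAL_FLOOR) * (wn + 1.0)
    den = max(1.0 - pm, SURVIVAL_FLOOR) * (wd + 1.0)
    return math.log(num / den)


def naive_score(wd: float, wn: float) -> float:
    """Weights-only baseline ln((Wn+1)/(Wd+1)); conservation omitted."""
    return math.log((wn + 1.0) / (wd + 1.0))


def classify(score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Damaging iff score < threshold; a boundary score is tolerated."""
    return DAMAGING if score < threshold else TOLERATED


@dataclass(frozen=True)
class ScoredVariant:
    """Full trace of one variant through the scoring pipeline."""

    record: MutationRecord
    model_id: str
    source: ModelSource
    state: int
    inputs: ScoringInputs
    informativeness: float  # KL of the chosen state vs background, nats
    score: float
    prediction: str
    warnings: tuple[str, ...] = ()


def score_variant(
    record: MutationRecord,
    profiles: ProfileSet,
    counts: Mapping[str, ModelCounts],
    scheme: WeightScheme,
    *,
    background: BackgroundComposition,
    loo: bool = False,
    threshold: float = DEFAULT_THRESHOLD,
) -> ScoredVariant:
    """Score one variant end to end.

    Pipeline: gather covering models -> pick the most informative state ->
    read Pw/Pm from its emissions -> fetch the model's weights, removing
    the variant's own count first when ``loo`` is set (the record must then
    be part of the counted training set) -> weighted score -> classify.

    A mismatch between the record's wild-type residue and the chosen
    state's dominant residue is recorded as a warning, not an error.
    """
    candidates = profiles.candidates(record.protein_id, record.substitution.position)
    chosen = select_informative_model(candidates, background)
    emission = chosen.model.emission(chosen.state)
    pw = max(emission[record.substitution.wildtype], EMISSION_FLOOR)
    pm = max(emission[record.substitution.mutant], EMISSION_FLOOR)

    model_counts = counts.get(chosen.model.model_id, ModelCounts(chosen.model.model_id))
    if loo and model_counts.total > 0:
        model_counts = loo_adjust(model_counts, record, scheme)
    weights = weights_from_counts(model_counts)

    inputs = ScoringInputs(pw=pw, pm=pm, wd=weights.wd, wn=weights.wn)
    score = weighted_score(inputs.pw, inputs.pm, inputs.wd, inputs.wn)
    warnings = []
    dominant = emission.dominant()
    if dominant != record.substitution.wildtype:
        warnings.append(
            f"wild-type {record.substitution.wildtype} is not the dominant residue "
            f"({dominant}) of model {chosen.model.model_id} state {chosen.state}"
        )
    return ScoredVariant(
        record=record,
        model_id=chosen.model.model_id,
        source=chosen.model.source,
        state=chosen.state,
        inputs=inputs,
        informativeness=kl_divergence(emission, background),
        score=score,
        prediction=classify(score, threshold),
        warnings=tuple(warnings),
    )


def score_dataset(
    dataset: MutationDataset,
    profiles: ProfileSet,
    scheme: WeightScheme,
    *,
    background: BackgroundComposition,
    training: MutationDataset | None = None,
    loo: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ScoredVariant]:
    """Score every record of ``dataset``.

    Weights are counted from ``training`` (default: the dataset itself).
    With ``loo`` set, a scored record that belongs to the training set has
    its own contribution removed before its weights are formed; records
    outside the training set are scored with the weights as-is.
    """
    training = training if training is not None else dataset
    counts = count_mappings(
        training,
        scheme,
        lambda rec: profiles.model_ids_covering(rec.protein_id, rec.substitution.position),
    )
    out = []
    for rec in dataset:
        out.append(
            score_variant(
                rec,
                profiles,
                counts,
                scheme,
                background=background,
                loo=loo and rec in training,
                threshold=threshold,
            )
        )
    return out


SCORE_COLUMNS = [
    "protein_id",
    "substitution",
    "model_id",
    "source",
    "state",
    "Pw",
    "Pm",
    "Wd",
    "Wn",
    "informativeness",
    "score",
    "prediction",
    "warnings",
]


def scores_to_frame(scored: Iterable[ScoredVariant]) -> pd.DataFrame:
    """Tabulate scored variants, sorted ascending by score (most damaging
    first) so the table doubles as a prioritization ranking."""
    rows = [
        {
            "protein_id": sv.record.protein_id,
            "substitution": str(sv.record.substitution),
            "model_id": sv.model_id,
            "source": sv.source.value,
            "state": sv.state,
            "Pw": float(f"{sv.inputs.pw:.6g}"),
            "Pm": float(f"{sv.inputs.pm:.6g}"),
            "Wd": float(f"{sv.inputs.wd:.6g}"),
            "Wn": float(f"{sv.inputs.wn:.6g}"),
            "informativeness": float(f"{sv.informativeness:.6g}"),
            "score": float(f"{sv.score:.6g}"),
            "prediction": sv.prediction,
            "warnings": " | ".join(sv.warnings),
        }
        for sv in scored
    ]
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return df.sort_values(["score", "protein_id", "substitution"], kind="mergesort").reset_index(
        drop=True
    )


def write_score_table(scored: Iterable[ScoredVariant], stream: IO[str] | str) -> None:
    scores_to_frame(scored).to_csv(stream, sep="\t", index=False)
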