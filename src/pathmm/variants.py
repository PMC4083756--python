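"""Amino-acid substitutions, disease-concept labels, and variant tables.

Variants are protein-level missense substitutions (for example R175H),
each labelled pathogenic ("disease") or "neutral".  Pathogenic variants
carry one or more root disease-concept tags drawn from a closed vocabulary
of 17 phenotype categories; a disease-specific analysis splits a dataset
into variants tagged with one concept versus everything else, treating
other diseases' variants as neutral for that concept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1

from .profiles import AMINO_ACIDS


class VariantError(ValueError):
    """Invalid substitution token or variant record."""


class ValidationError(VariantError):
    """One or more invalid rows in a variant table."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {msg}" for r, msg in problems)
        super().__init__(f"{len(problems)} invalid variant row(s): {lines}")


class DiseaseConcept(str, Enum):
    """The 17 root disease concepts used for disease-specific weighting."""

    BLOOD = "blood"
    BLOOD_COAGULATION = "blood_coagulation"
    DEVELOPMENTAL = "developmental"
    DIGESTIVE = "digestive"
    EAR_NOSE_THROAT = "ear_nose_throat"
    ENDOCRINE = "endocrine"
    EYE = "eye"
    GENITOURINARY = "genitourinary"
    HEART = "heart"
    IMMUNE = "immune"
    METABOLIC = "metabolic"
    MUSCULOSKELETAL = "musculoskeletal"
    NERVOUS_SYSTEM = "nervous_system"
    PSYCHIATRIC = "psychiatric"
    REPRODUCTIVE = "reproductive"
    RESPIRATORY = "respiratory"
    SKIN = "skin"

    @classmethod
    def parse(cls, name: str) -> "DiseaseConcept":
        try:
            return cls(name.strip().lower())
        except ValueError:
            raise VariantError(
                f"unknown disease concept {name!r} (expected one of "
                f"{', '.join(c.value for c in cls)})"
            ) from None


_SUB_1 = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")
_SUB_3 = re.compile(r"^(?:p\.)?([A-Za-z]{3})(\d+)([A-Za-z]{3})$")
_3TO1 = {k.lower(): v for k, v in protein_letters_3to1.items()}


@dataclass(frozen=True, order=True)
class Substitution:
    """A single amino-acid substitution in one-letter code, 1-based."""

    wildtype: str
    position: int
    mutant: str

    def __post_init__(self):
        for aa in (self.wildtype, self.mutant):
            if aa not in AMINO_ACIDS:
                raise VariantError(f"non-canonical amino acid {aa!r}")
        if self.wildtype == self.mutant:
            raise VariantError(f"synonymous substitution {self}")
        if self.position < 1:
            raise VariantError(f"non-positive residue position {self.position}")

    def __str__(self) -> str:
        return f"{self.wildtype}{self.position}{self.mutant}"


def parse_substitution(token: str) -> Substitution:
    """Parse ``R175H`` / ``p.G12D`` / ``p.Arg175His`` into a Substitution.

    Input is case-insensitive; three-letter codes are normalized to the
    one-letter representation.
    """
    token = token.strip()
    m = _SUB_1.match(token)
    if m:
        return Substitution(m.group(1).upper(), int(m.group(2)), m.group(3).upper())
    m = _SUB_3.match(token)
    if m:
        try:
            wt = _3TO1[m.group(1).lower()]
            mut = _3TO1[m.group(3).lower()]
        except KeyError as exc:
            raise VariantError(f"unknown three-letter code in {token!r}") from exc
        return Substitution(wt, int(m.group(2)), mut)
    raise VariantError(f"malformed substitution token {token!r}")


@dataclass(frozen=True)
class MutationRecord:
    """One labelled substitution on a protein.

    Disease records carry at least one concept tag; neutral records carry
    none.
    """

    protein_id: str
    substitution: Substitution
    label: str  # "disease" | "neutral"
    concepts: frozenset[DiseaseConcept] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.label not in ("disease", "neutral"):
            raise VariantError(f"label must be 'disease' or 'neutral', got {self.label!r}")
        object.__setattr__(self, "concepts", frozenset(self.concepts))
        if self.label == "neutral" and self.concepts:
            raise VariantError(
                f"{self.protein_id} {self.substitution}: neutral record with concept tags"
            )
        if self.label == "disease" and not self.concepts:
            raise VariantError(
                f"{self.protein_id} {self.substitution}: disease record without concepts"
            )

    @property
    def key(self) -> tuple[str, Substitution]:
        return (self.protein_id, self.substitution)

    @property
    def is_disease(self) -> bool:
        return self.label == "disease"


class MutationDataset:
    """An ordered collection of unique (protein, substitution) records."""

    def __init__(self, records: Iterable[MutationRecord]):
        self.records: list[MutationRecord] = list(records)
        seen: set[tuple[str, Substitution]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise VariantError(f"duplicate variant {rec.protein_id} {rec.substitution}")
            seen.add(rec.key)
        self._keys = seen

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    def __contains__(self, record: MutationRecord) -> bool:
        return record.key in self._keys

    def protein_ids(self) -> list[str]:
        return sorted({r.protein_id for r in self.records})

    def subset(self, keep) -> "MutationDataset":
        return MutationDataset(r for r in self.records if keep(r))

    def without(self, record: MutationRecord) -> "MutationDataset":
        return MutationDataset(r for r in self.records if r.key != record.key)


VARIANT_COLUMNS = ["protein_id", "substitution", "label", "concepts"]


def read_variant_table(stream: IO[str] | str | Path) -> MutationDataset:
    """Read a variant TSV (protein_id, substitution, label, concepts).

    ``concepts`` is a semicolon-separated list, empty for neutral rows.
    All invalid rows are collected into one :class:`ValidationError`.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise VariantError(f"variant table missing columns: {missing}")
    records: list[MutationRecord] = []
    problems: list[tuple[int, str]] = []
    seen: set[tuple[str, Substitution]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            sub = parse_substitution(row.substitution)
            concepts = frozenset(
                DiseaseConcept.parse(c) for c in row.concepts.split(";") if c.strip()
            )
            rec = MutationRecord(row.protein_id, sub, row.label.strip().lower(), concepts)
            if rec.key in seen:
                raise VariantError(f"duplicate variant {rec.protein_id} {sub}")
            seen.add(rec.key)
            records.append(rec)
        except VariantError as exc:
            problems.append((i, str(exc)))
    if problems:
        raise ValidationError(problems)
    return MutationDataset(records)


def write_variant_table(dataset: MutationDataset, stream: IO[str] | str | Path) -> None:
    rows = [
        {
            "protein_id": r.protein_id,
            "substitution": str(r.substitution),
            "label": r.label,
            "concepts": ";".join(sorted(c.value for c in r.concepts)),
        }
        for r in dataset
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(stream, sep="\t", index=False)


def concept_split(
    dataset: MutationDataset, concept: DiseaseConcept
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Split into (concept-tagged positives, everything else).

    Negatives include both neutral polymorphisms and disease variants of
    other concepts: for a disease-specific question the latter count as
    neutral.
    """
    positives = [r for r in dataset if concept in r.concepts]
    negatives = [r for r in dataset if concept not in r.concepts]
    return positives, negatives


def check_wildtype_consistency(
    dataset: MutationDataset, sequences: dict[str, str]
) -> list[str]:
    """Compare each record's wild-type residue with a protein sequence.

    Returns warning strings for mismatches and out-of-range positions;
    proteins absent from ``sequences`` are skipped.
    """
    warnings: list[str] = []
    for rec in dataset:
        seq = sequences.get(rec.protein_id)
        if seq is None:
            continue
        pos = rec.substitution.position
        if pos > len(seq):
            warnings.append(
                f"{rec.protein_id} {rec.substitution}: position beyond sequence "
                f"length {len(seq)}"
            )
        elif seq[pos - 1].upper() != rec.substitution.wildtype:
            warnings.append(
                f"{rec.protein_id} {rec.substitution}: sequence has "
                f"{seq[pos - 1].upper()} at position {pos}"
            )
    return warnings
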