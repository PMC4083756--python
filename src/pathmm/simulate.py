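"""Seeded synthetic fixtures: profiles, domain annotations, and
concept-labelled mutation datasets with a planted disease-specific signal.

The generator emulates the shape of a disease-specific training corpus:

* per protein, an ab initio profile with Dirichlet-sampled match-state
  emissions (one scalar, ``sharpness``, controls how conserved states are)
  and a few non-overlapping domain models;
* disjoint sets of "susceptible" proteins designated per disease concept;
* concept-tagged pathogenic variants planted preferentially (probability
  ``weight_bias``) in their concept's susceptible proteins, at conserved
  positions, mutating to a rare residue;
* neutral polymorphisms placed uniformly across proteins, biased toward
  diverse (low-divergence) positions, mutating to a commonly observed
  alternative residue.

With ``weight_bias`` high the disease-specific weights carry real signal;
with ``weight_bias = 0`` placement is uniform, weights are balanced across
models, and only conservation separates pathogenic from neutral variants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiles import (
    AMINO_ACIDS,
    AminoAcidDistribution,
    BackgroundComposition,
    ModelSource,
    ProfileHMM,
    ProfileSet,
    annotate_domain,
    kl_divergence,
    select_informative_model,
    write_hmmer3_profile,
)
from .variants import (
    DiseaseConcept,
    MutationDataset,
    MutationRecord,
    Substitution,
    write_variant_table,
)

_DOMAIN_SOURCES = (ModelSource.PFAM_A, ModelSource.SUPERFAMILY, ModelSource.PFAM_B)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    """Generator settings; identical configs yield bit-identical fixtures."""

    seed: int = 0
    n_proteins: int = 40
    protein_length: tuple[int, int] = (80, 200)
    n_domains: tuple[int, int] = (0, 3)
    #: Conservation sharpness: emissions ~ Dirichlet(1/sharpness per residue),
    #: so larger values give peakier (more conserved) match states.
    sharpness: float = 2.0
    concepts: tuple[str, ...] = (
        "musculoskeletal",
        "metabolic",
        "endocrine",
        "developmental",
    )
    n_concept: int = 300
    n_other: int = 300
    n_neutral: int = 600
    #: Probability a pathogenic variant is planted inside its concept's
    #: susceptible proteins; 0 means uniform placement (no planted signal).
    weight_bias: float = 0.9
    background: BackgroundComposition = field(
        default_factory=BackgroundComposition.uniform
    )

    def __post_init__(self):
        if not self.concepts:
            raise FixtureError("at least one concept is required")
        if not (0.0 <= self.weight_bias <= 1.0):
            raise FixtureError("weight_bias must be in [0, 1]")
        if self.sharpness <= 0:
            raise FixtureError("sharpness must be positive")
        object.__setattr__(
            self, "concepts", tuple(DiseaseConcept.parse(c).value for c in self.concepts)
        )

    @property
    def focal_concept(self) -> DiseaseConcept:
        return DiseaseConcept(self.concepts[0])


@dataclass
class Fixture:
    config: FixtureConfig
    profiles: ProfileSet
    annotations: pd.DataFrame
    sequences: dict[str, str]
    dataset: MutationDataset
    #: Planted truth: susceptible protein ids per concept.
    susceptible: dict[DiseaseConcept, set[str]]


def _sample_emissions(rng: np.random.Generator, length: int, sharpness: float) -> tuple:
    alpha = np.full(20, 1.0 / sharpness)
    rows = rng.dirichlet(alpha, size=length)
    rows = np.maximum(rows, 1e-9)
    rows /= rows.sum(axis=1, keepdims=True)
    return tuple(AminoAcidDistribution(r) for r in rows)


def generate_profiles(
    config: FixtureConfig, rng: np.random.Generator | None = None
) -> tuple[ProfileSet, pd.DataFrame, dict[str, str]]:
    """Sample ab initio and domain profiles; return the profile set, the
    domain annotation table, and per-protein consensus sequences.

    The consensus residue at each position is the dominant residue of the
    most informative covering model, so it agrees with what the scoring
    pipeline will treat as the conserved wild type.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pset = ProfileSet()
    ann_rows = []
    lo, hi = config.protein_length
    dlo, dhi = config.n_domains
    domain_serial = 0
    for p in range(config.n_proteins):
        pid = f"P{p + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        ab = ProfileHMM(
            model_id=pid,
            source=ModelSource.AB_INITIO,
            length=length,
            emissions=_sample_emissions(rng, length, config.sharpness),
            residue_map={i: i for i in range(1, length + 1)},
        )
        pset.add_protein(pid, ab)
        n_dom = int(rng.integers(dlo, dhi + 1))
        taken: list[tuple[int, int]] = []
        for d in range(n_dom):
            span = int(rng.integers(15, 41))
            # sample a start uniformly over the positions where the domain
            # fits without overlapping an already-placed one
            starts = [
                s
                for s in range(1, length - span + 2)
                if all(s + span - 1 < a or s > b for a, b in taken)
            ]
            if not starts:
                if d < dlo:
                    raise FixtureError(
                        f"cannot pack {dlo} domains into protein {pid} "
                        f"(length {length}); no gap fits span {span}"
                    )
                break  # optional domain; protein is saturated
            start = starts[int(rng.integers(len(starts)))]
            end = start + span - 1
            taken.append((start, end))
            domain_serial += 1
            did = f"D{domain_serial:04d}"
            source = _DOMAIN_SOURCES[int(rng.integers(len(_DOMAIN_SOURCES)))]
            dom = ProfileHMM(
                model_id=did,
                source=source,
                length=span,
                emissions=_sample_emissions(rng, span, config.sharpness),
                residue_map={},
            )
            pset.add_domain(pid, annotate_domain(dom, start, end, 1))
            ann_rows.append(
                {
                    "protein_id": pid,
                    "model_id": did,
                    "source": source.value,
                    "start": start,
                    "end": end,
                    "model_start": 1,
                }
            )
    annotations = pd.DataFrame(
        ann_rows,
        columns=["protein_id", "model_id", "source", "start", "end", "model_start"],
    )
    sequences = {
        pid: _consensus_sequence(pset, pid, config.background)
        for pid in pset.protein_ids()
    }
    return pset, annotations, sequences


def _consensus_sequence(pset: ProfileSet, pid: str, background: BackgroundComposition) -> str:
    length = pset.models_for(pid).ab_initio.length
    out = []
    for pos in range(1, length + 1):
        chosen = select_informative_model(pset.candidates(pid, pos), background)
        out.append(chosen.model.emission(chosen.state).dominant())
    return "".join(out)


def designate_susceptible(config: FixtureConfig) -> dict[DiseaseConcept, set[str]]:
    """Split proteins into disjoint susceptible blocks, one per concept,
    leaving one block unassigned (hosting mostly neutral variation)."""
    groups = len(config.concepts) + 1
    if config.n_proteins < groups:
        raise FixtureError(
            f"{config.n_proteins} proteins cannot host {len(config.concepts)} "
            "disjoint susceptible sets"
        )
    ids = [f"P{p + 1:04d}" for p in range(config.n_proteins)]
    blocks = np.array_split(np.arange(config.n_proteins), groups)
    return {
        DiseaseConcept(c): {ids[i] for i in blocks[j]}
        for j, c in enumerate(config.concepts)
    }


def generate_mutations(
    config: FixtureConfig,
    profiles: ProfileSet,
    susceptible: dict[DiseaseConcept, set[str]],
    rng: np.random.Generator | None = None,
) -> MutationDataset:
    """Plant concept, other-disease, and neutral variants onto the profiles."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    background = config.background
    protein_ids = profiles.protein_ids()

    # Per-protein caches: the informative covering emission and its KL at
    # every position (this is what scoring will see).
    emissions: dict[str, list[AminoAcidDistribution]] = {}
    kls: dict[str, np.ndarray] = {}
    for pid in protein_ids:
        length = profiles.models_for(pid).ab_initio.length
        ems, kl = [], np.empty(length)
        for pos in range(1, length + 1):
            chosen = select_informative_model(profiles.candidates(pid, pos), background)
            em = chosen.model.emission(chosen.state)
            ems.append(em)
            kl[pos - 1] = kl_divergence(em, background)
        emissions[pid] = ems
        kls[pid] = kl

    used: set[tuple[str, Substitution]] = set()
    records: list[MutationRecord] = []

    def pick_protein(target: set[str] | None) -> str:
        if target is not None and rng.random() < config.weight_bias:
            pool = sorted(target)
        else:
            pool = protein_ids
        return pool[int(rng.integers(len(pool)))]

    def place(
        n: int, label: str, concept_of: "callable", target_of: "callable"
    ) -> None:
        for i in range(n):
            concepts = concept_of(i)
            target = target_of(concepts)
            for _attempt in range(400):
                pid = pick_protein(target)
                kl = kls[pid]
                if label == "disease":
                    w = kl + 1e-9  # favour conserved positions
                else:
                    w = np.exp(-kl)  # favour diverse positions
                w = w / w.sum()
                pos = int(rng.choice(len(kl), p=w)) + 1
                em = emissions[pid][pos - 1]
                probs = em.as_array()
                wt_idx = int(np.argmax(probs))
                wt = AMINO_ACIDS[wt_idx]
                if label == "disease":
                    # least-observed residue: strongly disfavoured by the model
                    order = np.argsort(probs)
                    mut_idx = int(order[0]) if order[0] != wt_idx else int(order[1])
                else:
                    # a residue the model itself commonly emits
                    alt = probs.copy()
                    alt[wt_idx] = 0.0
                    alt = alt / alt.sum()
                    mut_idx = int(rng.choice(20, p=alt))
                sub = Substitution(wt, pos, AMINO_ACIDS[mut_idx])
                if (pid, sub) in used:
                    continue
                used.add((pid, sub))
                records.append(
                    MutationRecord(pid, sub, label, frozenset(concepts))
                )
                break
            else:
                raise FixtureError(
                    f"could not place {label} variant {i + 1}/{n}: position space "
                    "exhausted; reduce variant counts or enlarge proteins"
                )

    focal = config.focal_concept
    others = [DiseaseConcept(c) for c in config.concepts[1:]]

    place(
        config.n_concept,
        "disease",
        lambda i: {focal},
        lambda cs: susceptible[focal],
    )
    if config.n_other and not others:
        raise FixtureError("other-disease variants requested but only one concept configured")
    place(
        config.n_other,
        "disease",
        lambda i: {others[int(rng.integers(len(others)))]},
        lambda cs: susceptible[next(iter(cs))],
    )
    place(config.n_neutral, "neutral", lambda i: set(), lambda cs: None)
    return MutationDataset(records)


def simulate(config: FixtureConfig) -> Fixture:
    """Generate a complete fixture from one seed."""
    rng = np.random.default_rng(config.seed)
    profiles, annotations, sequences = generate_profiles(config, rng)
    susceptible = designate_susceptible(config)
    dataset = generate_mutations(config, profiles, susceptible, rng)
    return Fixture(
        config=config,
        profiles=profiles,
        annotations=annotations,
        sequences=sequences,
        dataset=dataset,
        susceptible=susceptible,
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Serialize a fixture: profiles/*.hmm, annotations.tsv, proteins.fasta,
    variants.tsv, truth.tsv, and a config echo."""
    outdir = Path(outdir)
    profdir = outdir / "profiles"
    profdir.mkdir(parents=True, exist_ok=True)
    for pid, models in fixture.profiles:
        write_hmmer3_profile(models.ab_initio, profdir / f"{pid}.hmm")
        for dom in models.domains:
            # serialize domain models with their intrinsic 1..length map
            bare = dom.with_residue_map({i: i for i in range(1, dom.length + 1)})
            write_hmmer3_profile(bare, profdir / f"{dom.model_id}.hmm")
    fixture.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    SeqIO.write(
        [
            SeqRecord(Seq(seq), id=pid, description="synthetic consensus")
            for pid, seq in sorted(fixture.sequences.items())
        ],
        outdir / "proteins.fasta",
        "fasta",
    )
    write_variant_table(fixture.dataset, outdir / "variants.tsv")
    truth = pd.DataFrame(
        [
            {"concept": c.value, "protein_id": pid}
            for c, pids in fixture.susceptible.items()
            for pid in sorted(pids)
        ]
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(fixture.config)
    cfg["background"] = list(fixture.config.background.p)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
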