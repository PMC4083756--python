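"""Profile-HMM models: parsing, conservation, and model selection.

A protein is represented by an ab initio profile HMM covering its full
length, optionally supplemented by domain models (SUPERFAMILY, Pfam-A,
Pfam-B) annotated onto residue ranges.  For a queried residue the most
informative covering model is chosen by the Kullback-Leibler divergence of
its match-state emission distribution from a background amino-acid
composition; the chosen state supplies the wild-type and mutant residue
probabilities used by the scoring equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

#: Canonical amino acids in the column order used by HMMER ASCII profiles.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Floor applied to parsed emission probabilities so log ratios stay finite.
EMISSION_FLOOR = 1e-9

_SUM_TOL = 1e-6


class ProfileError(ValueError):
    """Invalid profile content or usage."""


class ProfileParseError(ProfileError):
    """Malformed HMMER3 ASCII input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UncoveredResidueError(ProfileError):
    """The queried residue is outside the ab initio model's residue map."""


class AminoAcidDistribution:
    """A probability distribution over the 20 canonical amino acids.

    Accepts either a mapping ``{one-letter code: probability}`` or an array
    in :data:`AMINO_ACIDS` order.  Entries must be non-negative and sum to
    one within 1e-6.
    """

    __slots__ = ("p",)

    def __init__(self, probs: Mapping[str, float] | Sequence[float] | np.ndarray):
        if isinstance(probs, Mapping):
            arr = np.zeros(20)
            for aa, v in probs.items():
                if aa not in AA_INDEX:
                    raise ProfileError(f"non-canonical amino acid {aa!r}")
                arr[AA_INDEX[aa]] = v
        else:
            arr = np.asarray(probs, dtype=float)
        if arr.shape != (20,):
            raise ProfileError(f"expected 20 probabilities, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ProfileError("negative probability in distribution")
        if abs(arr.sum() - 1.0) > _SUM_TOL:
            raise ProfileError(f"probabilities sum to {arr.sum():.8f}, not 1")
        self.p = arr

    def __getitem__(self, aa: str) -> float:
        return float(self.p[AA_INDEX[aa]])

    def as_array(self) -> np.ndarray:
        return self.p.copy()

    def floored(self, floor: float = EMISSION_FLOOR) -> "AminoAcidDistribution":
        return type(self)(np.maximum(self.p, floor))

    @classmethod
    def uniform(cls) -> "AminoAcidDistribution":
        return cls(np.full(20, 0.05))

    @classmethod
    def point_mass(cls, aa: str) -> "AminoAcidDistribution":
        arr = np.zeros(20)
        arr[AA_INDEX[aa]] = 1.0
        return cls(arr)

    def dominant(self) -> str:
        """Most probable residue (ties broken by alphabet order)."""
        return AMINO_ACIDS[int(np.argmax(self.p))]

    def __eq__(self, other) -> bool:
        return isinstance(other, AminoAcidDistribution) and np.array_equal(self.p, other.p)

    def __repr__(self) -> str:
        top = sorted(zip(AMINO_ACIDS, self.p), key=lambda t: -t[1])[:3]
        return "AminoAcidDistribution(%s...)" % ", ".join(f"{a}={v:.3f}" for a, v in top)


class BackgroundComposition(AminoAcidDistribution):
    """Background amino-acid composition; strictly positive everywhere.

    Strict positivity keeps every Kullback-Leibler divergence finite.
    """

    def __init__(self, probs):
        super().__init__(probs)
        if np.any(self.p <= 0):
            raise ProfileError("background composition must be strictly positive")


class ModelSource(str, Enum):
    AB_INITIO = "ab_initio"
    SUPERFAMILY = "superfamily"
    PFAM_A = "pfam_a"
    PFAM_B = "pfam_b"


#: Tie-break priority for model selection: more curated sources win.
SELECTION_PRIORITY = {
    ModelSource.PFAM_A: 3,
    ModelSource.SUPERFAMILY: 2,
    ModelSource.PFAM_B: 1,
    ModelSource.AB_INITIO: 0,
}


@dataclass(frozen=True)
class ProfileHMM:
    """Match-state emissions of one profile HMM plus a residue-to-state map.

    ``residue_map`` maps 1-based protein residue positions to 1-based match
    state indices; for an ab initio model it is the identity over the
    protein, for a domain model it covers only the annotated range.
    """

    model_id: str
    source: ModelSource
    length: int
    emissions: tuple[AminoAcidDistribution, ...]
    residue_map: Mapping[int, int]

    def __post_init__(self):
        if self.length <= 0:
            raise ProfileError(f"model {self.model_id}: non-positive length")
        if len(self.emissions) != self.length:
            raise ProfileError(
                f"model {self.model_id}: {len(self.emissions)} emission rows "
                f"for length {self.length}"
            )
        states = list(self.residue_map.values())
        if any(not (1 <= s <= self.length) for s in states):
            raise ProfileError(f"model {self.model_id}: residue map state out of range")
        if len(set(states)) != len(states):
            raise ProfileError(f"model {self.model_id}: residue map not injective")

    def state_for(self, residue: int) -> int | None:
        """Match state covering a 1-based residue, or None."""
        return self.residue_map.get(residue)

    def emission(self, state: int) -> AminoAcidDistribution:
        if not (1 <= state <= self.length):
            raise ProfileError(f"state {state} outside [1, {self.length}]")
        return self.emissions[state - 1]

    def with_residue_map(self, residue_map: Mapping[int, int]) -> "ProfileHMM":
        return replace(self, residue_map=dict(residue_map))


@dataclass(frozen=True)
class ModelCandidate:
    """A model that covers the queried residue, with the covering state."""

    model: ProfileHMM
    state: int


def kl_divergence(dist: AminoAcidDistribution, background: BackgroundComposition) -> float:
    """Kullback-Leibler divergence sum(p * ln(p/q)) in nats; 0*ln(0/q) = 0."""
    return float(rel_entr(dist.p, background.p).sum())


# ---------------------------------------------------------------------------
# HMMER3 ASCII input/output
# ---------------------------------------------------------------------------

def read_hmmer3_profile(
    stream: IO[str] | str | Path,
    *,
    source: ModelSource = ModelSource.AB_INITIO,
    model_id: str | None = None,
) -> ProfileHMM:
    """Parse one HMMER3/f ASCII profile into a :class:`ProfileHMM`.

    Match-emission fields hold negative natural-log probabilities
    (``*`` meaning probability zero); each row is renormalized and floored
    at :data:`EMISSION_FLOOR`.  Insert-state and transition lines are
    skipped.  The residue map is taken from the MAP annotation column when
    present, otherwise it is the identity.
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return read_hmmer3_profile(fh, source=source, model_id=model_id)

    lines = stream.read().splitlines()
    if not lines or not lines[0].startswith("HMMER3"):
        raise ProfileParseError("expected an 'HMMER3/f' format line", line=1)

    name: str | None = None
    length: int | None = None
    alph: str | None = None
    body_start: int | None = None
    for i, raw in enumerate(lines[1:], start=2):
        tok = raw.split()
        if not tok:
            continue
        key = tok[0]
        if key == "NAME" and len(tok) > 1:
            name = tok[1]
        elif key == "LENG":
            try:
                length = int(tok[1])
            except (IndexError, ValueError):
                raise ProfileParseError("unreadable LENG value", line=i)
        elif key == "ALPH" and len(tok) > 1:
            alph = tok[1].lower()
        elif key == "HMM":
            body_start = i
            break
    if length is None:
        raise ProfileParseError("missing LENG header")
    if alph != "amino":
        raise ProfileParseError(f"unsupported alphabet {alph!r}; only 'amino' profiles are modelled")
    if body_start is None:
        raise ProfileParseError("missing HMM body")

    rows: list[np.ndarray] = []
    residue_map: dict[int, int] = {}
    expected = 1
    for i, raw in enumerate(lines[body_start:], start=body_start + 1):
        tok = raw.split()
        if not tok:
            continue
        if tok[0] == "//":
            break
        if not tok[0].isdigit():
            continue  # transition header, COMPO block, insert or transition line
        state = int(tok[0])
        if state != expected:
            raise ProfileParseError(
                f"match state {state} out of order (expected {expected})", line=i
            )
        if len(tok) < 21:
            raise ProfileParseError("match line holds fewer than 20 emission fields", line=i)
        vals = np.empty(20)
        for j, t in enumerate(tok[1:21]):
            if t == "*":
                vals[j] = math.inf
                continue
            try:
                vals[j] = float(t)
            except ValueError:
                raise ProfileParseError(f"non-numeric emission field {t!r}", line=i)
        probs = np.exp(-vals)
        total = probs.sum()
        if total <= 0:
            raise ProfileParseError("match line has zero total emission mass", line=i)
        probs = np.maximum(probs / total, EMISSION_FLOOR)
        rows.append(probs)
        # optional MAP annotation column (alignment/residue index)
        if len(tok) > 21 and tok[21] not in ("-", "."):
            try:
                residue_map[int(tok[21])] = state
            except ValueError:
                raise ProfileParseError(f"unreadable MAP field {tok[21]!r}", line=i)
        expected += 1

    if len(rows) != length:
        raise ProfileParseError(
            f"LENG is {length} but {len(rows)} match-emission lines were found"
        )
    if not residue_map:
        residue_map = {k: k for k in range(1, length + 1)}
    return ProfileHMM(
        model_id=model_id or name or "unnamed",
        source=source,
        length=length,
        emissions=tuple(AminoAcidDistribution(r) for r in rows),
        residue_map=residue_map,
    )


# Shared per-node transition probabilities for written profiles (match-heavy,
# arbitrary but valid); transitions are not used in scoring.
_TRANS = "  0.04082  3.91202  3.91202  0.69315  0.69315  0.69315  0.69315"
_TRANS_LAST = "  0.04082  3.91202        *  0.69315  0.69315  0.00000        *"
_INSERT = " ".join(["  2.99573"] * 20)


def write_hmmer3_profile(profile: ProfileHMM, stream: IO[str] | str | Path) -> None:
    """Serialize match emissions as a standalone HMMER3/f ASCII profile.

    Emission log-probabilities are printed at 10 decimal places so a
    write/read round trip preserves probabilities to better than 1e-9.
    Insert emissions and transitions are filled with fixed valid values;
    they are ignored on read.
    """
    if isinstance(stream, (str, Path)):
        with open(stream, "w") as fh:
            write_hmmer3_profile(profile, fh)
            return

    w = stream.write
    w("HMMER3/f [pathmm]\n")
    w(f"NAME  {profile.model_id}\n")
    w(f"LENG  {profile.length}\n")
    w("ALPH  amino\n")
    w("MAP   yes\n")
    w("HMM      " + "      ".join(AMINO_ACIDS) + "\n")
    w("         m->m     m->i     m->d     i->m     i->i     d->m     d->d\n")
    state_of: dict[int, int] = dict(profile.residue_map)
    residue_of = {s: r for r, s in state_of.items()}
    w("  COMPO " + _INSERT + "\n")
    w("        " + _INSERT + "\n")
    w("        " + _TRANS.lstrip() + "\n")
    for k in range(1, profile.length + 1):
        vals = profile.emissions[k - 1].p
        fields = " ".join(f"{-math.log(max(v, EMISSION_FLOOR)):14.10f}" for v in vals)
        mapcol = residue_of.get(k, "-")
        w(f"{k:7d} {fields} {mapcol:>6} - - - -\n")
        w("        " + _INSERT + "\n")
        w("        " + (_TRANS_LAST if k == profile.length else _TRANS).lstrip() + "\n")
    w("//\n")


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def candidates_for_residue(
    ab_initio: ProfileHMM,
    domain_models: Iterable[ProfileHMM],
    residue: int,
) -> list[ModelCandidate]:
    """All models covering the residue: the ab initio model plus any domain
    whose residue map includes the position."""
    state = ab_initio.state_for(residue)
    if state is None:
        raise UncoveredResidueError(
            f"residue {residue} not covered by ab initio model {ab_initio.model_id}"
        )
    out = [ModelCandidate(ab_initio, state)]
    for dom in domain_models:
        s = dom.state_for(residue)
        if s is not None:
            out.append(ModelCandidate(dom, s))
    return out


def select_informative_model(
    candidates: Sequence[ModelCandidate],
    background: BackgroundComposition,
) -> ModelCandidate:
    """Candidate whose covering state diverges most from the background.

    Informativeness is position-local: the KL divergence of the covering
    match state's emissions, not a model-wide average.  Exact ties fall to
    the more curated source (Pfam-A > SUPERFAMILY > Pfam-B > ab initio),
    then to model id, so the choice is permutation-invariant.
    """
    if not candidates:
        raise ProfileError("no candidate models")
    return max(
        candidates,
        key=lambda c: (
            kl_divergence(c.model.emission(c.state), background),
            SELECTION_PRIORITY[c.model.source],
            c.model.model_id,
        ),
    )


# ---------------------------------------------------------------------------
# Domain annotations and profile sets
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["protein_id", "model_id", "source", "start", "end", "model_start"]


def annotate_domain(profile: ProfileHMM, start: int, end: int, model_start: int) -> ProfileHMM:
    """Attach a residue map for a domain occupying protein residues
    ``start..end`` (1-based inclusive), aligned ungapped from ``model_start``."""
    if start < 1 or end < start:
        raise ProfileError(f"invalid domain range {start}..{end}")
    span = end - start + 1
    if model_start < 1 or model_start + span - 1 > profile.length:
        raise ProfileError(
            f"domain range {start}..{end} does not fit model {profile.model_id} "
            f"(length {profile.length}, model_start {model_start})"
        )
    return profile.with_residue_map(
        {start + i: model_start + i for i in range(span)}
    )


def read_annotation_table(stream: IO[str] | str | Path) -> pd.DataFrame:
    """Read a domain annotation TSV (protein_id, model_id, source, start,
    end, model_start; 1-based inclusive coordinates)."""
    df = pd.read_csv(stream, sep="\t", dtype={"protein_id": str, "model_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileError(f"annotation table missing columns: {missing}")
    for col in ("start", "end", "model_start"):
        df[col] = df[col].astype(int)
    bad = df[(df.start < 1) | (df.end < df.start) | (df.model_start < 1)]
    if len(bad):
        raise ProfileError(f"invalid annotation rows: {bad.index.tolist()}")
    df["source"] = df["source"].map(ModelSource)
    return df


@dataclass
class ProteinModels:
    """The ab initio model of one protein plus its annotated domains."""

    ab_initio: ProfileHMM
    domains: list[ProfileHMM] = field(default_factory=list)


class ProfileSet:
    """All profile models for a cohort of proteins, keyed by protein id."""

    def __init__(self):
        self._proteins: dict[str, ProteinModels] = {}

    def add_protein(self, protein_id: str, ab_initio: ProfileHMM) -> None:
        if protein_id in self._proteins:
            raise ProfileError(f"duplicate protein {protein_id}")
        self._proteins[protein_id] = ProteinModels(ab_initio=ab_initio)

    def add_domain(self, protein_id: str, domain: ProfileHMM) -> None:
        self._proteins[protein_id].domains.append(domain)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._proteins

    def __len__(self) -> int:
        return len(self._proteins)

    def protein_ids(self) -> list[str]:
        return sorted(self._proteins)

    def models_for(self, protein_id: str) -> ProteinModels:
        try:
            return self._proteins[protein_id]
        except KeyError:
            raise ProfileError(f"no profile for protein {protein_id!r}") from None

    def candidates(self, protein_id: str, residue: int) -> list[ModelCandidate]:
        pm = self.models_for(protein_id)
        return candidates_for_residue(pm.ab_initio, pm.domains, residue)

    def model_ids_covering(self, protein_id: str, residue: int) -> list[str]:
        return [c.model.model_id for c in self.candidates(protein_id, residue)]

    def __iter__(self) -> Iterator[tuple[str, ProteinModels]]:
        return iter(sorted(self._proteins.items()))


def load_profile_set(profiles_dir: str | Path, annotations: str | Path | pd.DataFrame) -> ProfileSet:
    """Build a :class:`ProfileSet` from a directory of ``*.hmm`` files and a
    domain annotation table.

    Files whose model id appears in the annotation table are domain models
    (annotated onto each listed protein with their own residue map); every
    other file is the ab initio model of the protein sharing its id.
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = read_annotation_table(annotations)
    raw: dict[str, ProfileHMM] = {}
    for path in sorted(Path(profiles_dir).glob("*.hmm")):
        prof = read_hmmer3_profile(path)
        raw[prof.model_id] = prof
    domain_ids = set(annotations["model_id"])
    pset = ProfileSet()
    for mid, prof in raw.items():
        if mid not in domain_ids:
            pset.add_protein(mid, prof)
    for row in annotations.itertuples(index=False):
        if row.model_id not in raw:
            raise ProfileError(f"annotation references unknown model {row.model_id!r}")
        dom = raw[row.model_id]
        dom = replace(dom, source=ModelSource(row.source))
        pset.add_domain(
            row.protein_id, annotate_domain(dom, row.start, row.end, row.model_start)
        )
    return pset
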