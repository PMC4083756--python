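"""Profile parsing, conservation measurement, and model selection."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pathmm import (
    AminoAcidDistribution,
    BackgroundComposition,
    ModelCandidate,
    ModelSource,
    ProfileHMM,
    candidates_for_residue,
    kl_divergence,
    read_hmmer3_profile,
    select_informative_model,
    write_hmmer3_profile,
)
from pathmm.profiles import (
    AMINO_ACIDS,
    ProfileError,
    ProfileParseError,
    UncoveredResidueError,
    annotate_domain,
)

from conftest import make_profile, random_distribution


def minimal_hmm_text(rows, name="toy", leng=None, alph="amino"):
    """Hand-built HMMER3/f text with the given match-emission log values."""
    leng = leng if leng is not None else len(rows)
    out = [f"HMMER3/f [test]", f"NAME  {name}", f"LENG  {leng}", f"ALPH  {alph}",
           "HMM   " + " ".join(AMINO_ACIDS),
           "      m->m m->i m->d i->m i->i d->m d->d"]
    for k, vals in enumerate(rows, start=1):
        out.append(f"{k} " + " ".join(str(v) for v in vals))
    out.append("//")
    return "\n".join(out) + "\n"


class TestReadHmmer3:
    def test_zero_log_value_is_certain_emission(self):
        # stored 0.0 => probability exp(-0) = 1 for that residue
        rows = [["0.0"] + ["*"] * 19]
        prof = read_hmmer3_profile(io.StringIO(minimal_hmm_text(rows)))
        em = prof.emission(1)
        assert em["A"] == pytest.approx(1.0, abs=1e-6)
        assert all(em[aa] <= 1e-8 for aa in AMINO_ACIDS[1:])

    def test_ln20_everywhere_gives_uniform_rows(self):
        v = f"{math.log(20):.6f}"
        rows = [[v] * 20 for _ in range(4)]
        prof = read_hmmer3_profile(io.StringIO(minimal_hmm_text(rows)))
        for k in range(1, 5):
            np.testing.assert_allclose(prof.emission(k).p, 0.05, atol=1e-6)

    def test_metadata_and_identity_residue_map(self):
        rows = [["0.0"] + ["*"] * 19] * 3
        prof = read_hmmer3_profile(io.StringIO(minimal_hmm_text(rows, name="abc")))
        assert prof.model_id == "abc"
        assert prof.length == 3
        assert prof.residue_map == {1: 1, 2: 2, 3: 3}

    def test_malformed_header_rejected(self):
        with pytest.raises(ProfileParseError, match="HMMER3"):
            read_hmmer3_profile(io.StringIO("NOT A PROFILE\n"))

    def test_leng_mismatch_rejected(self):
        rows = [["0.0"] + ["*"] * 19] * 2
        with pytest.raises(ProfileParseError, match="LENG"):
            read_hmmer3_profile(io.StringIO(minimal_hmm_text(rows, leng=5)))

    def test_non_numeric_emission_names_line(self):
        rows = [["0.0"] + ["*"] * 19, ["bogus"] + ["0.5"] * 19]
        with pytest.raises(ProfileParseError, match=r"line 8.*bogus"):
            read_hmmer3_profile(io.StringIO(minimal_hmm_text(rows)))

    def test_non_amino_alphabet_rejected(self):
        rows = [["0.0"] + ["*"] * 19]
        with pytest.raises(ProfileParseError, match="alphabet"):
            read_hmmer3_profile(io.StringIO(minimal_hmm_text(rows, alph="dna")))


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_write_read_preserves_emissions_to_1e9(self, seed):
        rng = np.random.default_rng(seed)
        prof = make_profile(rng, model_id=f"rt{seed}", length=int(rng.integers(1, 30)))
        buf = io.StringIO()
        write_hmmer3_profile(prof, buf)
        buf.seek(0)
        back = read_hmmer3_profile(buf)
        assert back.model_id == prof.model_id
        assert back.length == prof.length
        assert back.residue_map == dict(prof.residue_map)
        for a, b in zip(prof.emissions, back.emissions):
            np.testing.assert_allclose(a.p, b.p, atol=1e-9)

    def test_pyhmmer_parses_written_profile_identically(self, tmp_path, rng):
        """Independent oracle: the installed HMMER bindings read our output."""
        pyhmmer = pytest.importorskip("pyhmmer")
        prof = make_profile(rng, model_id="oracle", length=8)
        path = tmp_path / "oracle.hmm"
        write_hmmer3_profile(prof, path)
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            hmm = next(iter(fh))
        assert hmm.name in ("oracle", b"oracle")
        me = np.asarray(hmm.match_emissions)  # row 0 is the begin state
        for k in range(1, 9):
            np.testing.assert_allclose(me[k], prof.emissions[k - 1].p, atol=5e-7)


class TestKLDivergence:
    def test_identical_distributions_have_zero_divergence(self, background):
        assert kl_divergence(AminoAcidDistribution.uniform(), background) == 0.0

    def test_point_mass_vs_uniform_is_ln20(self, background):
        d = kl_divergence(AminoAcidDistribution.point_mass("W"), background)
        assert d == pytest.approx(math.log(20), abs=1e-12)

    def test_two_residue_split_vs_uniform_is_ln10(self, background):
        dist = AminoAcidDistribution({"A": 0.5, "C": 0.5})
        assert kl_divergence(dist, background) == pytest.approx(math.log(10), abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_sum_and_is_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        dist = random_distribution(rng)
        q = np.maximum(rng.dirichlet(np.full(20, 5.0)), 1e-6)
        bg = BackgroundComposition(q / q.sum())
        expected = sum(
            p * math.log(p / q) for p, q in zip(dist.p, bg.p) if p > 0
        )
        got = kl_divergence(dist, bg)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got >= 0.0

    def test_background_must_be_strictly_positive(self):
        with pytest.raises(ProfileError, match="positive"):
            BackgroundComposition({"A": 0.5, "C": 0.5})


class TestCandidates:
    def test_fallback_is_ab_initio_only(self, rng):
        ab = make_profile(rng, "P1", 50)
        assert [c.model.model_id for c in candidates_for_residue(ab, [], 10)] == ["P1"]

    def test_domain_coverage_adds_candidates(self, rng):
        ab = make_profile(rng, "P1", 50)
        pfam = annotate_domain(
            make_profile(rng, "PF1", 20, ModelSource.PFAM_A, residue_map={}), 5, 24, 1
        )
        sf = annotate_domain(
            make_profile(rng, "SF1", 30, ModelSource.SUPERFAMILY, residue_map={}), 1, 30, 1
        )
        assert len(candidates_for_residue(ab, [pfam, sf], 40)) == 1
        assert len(candidates_for_residue(ab, [pfam], 10)) == 2
        got = candidates_for_residue(ab, [pfam, sf], 10)
        assert len(got) == 3  # nested annotations all contribute

    def test_domain_state_follows_offset_mapping(self, rng):
        ab = make_profile(rng, "P1", 50)
        dom = annotate_domain(
            make_profile(rng, "D", 25, ModelSource.PFAM_B, residue_map={}), 10, 29, 3
        )
        cand = candidates_for_residue(ab, [dom], 12)[1]
        assert cand.state == 5  # model_start 3 + offset 2

    def test_uncovered_residue_errors(self, rng):
        ab = make_profile(rng, "P1", 50)
        with pytest.raises(UncoveredResidueError):
            candidates_for_residue(ab, [], 51)


class TestSelectInformativeModel:
    def _candidate(self, dist, source, model_id):
        prof = ProfileHMM(model_id, source, 1, (dist,), {1: 1})
        return ModelCandidate(prof, 1)

    def test_single_candidate_returned(self, background, rng):
        c = self._candidate(random_distribution(rng), ModelSource.AB_INITIO, "only")
        assert select_informative_model([c], background) is c

    def test_point_mass_beats_uniform(self, background):
        a = self._candidate(AminoAcidDistribution.point_mass("A"), ModelSource.AB_INITIO, "a")
        b = self._candidate(AminoAcidDistribution.uniform(), ModelSource.PFAM_A, "b")
        assert select_informative_model([a, b], background) is a

    def test_exact_tie_prefers_pfam_a(self, background):
        dist = AminoAcidDistribution.point_mass("C")
        a = self._candidate(dist, ModelSource.AB_INITIO, "ab")
        b = self._candidate(dist, ModelSource.PFAM_A, "pf")
        assert select_informative_model([a, b], background) is b
        assert select_informative_model([b, a], background) is b

    @given(st.integers(0, 2_000))
    def test_permutation_invariant(self, seed):
        background = BackgroundComposition.uniform()
        rng = np.random.default_rng(seed)
        sources = list(ModelSource)
        cands = [
            self._candidate(
                random_distribution(rng), sources[int(rng.integers(4))], f"m{i}"
            )
            for i in range(int(rng.integers(2, 6)))
        ]
        chosen = select_informative_model(cands, background)
        perm = [cands[i] for i in rng.permutation(len(cands))]
        assert select_informative_model(perm, background) is chosen

    def test_empty_list_errors(self, background):
        with pytest.raises(ProfileError):
            select_informative_model([], background)


class TestDomainAnnotation:
    def test_range_must_fit_model(self, rng):
        dom = make_profile(rng, "D", 10, ModelSource.PFAM_A, residue_map={})
        with pytest.raises(ProfileError, match="does not fit"):
            annotate_domain(dom, 5, 20, 1)

    def test_invariants_rejected_on_bad_map(self, rng):
        with pytest.raises(ProfileError, match="injective"):
            make_profile(rng, "X", 5, residue_map={1: 2, 3: 2})
        with pytest.raises(ProfileError, match="out of range"):
            make_profile(rng, "X", 5, residue_map={1: 6})
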