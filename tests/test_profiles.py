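"""Profile construction and the built-in forward/Viterbi scorer."""

import io
import math

import numpy as np
import pytest

from bmctyper import (ProfileLibrary, build_profile, forward_bitscore,
                      load_library, save_library, score_sequence, search,
                      viterbi_bitscore)
from bmctyper.alphabet import AA_INDEX, AMINO_ACIDS
from bmctyper.errors import (EmptyResultError, InvalidAlignmentError,
                             InvalidSequenceError)
from bmctyper.locus import ProteinRecord
from bmctyper.roles import Role

from conftest import random_protein
from oracles import enumerate_forward_logprob


class TestBuildProfile:
    def test_degenerate_identical_rows(self):
        p = build_profile(["ACDEF"] * 3, "H_azure")
        assert p.length == 5
        assert p.role is Role.BMC_H
        for j, aa in enumerate("ACDEF"):
            assert p.match_emissions[j].argmax() == AA_INDEX[aa]
        # +1/20 pseudocount on 3 observations
        assert p.match_emissions[0, AA_INDEX["A"]] == pytest.approx(3.05 / 4)

    def test_gap_majority_column_excluded(self):
        # column 3 (1-based) is gapped in 3/5 rows -> not a match state
        msa = ["AC-DE", "AC-DE", "AC-DE", "ACWDE", "ACWDE"]
        p = build_profile(msa, "P_amber")
        assert p.length == 4

    def test_gap_fraction_exactly_half_is_match(self):
        msa = ["A-C", "A-C", "AWC", "AWC"]
        p = build_profile(msa, "P_amber")
        assert p.length == 3

    @pytest.mark.parametrize("msa,match", [
        ([], "no rows"),
        (["ACD", "AC"], "ragged"),
        (["--", "--", "--"], "no match columns"),
    ])
    def test_rejects_bad_alignments(self, msa, match):
        with pytest.raises(InvalidAlignmentError, match=match):
            build_profile(msa, "H_azure")

    def test_row_order_invariance(self):
        rows = ["ACDEF", "AC-EF", "GCDEF", "ACDE-", "ACWEF"]
        a = build_profile(rows, "H_azure")
        b = build_profile(rows[::-1], "H_azure")
        np.testing.assert_array_equal(a.match_emissions, b.match_emissions)
        np.testing.assert_array_equal(a.transitions, b.transitions)

    def test_emission_and_transition_normalisation(self):
        p = build_profile(["AC-EF", "ACDEF", "AC---", "ACDEF"], "Ts_jade")
        assert np.allclose(p.match_emissions.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p.match_emissions > 0)
        assert np.all(p.transitions > 0)


class TestScoring:
    def test_consensus_scores_positive(self, peaked_profile):
        assert forward_bitscore(peaked_profile, peaked_profile.consensus()) > 0

    def test_empty_sequence_rejected(self, peaked_profile):
        with pytest.raises(InvalidSequenceError):
            score_sequence(peaked_profile, "")

    def test_forward_matches_exhaustive_enumeration(self):
        """DP forward equals the path-enumeration oracle to 1e-9 relative."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for L in (1, 2, 3):
            for rep in range(3):
                msa = [random_protein(rng, L) for _ in range(3)]
                prof = build_profile(msa, f"H_t{L}{rep}")
                for qlen in range(1, 6):
                    q = random_protein(rng, qlen)
                    from bmctyper import _dp
                    from bmctyper.alphabet import encode
                    dp = _dp.forward_logprob(encode(q), *prof.score_tables())
                    oracle = enumerate_forward_logprob(prof, q)
                    worst = max(worst, abs(dp - oracle) / abs(oracle))
        assert worst < 1e-9

    def test_forward_at_least_viterbi(self, peaked_profile):
        rng = np.random.default_rng(7)
        for _ in range(20):
            q = random_protein(rng, int(rng.integers(5, 40)))
            assert forward_bitscore(peaked_profile, q) >= \
                viterbi_bitscore(peaked_profile, q) - 1e-9

    def test_profile_samples_outscore_their_shuffles(self, peaked_profile):
        rng = np.random.default_rng(123)
        sampled = [peaked_profile.sample(rng) for _ in range(50)]
        shuffled = ["".join(rng.permutation(list(s))) for s in sampled]
        mean_s = np.mean([forward_bitscore(peaked_profile, s) for s in sampled])
        mean_r = np.mean([forward_bitscore(peaked_profile, s) for s in shuffled])
        assert mean_s > mean_r

    def test_tandem_duplication_yields_two_domains(self, peaked_profile):
        cons = peaked_profile.consensus()
        hit = score_sequence(peaked_profile, cons + cons, threshold=0.0)
        assert hit.n_domains == 2
        single = score_sequence(peaked_profile, cons, threshold=0.0)
        assert single.n_domains == 1
        assert 1 <= single.env_start <= single.env_end <= len(cons)

    def test_nonstandard_residues_score_as_background(self, peaked_profile):
        """Unknown letters emit background in model and null alike, so each
        flank position costs only the 1-bit flank-loop probability."""
        cons = peaked_profile.consensus()
        base = forward_bitscore(peaked_profile, cons)
        padded = forward_bitscore(peaked_profile, "XXBZ" + cons)
        assert base - 4.5 < padded < base


class TestSearch:
    def test_consensus_hit_shuffled_miss(self, peaked_profile):
        rng = np.random.default_rng(5)
        cons = peaked_profile.consensus()
        decoy = "".join(rng.permutation(list(cons)))
        lib = ProfileLibrary({peaked_profile.name: peaked_profile})
        recs = [ProteinRecord("real", "", 0, cons),
                ProteinRecord("decoy", "", 1, decoy)]
        hits = search(lib, recs)
        assert len(hits) == 2
        assert [h.profile_name for h in hits[0]] == [peaked_profile.name]
        assert hits[1] == []

    def test_empty_inputs_rejected(self, peaked_profile):
        lib = ProfileLibrary({peaked_profile.name: peaked_profile})
        with pytest.raises(EmptyResultError):
            search(lib, [])
        with pytest.raises(EmptyResultError):
            search(ProfileLibrary({}), [ProteinRecord("a", "", 0, "MKV")])


class TestSerialization:
    def test_round_trip_is_exact(self, small_library):
        buf = io.StringIO()
        save_library(small_library, buf)
        lib2 = load_library(io.StringIO(buf.getvalue()))
        assert set(lib2.profiles) == set(small_library.profiles)
        assert lib2.mode == small_library.mode
        for name, p in small_library.profiles.items():
            q = lib2.profiles[name]
            np.testing.assert_array_equal(p.match_emissions, q.match_emissions)
            np.testing.assert_array_equal(p.insert_emissions, q.insert_emissions)
            np.testing.assert_array_equal(p.transitions, q.transitions)
            assert (p.role, p.bmc_type, p.n_train) == (q.role, q.bmc_type, q.n_train)

    def test_scores_survive_round_trip(self, small_library):
        buf = io.StringIO()
        save_library(small_library, buf)
        lib2 = load_library(io.StringIO(buf.getvalue()))
        name = sorted(small_library.profiles)[0]
        q = small_library.profiles[name].consensus()
        assert forward_bitscore(lib2.profiles[name], q) == \
            forward_bitscore(small_library.profiles[name], q)
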