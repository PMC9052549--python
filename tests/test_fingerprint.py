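"""Fingerprints, inventory+order similarity, ranking, clustering, voting."""

import pytest
from hypothesis import given, settings, strategies as st

from bmctyper import (Fingerprint, call_type, cluster_loci, make_fingerprint,
                      rank_closest, similarity)
from bmctyper.annotate import BestAssignment
from bmctyper.errors import EmptyResultError
from bmctyper.roles import Role

from oracles import brute_force_similarity


def fp(labels, locus_id="L"):
    return Fingerprint(labels=list(labels), locus_id=locus_id)


def assignment(role, bmc_type=None, name="X_x", qid="q"):
    return BestAssignment(query_id=qid, profile_name=None if role is Role.NONE else name,
                          role=role, bmc_type=bmc_type,
                          bitscore=None if role is Role.NONE else 50.0,
                          is_shell=role.name.startswith("BMC_"))


labels_strategy = st.lists(st.sampled_from("ABCDEF"), min_size=1, max_size=6)


class TestMakeFingerprint:
    def test_none_assignments_excluded(self):
        a = [assignment(Role.BMC_H, name="H_azure"),
             assignment(Role.NONE),
             assignment(Role.BMC_P, name="P_amber")]
        f = make_fingerprint(a, "loc1")
        assert f.labels == ["H_azure", "P_amber"]

    def test_all_none_rejected(self):
        with pytest.raises(EmptyResultError, match="nothing to fingerprint"):
            make_fingerprint([assignment(Role.NONE)] * 3, "loc1")

    def test_fixture_locus_length(self, small_world):
        locus = small_world.loci[0]
        truth = locus.truth_fingerprint()
        assert len(truth) == sum(1 for l in locus.true_labels if l is not None)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        s = similarity(fp("ABCA"), fp("ABCA"))
        assert s.value == 1.0
        assert (s.best_offset, s.orientation) == (0, "forward")

    def test_disjoint_sets_score_zero(self):
        s = similarity(fp("ABC"), fp("DEF"))
        assert s.value == 0.0
        assert s.inventory_component == 0.0
        assert s.order_component == 0.0

    def test_reversed_locus_scores_one(self):
        s = similarity(fp("ABC"), fp("CBA"))
        assert s.value == 1.0
        assert s.orientation == "reversed"

    def test_reversal_search_disabled_drops_to_forward_best(self):
        s = similarity(fp("ABC"), fp("CBA"), search_reverse=False)
        # Jaccard 1; best forward overlap is 1 match out of 3
        assert s.value == pytest.approx(0.5 * 1 + 0.5 * (1 / 3))

    def test_empty_fingerprint_rejected(self):
        with pytest.raises(EmptyResultError):
            Fingerprint(labels=[], locus_id="x")

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(l1=labels_strategy, l2=labels_strategy)
    def test_matches_brute_force_and_algebra(self, l1, l2):
        """Symmetry, boundedness, and agreement with the literal
        offset x orientation maximisation."""
        s12 = similarity(fp(l1, "a"), fp(l2, "b"))
        s21 = similarity(fp(l2, "b"), fp(l1, "a"))
        assert 0.0 <= s12.value <= 1.0
        assert s12.value == pytest.approx(s21.value)
        assert s12.value == pytest.approx(brute_force_similarity(l1, l2))


class TestRankClosest:
    def test_own_source_ranks_first(self, small_world, small_registry):
        locus = small_world.loci[0]  # the registry's example for its type
        ranking = rank_closest(locus.truth_fingerprint(), small_registry)
        assert ranking[0][0] == locus.true_type
        assert ranking[0][1].value == 1.0

    def test_k_larger_than_registry(self, small_registry):
        ranking = rank_closest(fp("ABC"), small_registry, k=50)
        assert len(ranking) == len(small_registry)

    def test_default_k_is_five_with_large_registry(self):
        from bmctyper import default_registry

        ranking = rank_closest(fp("ABC"), default_registry())
        assert len(ranking) == 5

    def test_values_non_increasing(self, small_registry):
        ranking = rank_closest(fp(["SYN01__H_azure", "Q", "R"]), small_registry, k=50)
        values = [s.value for _, s in ranking]
        assert values == sorted(values, reverse=True)

    def test_empty_registry_rejected(self):
        with pytest.raises(EmptyResultError):
            rank_closest(fp("ABC"), {})


class TestClusterLoci:
    def test_identical_pair_plus_outlier(self):
        fps = [fp("ABCD", "l1"), fp("ABCD", "l2"), fp("WXYZ", "l3")]
        clusters = cluster_loci(fps, threshold=0.6)
        assert clusters == [["l1", "l2"], ["l3"]]

    def test_threshold_zero_single_cluster(self):
        fps = [fp("AB", "l1"), fp("CD", "l2")]
        assert cluster_loci(fps, threshold=0.0) == [["l1", "l2"]]

    def test_threshold_above_one_all_singletons(self):
        fps = [fp("AB", "l1"), fp("AB", "l2")]
        assert cluster_loci(fps, threshold=1.1) == [["l1"], ["l2"]]


class TestCallType:
    def test_six_way_tie_is_ambiguous(self):
        types = ["SPU5", "ACI", "SPU4", "SPU1", "EUT2D", "SPU6"]
        a = [assignment(Role.BMC_H, t, f"{t}__H_x", f"q{i}")
             for i, t in enumerate(types)]
        call = call_type(a)
        assert call.status == "ambiguous"
        assert call.confidence == pytest.approx(1 / 6)
        assert call.bmc_type is None

    def test_unanimous_vote_assigned(self):
        a = [assignment(Role.BMC_H, "PDU1A", "PDU1A__H_x", f"q{i}")
             for i in range(8)]
        call = call_type(a)
        assert (call.status, call.bmc_type, call.confidence) == \
            ("assigned", "PDU1A", 1.0)

    def test_three_two_split_assigned_at_point_six(self):
        a = ([assignment(Role.BMC_H, "X", "X__H_x", f"q{i}") for i in range(3)]
             + [assignment(Role.BMC_P, "Y", "Y__P_y", f"r{i}") for i in range(2)])
        call = call_type(a)
        assert (call.status, call.bmc_type) == ("assigned", "X")
        assert call.confidence == pytest.approx(0.6)

    def test_no_shell_status(self):
        a = [assignment(Role.SIGNATURE_ENZYME, "X", "X__SIG_x")]
        assert call_type(a).status == "no_shell"

    def test_vote_permutation_invariance(self):
        a = [assignment(Role.BMC_H, t, f"{t}__H_x", f"q{i}")
             for i, t in enumerate(["A", "B", "A", "A", "B"])]
        c1, c2 = call_type(a), call_type(a[::-1])
        assert c1.vote_table == c2.vote_table
        assert (c1.status, c1.bmc_type, c1.confidence) == \
            (c2.status, c2.bmc_type, c2.confidence)
        # confidence * total = modal count exactly
        assert c1.confidence * sum(c1.vote_table.values()) == pytest.approx(3)

    def test_signature_hint_on_ambiguous(self):
        a = [assignment(Role.BMC_H, "A", "A__H_x", "q1"),
             assignment(Role.BMC_P, "B", "B__P_y", "q2"),
             assignment(Role.SIGNATURE_ENZYME, "SPU1", "SPU1__SIG_z", "q3"),
             assignment(Role.SIGNATURE_ENZYME, "SPU2", "SPU2__SIG_w", "q4")]
        call = call_type(a)
        assert call.status == "ambiguous"
        assert call.signature_types == ["SPU1", "SPU2"]
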