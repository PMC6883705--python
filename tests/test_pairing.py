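"""Wilcoxon W, permutation significance, exclusive pairing, leftover
classification, shared-fusion verdicts and scenario calls."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wgdkit.model import ValidationError
from wgdkit.pairing import (
    PairingResult,
    ParalogTest,
    ScenarioCall,
    classify_history,
    classify_leftover,
    detect_shared_fusion,
    infer_exclusive_pairing,
    paralog_partner_test,
    permutation_pvalue,
    wilcoxon_w,
)
from wgdkit.synteny import RatioSummary
from wgdkit.words import WordSequence

from conftest import pair_count_w


class TestWilcoxonW:
    def test_complete_separation(self):
        assert wilcoxon_w([3, 4], [1, 2]) == 4

    def test_complete_reversal(self):
        assert wilcoxon_w([1, 2], [3, 4]) == 0

    def test_ties_get_half_credit(self):
        # 0 exceedances + 2 tied pairs at half credit each
        assert wilcoxon_w([1, 2, 2], [2, 3]) == pair_count_w([1, 2, 2], [2, 3]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_w([], [1])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 6), min_size=1, max_size=10),
        y=st.lists(st.integers(0, 6), min_size=1, max_size=10),
    )
    def test_matches_pair_counting_oracle(self, x, y):
        assert wilcoxon_w(x, y) == pytest.approx(pair_count_w(x, y))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 1000), min_size=1, max_size=8, unique=True),
        y=st.lists(st.integers(2000, 3000), min_size=1, max_size=8, unique=True),
    )
    def test_complementarity_without_ties(self, x, y):
        assert wilcoxon_w(x, y) + wilcoxon_w(y, x) == len(x) * len(y)

    def test_agrees_with_scipy_mannwhitneyu(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 20, size=12)
            y = rng.integers(0, 20, size=9)
            u = mannwhitneyu(x, y, alternative="two-sided").statistic
            assert wilcoxon_w(x, y) == pytest.approx(float(u))


def _seqs(**kwargs):
    return {k: WordSequence(k, list(v)) for k, v in kwargs.items()}


class TestPermutationPvalue:
    def test_perfect_match_is_significant(self):
        # query order identical to one target, others disjoint vocabulary
        targets = _seqs(t1=range(30), t2=range(100, 130), t3=range(200, 230))
        query = WordSequence("q", list(range(30)))
        res = permutation_pvalue(query, targets, "t1", N=5, n_perm=50, seed=1)
        assert res.p == 0.0

    def test_hopeless_target_has_maximal_p(self):
        # the tested target shares nothing; every permutation mixes in some
        # of the query's words and scores at least as well
        targets = _seqs(t1=[900] * 20, t2=list(range(20)), t3=list(range(20, 40)))
        query = WordSequence("q", list(range(20)))
        res = permutation_pvalue(query, targets, "t1", N=4, n_perm=50, seed=1)
        assert res.p >= 0.9

    def test_monte_carlo_matches_exhaustive_orderings(self):
        """On a tiny two-target system the permutation p must approach the
        exact value from enumerating all orderings of the pooled words."""
        from wgdkit.pairing import _permuted_sequences, _profiles, _w_vs_pooled_others
        from wgdkit.words import WordScoring

        targets = _seqs(t1=[0, 1, 2], t2=[3, 0, 4])
        query = WordSequence("q", [0, 1, 2, 3])
        N = 2
        scoring = WordScoring()
        profiles = _profiles(query, targets, N, scoring)
        w_obs = _w_vs_pooled_others(profiles, "t1")
        pool = [0, 1, 2, 3, 0, 4]
        count = total = 0
        for perm in itertools.permutations(pool):
            pseudo = {
                "t1": WordSequence("t1", list(perm[:3])),
                "t2": WordSequence("t2", list(perm[3:])),
            }
            p_prof = _profiles(query, pseudo, N, scoring)
            w = max(_w_vs_pooled_others(p_prof, t) for t in pseudo)
            total += 1
            count += w >= w_obs
        exact = count / total
        res = permutation_pvalue(query, targets, "t1", N=N, n_perm=600, seed=3)
        assert res.p == pytest.approx(exact, abs=0.06)

    def test_p_on_grid_and_validation(self):
        targets = _seqs(t1=range(10), t2=range(10, 20))
        query = WordSequence("q", list(range(10)))
        res = permutation_pvalue(query, targets, "t1", N=3, n_perm=20, seed=0)
        assert res.p in {k / 20 for k in range(21)}
        with pytest.raises(ValidationError):
            permutation_pvalue(query, targets, "t1", N=3, n_perm=0, seed=0)
        with pytest.raises(ValidationError):
            permutation_pvalue(query, targets, "missing", N=3, n_perm=5, seed=0)

    def test_best_hit_p_calibrated_under_null(self):
        """When the query is itself a random draw from the pooled words,
        the best-hit p-value is roughly uniform on its grid."""
        rng = np.random.default_rng(7)
        ps = []
        for k in range(30):
            pool = rng.integers(0, 40, size=60)
            targets = {
                "t1": WordSequence("t1", pool[:20].tolist()),
                "t2": WordSequence("t2", pool[20:40].tolist()),
                "t3": WordSequence("t3", pool[40:].tolist()),
            }
            query = WordSequence("q", rng.permutation(pool)[:20].tolist())
            t = paralog_partner_test(query, targets, N=4, n_perm=20, seed=k, alpha=0.05)
            ps.append(t.p_best)
        assert 0.25 <= np.mean(ps) <= 0.75
        assert np.std(ps) > 0.1  # not degenerate

    def test_deterministic_given_seed(self):
        targets = _seqs(t1=range(15), t2=range(10, 25), t3=range(5, 20))
        query = WordSequence("q", list(range(15)))
        a = permutation_pvalue(query, targets, "t1", N=4, n_perm=25, seed=9)
        b = permutation_pvalue(query, targets, "t1", N=4, n_perm=25, seed=9)
        assert a.p == b.p and a.W == b.W


def _fake_test(query, partner, p=0.0, ws=None):
    return ParalogTest(
        query_chrom=query,
        Ws=ws or {},
        best=partner[0] if partner else "x",
        p_best=p,
        partner=partner,
    )


class TestExclusivePairing:
    def test_forced_distinct_assignments_and_outlier(self):
        tests = {
            "c1": _fake_test("c1", ("g1",)),
            "c2": _fake_test("c2", ("g2",)),
        }
        pr = infer_exclusive_pairing(tests, ["g1", "g2", "g3"])
        assert pr.exclusive
        assert pr.assignments == {"c1": ("g1",), "c2": ("g2",)}
        assert pr.outlier == ["g3"]
        assert pr.mode_vote == "allo"

    def test_uniform_scores_give_no_confident_assignments(self):
        tests = {
            "c1": _fake_test("c1", None, p=0.6),
            "c2": _fake_test("c2", None, p=0.5),
        }
        pr = infer_exclusive_pairing(tests, ["g1", "g2", "g3"])
        assert not pr.exclusive and pr.outlier == [] and pr.mode_vote == "none"

    def test_collision_flagged_non_exclusive(self):
        tests = {
            "c1": _fake_test("c1", ("g1",)),
            "c2": _fake_test("c2", ("g1",)),
        }
        pr = infer_exclusive_pairing(tests, ["g1", "g2", "g3"])
        assert not pr.exclusive and pr.mode_vote == "none"

    def test_duplicate_leftover_votes_auto(self):
        tests = {
            "c1": _fake_test("c1", ("g1",)),
            "c2": _fake_test("c2", ("g2",)),
        }
        pr = infer_exclusive_pairing(tests, ["g1", "g2", "g3"], leftover_call="duplicate")
        assert pr.mode_vote == "auto" and pr.outlier == []

    def test_disjoint_pair_partner_votes_auto(self):
        tests = {
            "c1": _fake_test("c1", ("g1", "g3")),
            "c2": _fake_test("c2", ("g2",)),
        }
        pr = infer_exclusive_pairing(tests, ["g1", "g2", "g3"])
        assert pr.mode_vote == "auto"

    def test_overlapping_pair_partner_is_uninformative(self):
        tests = {
            "c1": _fake_test("c1", ("g1", "g2")),
            "c2": _fake_test("c2", ("g2",)),
        }
        pr = infer_exclusive_pairing(tests, ["g1", "g2", "g3"])
        assert pr.mode_vote == "none"

    def test_recovers_truth_on_allo_simulation(self, medium_sim):
        from wgdkit.experiments import pairing_analysis

        analysis = pairing_analysis(medium_sim, N=8, n_perm=30, seed=5, max_colors=3)
        assert analysis.results
        true_outliers = set(medium_sim.ledger.outlier_chroms)
        exclusive = [pr for pr in analysis.results if pr.exclusive]
        assert exclusive, "no exclusive pairing recovered on an allo simulation"
        for pr in exclusive:
            assert set(pr.outlier) <= true_outliers


class TestClassifyLeftover:
    def _system(self, duplicate):
        rng = np.random.default_rng(4)
        base_a = rng.integers(0, 500, size=40).tolist()
        base_b = rng.integers(500, 1000, size=40).tolist()
        qa = WordSequence("qa", base_a)
        qb = WordSequence("qb", base_b)
        partner_a = WordSequence("ga", list(base_a))
        partner_b = WordSequence("gb", list(base_b))
        if duplicate:
            leftover = WordSequence("gl", list(base_a))  # copy of qa's partner
        else:
            leftover = WordSequence("gl", rng.integers(1000, 1500, size=40).tolist())
        return qa, qb, partner_a, partner_b, leftover

    def test_duplicated_partner_detected(self):
        qa, qb, pa, pb, leftover = self._system(duplicate=True)
        v = classify_leftover(
            leftover, {"qa": qa, "qb": qb}, {"qa": pa, "qb": pb}, N=5, n_perm=40, seed=2
        )
        assert v["call"] == "duplicate" and v["best_query"] == "qa"

    def test_unrelated_outlier_detected(self):
        qa, qb, pa, pb, leftover = self._system(duplicate=False)
        v = classify_leftover(
            leftover, {"qa": qa, "qb": qb}, {"qa": pa, "qb": pb}, N=5, n_perm=40, seed=2
        )
        assert v["call"] == "outlier"


class TestSharedFusion:
    SPEC = {"orange": {"gra7"}, "green": {"gra4", "gra7"}}

    def test_both_portions_match_designated_partners(self):
        verdict = detect_shared_fusion(
            {"orange": (("gra7",), True), "green": (("gra4",), True)}, self.SPEC
        )
        assert verdict == "shared"

    def test_portion_pairing_elsewhere_rejects(self):
        verdict = detect_shared_fusion(
            {"orange": (("gra7",), True), "green": (("gra12",), True)}, self.SPEC
        )
        assert verdict == "not_shared"

    def test_unconfident_portion_is_undetermined(self):
        verdict = detect_shared_fusion(
            {"orange": (("gra7",), True), "green": (None, False)}, self.SPEC
        )
        assert verdict == "undetermined"


def _ratio(modal):
    rs = RatioSummary()
    rs.per_group = {"c": modal}
    rs.modal_ratio = modal
    from math import gcd

    g = gcd(*modal)
    rs.modal_ratio_reduced = (modal[0] // g, modal[1] // g)
    return rs


def _vote(label, mode_vote, outlier=()):
    return PairingResult(
        label=label,
        triplet=["g1", "g2", "g3"],
        assignments={},
        confident={},
        exclusive=mode_vote == "allo",
        outlier=list(outlier),
        mode_vote=mode_vote,
    )


class TestClassifyHistory:
    def test_six_to_three_is_extra_lineage_wgd(self):
        call = classify_history(_ratio((6, 3)))
        assert call.tetraploidy == "lineage_specific_extra"
        assert call.hexaploidy_mode == "undetermined"

    def test_two_to_three_without_pairing_support_is_independent(self):
        call = classify_history(_ratio((2, 3)), pairings=[_vote("c0", "none")] * 3)
        assert call.tetraploidy == "independent"

    def test_exclusive_pairings_with_outliers_call_shared_allo(self):
        votes = [_vote("c0", "allo", ["g3"]), _vote("c1", "allo", ["g3"]), _vote("c2", "none")]
        call = classify_history(_ratio((2, 3)), pairings=votes)
        call.validate()
        assert (call.tetraploidy, call.hexaploidy_mode) == ("shared", "allo")
        assert call.outlier_chroms == ["g3"]

    def test_duplicate_votes_call_shared_auto(self):
        votes = [_vote("c0", "auto"), _vote("c1", "auto"), _vote("c2", "allo", ["g3"])]
        call = classify_history(_ratio((2, 3)), pairings=votes)
        assert (call.tetraploidy, call.hexaploidy_mode) == ("shared", "auto")
        assert call.outlier_chroms == []

    def test_validator_rejects_inconsistent_call(self):
        call = ScenarioCall("shared", "allo", evidence={"shared_votes": 0, "n_triplets": 3})
        with pytest.raises(ValidationError):
            call.validate()
        with pytest.raises(ValidationError):
            ScenarioCall("independent", "allo").validate()
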