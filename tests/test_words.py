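"""Word encoding and sliding-window local alignment, with an independent
dynamic-programming oracle (Biopython's PairwiseAligner)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wgdkit.model import ChainParams, HomologPair, ValidationError
from wgdkit.words import (
    WordScoring,
    WordSequence,
    encode_word_sequence,
    local_word_alignment,
    propagate_paralog_words,
    seed_anchor_segments,
    windowed_score_profile,
)

from conftest import biopython_local_score, toy_genome


def _inter_setup(run_a, run_b):
    """Two genomes with ids a0.. / b0.. and matches given as rank pairs."""
    ga = toy_genome("A", {"a1": [f"a{i}" for i in range(20)]})
    gb = toy_genome("B", {"b1": [f"b{i}" for i in range(20)]})
    pairs = [HomologPair(f"a{i}", f"b{j}") for i, j in zip(run_a, run_b)]
    return ga, gb, pairs


class TestAnchors:
    def test_run_of_three_consecutive_matches_is_one_anchor(self):
        ga, gb, pairs = _inter_setup([3, 4, 5], [7, 8, 9])
        anchors = seed_anchor_segments(pairs, (ga, gb))
        assert len(anchors) == 1 and anchors[0].n_pairs == 3

    def test_run_of_two_needs_relaxed_seeding(self):
        ga, gb, pairs = _inter_setup([3, 4], [7, 8])
        assert seed_anchor_segments(pairs, (ga, gb)) == []
        relaxed = seed_anchor_segments(pairs, (ga, gb), ChainParams(D=0, A=2))
        assert len(relaxed) == 1

    def test_run_of_four_survives_stricter_seeding(self):
        ga, gb, pairs = _inter_setup([3, 4, 5, 6], [7, 8, 9, 10])
        anchors = seed_anchor_segments(pairs, (ga, gb), ChainParams(D=0, A=4))
        assert len(anchors) == 1 and anchors[0].n_pairs == 4

    def test_nonzero_d_rejected(self):
        ga, gb, pairs = _inter_setup([1], [1])
        with pytest.raises(ValidationError):
            seed_anchor_segments(pairs, (ga, gb), ChainParams(D=1, A=3))


class TestPropagation:
    def test_anchor_plus_intragenomic_pair_share_one_word(self):
        ga, gb, pairs = _inter_setup([3, 4, 5], [7, 8, 9])
        anchors = seed_anchor_segments(pairs, (ga, gb))
        assign = propagate_paralog_words(anchors, [HomologPair("a3", "a10")], [])
        assert assign["a3"] == assign["a10"] == assign["b7"]

    def test_two_anchors_merged_by_shared_paralog(self):
        ga = toy_genome("A", {"a1": [f"a{i}" for i in range(10)], "a2": [f"x{i}" for i in range(10)]})
        gb = toy_genome("B", {"b1": [f"b{i}" for i in range(10)]})
        inter = [HomologPair(f"a{i}", f"b{i}") for i in (0, 1, 2)] + [
            HomologPair(f"x{i}", f"b{i + 4}") for i in (0, 1, 2)
        ]
        anchors = seed_anchor_segments(inter, (ga, gb))
        assert len(anchors) == 2
        bridged = propagate_paralog_words(anchors, [HomologPair("a0", "x0")], [])
        # independent connected-components oracle over the same edge set
        import networkx as nx

        g = nx.Graph()
        for blk in anchors:
            for p in blk.pairs:
                g.add_edge(p.gene_a, p.gene_b)
        g.add_edge("a0", "x0")
        comp = next(c for c in nx.connected_components(g) if "a0" in c)
        words = {bridged[x] for x in comp if x in bridged}
        assert len(words) == 1

    def test_isolated_gene_gets_no_word(self):
        ga, gb, pairs = _inter_setup([3, 4, 5], [7, 8, 9])
        anchors = seed_anchor_segments(pairs, (ga, gb))
        assign = propagate_paralog_words(anchors, [], [])
        assert "a0" not in assign

    def test_intra_only_component_without_anchor_is_unworded(self):
        ga, gb, pairs = _inter_setup([3, 4, 5], [7, 8, 9])
        anchors = seed_anchor_segments(pairs, (ga, gb))
        assign = propagate_paralog_words(anchors, [HomologPair("a15", "a16")], [])
        assert "a15" not in assign and "a16" not in assign


class TestEncoding:
    def test_worded_genes_in_rank_order_others_skipped(self):
        g = toy_genome("G", {"c": ["g0", "g1", "g2", "g3", "g4"]})
        assign = {"g1": 7, "g3": 2, "g4": 9}
        ws = encode_word_sequence(g, "c", assign)
        assert ws.words == [7, 2, 9]
        assert ws.gene_ids == ["g1", "g3", "g4"]

    def test_no_worded_genes_empty_sequence(self):
        g = toy_genome("G", {"c": ["g0"]})
        assert len(encode_word_sequence(g, "c", {})) == 0

    def test_all_worded_full_length(self):
        g = toy_genome("G", {"c": ["g0", "g1", "g2"]})
        ws = encode_word_sequence(g, "c", {"g0": 1, "g1": 2, "g2": 3})
        assert len(ws) == 3

    def test_gene_filter_restricts(self):
        g = toy_genome("G", {"c": ["g0", "g1"]})
        ws = encode_word_sequence(g, "c", {"g0": 1, "g1": 2}, gene_filter=lambda x: x.id == "g1")
        assert ws.words == [2]


class TestAlignment:
    def test_identical_sequences_score_full_matches(self):
        assert local_word_alignment([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 20

    def test_disjoint_vocabularies_score_zero(self):
        assert local_word_alignment([1, 2, 3], [4, 5, 6]) == 0

    def test_single_gap_costs_one(self):
        assert local_word_alignment([1, 2, 3, 4], [1, 2, 9, 3, 4]) == 15

    def test_empty_inputs_score_zero(self):
        assert local_word_alignment([], [1, 2]) == 0

    def test_invalid_scoring_rejected(self):
        with pytest.raises(ValidationError):
            local_word_alignment([1], [1], match=0)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(
        q=st.lists(st.integers(0, 5), min_size=1, max_size=8),
        t=st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    def test_matches_dynamic_programming_oracle(self, q, t):
        assert local_word_alignment(q, t) == biopython_local_score(q, t)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        q=st.lists(st.integers(0, 4), min_size=2, max_size=8),
        t=st.lists(st.integers(0, 4), min_size=2, max_size=8),
    )
    def test_score_symmetric_under_joint_reversal(self, q, t):
        assert local_word_alignment(q, t) == local_word_alignment(q[::-1], t[::-1])


class TestProfiles:
    def test_identical_sequences_every_window_full(self):
        q = WordSequence("q", list(range(10)))
        t = WordSequence("t", list(range(10)))
        prof = windowed_score_profile(q, t, N=4)
        assert len(prof) == 7
        assert all(s == 16 for s in prof.scores)

    def test_disjoint_words_all_zero(self):
        q = WordSequence("q", [1] * 6)
        t = WordSequence("t", [2] * 6)
        prof = windowed_score_profile(q, t, N=3)
        assert all(s == 0 for s in prof.scores)

    def test_inverted_window_scores_by_reversal(self):
        q = WordSequence("q", [3, 2, 1])
        t = WordSequence("t", [1, 2, 3])
        prof = windowed_score_profile(q, t, N=3)
        assert prof.scores.tolist() == [12]

    def test_profile_length_and_bound(self, medium_sim):
        from wgdkit.experiments import word_assignment_for

        assign = word_assignment_for(medium_sim)
        col = medium_sim.genomes["columbine"]
        gra = medium_sim.genomes["grape"]
        q = encode_word_sequence(col, next(iter(col.chromosomes)), assign)
        t = encode_word_sequence(gra, next(iter(gra.chromosomes)), assign)
        N = 8
        prof = windowed_score_profile(q, t, N)
        assert len(prof) == max(0, len(q) - N + 1)
        assert all(0 <= s <= 4 * min(N, len(t)) for s in prof.scores)

    def test_query_shorter_than_window_warns_empty(self):
        q = WordSequence("q", [1, 2])
        t = WordSequence("t", [1, 2, 3])
        with pytest.warns(UserWarning, match="empty profile"):
            prof = windowed_score_profile(q, t, N=5)
        assert len(prof) == 0

    def test_partner_profiles_dominate_nonpartner(self, medium_sim):
        """On a shared-tetraploidy simulation, profiles between truly
        co-descended chromosome pairs stochastically dominate profiles
        between non-partner pairs."""
        from wgdkit.experiments import clean_triplets, word_assignment_for
        from wgdkit.pairing import wilcoxon_w

        sim = medium_sim
        assign = word_assignment_for(sim)
        color, colmap, gramap = clean_triplets(sim)[0]
        col, gra = sim.genomes["columbine"], sim.genomes["grape"]
        f = lambda g: g.color == color
        q = encode_word_sequence(col, colmap["A"], assign, gene_filter=f)
        partner = encode_word_sequence(gra, gramap["A"], assign, gene_filter=f)
        other = encode_word_sequence(gra, gramap["C"], assign, gene_filter=f)
        p_true = windowed_score_profile(q, partner, 8).scores
        p_other = windowed_score_profile(q, other, 8).scores
        w = wilcoxon_w(p_true, p_other)
        assert w > 0.8 * len(p_true) * len(p_other)
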