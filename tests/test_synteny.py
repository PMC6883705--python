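"""Collinear chaining against a brute-force oracle, block filters, median
Ks, WGD-block selection, and partner ratios."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wgdkit.model import ChainParams, Gene, Genome, HomologPair, UndefinedMedianError, ValidationError
from wgdkit.model import BlockPair, SyntenyBlock
from wgdkit.synteny import (
    BlockFilterSpec,
    annotate_median_ks,
    block_median_ks,
    chain_collinear,
    filter_blocks,
    partner_ratio,
    select_wgd_blocks,
)

from conftest import brute_force_chain_blocks, toy_genome


def _two_genomes(n_a=40, n_b=40):
    ga = toy_genome("A", {"a1": [f"a{i}" for i in range(n_a)]})
    gb = toy_genome("B", {"b1": [f"b{i}" for i in range(n_b)]})
    return ga, gb


def _pairs_from_points(points):
    return [HomologPair(f"a{ra}", f"b{rb}") for ra, rb in points]


def _chain(points, D, A):
    ga, gb = _two_genomes()
    blocks = chain_collinear(_pairs_from_points(points), (ga, gb), ChainParams(D=D, A=A))
    return blocks


class TestChaining:
    def test_perfect_diagonal_single_parallel_block(self):
        blocks = _chain([(i, i) for i in range(5)], D=0, A=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "parallel"
        assert blocks[0].n_pairs == 5

    def test_two_matches_below_min_pairs_gives_nothing(self):
        assert _chain([(0, 0), (1, 1)], D=0, A=3) == []

    def test_antiparallel_run_detected(self):
        blocks = _chain([(0, 9), (1, 8), (2, 7), (3, 6)], D=0, A=3)
        assert len(blocks) == 1
        assert blocks[0].orientation == "antiparallel"

    def test_gap_skips_up_to_d_genes(self):
        # consecutive matches skip 2 genes on the subject: needs D >= 2
        pts = [(0, 0), (1, 3), (2, 6)]
        assert _chain(pts, D=1, A=3) == []
        blocks = _chain(pts, D=2, A=3)
        assert len(blocks) == 1

    def test_matches_mixed_runs_match_bruteforce(self):
        pts = [(i, i) for i in range(0, 12, 2)] + [(1, 11), (3, 9), (5, 7), (7, 5), (9, 3), (11, 1)]
        params = ChainParams(D=1, A=3)
        blocks = _chain(pts, D=1, A=3)
        expected = brute_force_chain_blocks([(ra, rb, f"a{ra}", f"b{rb}", None) for ra, rb in pts], params)
        got = [(b.orientation, tuple((p.rank_a, p.rank_b) for p in b.pairs)) for b in blocks]
        assert got == expected

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        points=st.sets(
            st.tuples(st.integers(0, 12), st.integers(0, 12)), min_size=1, max_size=14
        ),
        D=st.integers(0, 3),
        A=st.integers(1, 4),
    )
    def test_chaining_equals_bruteforce_enumeration(self, points, D, A):
        """The DP greedy peel must agree with exhaustive chain enumeration
        on every random instance with at most 14 matches."""
        params = ChainParams(D=D, A=A)
        blocks = _chain(sorted(points), D=D, A=A)
        pts5 = [(ra, rb, f"a{ra}", f"b{rb}", None) for ra, rb in points]
        expected = brute_force_chain_blocks(pts5, params)
        got = [(b.orientation, tuple((p.rank_a, p.rank_b) for p in b.pairs)) for b in blocks]
        assert got == expected

    def test_every_output_block_satisfies_params(self, small_sim):
        params = ChainParams(D=20, A=5)
        blocks = chain_collinear(
            small_sim.inter_pairs("columbine", "grape"),
            (small_sim.genomes["columbine"], small_sim.genomes["grape"]),
            params,
        )
        assert blocks
        for b in blocks:
            b.validate_against(params)

    def test_unknown_gene_rejected(self):
        ga, gb = _two_genomes(5, 5)
        with pytest.raises(ValidationError, match="ghost"):
            chain_collinear([HomologPair("a0", "ghost")], (ga, gb), ChainParams(0, 1))

    def test_intra_genome_chaining(self):
        g = toy_genome("G", {"c1": [f"g{i}" for i in range(10)], "c2": [f"h{i}" for i in range(10)]})
        pairs = [HomologPair(f"g{i}", f"h{i}") for i in range(6)]
        blocks = chain_collinear(pairs, g, ChainParams(D=0, A=5))
        assert len(blocks) == 1
        assert {blocks[0].chrom_a, blocks[0].chrom_b} == {"c1", "c2"}


def _mk_block(ca, cb, n=5, ks_values=None, genome_a="col", genome_b="gra"):
    ks_values = ks_values or [None] * n
    pairs = [BlockPair(f"{ca}g{i}", f"{cb}g{i}", i, i, ks_values[i % len(ks_values)]) for i in range(n)]
    return SyntenyBlock(genome_a=genome_a, genome_b=genome_b, chrom_a=ca, chrom_b=cb, pairs=pairs)


class TestBlockFilters:
    TRIPLETS = {"t1": ["g1", "g2", "g3"], "t2": ["g4", "g5", "g6"]}

    def test_within_paralogs_drops_cross_triplet_blocks(self):
        spec = BlockFilterSpec(mode="within_grape_paralogs", paralog_map=self.TRIPLETS)
        keep = _mk_block("g1", "g2")
        drop = _mk_block("g1", "g4")
        assert filter_blocks([keep, drop], spec) == [keep]

    def test_all_three_keeps_complete_and_drops_partial(self):
        spec = BlockFilterSpec(mode="columbine_to_all_three", paralog_map=self.TRIPLETS)
        complete = [_mk_block("c1", g) for g in ("g1", "g2", "g3")]
        partial = [_mk_block("c2", g) for g in ("g4", "g5")]  # only 2/3 members
        out = filter_blocks(complete + partial, spec)
        assert out == complete

    def test_four_member_fission_group_needs_three(self):
        spec = BlockFilterSpec(
            mode="columbine_to_all_three",
            paralog_map={"t": ["g1", "g2", "g3", "g4"]},
        )
        blocks = [_mk_block("c1", g) for g in ("g1", "g2", "g3")]
        assert filter_blocks(blocks, spec) == blocks

    def test_idempotent_and_never_adds(self):
        spec = BlockFilterSpec(mode="columbine_to_all_three", paralog_map=self.TRIPLETS)
        blocks = [_mk_block("c1", g) for g in ("g1", "g2", "g3", "g4")]
        once = filter_blocks(blocks, spec)
        assert filter_blocks(once, spec) == once
        assert set(id(b) for b in once) <= set(id(b) for b in blocks)

    def test_unmapped_chromosome_rejected(self):
        spec = BlockFilterSpec(mode="within_grape_paralogs", paralog_map=self.TRIPLETS)
        with pytest.raises(ValidationError):
            filter_blocks([_mk_block("g1", "g99")], spec)

    def test_bad_group_size_rejected(self):
        with pytest.raises(ValidationError):
            BlockFilterSpec(mode="within_grape_paralogs", paralog_map={"t": ["g1", "g2"]})


class TestBlockKs:
    def test_uniform_ks(self):
        b = _mk_block("a", "b", n=4, ks_values=[1.5])
        assert block_median_ks(b) == 1.5

    def test_saturated_values_excluded_before_median(self):
        b = _mk_block("a", "b", n=3, ks_values=[0.5, 1.0, 11.0])
        assert block_median_ks(b) == pytest.approx(0.75)

    def test_all_saturated_flags_undefined(self):
        b = _mk_block("a", "b", n=2, ks_values=[12.0, 13.0])
        with pytest.raises(UndefinedMedianError):
            block_median_ks(b)
        annotate_median_ks([b])
        assert not b.median_ks_defined

    def test_selection_bounds_inclusive(self):
        vals = [1.5, 0.2, 1.0, 2.0, 2.01]
        blocks = []
        for v in vals:
            b = _mk_block("a", "b", n=2, ks_values=[v])
            annotate_median_ks([b])
            blocks.append(b)
        kept = select_wgd_blocks(blocks)
        assert [b.median_ks for b in kept] == [1.5, 1.0, 2.0]
        with pytest.raises(ValidationError):
            select_wgd_blocks(blocks, lo=2.0, hi=1.0)


class TestPartnerRatio:
    def test_three_to_two_structure(self):
        blocks, labels = [], []
        for color in ("red", "blue"):
            for gc in range(3):
                for cc in range(2):
                    blocks.append(_mk_block(f"{color}col{cc}", f"{color}gra{gc}"))
                    labels.append(color)
        rs = partner_ratio(blocks, dict(enumerate(labels)))
        assert rs.modal_ratio == (2, 3)
        assert rs.per_group == {"red": (2, 3), "blue": (2, 3)}

    def test_three_to_six_reported_unreduced(self):
        blocks, labels = [], []
        for gc in range(6):
            for cc in range(3):
                blocks.append(_mk_block(f"col{cc}", f"gra{gc}"))
                labels.append("c")
        rs = partner_ratio(blocks, dict(enumerate(labels)))
        assert rs.modal_ratio == (3, 6)
        assert rs.modal_ratio_reduced == (1, 2)

    def test_single_block_is_one_to_one(self):
        rs = partner_ratio([_mk_block("x", "y")], {0: "c"})
        assert rs.modal_ratio == (1, 1)

    def test_empty_input_empty_summary(self):
        rs = partner_ratio([], {})
        assert rs.modal_ratio is None and rs.per_group == {}
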