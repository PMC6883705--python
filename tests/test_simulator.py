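"""Simulator contracts: polyploidy arithmetic, biased fractionation,
rearrangement conservation, Ks ages, replay, determinism."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from wgdkit.model import ValidationError
from wgdkit.simulate import (
    SimulationConfig,
    apply_polyploidy,
    assign_ks,
    fractionate,
    generate_scenario,
    make_ancestral_genome,
    rearrange,
    replay,
    simulate_poppy_comparison,
)


def _gene_multiset(genome):
    return Counter(g.id for g in genome.genes())


def _chrom_layout(genome):
    return {
        cid: [(g.id, g.strand) for g in genes]
        for cid, genes in genome.chromosomes.items()
    }


class TestAncestralGenome:
    def test_counts_and_unique_families(self):
        g = make_ancestral_genome(7, 200, seed=1)
        assert g.n_chromosomes == 7
        assert g.n_genes == 1400
        fams = [x.family for x in g.genes()]
        assert len(set(fams)) == 1400

    def test_single_gene_genome(self):
        g = make_ancestral_genome(1, 1, seed=0)
        assert g.n_genes == 1

    def test_seed_determinism(self):
        a = make_ancestral_genome(3, 50, seed=9)
        b = make_ancestral_genome(3, 50, seed=9)
        c = make_ancestral_genome(3, 50, seed=10)
        assert _chrom_layout(a) == _chrom_layout(b)
        flags_a = [g.dosage_sensitive for g in a.genes()]
        flags_c = [g.dosage_sensitive for g in c.genes()]
        assert flags_a != flags_c

    def test_invalid_arguments(self):
        with pytest.raises(ValidationError):
            make_ancestral_genome(0, 10, seed=0)


class TestPolyploidy:
    def test_auto_doubles_chromosomes_and_copies(self):
        anc = make_ancestral_genome(7, 20, seed=1)
        tetra = apply_polyploidy(anc, mode="auto")
        assert tetra.n_chromosomes == 14
        fams = Counter(g.family for g in tetra.genes())
        assert set(fams.values()) == {2}

    def test_allo_merge_counts(self):
        a = make_ancestral_genome(13, 5, seed=1)
        b = make_ancestral_genome(7, 5, seed=2)
        for gene in b.genes():
            gene.id = "p:" + gene.id
        for cid in list(b.chromosomes):
            b.chromosomes["p:" + cid] = b.chromosomes.pop(cid)
        b.reindex()
        merged = apply_polyploidy([a, b], mode="allo")
        assert merged.n_chromosomes == 20

    def test_auto_twice_gives_four_copies(self):
        anc = make_ancestral_genome(7, 10, seed=1)
        octo = apply_polyploidy(apply_polyploidy(anc, "auto"), "auto")
        assert octo.n_chromosomes == 28
        fams = Counter(g.family for g in octo.genes())
        assert set(fams.values()) == {4}

    def test_allo_requires_two_parents(self):
        anc = make_ancestral_genome(2, 5, seed=1)
        with pytest.raises(ValidationError):
            apply_polyploidy([anc], mode="allo")


class TestFractionation:
    def test_zero_probability_is_identity(self):
        tetra = apply_polyploidy(make_ancestral_genome(3, 30, seed=4), "auto")
        out = fractionate(tetra, deletion_prob=0.0, bias=0.7, seed=1)
        assert _chrom_layout(out) == _chrom_layout(tetra)

    def test_full_deletion_leaves_single_copies(self):
        anc = make_ancestral_genome(3, 30, seed=4, dosage_sensitive_frac=0.0)
        tetra = apply_polyploidy(anc, "auto")
        out = fractionate(tetra, deletion_prob=1.0, bias=0.7, seed=1)
        fams = Counter(g.family for g in out.genes())
        assert set(fams.values()) == {1}

    def test_deletion_count_within_binomial_bounds(self):
        anc = make_ancestral_genome(5, 200, seed=4, dosage_sensitive_frac=0.0)
        tetra = apply_polyploidy(anc, "auto")  # 1000 duplicated families
        out = fractionate(tetra, deletion_prob=0.3, bias=0.7, seed=11)
        deleted = tetra.n_genes - out.n_genes
        sd = np.sqrt(1000 * 0.3 * 0.7)
        assert abs(deleted - 300) <= 3 * sd

    def test_bias_targets_sensitive_copy(self):
        anc = make_ancestral_genome(5, 200, seed=4, dosage_sensitive_frac=0.0)
        tetra = apply_polyploidy(anc, "auto")
        out = fractionate(tetra, deletion_prob=1.0, bias=0.9, seed=3, sensitive_copy="B")
        survivors = Counter(g.copy_label for g in out.genes())
        assert survivors["A"] > survivors["B"] * 3

    def test_dosage_sensitive_families_never_reduced(self):
        anc = make_ancestral_genome(4, 100, seed=4, dosage_sensitive_frac=0.3)
        tetra = apply_polyploidy(anc, "auto")
        out = fractionate(tetra, deletion_prob=1.0, bias=0.7, seed=1)
        for fam, genes in out.families().items():
            if any(g.dosage_sensitive for g in genes):
                assert len(genes) == 2

    def test_bias_range_enforced(self):
        tetra = apply_polyploidy(make_ancestral_genome(2, 10, seed=1), "auto")
        with pytest.raises(ValidationError):
            fractionate(tetra, deletion_prob=0.5, bias=0.3, seed=1)


class TestRearrange:
    def test_fusion_count_arithmetic_and_conservation(self):
        g = make_ancestral_genome(13, 20, seed=2)
        fused = rearrange(g, fusions=[("chr1", "chr2")], seed=0)
        assert fused.n_chromosomes == 12
        assert _gene_multiset(fused) == _gene_multiset(g)

    def test_seven_fusions_one_fission_reaches_seven(self):
        g = make_ancestral_genome(13, 20, seed=2)
        fusions = [(f"chr{i}", f"chr{i + 1}") for i in range(1, 13, 2)]  # 6 fusions
        out = rearrange(g, fusions=fusions, seed=0)
        out = rearrange(out, fusions=[("chr1+chr2", "chr3+chr4")], seed=0)
        out = rearrange(out, fissions=[("chr13", 10)], seed=0)
        assert out.n_chromosomes == 13 - 7 + 1
        assert _gene_multiset(out) == _gene_multiset(g)

    def test_inversion_is_involution(self):
        g = make_ancestral_genome(1, 10, seed=3)
        once = rearrange(g, inversions=[("chr1", 2, 5)], seed=0)
        assert _chrom_layout(once) != _chrom_layout(g)
        twice = rearrange(once, inversions=[("chr1", 2, 5)], seed=0)
        assert _chrom_layout(twice) == _chrom_layout(g)

    def test_inversion_flips_strands(self):
        g = make_ancestral_genome(1, 6, seed=3)
        before = [gene.strand for gene in g.chromosomes["chr1"]]
        out = rearrange(g, inversions=[("chr1", 1, 3)], seed=0)
        after = [gene.strand for gene in out.chromosomes["chr1"]]
        flip = {"+": "-", "-": "+"}
        assert after[1:4] == [flip[s] for s in reversed(before[1:4])]

    def test_breakpoint_outside_chromosome_rejected(self):
        g = make_ancestral_genome(1, 10, seed=3)
        with pytest.raises(ValidationError):
            rearrange(g, fissions=[("chr1", 50)], seed=0)


class TestKsAssignment:
    def test_zero_sigma_gives_exact_event_ages(self):
        cfg = SimulationConfig(genes_per_chrom=40, ks_sigma=0.0, tandem_rate=0.0, seed=5)
        sim = generate_scenario(cfg)
        ages = {round(p.ks, 6) for p in sim.intra_pairs("grape")}
        assert ages <= {cfg.t_tetra, cfg.t_hexa}
        inter = {round(p.ks, 6) for p in sim.inter_pairs("columbine", "grape")}
        assert inter <= {cfg.t_split, cfg.t_tetra}

    def test_tandem_pairs_have_birth_ages(self):
        cfg = SimulationConfig(genes_per_chrom=60, ks_sigma=0.0, tandem_rate=0.2, seed=5)
        sim = generate_scenario(cfg)
        tandem_ids = {g.id for g in sim.genomes["columbine"].genes() if g.birth is not None}
        assert tandem_ids
        event_ages = {cfg.t_tetra, cfg.t_split, cfg.t_hexa}
        for p in sim.intra_pairs("columbine"):
            if p.gene_a in tandem_ids or p.gene_b in tandem_ids:
                if round(p.ks, 6) not in event_ages:
                    assert p.ks < cfg.t_split  # tandems born after the split

    def test_ks_modes_recover_event_ages(self):
        cfg = SimulationConfig(
            genes_per_chrom=200, t_tetra=1.5, t_hexa=1.2, ks_sigma=0.15,
            tandem_rate=0.0, seed=6,
        )
        sim = generate_scenario(cfg)
        led = sim.ledger
        idx = {}
        for lin in ("grape",):
            idx.update({g.id: g for g in sim.genomes[lin].genes()})
        old, young = [], []
        for p in sim.intra_pairs("grape"):
            ca = idx[p.gene_a].copy_label
            cb = idx[p.gene_b].copy_label
            age = led.div_age("grape", ca, "grape", cb)
            (old if age == 1.5 else young).append(p.ks)
        assert len(old) >= 500 and len(young) >= 500
        assert abs(np.mean(old) - 1.5) < 0.02
        assert abs(np.mean(young) - 1.2) < 0.02

    def test_negative_sigma_rejected(self, small_sim):
        with pytest.raises(ValidationError):
            assign_ks(small_sim.ledger, small_sim.genomes, ks_sigma=-0.1, seed=0)


class TestGenerateScenario:
    def test_scenario1_copy_ratio_6_to_3(self):
        cfg = SimulationConfig(scenario=1, genes_per_chrom=40, deletion_prob=0.0,
                               tandem_rate=0.0, seed=7)
        sim = generate_scenario(cfg)
        col_copies = {g.copy_label for g in sim.genomes["columbine"].genes()}
        gra_copies = {g.copy_label for g in sim.genomes["grape"].genes()}
        assert len(col_copies) == 6
        assert len(gra_copies) == 3

    def test_scenario3_allo_names_one_outlier_subgenome(self, small_sim):
        assert small_sim.ledger.outlier_copy == "C"
        assert small_sim.ledger.outlier_chroms
        for chrom in small_sim.ledger.outlier_chroms:
            copies = {
                g.copy_label for g in small_sim.genomes["grape"].chromosomes[chrom]
            }
            assert "C" in copies

    def test_chromosome_counts_follow_event_arithmetic(self, small_sim):
        led = small_sim.ledger
        for lin in ("columbine", "grape"):
            counts = led.event_counts(lin)
            n_final = small_sim.genomes[lin].n_chromosomes
            n_start = n_final + counts["fusions"] - counts["fissions"]
            assert n_start >= 7

    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(genes_per_chrom=40, seed=99)
        a = generate_scenario(cfg)
        b = generate_scenario(SimulationConfig(genes_per_chrom=40, seed=99))
        for lin in a.genomes:
            assert _chrom_layout(a.genomes[lin]) == _chrom_layout(b.genomes[lin])
        for key in a.pairs:
            assert [(p.gene_a, p.gene_b, p.ks) for p in a.pairs[key]] == [
                (p.gene_a, p.gene_b, p.ks) for p in b.pairs[key]
            ]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(scenario=3, t_tetra=1.0, t_split=1.5, t_hexa=0.5)
        with pytest.raises(ValidationError):
            SimulationConfig(hexaploidy_mode="weird")
        with pytest.raises(ValidationError):
            SimulationConfig(fractionation_bias=0.2)

    def test_include_cacao_adds_third_genome(self):
        cfg = SimulationConfig(genes_per_chrom=40, include_cacao=True, seed=8)
        sim = generate_scenario(cfg)
        assert "cacao" in sim.genomes
        assert sim.inter_pairs("columbine", "cacao")
        assert sim.inter_pairs("cacao", "grape")


class TestReplayProperty:
    @pytest.mark.parametrize("scenario,mode", [(1, "auto"), (2, "allo"), (3, "allo"), (3, "auto")])
    def test_replay_reproduces_emitted_genomes(self, scenario, mode):
        cfg = SimulationConfig(scenario=scenario, hexaploidy_mode=mode,
                               genes_per_chrom=30, seed=17)
        sim = generate_scenario(cfg)
        rebuilt = replay(sim.ledger)
        assert set(rebuilt) == set(sim.genomes)
        for lin in sim.genomes:
            assert _chrom_layout(rebuilt[lin]) == _chrom_layout(sim.genomes[lin])

    def test_only_deletions_change_gene_content(self):
        cfg = SimulationConfig(genes_per_chrom=30, deletion_prob=0.0, tandem_rate=0.0,
                               progenitor_deletion_prob=0.0, seed=18)
        sim = generate_scenario(cfg)
        # no deletions anywhere: every family keeps all its copies
        assert not any(
            ev["op"] == "delete" and ev["genes"] for ev in sim.ledger.events
        )
        col = sim.genomes["columbine"]
        assert col.n_genes == 7 * 30 * 2


def test_poppy_comparison_has_four_and_two_copies():
    sim = simulate_poppy_comparison(seed=3, genes_per_chrom=40)
    poppy = {g.copy_label for g in sim.genomes["poppy"].genes()}
    col = {g.copy_label for g in sim.genomes["columbine"].genes()}
    assert len(poppy) == 4
    assert len(col) == 2
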