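"""Simulation-based experiment harnesses.

These functions wire the simulator to the synteny, word-alignment and
pairing machinery: partner-ratio measurement, triplet pairing analysis with
truth evaluation, scenario-recovery experiments over the full
scenario x hexaploidy-mode design, and the poppy-style comparison in which
one basal lineage carries an extra recent WGD.

Problem sizes used by the bundled experiments (replicate counts, genes per
chromosome, permutation counts) are the package's own defaults for
desk-scale reproduction; the full-size study conditions (7 chromosomes x
200 genes, 100 permutations) are used for the single-dataset checks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import ChainParams
from .pairing import (
    PairingResult,
    PermutationTest,
    ScenarioCall,
    classify_history,
    infer_exclusive_pairing,
    classify_leftover,
    paralog_partner_test,
    permutation_pvalue,
)
from .simulate import (
    SimulationConfig,
    SimulationResult,
    generate_scenario,
    simulate_poppy_comparison,
)
from .synteny import RatioSummary, annotate_median_ks, chain_collinear, partner_ratio
from .words import WordScoring, encode_word_sequence, propagate_paralog_words

__all__ = [
    "block_colors",
    "ratio_summary_for",
    "word_assignment_for",
    "clean_triplets",
    "pairing_analysis",
    "classify_simulation",
    "evaluate_call",
    "scenario_recovery_experiment",
    "ratio_experiment",
    "true_pairing_test",
    "poppy_partner_ratio",
]


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def block_colors(sim: SimulationResult, blocks) -> list[str]:
    """Ancestral homology group per block: the modal truth color of its
    gene pairs."""
    origins = {}
    for lin in sim.genomes:
        origins.update(sim.gene_origins(lin))
    labels = []
    for b in blocks:
        counts = Counter(origins[p.gene_a][0] for p in b.pairs if p.gene_a in origins)
        labels.append(counts.most_common(1)[0][0])
    return labels


def ratio_summary_for(
    sim: SimulationResult,
    lineage_a: str = "columbine",
    lineage_b: str = "grape",
    params: ChainParams = ChainParams(D=20, A=5),
) -> RatioSummary:
    """Chain inter-genome blocks and summarise distinct-partner counts per
    ancestral color.  Side "a" of the ratio is ``lineage_a``."""
    blocks = chain_collinear(
        sim.inter_pairs(lineage_a, lineage_b),
        (sim.genomes[lineage_a], sim.genomes[lineage_b]),
        params,
    )
    annotate_median_ks(blocks)
    colors = block_colors(sim, blocks)
    return partner_ratio(blocks, dict(enumerate(colors)))


def word_assignment_for(
    sim: SimulationResult,
    lineage_a: str = "columbine",
    lineage_b: str = "grape",
    anchor_params: ChainParams = ChainParams(D=0, A=3),
) -> dict[str, int]:
    """Seed anchors between the two genomes and propagate words through the
    intragenomic homology of both."""
    anchors = chain_collinear(
        sim.inter_pairs(lineage_a, lineage_b),
        (sim.genomes[lineage_a], sim.genomes[lineage_b]),
        anchor_params,
    )
    return propagate_paralog_words(
        anchors, sim.intra_pairs(lineage_a), sim.intra_pairs(lineage_b)
    )


def clean_triplets(
    sim: SimulationResult,
    lineage_a: str = "columbine",
    lineage_b: str = "grape",
) -> list[tuple[str, dict[str, str], dict[str, str]]]:
    """Colors whose basal units sit on two distinct chromosomes and whose
    core units sit on three: the triplets eligible for pairing analysis.
    Returns (color, basal copy->chrom, core copy->chrom) records."""
    out = []
    for color in sorted(sim.ledger.true_pairing):
        entry = sim.ledger.true_pairing[color]
        colmap = entry.get(lineage_a, {})
        gramap = entry.get(lineage_b, {})
        if len(colmap) == 2 and len(set(colmap.values())) == 2 and len(set(gramap.values())) == 3:
            out.append((color, dict(colmap), dict(gramap)))
    return out


@dataclass
class PairingAnalysis:
    results: list[PairingResult] = field(default_factory=list)
    truth: dict[str, dict[str, str]] = field(default_factory=dict)  # color -> copy->true chrom


def pairing_analysis(
    sim: SimulationResult,
    N: int = 8,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    max_colors: Optional[int] = None,
    scoring: WordScoring = WordScoring(),
    lineage_a: str = "columbine",
    lineage_b: str = "grape",
) -> PairingAnalysis:
    """Per-color triplet pairing tests between the basal paralog pair and
    the core triplet, on word sequences restricted to each color's region."""
    assign = word_assignment_for(sim, lineage_a, lineage_b)
    col = sim.genomes[lineage_a]
    gra = sim.genomes[lineage_b]
    analysis = PairingAnalysis()
    for color, colmap, gramap in clean_triplets(sim, lineage_a, lineage_b):
        if max_colors is not None and len(analysis.results) >= max_colors:
            break
        triplet = sorted(set(gramap.values()))
        targets = {
            c: encode_word_sequence(gra, c, assign, gene_filter=lambda g, col_=color: g.color == col_)
            for c in triplet
        }
        if min(len(w) for w in targets.values()) < N + 2:
            continue
        tests = {}
        queries = {}
        skip = False
        for k, copy in enumerate(sorted(colmap)):
            qchrom = colmap[copy]
            q = encode_word_sequence(
                col, qchrom, assign, gene_filter=lambda g, col_=color: g.color == col_
            )
            if len(q) < N + 2:
                skip = True
                break
            queries[qchrom] = q
            tests[qchrom] = paralog_partner_test(
                q,
                targets,
                N=N,
                n_perm=n_perm,
                seed=_derive_seed(seed, sum(ord(ch) for ch in color), k),
                alpha=alpha,
                scoring=scoring,
            )
        if skip or not tests:
            continue
        # when the pairing is exclusive, decide whether the leftover
        # triplet member is a duplicated partner (autopolyploidy) or a
        # hybridization-derived outlier
        leftover_call = None
        singles = {q: t.partner for q, t in tests.items() if t.partner is not None}
        if len(singles) == 2 and len({s[0] for s in singles.values()}) == 2:
            leftover = sorted(set(triplet) - {s[0] for s in singles.values()})
            if len(leftover) == 1 and len(targets[leftover[0]]) >= N + 2:
                partner_of = {q: targets[p[0]] for q, p in singles.items()}
                verdict = classify_leftover(
                    targets[leftover[0]],
                    queries,
                    partner_of,
                    N=N,
                    n_perm=n_perm,
                    seed=_derive_seed(seed, sum(ord(ch) for ch in color), 99),
                    alpha=alpha,
                    scoring=scoring,
                )
                leftover_call = verdict["call"]
        analysis.results.append(
            infer_exclusive_pairing(
                tests, triplet, alpha=alpha, label=color, leftover_call=leftover_call
            )
        )
        analysis.truth[color] = dict(colmap)
    return analysis


def classify_simulation(
    sim: SimulationResult,
    N: int = 8,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    max_colors: Optional[int] = 3,
    ratio_params: ChainParams = ChainParams(D=20, A=5),
) -> ScenarioCall:
    """Full classification of one simulated dataset: ratio first (a 3:6
    structure short-circuits to the extra-WGD call), then triplet pairing."""
    ratio = ratio_summary_for(sim, params=ratio_params)
    call = classify_history(ratio, pairings=())
    if call.tetraploidy == "lineage_specific_extra":
        return call
    analysis = pairing_analysis(
        sim, N=N, n_perm=n_perm, alpha=alpha, seed=seed, max_colors=max_colors
    )
    return classify_history(ratio, pairings=analysis.results)


_EXPECTED_TETRAPLOIDY = {1: "lineage_specific_extra", 2: "independent", 3: "shared"}


def evaluate_call(sim: SimulationResult, call: ScenarioCall) -> dict:
    """Score a scenario call against the truth ledger.

    Correct means: the tetraploidy class matches; for shared (scenario 3)
    calls the hexaploidy mode must also match, and under allohexaploidy
    every reported outlier chromosome must belong to the true outlier
    subgenome (with at least one reported).
    """
    cfg = sim.config
    expected = _EXPECTED_TETRAPLOIDY[cfg.scenario]
    tetra_ok = call.tetraploidy == expected
    mode_ok: Optional[bool] = None
    outlier_ok: Optional[bool] = None
    if cfg.scenario == 3 and tetra_ok:
        mode_ok = call.hexaploidy_mode == cfg.hexaploidy_mode
        if cfg.hexaploidy_mode == "allo" and mode_ok:
            true_set = set(sim.ledger.outlier_chroms)
            called = set(call.outlier_chroms)
            outlier_ok = bool(called) and called <= true_set
    correct = tetra_ok
    if mode_ok is not None:
        correct = correct and mode_ok
    if outlier_ok is not None:
        correct = correct and outlier_ok
    return {
        "tetraploidy_correct": tetra_ok,
        "mode_correct": mode_ok,
        "outlier_correct": outlier_ok,
        "correct": correct,
    }


def scenario_recovery_experiment(
    n_replicates: int = 20,
    seed: int = 0,
    genes_per_chrom: int = 120,
    n_perm: int = 50,
    N: int = 8,
    max_colors: int = 5,
    scenarios=(1, 2, 3),
    modes=("auto", "allo"),
) -> dict:
    """Classification accuracy over the scenario x hexaploidy-mode design.

    Returns per-cell and overall accuracy plus the individual calls.
    """
    cells = {}
    n_correct = n_total = 0
    for scenario in scenarios:
        for mode in modes:
            outcomes = []
            for r in range(n_replicates):
                rep_seed = _derive_seed(seed, scenario, 10 + (mode == "allo"), r)
                cfg = SimulationConfig(
                    scenario=scenario,
                    hexaploidy_mode=mode,
                    genes_per_chrom=genes_per_chrom,
                    seed=rep_seed,
                )
                sim = generate_scenario(cfg)
                call = classify_simulation(
                    sim, N=N, n_perm=n_perm, seed=rep_seed, max_colors=max_colors
                )
                outcomes.append(evaluate_call(sim, call))
            acc = sum(o["correct"] for o in outcomes) / len(outcomes)
            cells[(scenario, mode)] = {"accuracy": acc, "outcomes": outcomes}
            n_correct += sum(o["correct"] for o in outcomes)
            n_total += len(outcomes)
    return {
        "cells": cells,
        "overall_accuracy": n_correct / n_total,
        "n_correct": n_correct,
        "n_total": n_total,
    }


def ratio_experiment(
    n_replicates: int = 20,
    seed: int = 0,
    genes_per_chrom: int = 100,
) -> dict:
    """Modal partner-ratio recovery: scenario 2/3 simulations should give a
    basal:core ratio of 2:3 and scenario 1 simulations 6:3."""
    results = {"shared_arm": [], "extra_arm": []}
    # shared/independent arm: half scenario 3, half scenario 2
    for r in range(n_replicates):
        scenario = 3 if r % 2 == 0 else 2
        cfg = SimulationConfig(
            scenario=scenario,
            genes_per_chrom=genes_per_chrom,
            seed=_derive_seed(seed, 1000 + scenario, r),
        )
        ratio = ratio_summary_for(generate_scenario(cfg))
        results["shared_arm"].append(ratio.modal_ratio)
    for r in range(n_replicates):
        cfg = SimulationConfig(
            scenario=1,
            genes_per_chrom=genes_per_chrom,
            seed=_derive_seed(seed, 4000, r),
        )
        ratio = ratio_summary_for(generate_scenario(cfg))
        results["extra_arm"].append(ratio.modal_ratio)
    results["shared_correct"] = sum(1 for m in results["shared_arm"] if m == (2, 3))
    results["extra_correct"] = sum(1 for m in results["extra_arm"] if m == (6, 3))
    results["n"] = n_replicates
    return results


def true_pairing_test(
    seed: int = 1,
    genes_per_chrom: int = 200,
    N: int = 8,
    n_perm: int = 100,
    scenario: int = 3,
    mode: str = "allo",
) -> PermutationTest:
    """Permutation test of the *true* basal-core chromosome pairing on a
    freshly simulated dataset (first eligible color, basal copy A against
    its true partner within the core triplet)."""
    cfg = SimulationConfig(
        scenario=scenario,
        hexaploidy_mode=mode,
        genes_per_chrom=genes_per_chrom,
        seed=seed,
    )
    sim = generate_scenario(cfg)
    assign = word_assignment_for(sim)
    col, gra = sim.genomes["columbine"], sim.genomes["grape"]
    for color, colmap, gramap in clean_triplets(sim):
        triplet = sorted(set(gramap.values()))
        targets = {
            c: encode_word_sequence(gra, c, assign, gene_filter=lambda g, col_=color: g.color == col_)
            for c in triplet
        }
        copy = sorted(colmap)[0]
        q = encode_word_sequence(
            col, colmap[copy], assign, gene_filter=lambda g, col_=color: g.color == col_
        )
        if len(q) < N + 2 or min(len(w) for w in targets.values()) < N + 2:
            continue
        return permutation_pvalue(
            q,
            targets,
            gramap[copy],
            N=N,
            n_perm=n_perm,
            seed=_derive_seed(seed, 31),
        )
    raise RuntimeError("no eligible color triplet in the simulation")


def poppy_partner_ratio(
    seed: int = 1, genes_per_chrom: int = 150
) -> tuple[RatioSummary, float]:
    """Partner-count ratio between a recently re-duplicated basal lineage
    ("poppy", 4 copies per ancestral color) and the columbine-like lineage
    (2 copies).  Returns the summary and poppy-count / columbine-count of
    the modal ratio (expected 4:2 = 2.0)."""
    sim = simulate_poppy_comparison(seed=seed, genes_per_chrom=genes_per_chrom)
    ratio = ratio_summary_for(sim, lineage_a="poppy", lineage_b="columbine")
    a, b = ratio.modal_ratio
    return ratio, a / b
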