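"""One-command orchestration: simulate (or ingest) -> chain -> filter ->
Ks-select -> words -> profiles -> pairing tests -> classify -> karyotype ->
enrichment, with every stage's outputs written to the run directory.

Configuration is a TOML file with per-stage sections; the same dictionary
schema is accepted directly from Python.  Reports are reproducible
byte-identically from config+seed (timings go to the log, not the report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as wio
from .enrichment import detect_tandems, enrichment_scan
from .experiments import (
    classify_simulation,
    pairing_analysis,
    ratio_summary_for,
)
from .karyotype import count_events, paint_from_origins, write_painting
from .model import ChainParams, ValidationError
from .simulate import SimulationConfig, generate_scenario, simulate_annotations
from .synteny import annotate_median_ks, chain_collinear, select_wgd_blocks

__all__ = ["RunConfig", "RunReport", "load_config", "run_pipeline", "run_real_pipeline"]

logger = logging.getLogger("wgdkit")


@dataclass
class RunConfig:
    """Pipeline configuration (synthetic mode)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    chain_D: int = 20
    chain_A: int = 5
    ks_lo: float = 1.0
    ks_hi: float = 2.0
    ks_cap: float = 10.0
    N: int = 8
    n_perm: int = 100
    alpha: float = 0.05
    max_colors: Optional[int] = 5
    tandem_max_gap: int = 10
    outdir: Optional[str] = None


def load_config(path) -> RunConfig:
    """Read a TOML config with [simulation], [synteny], [words], [test] and
    [enrichment] sections (all optional)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim_kwargs = raw.get("simulation", {})
    plans = {}
    for key in ("columbine_plan", "grape_plan", "cacao_plan"):
        if key in sim_kwargs:
            from .simulate import LineagePlan

            plans[key] = LineagePlan(**sim_kwargs.pop(key))
    sim = SimulationConfig(**sim_kwargs, **plans)
    syn = raw.get("synteny", {})
    words = raw.get("words", {})
    test = raw.get("test", {})
    enr = raw.get("enrichment", {})
    return RunConfig(
        simulation=sim,
        chain_D=syn.get("D", 20),
        chain_A=syn.get("A", 5),
        ks_lo=syn.get("ks_lo", 1.0),
        ks_hi=syn.get("ks_hi", 2.0),
        ks_cap=syn.get("ks_cap", 10.0),
        N=words.get("N", 8),
        n_perm=test.get("n_perm", 100),
        alpha=test.get("alpha", 0.05),
        max_colors=test.get("max_colors", 5),
        tandem_max_gap=enr.get("tandem_max_gap", 10),
        outdir=raw.get("outdir"),
    )


@dataclass
class RunReport:
    """Deterministic summary of one pipeline run."""

    config: dict
    seed: int
    n_blocks: int
    n_wgd_blocks: int
    ratio_per_group: dict
    modal_ratio: Optional[list]
    pairing: list
    scenario_call: dict
    event_counts: dict
    enrichment_top: list
    outputs: dict

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def run_pipeline(config, outdir=None) -> RunReport:
    """Run the full synthetic-mode pipeline.

    ``config`` is a :class:`RunConfig`, a TOML path, or a dict of RunConfig
    fields.  Outputs (gene tables, pair tables, blocks, painting, report)
    are written under ``outdir`` when given.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = RunConfig(**config)
    cfg = config
    out = Path(outdir or cfg.outdir) if (outdir or cfg.outdir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    t0 = time.time()

    logger.info("simulating scenario %s (%s)", cfg.simulation.scenario, cfg.simulation.hexaploidy_mode)
    sim = generate_scenario(cfg.simulation)
    seed = cfg.simulation.seed
    if out is not None:
        for lin, genome in sim.genomes.items():
            p = out / f"genes_{lin}.tsv"
            wio.write_gene_table(genome, p)
            outputs[f"genes_{lin}"] = str(p)
        for key, pairs in sim.pairs.items():
            p = out / f"pairs_{key.replace(':', '_').replace('~', '_')}.tsv"
            wio.write_homolog_table(pairs, p)
            outputs[f"pairs_{key}"] = str(p)
        sim.ledger.write(out / "truth.json")
        outputs["truth"] = str(out / "truth.json")

    logger.info("chaining blocks at D:A=%d:%d", cfg.chain_D, cfg.chain_A)
    params = ChainParams(D=cfg.chain_D, A=cfg.chain_A)
    blocks = chain_collinear(
        sim.inter_pairs("columbine", "grape"),
        (sim.genomes["columbine"], sim.genomes["grape"]),
        params,
    )
    annotate_median_ks(blocks, cfg.ks_cap)
    wgd_blocks = select_wgd_blocks(blocks, cfg.ks_lo, cfg.ks_hi)
    if out is not None:
        wio.write_blocks(blocks, out / "blocks.tsv")
        wio.write_blocks(wgd_blocks, out / "blocks_wgd.tsv")
        outputs["blocks"] = str(out / "blocks.tsv")
        outputs["blocks_wgd"] = str(out / "blocks_wgd.tsv")

    logger.info("partner ratios")
    ratio = ratio_summary_for(sim, params=params)

    logger.info("word encoding + pairing tests (N=%d, %d permutations)", cfg.N, cfg.n_perm)
    analysis = pairing_analysis(
        sim, N=cfg.N, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=seed, max_colors=cfg.max_colors
    )
    pairing_report = [
        {
            "color": pr.label,
            "triplet": pr.triplet,
            "assignments": {q: list(a) if a else None for q, a in pr.assignments.items()},
            "exclusive": pr.exclusive,
            "outlier": pr.outlier,
            "mode_vote": pr.mode_vote,
            "p_values": {q: t.p_best for q, t in pr.tests.items()},
        }
        for pr in analysis.results
    ]

    logger.info("scenario classification")
    call = classify_simulation(
        sim, N=cfg.N, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=seed, max_colors=cfg.max_colors
    )
    call_report = {
        "tetraploidy": call.tetraploidy,
        "hexaploidy_mode": call.hexaploidy_mode,
        "outlier_chroms": call.outlier_chroms,
        "evidence": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in call.evidence.items()
        },
    }

    logger.info("karyotype event accounting")
    events = {}
    for lin in ("columbine", "grape"):
        painting = paint_from_origins(sim.genomes[lin])
        # initial units: distinct (color, copy) units present in the lineage
        units = {
            (g.color, g.copy_label) for g in sim.genomes[lin].genes() if g.origin
        }
        # an ancestral (pre-split) fusion joins two units without a
        # lineage-specific event; subtract junctions shared by construction
        n_ancestral_fusions = sum(
            1 for ev in sim.ledger.events if ev["op"] == "fuse" and ev.get("kind") == "ancestral"
        )
        initial_units = len(units) - n_ancestral_fusions
        try:
            ec = count_events(painting, initial_units)
            events[lin] = {
                "fusions_total": ec.fusions_total,
                "fusions_between_different": ec.fusions_between_different,
                "fusions_between_paralogs": ec.fusions_between_paralogs,
                "fissions": ec.fissions,
                "initial_units": initial_units,
                "n_chromosomes": painting.n_chromosomes,
            }
        except ValidationError as exc:
            events[lin] = {"error": str(exc)}
        if out is not None:
            write_painting(painting, out / f"painting_{lin}.tsv")
            outputs[f"painting_{lin}"] = str(out / f"painting_{lin}.tsv")

    logger.info("dosage-balance enrichment")
    col = sim.genomes["columbine"]
    annotations = simulate_annotations(col, seed=seed)
    universe = [g.id for g in col.genes()]
    fams = col.families()
    retained = [
        g.id
        for fam, genes in fams.items()
        if len({x.copy_label for x in genes}) >= 2
        for g in genes
    ]
    rows = enrichment_scan(retained, annotations, universe)
    tandem_families = detect_tandems(col, sim.intra_pairs("columbine"), cfg.tandem_max_gap)
    enrichment_top = [
        {"term": r.term, "p": r.p, "q": r.q, "direction": r.direction}
        for r in rows[:5]
    ]
    if out is not None:
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "term": r.term,
                    "a": r.table.a,
                    "b": r.table.b,
                    "c": r.table.c,
                    "d": r.table.d,
                    "p": r.p,
                    "q": r.q,
                    "direction": r.direction,
                }
                for r in rows
            ]
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        outputs["enrichment"] = str(out / "enrichment.tsv")

    report = RunReport(
        config=_config_echo(cfg),
        seed=seed,
        n_blocks=len(blocks),
        n_wgd_blocks=len(wgd_blocks),
        ratio_per_group={k: list(v) for k, v in ratio.per_group.items()},
        modal_ratio=list(ratio.modal_ratio) if ratio.modal_ratio else None,
        pairing=pairing_report,
        scenario_call=call_report,
        event_counts=events,
        enrichment_top=enrichment_top,
        outputs=outputs,
    )
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_json(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return report


def run_real_pipeline(
    genome_a_path,
    genome_b_path,
    pairs_path,
    format: str = "tsv",
    outdir=None,
    D: int = 20,
    A: int = 5,
    ks_lo: float = 1.0,
    ks_hi: float = 2.0,
    ks_cap: float = 10.0,
) -> dict:
    """Real-data mode: ingest gene position tables and a homolog table,
    chain blocks, and summarise Ks where available.

    When the homolog table carries no Ks values, the Ks-dependent stages
    (median annotation and WGD-block selection) are skipped with explicit
    warnings; the chained blocks are still written and reported.
    """
    import warnings

    ga = wio.read_gene_positions(genome_a_path, format=format, label=Path(genome_a_path).stem)
    gb = wio.read_gene_positions(genome_b_path, format=format, label=Path(genome_b_path).stem)
    pairs = wio.read_homolog_table(pairs_path, genomes=[ga, gb])
    blocks = chain_collinear(pairs, (ga, gb), ChainParams(D=D, A=A))
    report: dict = {"n_blocks": len(blocks), "ks_stages_run": False, "warnings": []}
    have_ks = any(p.ks is not None for p in pairs)
    if have_ks:
        annotate_median_ks(blocks, ks_cap)
        wgd = select_wgd_blocks(blocks, ks_lo, ks_hi)
        report["ks_stages_run"] = True
        report["n_wgd_blocks"] = len(wgd)
    else:
        msg = "homolog table has no Ks values: skipping median-Ks annotation and WGD-block selection"
        warnings.warn(msg, stacklevel=2)
        report["warnings"].append(msg)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        wio.write_blocks(blocks, out / "blocks.tsv")
        report["blocks_path"] = str(out / "blocks.tsv")
    return report
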