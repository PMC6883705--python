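"""Simulation of paleopolyploid genome evolution with a ground-truth ledger.

The simulator emulates the three candidate histories relating a basal-eudicot
("columbine-like") tetraploidy to the core-eudicot ("grape-like") *gamma*
hexaploidy:

* **Scenario 1** -- hexaploidy precedes the basal/core split and the basal
  lineage undergoes an additional, lineage-specific tetraploidy (basal
  lineage ends with 6 subgenome copies per ancestral chromosome, core with 3).
* **Scenario 2** -- the split comes first; tetraploidy in the basal lineage
  and the two-step hexaploidy in the core lineage are independent (2 vs 3).
* **Scenario 3** -- a single tetraploidy at the base of all eudicots is
  shared; the core lineage later gains a third genome copy, either by
  duplicating one of its existing subgenomes (*auto*) or by hybridization
  with a diverged diploid (*allo*), in which case the added subgenome is a
  detectable "outlier" (2 vs 3, with inherited gene-order signal).

Divergence "ages" are expressed directly in Ks units (synonymous
substitutions per synonymous site), absorbing the clock rate: Ks of a gene
pair is its divergence age plus truncated Gaussian noise.  Diploidization is
modelled as biased fractionation (loss of one duplicate per family, hitting
a designated "sensitive" subgenome with configurable bias), inversions,
lineage-specific fusions/fissions, and tandem duplication.

Every stochastic choice is logged in a :class:`TruthLedger`; replaying the
log from the ancestral genome reproduces the emitted genomes exactly, which
is the basis of the simulator's correctness tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import Gene, Genome, HomologPair, ValidationError

__all__ = [
    "LineagePlan",
    "SimulationConfig",
    "TruthLedger",
    "SimulationResult",
    "make_ancestral_genome",
    "apply_polyploidy",
    "fractionate",
    "rearrange",
    "assign_ks",
    "generate_scenario",
    "replay",
    "simulate_poppy_comparison",
    "simulate_annotations",
    "simulate_protein_alignments",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class LineagePlan:
    """Counts of lineage-specific karyotype events applied post-divergence."""

    fusions: int = 0            # fusions between chromosomes of different ancestral colors
    paralog_fusions: int = 0    # fusions joining the two WGD copies of one color
    fissions: int = 0

    @property
    def total_fusions(self) -> int:
        return self.fusions + self.paralog_fusions


_SCENARIO_TIMES = {
    # scenario: (t_tetra, t_hexa, t_split, t_extra)
    1: (1.5, 1.3, 1.1, 0.8),
    2: (1.5, 1.2, 1.7, None),
    3: (1.5, 1.2, 1.35, None),
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated history.

    Event ages are in Ks units.  Defaults follow the inferred eudicot
    history: 7 ancestral chromosomes, a tetraploidy peak near Ks=1.5 and a
    hexaploidy peak near Ks=1.2, basal-lineage karyotype reduction by
    7 fusions (5 between different ancestral chromosomes, 2 between WGD
    paralogs) and 1 fission, a single core-lineage fusion, and an ancestral
    fusion in the shared tetraploid ancestor.
    """

    n_ancestral_chroms: int = 7
    genes_per_chrom: int = 200
    scenario: int = 3
    hexaploidy_mode: str = "allo"
    t_tetra: Optional[float] = None
    t_hexa: Optional[float] = None
    t_split: Optional[float] = None
    t_extra: Optional[float] = None
    deletion_prob: float = 0.25
    fractionation_bias: float = 0.7
    dosage_sensitive_frac: float = 0.08
    inversions_per_lineage: int = 4
    tandem_rate: float = 0.03
    ks_sigma: float = 0.15
    seed: int = 0
    columbine_plan: LineagePlan = field(default_factory=lambda: LineagePlan(5, 2, 1))
    grape_plan: LineagePlan = field(default_factory=lambda: LineagePlan(1, 0, 0))
    cacao_plan: LineagePlan = field(default_factory=LineagePlan)
    ancestral_fusion: bool = True
    include_cacao: bool = False
    t_cacao: float = 0.9
    progenitor_deletion_prob: Optional[float] = None
    # order of terminal diploidization vs lineage-specific rearrangement is
    # not constrained by the data; exposed as a knob rather than fixed
    rearrange_before_fractionation: bool = False

    def __post_init__(self) -> None:
        defaults = _SCENARIO_TIMES.get(self.scenario)
        if defaults is None:
            raise ValidationError(f"scenario must be 1, 2 or 3, got {self.scenario}")
        if self.t_tetra is None:
            self.t_tetra = defaults[0]
        if self.t_hexa is None:
            self.t_hexa = defaults[1]
        if self.t_split is None:
            self.t_split = defaults[2]
        if self.t_extra is None:
            self.t_extra = defaults[3]
        self.validate()

    def validate(self) -> None:
        if self.hexaploidy_mode not in ("auto", "allo"):
            raise ValidationError(f"hexaploidy_mode must be auto|allo, got {self.hexaploidy_mode!r}")
        for name in ("deletion_prob", "dosage_sensitive_frac", "tandem_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if not 0.5 <= self.fractionation_bias <= 1.0:
            raise ValidationError(f"fractionation_bias must be in [0.5,1], got {self.fractionation_bias}")
        if self.ks_sigma < 0:
            raise ValidationError("ks_sigma must be >= 0")
        if self.n_ancestral_chroms < 1 or self.genes_per_chrom < 1:
            raise ValidationError("n_ancestral_chroms and genes_per_chrom must be >= 1")
        if self.scenario == 3:
            if not self.t_tetra > self.t_split > self.t_hexa:
                raise ValidationError("scenario 3 requires t_tetra > t_split > t_hexa")
        elif self.scenario == 2:
            if not self.t_split > self.t_tetra > self.t_hexa:
                raise ValidationError("scenario 2 requires t_split > t_tetra > t_hexa")
        else:
            if self.t_extra is None:
                raise ValidationError("scenario 1 requires t_extra")
            if not self.t_tetra > self.t_hexa > self.t_split > self.t_extra:
                raise ValidationError("scenario 1 requires t_tetra > t_hexa > t_split > t_extra")


# ---------------------------------------------------------------------------
# truth ledger


def _div_key(la: str, ca: str, lb: str, cb: str) -> tuple:
    a, b = (la, ca), (lb, cb)
    return (a, b) if a <= b else (b, a)


@dataclass
class TruthLedger:
    """Ground truth for one simulation: event log, divergence ages, pairing.

    ``events`` is an ordered, replayable operation log.  ``divergence`` maps
    sorted ``((lineage, copy), (lineage, copy))`` keys to divergence ages in
    Ks units.  ``true_pairing`` maps each ancestral color to the chromosome
    currently carrying each (lineage, copy) unit.  Under allohexaploidy,
    ``outlier_copy``/``outlier_chroms`` name the hybridization-derived
    subgenome of the core lineage.
    """

    events: list = field(default_factory=list)
    divergence: dict = field(default_factory=dict)
    true_pairing: dict = field(default_factory=dict)
    outlier_copy: Optional[str] = None
    outlier_chroms: list = field(default_factory=list)
    ancestral_args: dict = field(default_factory=dict)

    def log(self, op: str, **kwargs) -> None:
        self.events.append({"op": op, **kwargs})

    def set_div(self, la: str, ca: str, lb: str, cb: str, age: float) -> None:
        self.divergence[_div_key(la, ca, lb, cb)] = age

    def div_age(self, la: str, ca: str, lb: str, cb: str) -> float:
        return self.divergence[_div_key(la, ca, lb, cb)]

    def copies_of(self, lineage: str) -> set:
        out = set()
        for (a, b) in self.divergence:
            for lin, copy in (a, b):
                if lin == lineage:
                    out.add(copy)
        return out

    def event_counts(self, lineage: str) -> dict:
        counts = {"fusions": 0, "fissions": 0, "inversions": 0, "deletions": 0, "tandems": 0}
        for ev in self.events:
            if ev.get("lineage") != lineage:
                continue
            if ev["op"] == "fuse":
                counts["fusions"] += 1
            elif ev["op"] == "fission":
                counts["fissions"] += 1
            elif ev["op"] == "invert":
                counts["inversions"] += 1
            elif ev["op"] == "delete":
                counts["deletions"] += len(ev["genes"])
            elif ev["op"] == "tandem":
                counts["tandems"] += 1
        return counts

    def to_json(self) -> dict:
        return {
            "events": self.events,
            "divergence": {
                f"{a[0]}.{a[1]}~{b[0]}.{b[1]}": age for (a, b), age in sorted(self.divergence.items())
            },
            "true_pairing": self.true_pairing,
            "outlier_copy": self.outlier_copy,
            "outlier_chroms": self.outlier_chroms,
            "ancestral_args": self.ancestral_args,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2, sort_keys=True)


@dataclass
class SimulationResult:
    config: SimulationConfig
    genomes: dict            # lineage label -> Genome
    pairs: dict              # "intra:<lineage>" or "inter:<a>~<b>" -> list[HomologPair]
    ledger: TruthLedger

    def intra_pairs(self, lineage: str) -> list[HomologPair]:
        return self.pairs[f"intra:{lineage}"]

    def inter_pairs(self, a: str, b: str) -> list[HomologPair]:
        key = f"inter:{min(a, b)}~{max(a, b)}"
        return self.pairs[key]

    def gene_origins(self, lineage: str) -> dict[str, tuple[str, str]]:
        return {g.id: g.origin for g in self.genomes[lineage].genes()}


# ---------------------------------------------------------------------------
# engine: mechanical (replayable) operations


class _Engine:
    """Applies logged operations to a dict of genomes.  No randomness here:
    every stochastic choice is made by the generator and recorded in the log
    before application, which is what makes the log replayable."""

    def __init__(self, ledger: TruthLedger):
        self.ledger = ledger
        self.genomes: dict[str, Genome] = {}
        self.ancestral_snapshot: Optional[Genome] = None

    # -- operations -----------------------------------------------------

    def apply(self, ev: dict) -> None:
        getattr(self, "_op_" + ev["op"])(ev)

    def _op_make_ancestral(self, ev: dict) -> None:
        g = _build_ancestral(**ev["args"])
        self.genomes[ev["lineage"]] = g
        self.ancestral_snapshot = g.copy()

    def _op_wgd_auto(self, ev: dict) -> None:
        genome = self.genomes[ev["lineage"]]
        label_map = {k: tuple(v) for k, v in ev["label_map"].items()}
        new_chroms: dict[str, list[Gene]] = {}
        for cid, genes in genome.chromosomes.items():
            copies = {g.copy_label for g in genes}
            if len(copies) != 1:
                raise ValidationError(f"chromosome {cid} mixes subgenome copies; cannot double")
            old = copies.pop()
            keep, new = label_map[old]
            kept = [g.clone(origin=(g.color, keep)) for g in genes]
            dup = [
                g.clone(id=f"{g.id}|{new}", origin=(g.color, new)) for g in genes
            ]
            new_chroms[f"{cid}_{keep}"] = kept
            new_chroms[f"{cid}_{new}"] = dup
        genome.chromosomes = new_chroms
        genome.reindex()

    def _op_duplicate_subgenome(self, ev: dict) -> None:
        genome = self.genomes[ev["lineage"]]
        src, new = ev["src_copy"], ev["new_copy"]
        added: dict[str, list[Gene]] = {}
        for cid, genes in list(genome.chromosomes.items()):
            if genes and all(g.copy_label == src for g in genes):
                added[f"{cid}>{new}"] = [
                    g.clone(id=f"{g.id}|{new}", origin=(g.color, new)) for g in genes
                ]
        if not added:
            raise ValidationError(f"no pure {src!r}-copy chromosomes to duplicate")
        genome.chromosomes.update(added)
        genome.reindex()

    def _op_make_progenitor(self, ev: dict) -> None:
        assert self.ancestral_snapshot is not None
        copy = ev["copy"]
        prefix = ev.get("prefix", "")
        g = Genome(ev["lineage"])
        for cid, genes in self.ancestral_snapshot.chromosomes.items():
            g.chromosomes[f"{prefix}{cid}_{copy}"] = [
                gene.clone(id=f"{prefix}{gene.id}|{copy}", origin=(gene.color, copy))
                for gene in genes
            ]
        g.reindex()
        self.genomes[ev["lineage"]] = g

    def _op_merge(self, ev: dict) -> None:
        target = self.genomes[ev["lineage"]]
        source = self.genomes.pop(ev["source"])
        for cid, genes in source.chromosomes.items():
            if cid in target.chromosomes:
                raise ValidationError(f"merge collision on chromosome id {cid}")
            target.chromosomes[cid] = genes
        target.reindex()

    def _op_split(self, ev: dict) -> None:
        parent = self.genomes.pop(ev["parent"])
        for child, prefix in ev["children"]:
            g = Genome(child)
            for cid, genes in parent.chromosomes.items():
                g.chromosomes[f"{prefix}{cid}"] = [
                    gene.clone(id=f"{prefix}{gene.id}") for gene in genes
                ]
            g.reindex()
            self.genomes[child] = g

    def _op_delete(self, ev: dict) -> None:
        genome = self.genomes[ev["lineage"]]
        doomed = set(ev["genes"])
        for cid in list(genome.chromosomes):
            genes = [g for g in genome.chromosomes[cid] if g.id not in doomed]
            genome.chromosomes[cid] = genes
        genome.reindex()

    def _op_invert(self, ev: dict) -> None:
        genome = self.genomes[ev["lineage"]]
        genes = genome.chromosomes[ev["chrom"]]
        i, j = ev["start"], ev["end"]
        if not (0 <= i <= j < len(genes)):
            raise ValidationError(
                f"inversion interval [{i},{j}] outside chromosome {ev['chrom']} (L={len(genes)})"
            )
        seg = genes[i : j + 1][::-1]
        for g in seg:
            g.strand = "-" if g.strand == "+" else "+"
        genome.chromosomes[ev["chrom"]] = genes[:i] + seg + genes[j + 1 :]
        genome.reindex(ev["chrom"])

    def _op_fuse(self, ev: dict) -> None:
        genome = self.genomes[ev["lineage"]]
        a, b = ev["a"], ev["b"]
        for cid in (a, b):
            if cid not in genome.chromosomes:
                raise ValidationError(f"fusion references unknown chromosome {cid!r}")
        ga = genome.chromosomes.pop(a)
        gb = genome.chromosomes.pop(b)
        orient = ev["orientation"]
        if orient in ("head_head", "head_tail"):
            ga = _reverse_segment(ga)
        if orient in ("tail_tail", "head_tail"):
            gb = _reverse_segment(gb)
        genome.chromosomes[ev["new_id"]] = ga + gb
        genome.reindex(ev["new_id"])

    def _op_fission(self, ev: dict) -> None:
        genome = self.genomes[ev["lineage"]]
        cid, bp = ev["chrom"], ev["breakpoint"]
        genes = genome.chromosomes.pop(cid)
        if not (1 <= bp < len(genes)):
            genome.chromosomes[cid] = genes  # restore before failing
            raise ValidationError(f"fission breakpoint {bp} outside chromosome {cid} (L={len(genes)})")
        left, right = ev["new_ids"]
        genome.chromosomes[left] = genes[:bp]
        genome.chromosomes[right] = genes[bp:]
        genome.reindex(left)
        genome.reindex(right)

    def _op_tandem(self, ev: dict) -> None:
        genome = self.genomes[ev["lineage"]]
        genes = genome.chromosomes[ev["chrom"]]
        src = next(g for g in genes if g.id == ev["source"])
        dup = src.clone(id=ev["new_id"], birth=ev["birth"])
        genes.insert(src.rank + 1, dup)
        genome.reindex(ev["chrom"])


def _reverse_segment(genes: list[Gene]) -> list[Gene]:
    out = genes[::-1]
    for g in out:
        g.strand = "-" if g.strand == "+" else "+"
    return out


def _build_ancestral(
    n_chroms: int, genes_per_chrom: int, seed: int, dosage_sensitive_frac: float
) -> Genome:
    rng = np.random.default_rng(seed)
    g = Genome("ancestral")
    for c in range(n_chroms):
        color = f"c{c}"
        genes = []
        for i in range(genes_per_chrom):
            fam = f"F{c:02d}_{i:04d}"
            genes.append(
                Gene(
                    id=fam,
                    chrom=f"chr{c + 1}",
                    rank=i,
                    strand="+" if rng.random() < 0.5 else "-",
                    family=fam,
                    dosage_sensitive=bool(rng.random() < dosage_sensitive_frac),
                    origin=(color, "0"),
                )
            )
        g.add_chromosome(f"chr{c + 1}", genes)
    return g


# ---------------------------------------------------------------------------
# public primitives (spec surface)


def make_ancestral_genome(
    n_chroms: int,
    genes_per_chrom: int,
    seed: int,
    dosage_sensitive_frac: float = 0.08,
) -> Genome:
    """Build a pre-WGD ancestral genome: ``n_chroms`` chromosomes of
    ``genes_per_chrom`` genes with unique family labels, random strands and
    dosage-sensitivity flags drawn at the configured fraction."""
    if n_chroms < 1 or genes_per_chrom < 1:
        raise ValidationError("n_chroms and genes_per_chrom must be >= 1")
    return _build_ancestral(n_chroms, genes_per_chrom, seed, dosage_sensitive_frac)


def apply_polyploidy(parents, mode: str = "auto") -> Genome:
    """Whole-genome duplication (``auto``: one parent doubled) or
    allopolyploid merge (``allo``: two parents sharing family vocabulary).

    Every resulting gene copy carries its subgenome of origin in
    ``Gene.origin``.
    """
    if mode == "auto":
        if isinstance(parents, Genome):
            parent = parents
        else:
            parents = list(parents)
            if len(parents) != 1:
                raise ValidationError("auto polyploidy takes exactly one parent")
            parent = parents[0]
        ledger = TruthLedger()
        eng = _Engine(ledger)
        eng.genomes["x"] = parent.copy()
        copies = sorted({g.copy_label or "0" for g in parent.genes()})
        label_map = {c: (f"{c}A" if c != "0" else "A", f"{c}B" if c != "0" else "B") for c in copies}
        eng.apply({"op": "wgd_auto", "lineage": "x", "label_map": label_map})
        out = eng.genomes["x"]
        out.label = parent.label
        return out
    elif mode == "allo":
        parents = list(parents) if not isinstance(parents, Genome) else [parents]
        if len(parents) != 2:
            raise ValidationError("allo polyploidy takes exactly two parents")
        a, b = parents
        merged = Genome(a.label)
        for src in (a, b):
            for cid, genes in src.chromosomes.items():
                if cid in merged.chromosomes:
                    raise ValidationError(f"chromosome id collision {cid!r} in allo merge")
                merged.chromosomes[cid] = [g.clone() for g in genes]
        merged.reindex()
        merged.validate()
        return merged
    raise ValidationError(f"mode must be auto|allo, got {mode!r}")


def fractionate(
    genome: Genome,
    deletion_prob: float,
    bias: float,
    seed: int,
    sensitive_copy: Optional[str] = None,
) -> Genome:
    """Biased post-WGD gene loss.

    For each multi-copy, non-dosage-sensitive family, one copy is deleted
    with probability ``deletion_prob``; the lost copy comes from the
    designated sensitive subgenome with probability ``bias``.  Dosage-
    sensitive families are never reduced.  Returns a new genome.
    """
    if not 0.5 <= bias <= 1.0:
        raise ValidationError(f"bias must be in [0.5,1], got {bias}")
    if not 0.0 <= deletion_prob <= 1.0:
        raise ValidationError("deletion_prob must be in [0,1]")
    out = genome.copy()
    rng = np.random.default_rng(seed)
    doomed = _choose_fractionation_losses(out, deletion_prob, bias, sensitive_copy, rng)
    eng = _Engine(TruthLedger())
    eng.genomes["x"] = out
    eng.apply({"op": "delete", "lineage": "x", "genes": doomed})
    return eng.genomes["x"]


def _choose_fractionation_losses(
    genome: Genome,
    deletion_prob: float,
    bias: float,
    sensitive_copy: Optional[str],
    rng: np.random.Generator,
) -> list[str]:
    doomed = []
    fams = genome.families()
    for fam in sorted(fams):
        genes = fams[fam]
        by_copy: dict[str, list[Gene]] = {}
        for g in genes:
            by_copy.setdefault(g.copy_label or "0", []).append(g)
        if len(by_copy) < 2:
            continue
        if any(g.dosage_sensitive for g in genes):
            continue
        if rng.random() >= deletion_prob:
            continue
        copies = sorted(by_copy)
        sens = sensitive_copy if sensitive_copy in by_copy else copies[-1]
        others = [c for c in copies if c != sens]
        victim_copy = sens if rng.random() < bias else others[int(rng.integers(len(others)))]
        victim = min(by_copy[victim_copy], key=lambda g: g.id)
        doomed.append(victim.id)
    return doomed


def rearrange(
    genome: Genome,
    fusions: Optional[list[tuple[str, str]]] = None,
    fissions: Optional[list[tuple[str, int]]] = None,
    inversions: Optional[list[tuple[str, int, int]]] = None,
    seed: int = 0,
    orientations: Optional[list[str]] = None,
) -> Genome:
    """Apply explicit fusion/fission/inversion lists to a copy of ``genome``.

    Chromosome count changes by ``fissions - fusions``; the gene multiset is
    conserved exactly.  Fusion orientations are drawn uniformly when not
    given.  Inversions reverse both order and strand within the interval.
    """
    out = genome.copy()
    rng = np.random.default_rng(seed)
    eng = _Engine(TruthLedger())
    eng.genomes["x"] = out
    for chrom, i, j in inversions or []:
        eng.apply({"op": "invert", "lineage": "x", "chrom": chrom, "start": i, "end": j})
    for k, (a, b) in enumerate(fusions or []):
        orient = (
            orientations[k]
            if orientations is not None
            else ["tail_head", "tail_tail", "head_head", "head_tail"][int(rng.integers(4))]
        )
        eng.apply(
            {"op": "fuse", "lineage": "x", "a": a, "b": b, "orientation": orient, "new_id": f"{a}+{b}"}
        )
    for chrom, bp in fissions or []:
        eng.apply(
            {
                "op": "fission",
                "lineage": "x",
                "chrom": chrom,
                "breakpoint": bp,
                "new_ids": [f"{chrom}/1", f"{chrom}/2"],
            }
        )
    return eng.genomes["x"]


# ---------------------------------------------------------------------------
# Ks assignment


def assign_ks(
    ledger: TruthLedger,
    genomes: dict[str, Genome],
    ks_sigma: float,
    seed: int,
) -> dict[str, list[HomologPair]]:
    """Emit homolog-pair tables with Ks = divergence age + Gaussian noise.

    Pairs that diverged at the same event share an age; noise is zero-mean
    with sigma ``ks_sigma``, truncated at 0.  Returns a dict with keys
    ``intra:<lineage>`` and ``inter:<a>~<b>``.
    """
    if ks_sigma < 0:
        raise ValidationError("ks_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, list[HomologPair]] = {}
    lineages = sorted(genomes)
    fam_index = {
        lin: _family_gene_list(genomes[lin]) for lin in lineages
    }
    for i, lin in enumerate(lineages):
        out[f"intra:{lin}"] = _pairs_for(
            ledger, fam_index[lin], fam_index[lin], lin, lin, ks_sigma, rng
        )
        for lin_b in lineages[i + 1 :]:
            out[f"inter:{min(lin, lin_b)}~{max(lin, lin_b)}"] = _pairs_for(
                ledger, fam_index[lin], fam_index[lin_b], lin, lin_b, ks_sigma, rng
            )
    return out


def _family_gene_list(genome: Genome) -> dict[str, list[Gene]]:
    fams: dict[str, list[Gene]] = {}
    for g in genome.genes():
        if g.family is not None:
            fams.setdefault(g.family, []).append(g)
    return fams


def _pair_age(ledger: TruthLedger, lin_a: str, ga: Gene, lin_b: str, gb: Gene) -> float:
    ca, cb = ga.copy_label or "0", gb.copy_label or "0"
    if lin_a == lin_b and ca == cb:
        births = [t for t in (ga.birth, gb.birth) if t is not None]
        if not births:
            raise ValidationError(
                f"genes {ga.id},{gb.id}: same copy, no tandem birth recorded"
            )
        return min(births)
    return ledger.div_age(lin_a, ca, lin_b, cb)


def _pairs_for(ledger, fams_a, fams_b, lin_a, lin_b, sigma, rng) -> list[HomologPair]:
    pairs = []
    same = lin_a == lin_b
    kind = "intra" if same else "inter"
    for fam in sorted(set(fams_a) & set(fams_b)):
        genes_a = fams_a[fam]
        genes_b = fams_b[fam]
        for ia, ga in enumerate(genes_a):
            bs = genes_b[ia + 1 :] if same else genes_b
            for gb in bs:
                age = _pair_age(ledger, lin_a, ga, lin_b, gb)
                ks = max(0.0, age + (rng.normal(0.0, sigma) if sigma > 0 else 0.0))
                pairs.append(HomologPair(gene_a=ga.id, gene_b=gb.id, ks=ks, kind=kind))
    return pairs


# ---------------------------------------------------------------------------
# scenario generator


class _Generator:
    """Drives a full scenario: makes stochastic choices, logs, applies."""

    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.ledger = TruthLedger()
        self.engine = _Engine(self.ledger)
        self.ss = np.random.SeedSequence(config.seed)
        self.rng = np.random.default_rng(self.ss.spawn(1)[0])

    # -- logged ops ------------------------------------------------------

    def do(self, op: str, **kwargs) -> None:
        self.ledger.log(op, **kwargs)
        self.engine.apply({"op": op, **kwargs})

    # -- stochastic choosers ---------------------------------------------

    def _chrom_unit_sets(self, lineage: str) -> dict[str, set[tuple[str, str]]]:
        g = self.engine.genomes[lineage]
        return {cid: {gene.origin for gene in genes} for cid, genes in g.chromosomes.items() if genes}

    def fractionation_round(self, lineage: str, sensitive: Optional[str], time: float) -> None:
        genome = self.engine.genomes[lineage]
        doomed = _choose_fractionation_losses(
            genome, self.cfg.deletion_prob, self.cfg.fractionation_bias, sensitive, self.rng
        )
        self.do("delete", lineage=lineage, time=time, genes=doomed, sensitive=sensitive)

    def uniform_deletion_round(self, lineage: str, prob: float, time: float) -> None:
        genome = self.engine.genomes[lineage]
        doomed = [g.id for g in genome.genes() if self.rng.random() < prob]
        self.do("delete", lineage=lineage, time=time, genes=doomed)

    def inversion_round(self, lineage: str, n: int, time: float) -> None:
        genome = self.engine.genomes[lineage]
        for _ in range(n):
            cids = sorted(cid for cid, genes in genome.chromosomes.items() if len(genes) >= 4)
            if not cids:
                return
            weights = np.array([len(genome.chromosomes[c]) for c in cids], dtype=float)
            cid = cids[int(self.rng.choice(len(cids), p=weights / weights.sum()))]
            L = len(genome.chromosomes[cid])
            i, j = sorted(self.rng.choice(L, size=2, replace=False).tolist())
            if i == j:
                continue
            self.do("invert", lineage=lineage, time=time, chrom=cid, start=int(i), end=int(j))

    def fuse_pair(self, lineage: str, a: str, b: str, time: float, kind: str) -> None:
        orient = ["tail_head", "tail_tail", "head_head", "head_tail"][int(self.rng.integers(4))]
        self.do(
            "fuse",
            lineage=lineage,
            time=time,
            a=a,
            b=b,
            orientation=orient,
            new_id=f"{a}+{b}",
            kind=kind,
        )

    def rearrangement_round(self, lineage: str, plan: LineagePlan, time: float) -> None:
        for _ in range(plan.paralog_fusions):
            units = self._chrom_unit_sets(lineage)
            # fuse two whole WGD-derived paralogous chromosomes: both carry
            # exactly one color, the same one, in different copies, so the
            # junction is a same-color different-copy adjacency
            candidates = []
            cids = sorted(units)
            for ai, a in enumerate(cids):
                for b in cids[ai + 1 :]:
                    colors_a = {c for c, _ in units[a]}
                    colors_b = {c for c, _ in units[b]}
                    if (
                        len(units[a]) == 1
                        and len(units[b]) == 1
                        and colors_a == colors_b
                        and units[a] != units[b]
                    ):
                        candidates.append((a, b))
            if not candidates:
                break
            a, b = candidates[int(self.rng.integers(len(candidates)))]
            self.fuse_pair(lineage, a, b, time, kind="paralog")
        for _ in range(plan.fusions):
            units = self._chrom_unit_sets(lineage)
            candidates = []
            for a in sorted(units):
                for b in sorted(units):
                    if a >= b:
                        continue
                    if {c for c, _ in units[a]}.isdisjoint({c for c, _ in units[b]}):
                        candidates.append((a, b))
            if not candidates:
                break
            a, b = candidates[int(self.rng.integers(len(candidates)))]
            self.fuse_pair(lineage, a, b, time, kind="different")
        for _ in range(plan.fissions):
            genome = self.engine.genomes[lineage]
            cids = sorted(c for c, genes in genome.chromosomes.items() if len(genes) >= 20)
            if not cids:
                break
            cid = cids[int(self.rng.integers(len(cids)))]
            L = len(genome.chromosomes[cid])
            bp = int(self.rng.integers(5, L - 5))
            self.do(
                "fission",
                lineage=lineage,
                time=time,
                chrom=cid,
                breakpoint=bp,
                new_ids=[f"{cid}/1", f"{cid}/2"],
            )

    def tandem_round(self, lineage: str, max_age: float, time: float) -> None:
        genome = self.engine.genomes[lineage]
        snapshot = [(g.chrom, g.id) for g in genome.genes()]
        counter = 0
        for chrom, gid in snapshot:
            if self.rng.random() >= self.cfg.tandem_rate:
                continue
            counter += 1
            birth = float(self.rng.uniform(0.0, max_age))
            self.do(
                "tandem",
                lineage=lineage,
                time=time,
                chrom=chrom,
                source=gid,
                new_id=f"{gid}.t{counter}",
                birth=birth,
            )

    # -- divergence bookkeeping ------------------------------------------

    def register_wgd_div(self, lineage: str, label_map: dict, time: float) -> None:
        led = self.ledger
        for old, (keep, new) in label_map.items():
            led.set_div(lineage, keep, lineage, new, time)
        # inherit divergences of the source copy for both children
        for old, (keep, new) in label_map.items():
            for key, age in list(led.divergence.items()):
                (la, ca), (lb, cb) = key
                for child in (keep, new):
                    if (la, ca) == (lineage, old) and (lb, cb) != (lineage, old):
                        led.set_div(lineage, child, lb, cb, age)
                    elif (lb, cb) == (lineage, old) and (la, ca) != (lineage, old):
                        led.set_div(la, ca, lineage, child, age)
        # divergence between children of different source copies
        olds = sorted(label_map)
        for i, oa in enumerate(olds):
            for ob in olds[i + 1 :]:
                age = led.div_age(lineage, oa, lineage, ob)
                for xa in label_map[oa]:
                    for xb in label_map[ob]:
                        led.set_div(lineage, xa, lineage, xb, age)
        # retire source labels that were not reused as child labels
        children = {c for pair in label_map.values() for c in pair}
        stale = {(lineage, old) for old in label_map if old not in children}
        if stale:
            led.divergence = {
                k: v for k, v in led.divergence.items() if k[0] not in stale and k[1] not in stale
            }

    def register_split_div(self, parent: str, children: list[str], t_split: float) -> None:
        led = self.ledger
        copies = sorted(led.copies_of(parent)) or ["0"]
        old = dict(led.divergence)
        within: dict[tuple[str, str], float] = {}
        for i, ca in enumerate(copies):
            for cb in copies[i + 1 :]:
                within[(ca, cb)] = old[_div_key(parent, ca, parent, cb)]
        external = [
            (k, v) for k, v in old.items() if (k[0][0] == parent) != (k[1][0] == parent)
        ]
        led.divergence = {k: v for k, v in old.items() if parent not in (k[0][0], k[1][0])}
        new: dict = {}
        for li, la in enumerate(children):
            for (ca, cb), age in within.items():
                new[_div_key(la, ca, la, cb)] = age
            for lb in children[li + 1 :]:
                for ca in copies:
                    for cb in copies:
                        if ca == cb:
                            age = t_split
                        else:
                            key = (ca, cb) if ca < cb else (cb, ca)
                            age = max(t_split, within[key])
                        new[_div_key(la, ca, lb, cb)] = age
            for k, v in external:
                (xa, cxa), (xb, cxb) = k
                if xa == parent:
                    other, cp = (xb, cxb), cxa
                else:
                    other, cp = (xa, cxa), cxb
                new[_div_key(la, cp, other[0], other[1])] = v
        led.divergence.update(new)

    # -- composite events -------------------------------------------------

    def wgd(self, lineage: str, label_map: dict, time: float) -> None:
        self.do("wgd_auto", lineage=lineage, time=time, label_map={k: list(v) for k, v in label_map.items()})
        self.register_wgd_div(lineage, label_map, time)

    def split(self, parent: str, children: list[tuple[str, str]], time: float) -> None:
        self.do("split", parent=parent, time=time, children=[list(c) for c in children])
        self.register_split_div(parent, [c[0] for c in children], time)

    def hexaploidy(self, lineage: str, time: float, t_cross: float, cross_lineages: list[str]) -> None:
        """Second polyploidy step: add a third subgenome copy 'C'."""
        cfg = self.cfg
        led = self.ledger
        copies = sorted(led.copies_of(lineage))
        if cfg.hexaploidy_mode == "auto":
            src = copies[0]
            self.do("duplicate_subgenome", lineage=lineage, time=time, src_copy=src, new_copy="C")
            led.set_div(lineage, "C", lineage, src, time)
            for key, age in list(led.divergence.items()):
                (la, ca), (lb, cb) = key
                if (la, ca) == (lineage, src) and (lb, cb) != (lineage, "C"):
                    led.set_div(lineage, "C", lb, cb, age)
                elif (lb, cb) == (lineage, src) and (la, ca) != (lineage, "C"):
                    led.set_div(la, ca, lineage, "C", age)
        else:
            prefix = self._lineage_prefix(lineage)
            prog = f"{lineage}_progenitor"
            self.do("make_progenitor", lineage=prog, copy="C", prefix=prefix)
            # the hybridizing diploid is modelled as substantially diverged
            # in gene order at the time of the merge (cf. the reduced
            # genomes that formed allopolyploid wheat or A. suecica)
            p_del = (
                cfg.progenitor_deletion_prob
                if cfg.progenitor_deletion_prob is not None
                else cfg.deletion_prob
            )
            self.uniform_deletion_round(prog, p_del, time)
            self.inversion_round(prog, 2 * cfg.inversions_per_lineage, time)
            self.do("merge", lineage=lineage, source=prog, time=time)
            for c in copies:
                led.set_div(lineage, "C", lineage, c, time)
            for other in cross_lineages:
                for c in sorted(led.copies_of(other)):
                    led.set_div(lineage, "C", other, c, t_cross)
            self.ledger.outlier_copy = "C"

    def _lineage_prefix(self, lineage: str) -> str:
        g = self.engine.genomes[lineage]
        first = next(iter(g.chromosomes))
        # chromosomes are prefixed at split time; recover the prefix if any
        return first.split("chr")[0] if "chr" in first else ""

    # -- finalization ------------------------------------------------------

    def compute_true_pairing(self, lineages: list[str]) -> None:
        pairing: dict[str, dict] = {}
        colors = set()
        for lin in lineages:
            for g in self.engine.genomes[lin].genes():
                colors.add(g.color)
        for color in sorted(colors):
            pairing[color] = {}
            for lin in lineages:
                counts: dict[str, dict[str, int]] = {}
                for g in self.engine.genomes[lin].genes():
                    if g.color == color:
                        counts.setdefault(g.copy_label, {}).setdefault(g.chrom, 0)
                        counts[g.copy_label][g.chrom] += 1
                pairing[color][lin] = {
                    copy: max(sorted(chroms), key=lambda c: chroms[c])
                    for copy, chroms in sorted(counts.items())
                }
        self.ledger.true_pairing = pairing

    def compute_outlier_chroms(self, lineage: str) -> None:
        if self.ledger.outlier_copy is None:
            return
        chroms = set()
        for g in self.engine.genomes[lineage].genes():
            if g.copy_label == self.ledger.outlier_copy:
                chroms.add(g.chrom)
        self.ledger.outlier_chroms = sorted(chroms)


def generate_scenario(config: SimulationConfig) -> SimulationResult:
    """Generate a full simulated dataset under the configured history.

    Returns genomes for the basal ("columbine") and core ("grape") lineages
    (plus "cacao" when configured), all intra-/inter-genome homolog tables
    with Ks, and the ground-truth ledger.  Byte-identical outputs for
    identical config+seed.
    """
    cfg = config
    gen = _Generator(cfg)
    led = gen.ledger
    anc_args = {
        "n_chroms": cfg.n_ancestral_chroms,
        "genes_per_chrom": cfg.genes_per_chrom,
        "seed": cfg.seed,
        "dosage_sensitive_frac": cfg.dosage_sensitive_frac,
    }
    led.ancestral_args = anc_args
    gen.do("make_ancestral", lineage="anc", args=anc_args)

    if cfg.scenario == 3:
        _generate_scenario3(gen)
    elif cfg.scenario == 2:
        _generate_scenario2(gen)
    else:
        _generate_scenario1(gen)

    lineages = sorted(gen.engine.genomes)
    gen.compute_true_pairing(lineages)
    if "grape" in gen.engine.genomes:
        gen.compute_outlier_chroms("grape")
    for g in gen.engine.genomes.values():
        g.validate()
    pairs = assign_ks(
        led,
        gen.engine.genomes,
        cfg.ks_sigma,
        seed=int(np.random.SeedSequence([cfg.seed, 7919]).generate_state(1)[0] % (2**31)),
    )
    return SimulationResult(config=cfg, genomes=dict(gen.engine.genomes), pairs=pairs, ledger=led)


def _ancestral_fusion(gen: _Generator, lineage: str, time: float) -> None:
    """The fusion inherited by all descendants: joins one copy of the first
    two ancestral chromosomes (the 'orange'+'green' junction)."""
    genome = gen.engine.genomes[lineage]
    targets = {}
    for cid, genes in genome.chromosomes.items():
        units = {g.origin for g in genes}
        if ("c0", "A") in units:
            targets["a"] = cid
        if ("c1", "A") in units:
            targets["b"] = cid
    if "a" in targets and "b" in targets and targets["a"] != targets["b"]:
        gen.fuse_pair(lineage, targets["a"], targets["b"], time, kind="ancestral")


def _terminal_round(gen: _Generator, lineage: str, plan: LineagePlan, sensitive, t0: float) -> None:
    cfg = gen.cfg
    if cfg.rearrange_before_fractionation:
        gen.rearrangement_round(lineage, plan, t0)
        gen.fractionation_round(lineage, sensitive, t0)
    else:
        gen.fractionation_round(lineage, sensitive, t0)
        gen.rearrangement_round(lineage, plan, t0)
    gen.inversion_round(lineage, cfg.inversions_per_lineage, t0)
    if cfg.tandem_rate > 0:
        gen.tandem_round(lineage, max_age=t0, time=t0)


def _generate_scenario3(gen: _Generator) -> None:
    cfg = gen.cfg
    gen.wgd("anc", {"0": ("A", "B")}, cfg.t_tetra)
    # shared tetraploid ancestor: diploidization differences between the two
    # subgenomes accumulated here are inherited by BOTH descendant lineages
    gen.fractionation_round("anc", "B", cfg.t_tetra)
    gen.inversion_round("anc", cfg.inversions_per_lineage, cfg.t_tetra)
    if cfg.ancestral_fusion:
        _ancestral_fusion(gen, "anc", cfg.t_tetra)
    gen.split("anc", [("columbine", "col:"), ("grape", "gra:")], cfg.t_split)
    gen.hexaploidy("grape", cfg.t_hexa, t_cross=cfg.t_split, cross_lineages=["columbine"])
    if cfg.include_cacao:
        gen.fractionation_round("grape", "C", cfg.t_hexa)
        gen.split("grape", [("grape", "g."), ("cacao", "cac:")], cfg.t_cacao)
        _terminal_round(gen, "cacao", cfg.cacao_plan, "C", cfg.t_cacao)
        gen.rearrangement_round("grape", cfg.grape_plan, cfg.t_cacao)
        gen.inversion_round("grape", cfg.inversions_per_lineage, cfg.t_cacao)
        if cfg.tandem_rate > 0:
            gen.tandem_round("grape", max_age=cfg.t_cacao, time=cfg.t_cacao)
    else:
        _terminal_round(gen, "grape", cfg.grape_plan, "C", cfg.t_hexa)
    _terminal_round(gen, "columbine", cfg.columbine_plan, "B", cfg.t_split)


def _generate_scenario2(gen: _Generator) -> None:
    cfg = gen.cfg
    gen.split("anc", [("columbine", "col:"), ("grape", "gra:")], cfg.t_split)
    # columbine: independent tetraploidy
    gen.wgd("columbine", {"0": ("A", "B")}, cfg.t_tetra)
    gen.fractionation_round("columbine", "B", cfg.t_tetra)
    gen.inversion_round("columbine", cfg.inversions_per_lineage, cfg.t_tetra)
    _terminal_round(gen, "columbine", cfg.columbine_plan, "B", cfg.t_tetra)
    # grape: independent two-step hexaploidy
    gen.wgd("grape", {"0": ("A", "B")}, cfg.t_tetra)
    gen.fractionation_round("grape", "B", cfg.t_tetra)
    gen.inversion_round("grape", cfg.inversions_per_lineage, cfg.t_tetra)
    gen.hexaploidy("grape", cfg.t_hexa, t_cross=cfg.t_split, cross_lineages=["columbine"])
    if cfg.include_cacao:
        gen.fractionation_round("grape", "C", cfg.t_hexa)
        gen.split("grape", [("grape", "g."), ("cacao", "cac:")], cfg.t_cacao)
        _terminal_round(gen, "cacao", cfg.cacao_plan, "C", cfg.t_cacao)
        gen.rearrangement_round("grape", cfg.grape_plan, cfg.t_cacao)
        gen.inversion_round("grape", cfg.inversions_per_lineage, cfg.t_cacao)
        if cfg.tandem_rate > 0:
            gen.tandem_round("grape", max_age=cfg.t_cacao, time=cfg.t_cacao)
    else:
        _terminal_round(gen, "grape", cfg.grape_plan, "C", cfg.t_hexa)


def _generate_scenario1(gen: _Generator) -> None:
    cfg = gen.cfg
    gen.wgd("anc", {"0": ("A", "B")}, cfg.t_tetra)
    gen.fractionation_round("anc", "B", cfg.t_tetra)
    gen.inversion_round("anc", cfg.inversions_per_lineage, cfg.t_tetra)
    if cfg.ancestral_fusion:
        _ancestral_fusion(gen, "anc", cfg.t_tetra)
    gen.hexaploidy("anc", cfg.t_hexa, t_cross=cfg.t_split, cross_lineages=[])
    gen.fractionation_round("anc", "C", cfg.t_hexa)
    gen.inversion_round("anc", cfg.inversions_per_lineage, cfg.t_hexa)
    gen.split("anc", [("columbine", "col:"), ("grape", "gra:")], cfg.t_split)
    # basal lineage: the additional, lineage-specific tetraploidy
    copies = sorted(gen.ledger.copies_of("columbine"))
    gen.wgd("columbine", {c: (c, f"{c}2") for c in copies}, cfg.t_extra)
    gen.fractionation_round("columbine", None, cfg.t_extra)
    gen.inversion_round("columbine", cfg.inversions_per_lineage, cfg.t_extra)
    _terminal_round(gen, "columbine", cfg.columbine_plan, None, cfg.t_extra)
    _terminal_round(gen, "grape", cfg.grape_plan, "C", cfg.t_split)


# ---------------------------------------------------------------------------
# replay


def replay(ledger: TruthLedger) -> dict[str, Genome]:
    """Re-apply the logged events from the ancestral genome; returns the
    reconstructed genomes.  Must reproduce the emitted genomes exactly."""
    eng = _Engine(TruthLedger())
    for ev in ledger.events:
        eng.apply(ev)
    for g in eng.genomes.values():
        g.validate()
    return dict(eng.genomes)


# ---------------------------------------------------------------------------
# auxiliary simulations


def simulate_poppy_comparison(seed: int = 0, **overrides) -> SimulationResult:
    """Two basal-type lineages from a shared tetraploid ancestor, one of
    which ("poppy") undergoes one additional recent WGD after the split.

    Per ancestral color the poppy-like lineage carries 4 paralogous regions
    to the columbine-like lineage's 2 (a 4:2 synteny relationship).
    """
    params = dict(
        scenario=3,
        hexaploidy_mode="auto",
        seed=seed,
    )
    params.update(overrides)
    cfg = SimulationConfig(**params)
    gen = _Generator(cfg)
    anc_args = {
        "n_chroms": cfg.n_ancestral_chroms,
        "genes_per_chrom": cfg.genes_per_chrom,
        "seed": cfg.seed,
        "dosage_sensitive_frac": cfg.dosage_sensitive_frac,
    }
    gen.ledger.ancestral_args = anc_args
    gen.do("make_ancestral", lineage="anc", args=anc_args)
    gen.wgd("anc", {"0": ("A", "B")}, cfg.t_tetra)
    gen.fractionation_round("anc", "B", cfg.t_tetra)
    gen.inversion_round("anc", cfg.inversions_per_lineage, cfg.t_tetra)
    gen.split("anc", [("columbine", "col:"), ("poppy", "pop:")], cfg.t_split)
    t_recent = cfg.t_split / 3.0
    copies = sorted(gen.ledger.copies_of("poppy"))
    gen.wgd("poppy", {c: (c, f"{c}2") for c in copies}, t_recent)
    gen.fractionation_round("poppy", None, t_recent)
    gen.inversion_round("poppy", cfg.inversions_per_lineage, t_recent)
    gen.fractionation_round("columbine", "B", cfg.t_split)
    gen.inversion_round("columbine", cfg.inversions_per_lineage, cfg.t_split)
    lineages = sorted(gen.engine.genomes)
    gen.compute_true_pairing(lineages)
    for g in gen.engine.genomes.values():
        g.validate()
    pairs = assign_ks(
        gen.ledger,
        gen.engine.genomes,
        cfg.ks_sigma,
        seed=int(np.random.SeedSequence([cfg.seed, 104729]).generate_state(1)[0] % (2**31)),
    )
    return SimulationResult(config=cfg, genomes=dict(gen.engine.genomes), pairs=pairs, ledger=gen.ledger)


def simulate_annotations(
    genome: Genome,
    seed: int = 0,
    n_background_terms: int = 10,
    background_frac: float = 0.06,
    dosage_term: str = "TERM:dosage_balance",
    leak_frac: float = 0.03,
) -> dict[str, set[str]]:
    """Flat gene->term annotation where dosage-sensitive genes share one term
    (plus a small leak into other genes) and background terms are random.

    Emulates functional categories such as ribosomal proteins and
    transcription factors whose retention after WGD is dosage-constrained.
    """
    rng = np.random.default_rng(seed)
    ann: dict[str, set[str]] = {}
    genes = sorted(genome.genes(), key=lambda g: g.id)
    for g in genes:
        terms = set()
        if g.dosage_sensitive or rng.random() < leak_frac:
            terms.add(dosage_term)
        for t in range(n_background_terms):
            if rng.random() < background_frac:
                terms.add(f"TERM:background_{t:02d}")
        if terms:
            ann[g.id] = terms
    return ann


_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_protein_alignments(
    result: SimulationResult,
    n_families: int = 40,
    length: int = 120,
    rate: float = 0.12,
    noise: float = 0.0,
    seed: int = 0,
    lineages: Optional[list[str]] = None,
) -> dict[str, dict[str, str]]:
    """Equal-length protein-like alignments for homologous families.

    Sequences evolve down the true copy genealogy (built from the ledger's
    divergence ages) with per-site substitution probability
    ``1 - exp(-rate * branch_length)``; ``noise`` adds independent per-gene
    substitutions that blur the phylogenetic signal.  Purely to exercise the
    distance/UPGMA machinery; no substitution-model realism intended.
    """
    from .trees import upgma  # local import; trees does not import simulate

    rng = np.random.default_rng(seed)
    lineages = lineages or sorted(result.genomes)
    fam_members: dict[str, list[tuple[str, Gene]]] = {}
    for lin in lineages:
        for g in result.genomes[lin].genes():
            if g.family is not None and g.birth is None:
                fam_members.setdefault(g.family, []).append((lin, g))
    eligible = [f for f in sorted(fam_members) if len(fam_members[f]) >= 3]
    stride = max(1, len(eligible) // n_families) if n_families else 1
    selected = eligible[::stride][:n_families]
    out: dict[str, dict[str, str]] = {}
    for fam in selected:
        members = fam_members[fam]
        labels = [g.id for _, g in members]
        n = len(members)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                la, ga = members[i]
                lb, gb = members[j]
                age = _pair_age(result.ledger, la, ga, lb, gb)
                d[i, j] = d[j, i] = 2.0 * age
        tree = upgma(labels, d)
        root_seq = rng.integers(0, 20, size=length)
        seqs: dict[str, np.ndarray] = {}
        _evolve_down(tree, root_seq, rate, rng, seqs)
        fam_out = {}
        for label in labels:
            s = seqs[label].copy()
            if noise > 0:
                mask = rng.random(length) < noise
                s[mask] = (s[mask] + rng.integers(1, 20, size=int(mask.sum()))) % 20
            fam_out[label] = "".join(_AA[k] for k in s)
        out[fam] = fam_out
    return out


def _evolve_down(node, seq: np.ndarray, rate: float, rng, seqs: dict) -> None:
    for child in node.children:
        bl = child.length or 0.0
        p = 1.0 - np.exp(-rate * bl)
        s = seq.copy()
        mask = rng.random(seq.size) < p
        s[mask] = (s[mask] + rng.integers(1, 20, size=int(mask.sum()))) % 20
        if child.is_tip():
            seqs[child.name] = s
        else:
            _evolve_down(child, s, rate, rng, seqs)
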