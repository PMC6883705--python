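"""Tandem-duplicate detection and 2x2 Fisher/FDR enrichment machinery.

The enrichment test asks whether membership in a gene set (e.g. genes
retained in duplicate after WGD, or tandemly duplicated genes) and
membership in a functional category are independent, one category at a
time, with Benjamini-Hochberg control of the false discovery rate.  Under
the dosage-balance hypothesis, WGD-retained genes are enriched and tandem
duplicates depleted for stoichiometry-sensitive categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.stats import fisher_exact

from .model import Genome, HomologPair, ValidationError

__all__ = [
    "ContingencyTable",
    "EnrichmentRow",
    "detect_tandems",
    "fisher_2x2",
    "bh_fdr",
    "enrichment_scan",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (in set, annotated)=a, (in set, not)=b, (not, annotated)=c,
    (not, not)=d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio_direction(self) -> str:
        # sign of ad - bc decides enrichment vs depletion of the annotation
        return "enriched" if self.a * self.d >= self.b * self.c else "depleted"

    def has_zero_margin(self) -> bool:
        return 0 in (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class EnrichmentRow:
    term: str
    table: ContingencyTable
    p: float
    q: float
    direction: str
    flagged: bool = False


def detect_tandems(
    genome: Genome, intra_pairs: Iterable[HomologPair], max_gap: int = 10
) -> list[set[str]]:
    """Tandem families: connected components of intragenomic homolog pairs
    whose genes share a chromosome and differ in rank by at most
    ``max_gap``+1 (i.e. at most ``max_gap`` intervening genes)."""
    idx = genome.index()
    g = nx.Graph()
    for p in intra_pairs:
        ga = idx.get(p.gene_a)
        gb = idx.get(p.gene_b)
        if ga is None or gb is None:
            continue
        if ga.chrom == gb.chrom and abs(ga.rank - gb.rank) <= max_gap + 1:
            g.add_edge(ga.id, gb.id)
    return sorted((set(c) for c in nx.connected_components(g)), key=lambda s: min(s))


def fisher_2x2(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (probability-mass summation with fixed
    margins).  A zero margin returns p = 1 by convention (callers flag it)."""
    if t.has_zero_margin():
        return 1.0
    _, p = fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(1.0, p))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values (capped at 1, monotone
    over the sorted order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0,1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running = 1.0
    for rank_pos in range(n - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, p[i] * n / (rank_pos + 1))
        adjusted[i] = running
    return adjusted.tolist()


def enrichment_scan(
    gene_set: Iterable[str],
    annotations: dict[str, set[str]],
    universe: Iterable[str],
    min_annotated: int = 1,
) -> list[EnrichmentRow]:
    """Fisher/FDR scan of every term with at least ``min_annotated``
    annotated genes in the universe.  Rows are ordered by q then p then
    term.  ``gene_set`` must be a subset of ``universe`` (genes outside the
    universe -- e.g. on unplaced scaffolds -- are the caller's exclusion)."""
    universe = set(universe)
    gene_set = set(gene_set)
    if not universe:
        raise ValidationError("empty universe")
    if not gene_set <= universe:
        raise ValidationError("gene_set must be a subset of the universe")
    term_genes: dict[str, set[str]] = {}
    for gid in universe:
        for term in annotations.get(gid, ()):
            term_genes.setdefault(term, set()).add(gid)
    rows: list[EnrichmentRow] = []
    for term in sorted(term_genes):
        annotated = term_genes[term]
        if len(annotated) < min_annotated:
            continue
        a = len(gene_set & annotated)
        b = len(gene_set) - a
        c = len(annotated) - a
        d = len(universe) - len(gene_set) - c
        table = ContingencyTable(a, b, c, d)
        p = fisher_2x2(table)
        rows.append(
            EnrichmentRow(
                term=term,
                table=table,
                p=p,
                q=1.0,
                direction=table.odds_ratio_direction,
                flagged=table.has_zero_margin(),
            )
        )
    qs = bh_fdr([r.p for r in rows])
    for r, q in zip(rows, qs):
        r.q = float(q)
    rows.sort(key=lambda r: (r.q, r.p, r.term))
    return rows
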