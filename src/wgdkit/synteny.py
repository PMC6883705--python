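"""Collinear synteny-block chaining, block filters, and partner-ratio logic.

Chaining follows the D:A convention: ``D`` is the maximum genic distance
between consecutive matches (consecutive chained matches may skip at most D
intervening genes on either chromosome; D=0 means strictly consecutive) and
``A`` is the minimum number of aligned gene pairs per block.  Chains
maximise pair count; ties are broken by smaller total rank gap, then by the
lexicographically smallest match sequence, so output is fully deterministic.
Both parallel and antiparallel (inverted) chains are detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Callable, Iterable, Optional, Union

import numpy as np

from .model import (
    BlockPair,
    ChainParams,
    Gene,
    Genome,
    HomologPair,
    SyntenyBlock,
    UndefinedMedianError,
    ValidationError,
)

__all__ = [
    "BlockFilterSpec",
    "RatioSummary",
    "chain_collinear",
    "filter_blocks",
    "block_median_ks",
    "select_wgd_blocks",
    "partner_ratio",
]


# ---------------------------------------------------------------------------
# chaining


def _gene_lookup(genomes: list[Genome]) -> dict[str, tuple[str, Gene]]:
    lut: dict[str, tuple[str, Gene]] = {}
    for genome in genomes:
        for g in genome.genes():
            lut[g.id] = (genome.label, g)
    return lut


Match = tuple[int, int, str, str, Optional[float]]  # rank_a, rank_b, gene_a, gene_b, ks


def chain_collinear(
    pairs: Iterable[HomologPair],
    genomes: Union[Genome, tuple[Genome, Genome], list[Genome]],
    params: ChainParams,
) -> list[SyntenyBlock]:
    """Chain homolog pairs into maximal collinear synteny blocks.

    ``genomes`` is the one (intra-genome) or two genomes the pairs live in.
    Within each chromosome pair, matches are greedily peeled into chains:
    the best remaining chain (most pairs, then smallest total gap) is
    extracted and its matches removed until no chain of >=A pairs remains.
    A match may appear in one block per chromosome pair but may recur in
    blocks of other chromosome pairs.
    """
    if isinstance(genomes, Genome):
        genome_list = [genomes]
    else:
        genome_list = list(genomes)
    lut = _gene_lookup(genome_list)
    intra = len(genome_list) == 1 or genome_list[0].label == genome_list[-1].label

    by_chrompair: dict[tuple[str, str, str, str], list[Match]] = {}
    for p in pairs:
        if p.gene_a not in lut or p.gene_b not in lut:
            missing = p.gene_a if p.gene_a not in lut else p.gene_b
            raise ValidationError(f"pair references unknown gene {missing!r}")
        (lab_a, ga), (lab_b, gb) = lut[p.gene_a], lut[p.gene_b]
        if not intra and lab_a == lab_b:
            continue  # same-genome pair supplied alongside two genomes
        if not intra and lab_a != genome_list[0].label:
            ga, gb = gb, ga
            lab_a, lab_b = lab_b, lab_a
        if intra:
            # orient intra matches canonically (chrom_a <= chrom_b, and
            # rank_a < rank_b on the same chromosome)
            if (ga.chrom, ga.rank) > (gb.chrom, gb.rank):
                ga, gb = gb, ga
        key = (lab_a, lab_b, ga.chrom, gb.chrom)
        by_chrompair.setdefault(key, []).append((ga.rank, gb.rank, ga.id, gb.id, p.ks))

    blocks: list[SyntenyBlock] = []
    for key in sorted(by_chrompair):
        lab_a, lab_b, ca, cb = key
        matches = sorted(set(by_chrompair[key]))
        blocks.extend(
            _peel_chains(matches, lab_a, lab_b, ca, cb, params)
        )
    return blocks


def _chain_key(chain: list[Match]) -> tuple:
    gap = sum(
        (b[0] - a[0] - 1) + (abs(b[1] - a[1]) - 1) for a, b in zip(chain, chain[1:])
    )
    return (-len(chain), gap, tuple((m[0], m[1]) for m in chain))


def _peel_chains(
    matches: list[Match], lab_a: str, lab_b: str, ca: str, cb: str, params: ChainParams
) -> list[SyntenyBlock]:
    """Greedy peeling: extract the best remaining chain (most pairs, then
    smallest total gap, then lexicographically smallest (rank_a, rank_b)
    sequence), remove its matches, repeat while a chain of >=A remains."""
    blocks = []
    # one match per (rank_a, rank_b) point per chromosome pair
    seen_pts = set()
    pts: list[Match] = []
    for m in matches:
        if (m[0], m[1]) not in seen_pts:
            seen_pts.add((m[0], m[1]))
            pts.append(m)
    ra = np.asarray([m[0] for m in pts], dtype=np.int64)
    rb = np.asarray([m[1] for m in pts], dtype=np.int64)
    active = np.ones(len(pts), dtype=np.bool_)
    while active.any():
        best = None
        for orientation, sign in (("parallel", 1), ("antiparallel", -1)):
            res = _best_chain_core(ra, sign * rb, rb, active, params.D)
            if res is None:
                continue
            length, gap, idx = res
            chain = [pts[k] for k in idx]
            key = (-length, gap, tuple((m[0], m[1]) for m in chain))
            if best is None or key < best[0]:
                best = (key, orientation, chain, idx)
        if best is None or len(best[2]) < params.A:
            break
        _, orientation, chain, idx = best
        if len(chain) == 1:
            orientation = "parallel"  # undefined for a single match
        pairs = [BlockPair(m[2], m[3], m[0], m[1], m[4]) for m in chain]
        blocks.append(
            SyntenyBlock(
                genome_a=lab_a,
                genome_b=lab_b,
                chrom_a=ca,
                chrom_b=cb,
                pairs=pairs,
                orientation=orientation,
            )
        )
        active[np.asarray(idx, dtype=np.int64)] = False
    return blocks


def _best_chain_py(ra, rb2, rb_cmp, active, D):
    """Best chain over active matches for one orientation (rb2 is the
    orientation-signed subject rank; rb_cmp the actual subject rank used in
    lexicographic tie-breaks).  Returns (length, gap, indices) with indices
    in original array order, or None."""
    idx = [i for i in range(len(ra)) if active[i]]
    if not idx:
        return None
    idx.sort(key=lambda i: (ra[i], rb2[i]))
    n = len(idx)
    length = [1] * n
    gap = [0] * n
    parent = [-1] * n

    def seq(i):
        out = []
        while i != -1:
            out.append((int(ra[idx[i]]), int(rb_cmp[idx[i]])))
            i = parent[i]
        return out[::-1]

    for i in range(n):
        ai, bi = ra[idx[i]], rb2[idx[i]]
        for j in range(i):
            da = ai - ra[idx[j]]
            db = bi - rb2[idx[j]]
            if da < 1 or db < 1 or da > D + 1 or db > D + 1:
                continue
            cl = length[j] + 1
            cg = gap[j] + (da - 1) + (db - 1)
            if (
                cl > length[i]
                or (cl == length[i] and cg < gap[i])
                or (
                    cl == length[i]
                    and cg == gap[i]
                    and parent[i] != -1
                    and seq(j) < seq(parent[i])
                )
            ):
                length[i] = cl
                gap[i] = cg
                parent[i] = j
    best_i = 0
    for i in range(1, n):
        if (
            length[i] > length[best_i]
            or (length[i] == length[best_i] and gap[i] < gap[best_i])
            or (
                length[i] == length[best_i]
                and gap[i] == gap[best_i]
                and seq(i) < seq(best_i)
            )
        ):
            best_i = i
    chain = []
    k = best_i
    while k != -1:
        chain.append(idx[k])
        k = parent[k]
    chain.reverse()
    return (length[best_i], gap[best_i], chain)


try:  # numba-accelerated DP (same contract and tie-breaks as _best_chain_py)
    from numba import njit as _njit

    @_njit(cache=True)
    def _nb_seq_cmp(parent, ra, rb_cmp, idx, a, b, buf_a, buf_b):
        # reconstruct the two chains (front-to-back) and compare lexicographically
        na = 0
        k = a
        while k != -1:
            buf_a[na] = k
            na += 1
            k = parent[k]
        nb = 0
        k = b
        while k != -1:
            buf_b[nb] = k
            nb += 1
            k = parent[k]
        n = na if na < nb else nb
        for s in range(n):
            ia = idx[buf_a[na - 1 - s]]
            ib = idx[buf_b[nb - 1 - s]]
            if ra[ia] != ra[ib]:
                return -1 if ra[ia] < ra[ib] else 1
            if rb_cmp[ia] != rb_cmp[ib]:
                return -1 if rb_cmp[ia] < rb_cmp[ib] else 1
        if na == nb:
            return 0
        return -1 if na < nb else 1

    @_njit(cache=True)
    def _best_chain_nb(ra, rb2, rb_cmp, idx, D):
        n = idx.shape[0]
        length = np.ones(n, dtype=np.int64)
        gap = np.zeros(n, dtype=np.int64)
        parent = -np.ones(n, dtype=np.int64)
        buf_a = np.zeros(n, dtype=np.int64)
        buf_b = np.zeros(n, dtype=np.int64)
        for i in range(n):
            ai = ra[idx[i]]
            bi = rb2[idx[i]]
            for j in range(i):
                da = ai - ra[idx[j]]
                db = bi - rb2[idx[j]]
                if da < 1 or db < 1 or da > D + 1 or db > D + 1:
                    continue
                cl = length[j] + 1
                cg = gap[j] + (da - 1) + (db - 1)
                take = False
                if cl > length[i]:
                    take = True
                elif cl == length[i] and cg < gap[i]:
                    take = True
                elif cl == length[i] and cg == gap[i] and parent[i] != -1:
                    if _nb_seq_cmp(parent, ra, rb_cmp, idx, j, parent[i], buf_a, buf_b) < 0:
                        take = True
                if take:
                    length[i] = cl
                    gap[i] = cg
                    parent[i] = j
        best_i = 0
        for i in range(1, n):
            take = False
            if length[i] > length[best_i]:
                take = True
            elif length[i] == length[best_i] and gap[i] < gap[best_i]:
                take = True
            elif length[i] == length[best_i] and gap[i] == gap[best_i]:
                if _nb_seq_cmp(parent, ra, rb_cmp, idx, i, best_i, buf_a, buf_b) < 0:
                    take = True
            if take:
                best_i = i
        m = length[best_i]
        chain = np.zeros(m, dtype=np.int64)
        k = best_i
        s = m - 1
        while k != -1:
            chain[s] = idx[k]
            s -= 1
            k = parent[k]
        return length[best_i], gap[best_i], chain

    _HAVE_NUMBA_CHAIN = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA_CHAIN = False


def _best_chain_core(ra, rb2, rb_cmp, active, D):
    if not _HAVE_NUMBA_CHAIN:
        return _best_chain_py(ra, rb2, rb_cmp, active, D)
    idx = np.nonzero(active)[0]
    if idx.size == 0:
        return None
    order = np.lexsort((rb2[idx], ra[idx]))
    idx = idx[order].astype(np.int64)
    length, gap, chain = _best_chain_nb(
        np.asarray(ra, dtype=np.int64),
        np.asarray(rb2, dtype=np.int64),
        np.asarray(rb_cmp, dtype=np.int64),
        idx,
        int(D),
    )
    return int(length), int(gap), [int(k) for k in chain]


# ---------------------------------------------------------------------------
# block filters


@dataclass
class BlockFilterSpec:
    """Specification for the homology-structure block filters.

    ``paralog_map`` groups core-genome chromosomes into their
    triplication-derived paralog sets (groups of 3; 4 allowed for the
    fission-split group).  ``within_grape_paralogs`` keeps intra-genome
    blocks only between chromosomes of the same group;
    ``columbine_to_all_three`` keeps a basal-chromosome's blocks to a group
    only if that chromosome has at least one block with *every* member.
    """

    mode: str
    paralog_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("within_grape_paralogs", "columbine_to_all_three"):
            raise ValidationError(f"unknown filter mode {self.mode!r}")
        for name, members in self.paralog_map.items():
            if not 3 <= len(members) <= 4:
                raise ValidationError(
                    f"paralog group {name!r} must have 3 (or 4, fission) members"
                )

    def group_of(self, chrom: str) -> str:
        for name, members in self.paralog_map.items():
            if chrom in members:
                return name
        raise ValidationError(f"chromosome {chrom!r} not covered by paralog map")


def filter_blocks(blocks: list[SyntenyBlock], spec: BlockFilterSpec) -> list[SyntenyBlock]:
    """Apply the configured homology-structure filter.  Idempotent; never
    adds blocks."""
    if spec.mode == "within_grape_paralogs":
        return [b for b in blocks if spec.group_of(b.chrom_a) == spec.group_of(b.chrom_b)]
    # columbine_to_all_three: chrom_a is the basal chromosome, chrom_b core
    seen: dict[tuple[str, str], set[str]] = {}
    for b in blocks:
        group = spec.group_of(b.chrom_b)
        seen.setdefault((b.chrom_a, group), set()).add(b.chrom_b)
    kept = []
    for b in blocks:
        group = spec.group_of(b.chrom_b)
        members = set(spec.paralog_map[group])
        matched = seen[(b.chrom_a, group)] & members
        if matched == members:
            kept.append(b)
        elif len(members) == 4 and len(matched) >= 3:
            # fission-split group: matching 3 of 4 members suffices
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# block Ks


def block_median_ks(block: SyntenyBlock, ks_cap: float = 10.0) -> float:
    """Median Ks over the block's gene pairs after excluding Ks > ``ks_cap``
    (saturation).  Raises :class:`UndefinedMedianError` when no usable Ks
    remains; callers flag the block rather than silently dropping it."""
    vals = [p.ks for p in block.pairs if p.ks is not None and p.ks <= ks_cap]
    if not vals:
        raise UndefinedMedianError(
            f"block {block.chrom_a}~{block.chrom_b}: no Ks <= {ks_cap}"
        )
    return float(median(vals))


def annotate_median_ks(blocks: list[SyntenyBlock], ks_cap: float = 10.0) -> list[SyntenyBlock]:
    """Set ``median_ks`` on each block in place; blocks with no usable Ks
    are flagged ``median_ks_defined=False``."""
    for b in blocks:
        try:
            b.median_ks = block_median_ks(b, ks_cap)
            b.median_ks_defined = True
        except UndefinedMedianError:
            b.median_ks = None
            b.median_ks_defined = False
    return blocks


def select_wgd_blocks(
    blocks: list[SyntenyBlock], lo: float = 1.0, hi: float = 2.0
) -> list[SyntenyBlock]:
    """Keep putative WGD-derived blocks: ``lo <= median_ks <= hi``
    (inclusive bounds).  Blocks with undefined medians are dropped."""
    if lo > hi:
        raise ValidationError(f"lo={lo} > hi={hi}")
    return [
        b
        for b in blocks
        if b.median_ks_defined and b.median_ks is not None and lo <= b.median_ks <= hi
    ]


# ---------------------------------------------------------------------------
# partner ratios


@dataclass
class RatioSummary:
    """Distinct-partner-chromosome counts per homology group.

    ``per_group`` maps each group (ancestral color) to the pair
    ``(n_chroms_a, n_chroms_b)`` of distinct partner chromosomes in the two
    genomes.  ``modal_ratio`` is the most common unreduced pair;
    ``modal_ratio_reduced`` the same pair divided by its gcd.
    """

    per_group: dict[str, tuple[int, int]] = field(default_factory=dict)
    modal_ratio: Optional[tuple[int, int]] = None
    modal_ratio_reduced: Optional[tuple[int, int]] = None


def partner_ratio(
    blocks: list[SyntenyBlock],
    grouping: Union[dict[int, str], Callable[[SyntenyBlock], str]],
) -> RatioSummary:
    """Count, per homology group, the distinct partner chromosomes on each
    side, and report the modal (unreduced) ratio across groups.

    ``grouping`` assigns each block a group label (ancestral color): either
    a callable on blocks or a dict keyed by block index.
    """
    summary = RatioSummary()
    if not blocks:
        return summary
    groups: dict[str, tuple[set[str], set[str]]] = {}
    for i, b in enumerate(blocks):
        label = grouping(b) if callable(grouping) else grouping[i]
        chroms_a, chroms_b = groups.setdefault(label, (set(), set()))
        chroms_a.add(b.chrom_a)
        chroms_b.add(b.chrom_b)
    from math import gcd
    from collections import Counter

    for label in sorted(groups):
        a, b = groups[label]
        summary.per_group[label] = (len(a), len(b))
    counts = Counter(summary.per_group.values())
    # modal ratio: most common; ties broken toward the smaller pair
    summary.modal_ratio = min(counts, key=lambda r: (-counts[r], r))
    g = gcd(*summary.modal_ratio)
    summary.modal_ratio_reduced = (summary.modal_ratio[0] // g, summary.modal_ratio[1] // g)
    return summary
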