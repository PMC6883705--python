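"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from wgdkit.model import ChainParams, Gene, Genome
from wgdkit.simulate import SimulationConfig, generate_scenario


@pytest.fixture(scope="session")
def small_sim():
    """A small scenario-3 allopolyploid simulation shared across tests."""
    cfg = SimulationConfig(genes_per_chrom=60, seed=12345)
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def medium_sim():
    """A scenario-3 allopolyploid simulation large enough for pairing tests."""
    cfg = SimulationConfig(genes_per_chrom=120, seed=2024)
    return generate_scenario(cfg)


def toy_genome(label: str, chrom_genes: dict[str, list[str]]) -> Genome:
    """Genome from {chrom: [gene ids]} with ranks in listed order."""
    g = Genome(label)
    for cid, ids in chrom_genes.items():
        g.add_chromosome(
            cid, [Gene(id=i, chrom=cid, rank=k) for k, i in enumerate(ids)]
        )
    return g


# ---------------------------------------------------------------------------
# brute-force chaining oracle


def _chain_key_oracle(chain):
    gap = sum(
        (b[0] - a[0] - 1) + (abs(b[1] - a[1]) - 1) for a, b in zip(chain, chain[1:])
    )
    return (-len(chain), gap, tuple((m[0], m[1]) for m in chain))


def _all_chains(points, D, sign):
    """Every maximal-extension-free chain is included by enumerating ALL
    chains (subsets in valid order); exponential, for tiny instances only."""
    pts = sorted(points, key=lambda m: (m[0], sign * m[1]))
    chains = []

    def extend(chain, start):
        chains.append(list(chain))
        for i in range(start, len(pts)):
            prev = chain[-1]
            da = pts[i][0] - prev[0]
            db = sign * (pts[i][1] - prev[1])
            if 1 <= da <= D + 1 and 1 <= db <= D + 1:
                chain.append(pts[i])
                extend(chain, i + 1)
                chain.pop()

    for i in range(len(pts)):
        extend([pts[i]], i + 1)
    return chains


def brute_force_chain_blocks(points, params: ChainParams):
    """Greedy peeling with exhaustively enumerated chains: the independent
    oracle for chain_collinear on instances of <= ~15 matches.

    Returns a list of (orientation, tuple of (rank_a, rank_b)) blocks in
    extraction order.
    """
    remaining = set(points)
    blocks = []
    while remaining:
        best = None
        for orientation, sign in (("parallel", 1), ("antiparallel", -1)):
            for chain in _all_chains(remaining, params.D, sign):
                key = _chain_key_oracle(chain)
                if best is None or key < best[0]:
                    best = (key, orientation, chain)
        if best is None or len(best[2]) < params.A:
            break
        _, orientation, chain = best
        if len(chain) == 1:
            orientation = "parallel"
        blocks.append((orientation, tuple((m[0], m[1]) for m in chain)))
        remaining -= set(chain)
    return blocks


# ---------------------------------------------------------------------------
# Smith-Waterman oracle over word symbols (Biopython)


def biopython_local_score(q, t, match=4, mismatch=-1, gap=-1):
    """Independent local-alignment oracle via Bio.Align.PairwiseAligner,
    mapping integer word symbols to unicode characters."""
    from Bio import Align

    vocab = sorted(set(q) | set(t))
    table = {w: chr(0x100 + i) for i, w in enumerate(vocab)}
    qs = "".join(table[w] for w in q)
    ts = "".join(table[w] for w in t)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    if not qs or not ts:
        return 0
    return int(aligner.score(qs, ts))


# ---------------------------------------------------------------------------
# Wilcoxon pair-counting oracle


def pair_count_w(x, y):
    w = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                w += 1.0
            elif xi == yi:
                w += 0.5
    return w


# ---------------------------------------------------------------------------
# Fisher enumeration oracle


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration over all
    tables with the observed margins."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(aa):
        bb = r1 - aa
        cc = c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return 0.0
        return comb(r1, aa) * comb(r2, cc) / denom

    p_obs = prob(a)
    total = 0.0
    for aa in range(0, min(r1, c1) + 1):
        p = prob(aa)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)
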