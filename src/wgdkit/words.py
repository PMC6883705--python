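"""Gene-order "word" encoding and sliding-window local alignment.

Chromosomes are recoded as ordered sequences of homology-class symbols
("words"): anchors are seeded by strictly consecutive inter-genome matches
(D:A = 0:3 by default; 0:2 for more diverged genome pairs), words are then
propagated to paralogous copies through intragenomic gene-to-gene homology
(D:A = 0:1), and gene-order similarity between two chromosomes is the
distribution of maximum local-alignment scores of length-N query windows
against the whole target, taking the better of the forward and the
inverted window (match=4, gap=-1, mismatch=-1 by default).

Alignment is over opaque word symbols; the strand of the underlying genes
is ignored -- inversions are handled by the whole-window reversal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .model import ChainParams, Genome, HomologPair, ValidationError
from .synteny import chain_collinear

__all__ = [
    "WordSequence",
    "ScoreProfile",
    "WordScoring",
    "seed_anchor_segments",
    "propagate_paralog_words",
    "encode_word_sequence",
    "local_word_alignment",
    "windowed_score_profile",
]


# ---------------------------------------------------------------------------
# Smith-Waterman over integer word symbols (numba-jitted with a pure-Python
# fallback; linear gap penalty, local alignment, score floor 0)


def _sw_py(q, t, match: int, mismatch: int, gap: int) -> int:
    m, n = len(q), len(t)
    best = 0
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = match if qi == t[j - 1] else mismatch
            v = prev[j - 1] + s
            if prev[j] + gap > v:
                v = prev[j] + gap
            if cur[j - 1] + gap > v:
                v = cur[j - 1] + gap
            if v < 0:
                v = 0
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best


def _window_scores_py(q, t, N: int, match: int, mismatch: int, gap: int):
    n_win = len(q) - N + 1
    out = np.zeros(n_win, dtype=np.int64)
    for w in range(n_win):
        win = q[w : w + N]
        fwd = _sw_py(win, t, match, mismatch, gap)
        rev = _sw_py(win[::-1], t, match, mismatch, gap)
        out[w] = max(fwd, rev)
    return out


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True)
    def _sw_nb(q, t, match, mismatch, gap):  # type: ignore[no-redef]
        m, n = q.shape[0], t.shape[0]
        best = 0
        prev = np.zeros(n + 1, dtype=np.int64)
        cur = np.zeros(n + 1, dtype=np.int64)
        for i in range(1, m + 1):
            qi = q[i - 1]
            cur[0] = 0
            for j in range(1, n + 1):
                s = match if qi == t[j - 1] else mismatch
                v = prev[j - 1] + s
                if prev[j] + gap > v:
                    v = prev[j] + gap
                if cur[j - 1] + gap > v:
                    v = cur[j - 1] + gap
                if v < 0:
                    v = 0
                cur[j] = v
                if v > best:
                    best = v
            prev, cur = cur, prev
        return best

    @njit(cache=True)
    def _window_scores_nb(q, t, N, match, mismatch, gap):  # type: ignore[no-redef]
        n_win = q.shape[0] - N + 1
        out = np.zeros(n_win, dtype=np.int64)
        for w in range(n_win):
            win = np.ascontiguousarray(q[w : w + N])
            rwin = win[::-1].copy()
            fwd = _sw_nb(win, t, match, mismatch, gap)
            rev = _sw_nb(rwin, t, match, mismatch, gap)
            out[w] = fwd if fwd >= rev else rev
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class WordScoring:
    """Scoring for word alignment.  The mismatch penalty is exposed because
    only match and gap are canonical; any negative mismatch preserves the
    ranking logic."""

    match: int = 4
    gap: int = -1
    mismatch: int = -1

    def __post_init__(self) -> None:
        if not (self.match > 0 >= self.gap and 0 >= self.mismatch):
            raise ValidationError("require match > 0 >= gap and 0 >= mismatch")


# ---------------------------------------------------------------------------
# word data types


@dataclass
class WordSequence:
    """A chromosome recoded as its ordered anchored words.

    ``words`` holds one symbol per anchored gene in rank order; genes with
    no homology class are absent.  ``gene_ids`` parallels ``words``.
    """

    chrom: str
    words: list[int] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.words)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.words, dtype=np.int64)


@dataclass
class ScoreProfile:
    """Per-window maximum alignment scores of a query against a target."""

    query_chrom: str
    target_chrom: str
    N: int
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# operations


def seed_anchor_segments(
    pairs: Iterable[HomologPair],
    genomes,
    params: ChainParams = ChainParams(D=0, A=3),
):
    """Anchor blocks: runs of at least A strictly consecutive matching genes
    between two genomes (D=0).  Same contract as
    :func:`wgdkit.synteny.chain_collinear`; A=2 relaxes the seeding for more
    diverged genome pairs."""
    if params.D != 0:
        raise ValidationError("anchor seeding requires D=0 (strictly consecutive genes)")
    return chain_collinear(pairs, genomes, params)


def propagate_paralog_words(
    anchors,
    intra_pairs_a: Iterable[HomologPair],
    intra_pairs_b: Iterable[HomologPair],
) -> dict[str, int]:
    """Assign word ids by transitive closure over anchor matches and
    intragenomic gene-to-gene homology (D:A = 0:1 propagation).

    Homology classes are connected components of the graph whose edges are
    (i) the aligned gene pairs of the anchors and (ii) all intragenomic
    pairs of both genomes.  Only components containing at least one anchor
    gene receive a word; isolated or anchor-free genes carry no word.
    Word ids are deterministic (sorted by smallest member gene id).
    """
    g = nx.Graph()
    anchor_genes: set[str] = set()
    for block in anchors:
        for p in block.pairs:
            g.add_edge(p.gene_a, p.gene_b)
            anchor_genes.add(p.gene_a)
            anchor_genes.add(p.gene_b)
    for pairs in (intra_pairs_a, intra_pairs_b):
        for p in pairs:
            g.add_edge(p.gene_a, p.gene_b)
    assignment: dict[str, int] = {}
    components = [
        sorted(c) for c in nx.connected_components(g) if anchor_genes & set(c)
    ]
    components.sort(key=lambda c: c[0])
    for wid, comp in enumerate(components):
        for gene in comp:
            assignment[gene] = wid
    return assignment


def encode_word_sequence(
    genome: Genome,
    chrom: str,
    assignment: dict[str, int],
    gene_filter=None,
) -> WordSequence:
    """Recode one chromosome as its word sequence (worded genes in rank
    order; unworded genes skipped).  ``gene_filter`` optionally restricts to
    a subset of genes, e.g. the portion of one ancestral color."""
    ws = WordSequence(chrom=chrom)
    for g in genome.chromosomes[chrom]:
        if gene_filter is not None and not gene_filter(g):
            continue
        if g.id in assignment:
            ws.words.append(assignment[g.id])
            ws.gene_ids.append(g.id)
    return ws


def local_word_alignment(
    query,
    target,
    match: int = 4,
    gap: int = -1,
    mismatch: int = -1,
) -> int:
    """Maximum Smith-Waterman-style local alignment score between two word
    lists (linear gap penalty, score floor 0).  Empty input scores 0."""
    WordScoring(match=match, gap=gap, mismatch=mismatch)  # validate
    q = np.asarray(list(query), dtype=np.int64)
    t = np.asarray(list(target), dtype=np.int64)
    if q.size == 0 or t.size == 0:
        return 0
    if _HAVE_NUMBA:
        return int(_sw_nb(q, t, match, mismatch, gap))
    return int(_sw_py(q.tolist(), t.tolist(), match, mismatch, gap))


def windowed_score_profile(
    query: WordSequence,
    target: WordSequence,
    N: int,
    scoring: WordScoring = WordScoring(),
) -> ScoreProfile:
    """Slide a window of N words along the query; each window's score is the
    maximum of aligning the window and its reversal against the whole
    target.  Windows shorter than N at the sequence end are not scored, so
    the profile has ``max(0, len(query) - N + 1)`` entries."""
    if N < 2:
        raise ValidationError(f"window size N must be >= 2, got {N}")
    profile = ScoreProfile(query_chrom=query.chrom, target_chrom=target.chrom, N=N)
    if len(query) < N:
        warnings.warn(
            f"query {query.chrom} has {len(query)} words < N={N}; empty profile",
            stacklevel=2,
        )
        return profile
    q = query.as_array()
    t = target.as_array()
    if t.size == 0:
        profile.scores = np.zeros(len(q) - N + 1, dtype=np.int64)
        return profile
    if _HAVE_NUMBA:
        profile.scores = _window_scores_nb(
            q, t, N, scoring.match, scoring.mismatch, scoring.gap
        )
    else:
        profile.scores = _window_scores_py(
            q.tolist(), t.tolist(), N, scoring.match, scoring.mismatch, scoring.gap
        )
    return profile
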