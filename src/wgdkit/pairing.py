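"""Chromosome pairing tests and polyploidy-scenario classification.

For one basal-lineage ("columbine") chromosome and the three paralogous
core-lineage ("grape") chromosomes of the same ancestral color, the pairing
statistic is the Wilcoxon rank-sum W between the windowed alignment-score
profile of the best-matching grape chromosome and the pooled profiles of
the other grape chromosomes.  Significance comes from a permutation null:
all grape words in the comparison set are pooled and redrawn (without
replacement) into pseudo-chromosomes of the observed sizes, profiles and W
are recomputed, and the p-value is the fraction of permutations whose W is
at least the observed one (one-sided), on the 1/n_perm grid.

Because the best hit is *selected*, each permutation's reference statistic
is the maximum W across its pseudo-chromosomes -- the permuted analogue of
the selection -- which keeps the test conservative.

Scenario logic: a modal 3:6 partner ratio implies a lineage-specific extra
WGD in the basal lineage (scenario 1).  A modal 3:2 ratio with confident
*exclusive* pairing (each basal paralog matching a different grape
chromosome) implies the tetraploidy is shared (scenario 3); without
confident pairing the histories are independent (scenario 2).  Among
shared calls, the leftover grape chromosome of each triplet is either a
true hybridization-derived outlier (allohexaploidy: it pairs with neither
basal paralog in particular) or a duplicate of one partner
(autohexaploidy: run as a query itself, it pairs significantly with one
basal paralog, at the same similarity level as that paralog's own
partner); the two are separated by :func:`classify_leftover`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .model import ValidationError
from .synteny import RatioSummary
from .words import ScoreProfile, WordScoring, WordSequence, windowed_score_profile

__all__ = [
    "PermutationTest",
    "ParalogTest",
    "PairingResult",
    "ScenarioCall",
    "wilcoxon_w",
    "permutation_pvalue",
    "paralog_partner_test",
    "classify_leftover",
    "infer_exclusive_pairing",
    "detect_shared_fusion",
    "classify_history",
]


def wilcoxon_w(best_scores, other_scores) -> float:
    """Wilcoxon rank-sum W: the number of (x, y) pairs with x > y plus half
    the tied pairs (the Mann-Whitney convention)."""
    x = np.asarray(best_scores, dtype=float)
    y = np.asarray(other_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_w requires two non-empty samples")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    return w


def _profiles(
    query: WordSequence,
    targets: dict[str, WordSequence],
    N: int,
    scoring: WordScoring,
) -> dict[str, ScoreProfile]:
    return {t: windowed_score_profile(query, ws, N, scoring) for t, ws in targets.items()}


def _w_vs_pooled_others(profiles: dict[str, ScoreProfile], target: str) -> float:
    x = profiles[target].scores
    others = [profiles[t].scores for t in sorted(profiles) if t != target]
    y = np.concatenate(others) if others else np.zeros(0)
    return wilcoxon_w(x, y)


def _permuted_sequences(
    targets: dict[str, WordSequence], rng: np.random.Generator
) -> dict[str, WordSequence]:
    """Pool all target words and redraw pseudo-chromosomes of the observed
    sizes, without replacement."""
    ids = sorted(targets)
    pool = np.concatenate([targets[t].as_array() for t in ids]) if ids else np.zeros(0)
    perm = rng.permutation(pool)
    out = {}
    offset = 0
    for t in ids:
        n = len(targets[t])
        out[t] = WordSequence(chrom=t, words=perm[offset : offset + n].tolist())
        offset += n
    return out


@dataclass
class PermutationTest:
    """Observed W for one query-target pairing and its permutation p-value."""

    query_chrom: str
    target_chrom: str
    W: float
    p: float
    n_perm: int
    perm_ws: np.ndarray = field(default_factory=lambda: np.zeros(0))


def permutation_pvalue(
    query: WordSequence,
    targets: dict[str, WordSequence],
    target_id: str,
    N: int,
    n_perm: int = 100,
    seed: int = 0,
    scoring: WordScoring = WordScoring(),
) -> PermutationTest:
    """Permutation test of the pairing between ``query`` and ``target_id``
    within the comparison set ``targets``.

    p = (number of permutations whose maximum pseudo-chromosome W is >= the
    observed W of ``target_id`` vs pooled others) / n_perm.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if target_id not in targets:
        raise ValidationError(f"target {target_id!r} not in comparison set")
    profiles = _profiles(query, targets, N, scoring)
    w_obs = _w_vs_pooled_others(profiles, target_id)
    rng = np.random.default_rng(seed)
    perm_ws = np.zeros(n_perm)
    for k in range(n_perm):
        pseudo = _permuted_sequences(targets, rng)
        p_profiles = _profiles(query, pseudo, N, scoring)
        perm_ws[k] = max(_w_vs_pooled_others(p_profiles, t) for t in sorted(pseudo))
    p = float(np.sum(perm_ws >= w_obs)) / n_perm
    return PermutationTest(
        query_chrom=query.chrom,
        target_chrom=target_id,
        W=w_obs,
        p=p,
        n_perm=n_perm,
        perm_ws=perm_ws,
    )


@dataclass
class ParalogTest:
    """Partner call for one basal paralog against a grape triplet.

    ``partner`` is a 1-tuple with the single best hit when its permutation
    test is significant; a 2-tuple when instead the top two profiles pooled
    beat the third significantly *and* the runner-up matches at partner
    level (``pair_ratio``) -- the duplicated-partner route; else ``None``.
    """

    query_chrom: str
    Ws: dict[str, float]
    best: str
    p_best: float
    partner: Optional[tuple[str, ...]]
    p_pair: Optional[float] = None
    pair_ratio: Optional[float] = None
    tie_flag: bool = False


def paralog_partner_test(
    query: WordSequence,
    targets: dict[str, WordSequence],
    N: int,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    partner_level: float = 0.9,
    scoring: WordScoring = WordScoring(),
) -> ParalogTest:
    """Partner test for one basal paralog.

    Round 1: the best hit (largest W vs pooled others; ties broken toward
    the larger median profile score, then flagged) is tested against the
    permutation null and assigned as the single partner when p <= alpha.
    When round 1 fails with three targets, a duplicated partner is
    considered: the top two profiles pooled against the third, with the
    matching permuted statistic (top-two selection repeated inside each
    permutation).  The pair is accepted only when the runner-up also
    matches at *partner level* -- its median profile score is at least
    ``partner_level`` times the best hit's -- which separates a genuine
    duplicated partner (scores tied at partner level) from one strong and
    one mediocre target.
    """
    profiles = _profiles(query, targets, N, scoring)
    ids = sorted(targets)
    ws = {t: _w_vs_pooled_others(profiles, t) for t in ids}

    def tie_key(t):
        return (ws[t], float(np.median(profiles[t].scores)), t)

    ranked = sorted(ids, key=tie_key, reverse=True)
    best = ranked[0]
    tie_flag = len(ranked) > 1 and ws[ranked[0]] == ws[ranked[1]]
    w_obs = ws[best]
    pair_obs = None
    if len(ids) >= 3:
        top2 = ranked[:2]
        x = np.concatenate([profiles[t].scores for t in sorted(top2)])
        y = np.concatenate([profiles[t].scores for t in ranked[2:]])
        pair_obs = wilcoxon_w(x, y)

    rng = np.random.default_rng(seed)
    perm_max = np.zeros(n_perm)
    perm_pair = np.zeros(n_perm)
    for k in range(n_perm):
        pseudo = _permuted_sequences(targets, rng)
        p_profiles = _profiles(query, pseudo, N, scoring)
        p_ws = {t: _w_vs_pooled_others(p_profiles, t) for t in ids}
        perm_max[k] = max(p_ws.values())
        if pair_obs is not None:
            p_ranked = sorted(ids, key=lambda t: (p_ws[t], t), reverse=True)
            px = np.concatenate([p_profiles[t].scores for t in sorted(p_ranked[:2])])
            py = np.concatenate([p_profiles[t].scores for t in p_ranked[2:]])
            perm_pair[k] = wilcoxon_w(px, py)

    p_best = float(np.sum(perm_max >= w_obs)) / n_perm
    p_pair = (
        float(np.sum(perm_pair >= pair_obs)) / n_perm if pair_obs is not None else None
    )
    pair_ratio = None
    if len(ranked) >= 2:
        m_best = float(np.median(profiles[ranked[0]].scores))
        m_second = float(np.median(profiles[ranked[1]].scores))
        pair_ratio = m_second / max(m_best, 1.0)
    if p_best <= alpha:
        partner: Optional[tuple[str, ...]] = (best,)
    elif (
        p_pair is not None
        and p_pair <= alpha
        and pair_ratio is not None
        and pair_ratio >= partner_level
    ):
        partner = tuple(sorted(ranked[:2]))
    else:
        partner = None
    return ParalogTest(
        query_chrom=query.chrom,
        Ws=ws,
        best=best,
        p_best=p_best,
        partner=partner,
        p_pair=p_pair,
        pair_ratio=pair_ratio,
        tie_flag=tie_flag,
    )


def classify_leftover(
    leftover: WordSequence,
    basal_queries: dict[str, WordSequence],
    partner_of: dict[str, WordSequence],
    N: int,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    partner_level: float = 0.9,
    scoring: WordScoring = WordScoring(),
) -> dict:
    """Is the leftover triplet member a duplicated partner or a true outlier?

    Two conditions must both hold for the *duplicate* (autopolyploidy)
    call: (i) run as a query against the two basal paralogs, the leftover
    pairs significantly with one of them (same pooled-word permutation
    null as the forward test); and (ii) the match is at *partner level* --
    the median windowed score of the leftover against that paralog is at
    least ``partner_level`` times the median score of the paralog's own
    assigned partner (``partner_of``) against it.  A hybridization-derived
    outlier can show a weak lean under (i), because biased fractionation
    leaves one subgenome systematically more complete, but it matches far
    below partner level.  Returns a dict with the reverse-test p, the
    best basal hit, the partner-level ratio, and ``call`` in
    {"duplicate", "outlier"}.
    """
    t = paralog_partner_test(
        leftover, basal_queries, N=N, n_perm=n_perm, seed=seed, alpha=alpha, scoring=scoring
    )
    out = {"p_reverse": t.p_best, "best_query": t.best, "ratio": None, "call": "outlier"}
    if t.p_best <= alpha:
        qhat = t.best
        partner_ws = partner_of.get(qhat)
        if partner_ws is not None:
            p1 = windowed_score_profile(leftover, basal_queries[qhat], N, scoring).scores
            p2 = windowed_score_profile(partner_ws, basal_queries[qhat], N, scoring).scores
            if p1.size and p2.size:
                ratio = float(np.median(p1)) / max(float(np.median(p2)), 1.0)
                out["ratio"] = ratio
                if ratio >= partner_level:
                    out["call"] = "duplicate"
    return out


@dataclass
class PairingResult:
    """Pairing of a basal paralog pair against one grape triplet.

    ``mode_vote`` summarises the triplet's evidence: with a confident
    exclusive pairing, ``"allo"`` when the leftover chromosome pairs with
    neither basal paralog (it is the ``outlier``) and ``"auto"`` when it
    pairs significantly with one (a duplicated partner); ``"none"``
    without exclusive pairing.
    """

    label: str
    triplet: list[str]
    assignments: dict[str, Optional[tuple[str, ...]]]
    confident: dict[str, bool]
    exclusive: bool
    outlier: list[str]
    mode_vote: str
    tests: dict[str, ParalogTest] = field(default_factory=dict)

    @property
    def supports_shared(self) -> bool:
        return self.mode_vote in ("allo", "auto")


def infer_exclusive_pairing(
    tests: dict[str, ParalogTest],
    triplet: Sequence[str],
    alpha: float = 0.05,
    label: str = "",
    leftover_call: Optional[str] = None,
) -> PairingResult:
    """Combine per-paralog partner tests into a triplet-level pairing call.

    Confident assignments must be distinct across the basal paralogs or the
    result is flagged non-exclusive; with two exclusive single-partner
    assignments the remaining triplet member is the leftover.  Its nature
    is ``leftover_call`` (see :func:`classify_leftover`): ``"duplicate"``
    means an autopolyploid vote with no outlier; ``"outlier"`` or ``None``
    means the allopolyploid vote with the leftover as the outlier.
    """
    if not tests:
        raise ValidationError("no paralog tests supplied")
    assignments = {q: t.partner for q, t in tests.items()}
    confident = {q: t.partner is not None for q, t in tests.items()}
    singles = [t.partner for t in tests.values() if t.partner is not None and len(t.partner) == 1]
    pairs = [t.partner for t in tests.values() if t.partner is not None and len(t.partner) == 2]
    exclusive = (
        len(singles) == len(tests)
        and len({s[0] for s in singles}) == len(singles)
        and len(tests) >= 2
    )
    leftover: list[str] = []
    if exclusive:
        assigned = {s[0] for s in singles}
        leftover = sorted(set(triplet) - assigned)
    # one paralog matching a duplicated partner pair, the other a disjoint
    # single, together covering the triplet: the direct auto signature
    disjoint_pair_auto = (
        len(pairs) == 1
        and len(singles) == len(tests) - 1
        and len(tests) >= 2
        and not (set(pairs[0]) & {s[0] for s in singles})
        and set(pairs[0]) | {s[0] for s in singles} == set(triplet)
    )
    if exclusive and leftover:
        if leftover_call == "duplicate":
            mode_vote = "auto"
            outlier: list[str] = []
        else:
            mode_vote = "allo"
            outlier = leftover
    elif disjoint_pair_auto:
        mode_vote = "auto"
        outlier = []
    else:
        mode_vote = "none"
        outlier = []
    return PairingResult(
        label=label,
        triplet=list(triplet),
        assignments=assignments,
        confident=confident,
        exclusive=exclusive,
        outlier=outlier,
        mode_vote=mode_vote,
        tests=dict(tests),
    )


def detect_shared_fusion(
    portion_pairings: dict[str, tuple[Optional[tuple[str, ...]], bool]],
    fusion_spec: dict[str, set],
) -> str:
    """Verdict on whether a chromosomal fusion predates the lineage split.

    ``portion_pairings`` maps each homologous portion (ancestral color) of
    the fused query chromosome to its ``(assigned partner chromosomes,
    confident)`` pairing; ``fusion_spec`` maps the portion to the designated
    partner chromosome set (a set, to allow a fission-split partner).
    ``shared`` requires every portion to pair confidently inside its
    designated set; a confident pairing outside the set is ``not_shared``;
    anything else is ``undetermined``.
    """
    verdict = "shared"
    for portion, (assigned, conf) in portion_pairings.items():
        allowed = fusion_spec.get(portion, set())
        if not conf or assigned is None:
            verdict = "undetermined"
            continue
        if not set(assigned) & set(allowed):
            return "not_shared"
    return verdict


@dataclass
class ScenarioCall:
    """Classification of the polyploid history.

    ``tetraploidy``: ``shared`` (basal tetraploidy is the first step of the
    core hexaploidy), ``independent`` (separate events post-split), or
    ``lineage_specific_extra`` (core-type triplication plus an extra basal
    WGD).  ``hexaploidy_mode`` is resolved only for shared calls.
    """

    tetraploidy: str
    hexaploidy_mode: str
    outlier_chroms: list[str] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.tetraploidy not in ("shared", "independent", "lineage_specific_extra"):
            raise ValidationError(f"bad tetraploidy call {self.tetraploidy!r}")
        if self.hexaploidy_mode not in ("auto", "allo", "undetermined"):
            raise ValidationError(f"bad hexaploidy mode {self.hexaploidy_mode!r}")
        votes = self.evidence.get("shared_votes")
        n = self.evidence.get("n_triplets")
        if votes is not None and n:
            if self.tetraploidy == "shared" and votes < min(2, n):
                raise ValidationError("shared call without pairing support")
        if self.tetraploidy != "shared" and self.hexaploidy_mode != "undetermined":
            raise ValidationError("hexaploidy mode is only resolved for shared calls")


def classify_history(
    ratio: RatioSummary,
    pairings: Sequence[PairingResult] = (),
    fusion_verdicts: Sequence[str] = (),
    basal_side: str = "a",
) -> ScenarioCall:
    """Scenario call from the partner-ratio summary, the triplet pairing
    results, and (optionally) shared-fusion verdicts.

    ``basal_side`` says which side of the ratio pairs is the basal lineage
    ("a" or "b").
    """
    evidence: dict = {
        "modal_ratio": ratio.modal_ratio,
        "n_triplets": len(pairings),
        "fusion_verdicts": list(fusion_verdicts),
    }
    if ratio.modal_ratio is None:
        return ScenarioCall("independent", "undetermined", evidence=evidence)
    a, b = ratio.modal_ratio
    basal, core = (a, b) if basal_side == "a" else (b, a)
    evidence["basal_core_counts"] = (basal, core)
    if core > 0 and basal >= 2 * core - 1 and basal > core:
        # ~3:6 structure: extra WGD on top of the core-type triplication
        return ScenarioCall("lineage_specific_extra", "undetermined", evidence=evidence)
    shared_votes = sum(1 for p in pairings if p.supports_shared)
    evidence["shared_votes"] = shared_votes
    supporting = [p for p in pairings if p.supports_shared]
    # triplets voting "none" are uninformative, not contrary evidence; two
    # independent triplets with subgenome-specific pairing already reject
    # independent tetraploidies (spurious shared votes are rare under the
    # permutation null)
    required = min(2, len(pairings))
    if not pairings or shared_votes < required:
        call = ScenarioCall("independent", "undetermined", evidence=evidence)
        call.validate()
        return call
    auto_votes = sum(1 for p in supporting if p.mode_vote == "auto")
    allo_votes = sum(1 for p in supporting if p.mode_vote == "allo")
    evidence["auto_votes"] = auto_votes
    evidence["allo_votes"] = allo_votes
    if fusion_verdicts:
        evidence["shared_fusion_support"] = sum(1 for v in fusion_verdicts if v == "shared")
    if auto_votes >= allo_votes and auto_votes > 0:
        mode = "auto"
        outliers: list[str] = []
    else:
        mode = "allo"
        outliers = sorted({c for p in supporting if p.mode_vote == "allo" for c in p.outlier})
    call = ScenarioCall("shared", mode, outlier_chroms=outliers, evidence=evidence)
    call.validate()
    return call
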