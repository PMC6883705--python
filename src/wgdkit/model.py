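"""Core domain types for rank-coordinate comparative genomics.

The working coordinate system throughout the package is *gene rank* (ordinal
position along a chromosome), not base pairs: every downstream procedure --
collinear chaining, word encoding, window alignment -- is stated in genic
units.  Base-pair positions, when read from annotation files, are retained
only as metadata on :class:`Gene`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class ParseError(ValueError):
    """Raised for malformed records in input files (names the offending line)."""


class SaturationError(ValueError):
    """Raised when a distance correction is undefined (divergence saturated)."""


class UndefinedMedianError(ValueError):
    """Raised when a block has no Ks values under the saturation cap."""


@dataclass
class Gene:
    """A gene model as an ordinal unit on a chromosome.

    ``rank`` is the 0-based position among the genes of its chromosome;
    ranks on a chromosome are always exactly ``0..L-1``.  ``family`` is an
    optional homology-class label (shared by all copies descending from one
    ancestral gene).  ``origin`` carries simulation provenance as an
    ``(ancestral_color, subgenome_copy)`` pair; it is ``None`` for real data.
    ``birth`` is the age (Ks units) of a tandem copy, ``None`` for genes
    present since the family's origin.
    """

    id: str
    chrom: str
    rank: int
    strand: str = "+"
    family: Optional[str] = None
    dosage_sensitive: bool = False
    origin: Optional[tuple[str, str]] = None
    start: Optional[int] = None
    end: Optional[int] = None
    birth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ValidationError(f"gene {self.id}: negative rank {self.rank}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def color(self) -> Optional[str]:
        return self.origin[0] if self.origin is not None else None

    @property
    def copy_label(self) -> Optional[str]:
        return self.origin[1] if self.origin is not None else None

    def clone(self, **changes) -> "Gene":
        return replace(self, **changes)


@dataclass
class Genome:
    """An ordered collection of chromosomes, each an ordered list of genes."""

    label: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)

    def add_chromosome(self, chrom_id: str, genes: list[Gene]) -> None:
        if chrom_id in self.chromosomes:
            raise ValidationError(f"duplicate chromosome id {chrom_id!r}")
        self.chromosomes[chrom_id] = genes
        self.reindex(chrom_id)

    def reindex(self, chrom_id: Optional[str] = None) -> None:
        """Re-assign ranks 0..L-1 (and chrom fields) after any reordering."""
        targets = [chrom_id] if chrom_id is not None else list(self.chromosomes)
        for cid in targets:
            for i, g in enumerate(self.chromosomes[cid]):
                g.rank = i
                g.chrom = cid

    def genes(self) -> Iterator[Gene]:
        for genes in self.chromosomes.values():
            yield from genes

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def index(self) -> dict[str, Gene]:
        idx: dict[str, Gene] = {}
        for g in self.genes():
            if g.id in idx:
                raise ValidationError(f"duplicate gene id {g.id!r} in genome {self.label!r}")
            idx[g.id] = g
        return idx

    def families(self) -> dict[str, list[Gene]]:
        fams: dict[str, list[Gene]] = {}
        for g in self.genes():
            if g.family is not None:
                fams.setdefault(g.family, []).append(g)
        return fams

    def validate(self) -> None:
        seen: set[str] = set()
        for cid, genes in self.chromosomes.items():
            for i, g in enumerate(genes):
                if g.chrom != cid:
                    raise ValidationError(
                        f"gene {g.id}: chrom field {g.chrom!r} does not match container {cid!r}"
                    )
                if g.rank != i:
                    raise ValidationError(
                        f"gene {g.id} on {cid}: rank {g.rank} != position {i}"
                    )
                if g.id in seen:
                    raise ValidationError(f"duplicate gene id {g.id!r}")
                seen.add(g.id)

    def copy(self) -> "Genome":
        return Genome(
            self.label,
            {cid: [g.clone() for g in genes] for cid, genes in self.chromosomes.items()},
        )


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class HomologPair:
    """A gene-level homology relation, optionally with a Ks value.

    Ks is the number of synonymous substitutions per synonymous site, a proxy
    for the divergence age of the pair.  Pairs are unordered: construction
    canonicalises ``(gene_a, gene_b)`` lexicographically.
    """

    gene_a: str
    gene_b: str
    ks: Optional[float] = None
    kind: str = "intra"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-pair {self.gene_a!r}")
        if self.ks is not None and self.ks < 0:
            raise ValidationError(f"negative ks for pair {self.gene_a}-{self.gene_b}")
        if self.kind not in ("intra", "inter"):
            raise ValidationError(f"kind must be 'intra' or 'inter', got {self.kind!r}")
        a, b = _canonical(self.gene_a, self.gene_b)
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def dedupe_pairs(pairs: Iterable[HomologPair]) -> list[HomologPair]:
    """Drop duplicate unordered pairs, keeping the first occurrence."""
    seen: set[tuple[str, str]] = set()
    out: list[HomologPair] = []
    for p in pairs:
        if p.key not in seen:
            seen.add(p.key)
            out.append(p)
    return out


@dataclass(frozen=True)
class ChainParams:
    """DAGChainer-style chaining parameters.

    ``D`` is the maximum genic distance between two consecutive matches in a
    chain: consecutive matches may skip at most D intervening genes on either
    chromosome (D=0 means strictly consecutive genes).  ``A`` is the minimum
    number of aligned gene pairs required to call a block.
    """

    D: int = 20
    A: int = 5

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValidationError(f"D must be >= 0, got {self.D}")
        if self.A < 1:
            raise ValidationError(f"A must be >= 1, got {self.A}")


@dataclass(frozen=True)
class BlockPair:
    """One aligned gene pair inside a synteny block, with rank coordinates."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    ks: Optional[float] = None


@dataclass
class SyntenyBlock:
    """A chained run of collinear homologous gene pairs between two regions.

    ``orientation`` is ``"parallel"`` when subject ranks increase with query
    ranks and ``"antiparallel"`` when they decrease (an inverted block).
    """

    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    pairs: list[BlockPair]
    orientation: str = "parallel"
    median_ks: Optional[float] = None
    median_ks_defined: bool = True

    def __post_init__(self) -> None:
        if self.orientation not in ("parallel", "antiparallel"):
            raise ValidationError(f"bad orientation {self.orientation!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def validate_against(self, params: ChainParams) -> None:
        """Assert the chaining contract: >=A pairs, monotone ranks, gaps <= D."""
        if self.n_pairs < params.A:
            raise ValidationError(
                f"block {self.chrom_a}~{self.chrom_b}: {self.n_pairs} pairs < A={params.A}"
            )
        sign = 1 if self.orientation == "parallel" else -1
        for prev, cur in zip(self.pairs, self.pairs[1:]):
            da = cur.rank_a - prev.rank_a
            db = sign * (cur.rank_b - prev.rank_b)
            if da < 1:
                raise ValidationError("query ranks not strictly increasing")
            if db < 1:
                raise ValidationError("subject ranks not monotone for orientation")
            if da > params.D + 1 or db > params.D + 1:
                raise ValidationError(f"rank gap exceeds D={params.D}")
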