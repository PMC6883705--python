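"""Fusion/fission accounting on painted karyotypes.

A painted karyotype annotates each chromosome as an ordered list of
segments labelled by ancestral chromosome ("color") and WGD copy.  Counting
is parsimony-based: the minimum number of fusions and fissions consistent
with the painting, given the number of initial ancestral units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import Genome, ValidationError

__all__ = [
    "PaintedKaryotype",
    "EventCount",
    "event_arithmetic",
    "count_events",
    "paint_from_origins",
    "read_painting",
    "write_painting",
]


@dataclass(frozen=True)
class Segment:
    color: str
    copy: str

    @property
    def label(self) -> tuple[str, str]:
        return (self.color, self.copy)


@dataclass
class PaintedKaryotype:
    """Chromosomes as ordered ancestral-color segments."""

    chromosomes: dict[str, list[Segment]] = field(default_factory=dict)
    palette: Optional[set] = None

    def validate(self) -> None:
        for cid, segs in self.chromosomes.items():
            if not segs:
                raise ValidationError(f"chromosome {cid!r} has no painted segments")
            if self.palette is not None:
                for s in segs:
                    if s.color not in self.palette:
                        raise ValidationError(
                            f"chromosome {cid}: color {s.color!r} not in palette"
                        )

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)


@dataclass
class EventCount:
    fusions_total: int
    fusions_between_different: int
    fusions_between_paralogs: int
    fissions: int

    def __post_init__(self) -> None:
        if min(
            self.fusions_total,
            self.fusions_between_different,
            self.fusions_between_paralogs,
            self.fissions,
        ) < 0:
            raise ValidationError("event counts must be non-negative")
        if self.fusions_total != self.fusions_between_different + self.fusions_between_paralogs:
            raise ValidationError("fusion counts do not add up")


def event_arithmetic(n_start: int, n_end: int, fissions: int) -> int:
    """Fusions implied by a chromosome-number change: ``n_start - n_end +
    fissions``.  Raises when the arithmetic would require a negative count."""
    if min(n_start, n_end, fissions) < 0:
        raise ValidationError("inputs must be non-negative")
    fusions = n_start - n_end + fissions
    if fusions < 0:
        raise ValidationError(
            f"infeasible: {n_start}->{n_end} with {fissions} fissions implies {fusions} fusions"
        )
    return fusions


def count_events(painting: PaintedKaryotype, initial_units: int) -> EventCount:
    """Minimum fusion/fission counts consistent with a complete painting.

    Fissions: each (color, copy) unit split across k chromosomes implies
    k-1 fissions.  Fusions: ``initial_units - n_chromosomes + fissions``.
    A fusion junction joining two copies of the same color (adjacent
    segments sharing color, differing copy) is counted as a fusion between
    WGD-derived paralogous chromosomes; the rest are between different
    chromosomes.
    """
    painting.validate()
    occurrences: dict[tuple[str, str], int] = {}
    for cid, segs in painting.chromosomes.items():
        seen_here = set()
        for s in segs:
            if s.label not in seen_here:
                seen_here.add(s.label)
                occurrences[s.label] = occurrences.get(s.label, 0) + 1
    fissions = sum(k - 1 for k in occurrences.values())
    fusions_total = event_arithmetic(initial_units, painting.n_chromosomes, fissions)
    paralog = 0
    for segs in painting.chromosomes.values():
        for a, b in zip(segs, segs[1:]):
            if a.color == b.color and a.copy != b.copy:
                paralog += 1
    if paralog > fusions_total:
        raise ValidationError(
            f"painting implies {paralog} paralogous junctions but only "
            f"{fusions_total} fusions are feasible"
        )
    return EventCount(
        fusions_total=fusions_total,
        fusions_between_different=fusions_total - paralog,
        fusions_between_paralogs=paralog,
        fissions=fissions,
    )


def paint_from_origins(genome: Genome, min_run: int = 3) -> PaintedKaryotype:
    """Painting helper from per-gene (color, copy) origin labels.

    Collapses each chromosome's gene sequence into maximal runs of one
    (color, copy) label, ignoring runs shorter than ``min_run`` genes
    (absorbed into their neighbours) so single stray genes do not create
    spurious segments.
    """
    chroms: dict[str, list[Segment]] = {}
    palette: set = set()
    for cid, genes in genome.chromosomes.items():
        runs: list[tuple[tuple[str, str], int]] = []
        for g in genes:
            if g.origin is None:
                continue
            label = (g.color, g.copy_label)
            if runs and runs[-1][0] == label:
                runs[-1] = (label, runs[-1][1] + 1)
            else:
                runs.append((label, 1))
        runs = [r for r in runs if r[1] >= min_run]
        # merge adjacent same-label runs left after dropping short ones
        segs: list[Segment] = []
        for label, _ in runs:
            if not segs or segs[-1].label != label:
                segs.append(Segment(color=label[0], copy=label[1]))
        if segs:
            chroms[cid] = segs
            palette.update(s.color for s in segs)
    return PaintedKaryotype(chromosomes=chroms, palette=palette)


def read_painting(path) -> PaintedKaryotype:
    """Painting TSV: columns chrom, segment_index, color, copy."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "segment_index", "color", "copy"}
    if not required.issubset(df.columns):
        raise ValidationError(f"painting table needs columns {sorted(required)}")
    chroms: dict[str, list[Segment]] = {}
    palette: set = set()
    df["segment_index"] = df["segment_index"].astype(int)
    for cid, sub in df.groupby("chrom", sort=False):
        segs = [
            Segment(color=row["color"], copy=row["copy"])
            for _, row in sub.sort_values("segment_index").iterrows()
        ]
        chroms[str(cid)] = segs
        palette.update(s.color for s in segs)
    return PaintedKaryotype(chromosomes=chroms, palette=palette)


def write_painting(painting: PaintedKaryotype, path) -> None:
    rows = []
    for cid, segs in painting.chromosomes.items():
        for i, s in enumerate(segs):
            rows.append({"chrom": cid, "segment_index": i, "color": s.color, "copy": s.copy})
    pd.DataFrame(rows, columns=["chrom", "segment_index", "color", "copy"]).to_csv(
        path, sep="\t", index=False
    )
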