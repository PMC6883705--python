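"""Readers and writers for the standard formats the pipeline touches.

Coordinate dialects: GFF3 is 1-based inclusive, BED 0-based half-open; both
are converted to 0-based gene ranks at parse time.  Ties in start coordinate
are broken lexicographically by gene id so that ranks are deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .model import (
    BlockPair,
    Gene,
    Genome,
    HomologPair,
    ParseError,
    SyntenyBlock,
    ValidationError,
    dedupe_pairs,
)

PathLike = Union[str, Path]

# Columns of the genome gene-table TSV (the simulator's native emit format).
GENE_TABLE_COLUMNS = [
    "gene_id",
    "chrom",
    "rank",
    "strand",
    "family",
    "dosage_sensitive",
    "color",
    "copy",
    "start",
    "end",
    "birth",
]


def read_gene_positions(path: PathLike, format: str = "gff3", label: Optional[str] = None) -> Genome:
    """Read gene positions into a :class:`Genome` with ranks assigned.

    ``format`` is one of ``gff3``, ``bed`` or ``tsv`` (the package's own
    gene-table dialect).  Genes are sorted by start coordinate within each
    chromosome (ties broken by gene id) and ranked 0..L-1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label = label or path.stem
    if format == "gff3":
        records = _read_gff3(path)
    elif format == "bed":
        records = _read_bed(path)
    elif format == "tsv":
        return read_gene_table(path, label=label)
    else:
        raise ValidationError(f"unknown format {format!r}")

    genome = Genome(label)
    seen: set[str] = set()
    by_chrom: dict[str, list[tuple[int, str, dict]]] = {}
    for rec in records:
        if rec["id"] in seen:
            raise ValidationError(f"duplicate gene id {rec['id']!r} in {path}")
        seen.add(rec["id"])
        by_chrom.setdefault(rec["chrom"], []).append((rec["start"], rec["id"], rec))
    for chrom in by_chrom:
        genes = []
        for _, _, rec in sorted(by_chrom[chrom], key=lambda t: (t[0], t[1])):
            genes.append(
                Gene(
                    id=rec["id"],
                    chrom=chrom,
                    rank=len(genes),
                    strand=rec["strand"],
                    start=rec["start"],
                    end=rec["end"],
                )
            )
        genome.add_chromosome(chrom, genes)
    genome.validate()
    return genome


def _read_gff3(path: Path) -> list[dict]:
    """Parse gene features from a GFF3 file (1-based inclusive coordinates)."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
            from_string=False,
        )
    except Exception as exc:  # gffutils raises assorted errors for bad input
        raise ParseError(f"malformed GFF3 {path}: {exc}") from exc
    records = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        records.append(
            {"id": gid, "chrom": feat.seqid, "start": feat.start, "end": feat.end, "strand": strand}
        )
    if not records:
        raise ParseError(f"no gene features found in {path}")
    return records


def _read_bed(path: Path) -> list[dict]:
    """Parse a BED file (0-based half-open); name column is the gene id."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED record needs >=4 columns")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            records.append(
                {"id": fields[3], "chrom": fields[0], "start": start, "end": end, "strand": strand}
            )
    if not records:
        raise ParseError(f"no BED records found in {path}")
    return records


def read_gene_table(path: PathLike, label: Optional[str] = None) -> Genome:
    """Read the package's gene-table TSV (full metadata round-trip format)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "rank", "strand"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: gene table needs columns {sorted(required)}")
    genome = Genome(label or path.stem)
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("rank")
        genes = []
        for _, row in sub.iterrows():
            origin = None
            if "color" in df.columns and pd.notna(row.get("color")):
                origin = (str(row["color"]), str(row.get("copy", "")))
            genes.append(
                Gene(
                    id=str(row["gene_id"]),
                    chrom=str(chrom),
                    rank=int(row["rank"]),
                    strand=str(row["strand"]),
                    family=str(row["family"]) if pd.notna(row.get("family")) else None,
                    dosage_sensitive=bool(row.get("dosage_sensitive", False)),
                    origin=origin,
                    start=int(row["start"]) if pd.notna(row.get("start")) else None,
                    end=int(row["end"]) if pd.notna(row.get("end")) else None,
                    birth=float(row["birth"]) if pd.notna(row.get("birth")) else None,
                )
            )
        genome.add_chromosome(str(chrom), genes)
    genome.validate()
    return genome


def write_gene_table(genome: Genome, path: PathLike) -> None:
    rows = []
    for g in genome.genes():
        rows.append(
            {
                "gene_id": g.id,
                "chrom": g.chrom,
                "rank": g.rank,
                "strand": g.strand,
                "family": g.family,
                "dosage_sensitive": g.dosage_sensitive,
                "color": g.color,
                "copy": g.copy_label,
                "start": g.start,
                "end": g.end,
                "birth": g.birth,
            }
        )
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_gff3(genome: Genome, path: PathLike) -> None:
    """Emit genes as GFF3 features (1-based inclusive, synthetic coordinates
    from ranks when base-pair positions are absent)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, genes in genome.chromosomes.items():
            for g in genes:
                start = g.start if g.start is not None else g.rank * 1000 + 1
                end = g.end if g.end is not None else start + 500
                fh.write(
                    f"{cid}\twgdkit\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.id}\n"
                )


def read_homolog_table(
    path: PathLike,
    genomes: Optional[Iterable[Genome]] = None,
    kind: Optional[str] = None,
) -> list[HomologPair]:
    """Read a homolog-pair TSV with columns ``gene_a``, ``gene_b``, optional
    ``ks`` (and optional ``kind``).  Pairs are deduplicated as unordered.

    When ``genomes`` are supplied, every gene id must occur in one of them.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise ParseError(f"{path}: homolog table needs columns gene_a, gene_b")
    known: Optional[set[str]] = None
    if genomes is not None:
        known = set()
        for g in genomes:
            known.update(gene.id for gene in g.genes())
    pairs = []
    for i, row in df.iterrows():
        ks = None
        if "ks" in df.columns and pd.notna(row["ks"]):
            ks = float(row["ks"])
        k = kind or (str(row["kind"]) if "kind" in df.columns and pd.notna(row.get("kind")) else "intra")
        if known is not None:
            for gid in (row["gene_a"], row["gene_b"]):
                if gid not in known:
                    raise ValidationError(f"{path}: unknown gene id {gid!r} (row {i})")
        pairs.append(HomologPair(gene_a=row["gene_a"], gene_b=row["gene_b"], ks=ks, kind=k))
    return dedupe_pairs(pairs)


def write_homolog_table(pairs: Iterable[HomologPair], path: PathLike) -> None:
    rows = [
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "ks": p.ks, "kind": p.kind} for p in pairs
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "ks", "kind"]).to_csv(
        path, sep="\t", index=False
    )


def write_blocks(blocks: Iterable[SyntenyBlock], path: PathLike) -> None:
    """Block writer: chrom_a, chrom_b, n_pairs, orientation, median_ks, pair list."""
    rows = []
    for b in blocks:
        rows.append(
            {
                "genome_a": b.genome_a,
                "genome_b": b.genome_b,
                "chrom_a": b.chrom_a,
                "chrom_b": b.chrom_b,
                "n_pairs": b.n_pairs,
                "orientation": b.orientation,
                "median_ks": b.median_ks if b.median_ks_defined else "NA",
                "pairs": ";".join(
                    f"{p.gene_a},{p.gene_b},{p.rank_a},{p.rank_b},{'' if p.ks is None else p.ks}"
                    for p in b.pairs
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "genome_a",
            "genome_b",
            "chrom_a",
            "chrom_b",
            "n_pairs",
            "orientation",
            "median_ks",
            "pairs",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_blocks(path: PathLike) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    blocks = []
    for _, row in df.iterrows():
        pairs = []
        for entry in str(row["pairs"]).split(";"):
            ga, gb, ra, rb, ks = entry.split(",")
            pairs.append(
                BlockPair(ga, gb, int(ra), int(rb), float(ks) if ks else None)
            )
        mk = row["median_ks"]
        defined = mk != "NA" and pd.notna(mk)
        blocks.append(
            SyntenyBlock(
                genome_a=row["genome_a"],
                genome_b=row["genome_b"],
                chrom_a=row["chrom_a"],
                chrom_b=row["chrom_b"],
                pairs=pairs,
                orientation=row["orientation"],
                median_ks=float(mk) if defined else None,
                median_ks_defined=bool(defined),
            )
        )
    return blocks


def read_annotations(path: PathLike) -> dict[str, set[str]]:
    """Read a flat gene->term annotation TSV (columns gene_id, term_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise ParseError(f"{path}: annotation table needs columns gene_id, term_id")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["gene_id"], set()).add(row["term_id"])
    return out


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
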