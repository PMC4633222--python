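"""Genome sequences, annotations and interval queries.

Internal coordinates are 0-based, half-open (BED convention). Printed DMR
tables from array platforms use 1-based inclusive coordinates; the
``table-1-based`` dialect converts on ingestion and :func:`interval_to_table`
converts back, so a round trip reproduces the printed columns exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

VALID_ALPHABET = set("ACGTN")
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "low-complexity", "simple")

#: Sentinel for "no island on this chromosome" — deliberately not 0.
UNDEFINED_DISTANCE = None


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bases; 0 when the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("gap_to requires intervals on the same chromosome")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    #: Length of the island's own genomic extent, in bases.
    island_length: int = -1

    def __post_init__(self) -> None:
        if self.island_length == -1:
            object.__setattr__(self, "island_length", len(self.interval))
        if self.island_length != len(self.interval):
            raise ValueError("island_length must equal end - start of the island")


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, transcription start site and exons.

    ``tss`` is the strand-appropriate terminus of the gene span: the leftmost
    base for + genes, the base before ``end`` for - genes.
    """

    gene_id: str
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id!r}: exons overlap")
        object.__setattr__(self, "exons", exons)
        expected = exons[0].start if self.strand == "+" else exons[-1].end - 1
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id!r}: tss {self.tss} does not match the "
                f"strand-appropriate gene terminus {expected}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    repeat_class: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(
                f"repeat_class {self.repeat_class!r} not in {REPEAT_CLASSES}"
            )


@dataclass
class AnnotationSet:
    """CpG islands, genes and repeats with per-chromosome interval indexes."""

    islands: list[CpGIsland] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatElement] = field(default_factory=list)
    _island_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _repeat_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _gene_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.reindex()

    def reindex(self) -> None:
        self._island_trees = {}
        self._repeat_trees = {}
        self._gene_trees = {}
        for isl in self.islands:
            iv = isl.interval
            self._island_trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, isl
            )
        for rep in self.repeats:
            iv = rep.interval
            self._repeat_trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, rep
            )
        for gene in self.genes:
            sp = gene.span
            self._gene_trees.setdefault(sp.chrom, IntervalTree()).addi(
                sp.start, sp.end, gene
            )

    def islands_on(self, chrom: str) -> list[CpGIsland]:
        return [isl for isl in self.islands if isl.interval.chrom == chrom]

    def overlapping_islands(self, query: GenomicInterval) -> list[CpGIsland]:
        tree = self._island_trees.get(query.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(query.start, query.end)]

    def overlapping_repeats(self, query: GenomicInterval) -> list[RepeatElement]:
        tree = self._repeat_trees.get(query.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(query.start, query.end)]

    def overlapping_genes(self, query: GenomicInterval) -> list[GeneModel]:
        tree = self._gene_trees.get(query.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(query.start, query.end)]

    def validate_against_genome(self, genome: Mapping[str, SequenceRecord]) -> None:
        intervals: list[GenomicInterval] = [i.interval for i in self.islands]
        intervals += [r.interval for r in self.repeats]
        intervals += [g.span for g in self.genes]
        for iv in intervals:
            if iv.chrom not in genome:
                raise ValueError(f"annotation chromosome {iv.chrom!r} not in genome")
            if iv.end > len(genome[iv.chrom]):
                raise ValueError(
                    f"annotation {iv.chrom}:{iv.start}-{iv.end} exceeds sequence length"
                )


def nearest_island_distance(
    query: GenomicInterval,
    annotations: AnnotationSet,
    *,
    use_midpoint: bool = False,
) -> int | None:
    """Distance in bases from ``query`` to the nearest CpG island.

    Returns 0 when the query overlaps an island, the minimal edge-to-edge gap
    otherwise, and ``None`` (undefined) when the chromosome carries no island.
    With ``use_midpoint`` the query is collapsed to its midpoint first.
    """
    islands = annotations.islands_on(query.chrom)
    if not islands:
        return UNDEFINED_DISTANCE
    if use_midpoint:
        mid = query.midpoint
        query = GenomicInterval(query.chrom, mid, mid + 1)
    if annotations.overlapping_islands(query):
        return 0
    return min(query.gap_to(isl.interval) for isl in islands)


# ---------------------------------------------------------------------------
# I/O


def read_genome_fasta(path: str | Path) -> dict[str, SequenceRecord]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = SequenceRecord(rec.id, str(rec.seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_genome_fasta(genome: Mapping[str, SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in genome.values():
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")


def _parse_bed_intervals(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """BED 3+ columns -> (interval, name) pairs; malformed lines are rejected
    with their line number."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def read_islands_bed(path: str | Path) -> list[CpGIsland]:
    return [CpGIsland(iv) for iv, _name in _parse_bed_intervals(path)]


def read_repeats_bed(path: str | Path) -> list[RepeatElement]:
    """BED with the repeat class in column 4."""
    repeats = []
    for iv, name in _parse_bed_intervals(path):
        repeats.append(RepeatElement(iv, name))
    return repeats


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/exon features from GFF3 via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons = tuple(
            GenomicInterval(ex.seqid, ex.start - 1, ex.end, gene.strand)
            for ex in db.children(gene, featuretype="exon", order_by="start")
        )
        if not exons:
            exons = (GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand),)
        tss = exons[0].start if gene.strand == "+" else exons[-1].end - 1
        genes.append(GeneModel(gene.id, gene.strand, tss, exons))
    return genes


def repair_table_end(start_1based: int, printed_end: int) -> int:
    """Restore an apparently truncated end coordinate (lost leading digits).

    Prepends leading digits taken from the start coordinate until the result
    exceeds the start; used only under an explicit repair policy and logged.
    """
    start_str = str(start_1based)
    end_str = str(printed_end)
    for n_prefix in range(1, len(start_str) - len(end_str) + 1):
        candidate = int(start_str[:n_prefix] + end_str)
        if candidate > start_1based:
            return candidate
    raise ValueError(
        f"cannot repair end {printed_end} against start {start_1based}"
    )


def read_table_intervals(
    path: str | Path, *, repair_coordinates: bool = False
) -> pd.DataFrame:
    """Ingest a 1-based-inclusive DMR table (TSV with header).

    Requires columns ``probe_id, chrom, start, end``; further columns pass
    through. Output ``start``/``end`` are 0-based half-open; the printed
    columns are preserved as ``start_1based``/``end_1based``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"probe_id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    starts, ends = [], []
    for idx, row in df.iterrows():
        start1, end1 = int(row["start"]), int(row["end"])
        if end1 < start1:
            if not repair_coordinates:
                raise ValueError(
                    f"{path}: row {idx} ({row['probe_id']}): end {end1} < start "
                    f"{start1}; enable repair_coordinates to attempt recovery"
                )
            repaired = repair_table_end(start1, end1)
            log.warning(
                "repaired end coordinate of %s: %d -> %d (start %d)",
                row["probe_id"], end1, repaired, start1,
            )
            end1 = repaired
        starts.append(start1)
        ends.append(end1)
    out = df.copy()
    out["start_1based"] = starts
    out["end_1based"] = ends
    out["start"] = [s - 1 for s in starts]
    out["end"] = ends
    return out


def interval_to_table(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> printed 1-based inclusive columns."""
    return start + 1, end


def read_annotations(
    paths: Mapping[str, str | Path],
    dialect: str = "bed",
    *,
    genome: Mapping[str, SequenceRecord] | None = None,
) -> AnnotationSet:
    """Assemble an :class:`AnnotationSet` from annotation files.

    ``paths`` may provide ``islands`` (BED), ``genes`` (GFF3) and ``repeats``
    (BED). ``dialect`` applies to island/repeat files: ``bed`` (0-based) or
    ``table-1-based`` is handled by :func:`read_table_intervals` separately.
    """
    if dialect not in ("bed", "gff"):
        raise ValueError(f"unsupported dialect {dialect!r} for read_annotations")
    islands = read_islands_bed(paths["islands"]) if "islands" in paths else []
    genes = read_genes_gff3(paths["genes"]) if "genes" in paths else []
    repeats = read_repeats_bed(paths["repeats"]) if "repeats" in paths else []
    ann = AnnotationSet(islands=islands, genes=genes, repeats=repeats)
    if genome is not None:
        ann.validate_against_genome(genome)
    log.info(
        "loaded annotations: %d islands, %d genes, %d repeats",
        len(islands), len(genes), len(repeats),
    )
    return ann


def write_islands_bed(islands: Iterable[CpGIsland], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, isl in enumerate(islands):
            iv = isl.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tisland_{i}\n")


def write_repeats_bed(repeats: Iterable[RepeatElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rep in repeats:
            iv = rep.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rep.repeat_class}\n")
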