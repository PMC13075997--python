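"""Gene annotation and genome sequence data model.

Coordinates are 0-based half-open throughout (BED convention). BED12 is read
and written natively; minimal GTF (gene/exon features, 1-based closed) is
converted on input. A gene is represented by a single transcript model — the
annotation row supplied — so "exon density" always refers to that model's
exon count.

Strand-aware accessors (TSS/TES, transcription-ordered exons) treat the span
start as TSS on ``+`` and the span end as TES; ordinals (first exon, second
exon, ...) follow the direction of transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap rule: >= 1 shared base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene span with its ordered exon blocks (one transcript model).

    Exons are kept in genome-coordinate order (sorted by start); introns are
    the gaps between consecutive exons. A gene is intron-containing iff it
    has >= 2 exons.
    """

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    category: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: at least one exon required")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon chromosome {ex.chrom} != span "
                    f"chromosome {self.span.chrom}"
                )
            if ex.start < self.span.start or ex.end > self.span.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside span"
                )
            if prev_end is not None and ex.start < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon blocks overlap or are unsorted"
                )
            prev_end = ex.end
        if self.exons[0].start != self.span.start or self.exons[-1].end != self.span.end:
            raise AnnotationError(
                f"gene {self.gene_id}: first/last exon must abut the span ends"
            )

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def length(self) -> int:
        return self.span.length

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def intron_containing(self) -> bool:
        return len(self.exons) >= 2

    @property
    def tss(self) -> int:
        """Transcription start site coordinate (strand-aware)."""
        return self.span.start if self.strand != "-" else self.span.end

    @property
    def tes(self) -> int:
        """Transcription end site coordinate (strand-aware)."""
        return self.span.end if self.strand != "-" else self.span.start

    def exons_in_transcription_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand != "-" else list(reversed(self.exons))

    def introns_in_transcription_order(self) -> list[GenomicInterval]:
        intr = introns_of(self)
        return intr if self.strand != "-" else list(reversed(intr))


class GenomeSequence:
    """Per-chromosome sequences over {A, C, G, T, N} with length bookkeeping."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self.lengths = {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_size(self) -> int:
        """Total genome size G in base pairs."""
        return sum(self.lengths.values())

    def fetch(self, interval: GenomicInterval) -> str:
        if interval.chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        L = self.lengths[interval.chrom]
        if interval.start < 0 or interval.end > L:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"outside chromosome bounds [0,{L})"
            )
        return self.sequences[interval.chrom][interval.start : interval.end]

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation I/O


def _parse_bed12_line(line: str, lineno: int) -> GeneModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise AnnotationError(f"line {lineno}: expected 12 BED fields, got {len(fields)}")
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3]
        strand = fields[5] if fields[5] in STRANDS else "."
        block_count = int(fields[9])
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except (ValueError, IndexError) as exc:
        raise AnnotationError(f"line {lineno}: malformed BED12 record: {exc}") from exc
    if len(block_sizes) != block_count or len(block_starts) != block_count:
        raise AnnotationError(f"line {lineno}: block count disagrees with block lists")
    if block_starts != sorted(block_starts):
        raise AnnotationError(f"line {lineno}: blockStarts not sorted")
    exons = []
    for bs, sz in zip(block_starts, block_sizes):
        exons.append(GenomicInterval(chrom, start + bs, start + bs + sz, strand))
    span = GenomicInterval(chrom, start, end, strand)
    category = fields[12] if len(fields) > 12 else ""
    return GeneModel(gene_id=name, span=span, exons=exons, category=category)


def _read_gtf(path) -> list[GeneModel]:
    """Minimal GTF reader: gene and exon features, gene_id attribute."""
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"line {lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            gid = None
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gid = token.split(None, 1)[1].strip().strip('"')
                    break
            if gid is None:
                raise AnnotationError(f"line {lineno}: missing gene_id attribute")
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from exc
            if feature == "gene":
                spans[gid] = iv
                if gid not in order:
                    order.append(gid)
            else:
                exons.setdefault(gid, []).append(iv)
                if gid not in order:
                    order.append(gid)
    genes = []
    for gid in order:
        ex = sorted(exons.get(gid, []), key=lambda e: e.start)
        if not ex:
            raise AnnotationError(f"gene {gid}: no exon features")
        hull = GenomicInterval(ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand)
        declared = spans.get(gid)
        if declared is not None and (declared.start, declared.end) != (hull.start, hull.end):
            logger.warning(
                "gene %s: gene feature span %d-%d differs from exon hull %d-%d; "
                "using the exon hull",
                gid, declared.start, declared.end, hull.start, hull.end,
            )
        genes.append(GeneModel(gene_id=gid, span=hull, exons=ex))
    return genes


def read_annotation(path) -> list[GeneModel]:
    """Read gene models from BED12 or minimal GTF; input order preserved."""
    path = str(path)
    if path.endswith((".gtf", ".gff")):
        return _read_gtf(path)
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_parse_bed12_line(line, lineno))
    return genes


def write_annotation(genes: list[GeneModel], path) -> None:
    """Write gene models as BED12 (category in column 13 when set)."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e.length) for e in g.exons)
            starts = ",".join(str(e.start - g.span.start) for e in g.exons)
            cols = [
                g.span.chrom,
                str(g.span.start),
                str(g.span.end),
                g.gene_id,
                "0",
                g.strand,
                str(g.span.start),
                str(g.span.end),
                "0",
                str(g.n_exons),
                sizes,
                starts,
            ]
            if g.category:
                cols.append(g.category)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# per-gene structural features


def introns_of(gene: GeneModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons, in genome-coordinate order."""
    out = []
    for a, b in zip(gene.exons, gene.exons[1:]):
        if b.start > a.end:
            out.append(GenomicInterval(gene.span.chrom, a.end, b.start, gene.strand))
    return out


def exon_density(gene: GeneModel) -> float:
    """Exons per kilobase of gene span: exon count / (gene length / 1000)."""
    if gene.length <= 0:
        raise ValueError(f"gene {gene.gene_id}: zero-length span")
    return gene.n_exons / (gene.length / 1000.0)


def gc_count(interval: GenomicInterval, seq: GenomeSequence) -> int:
    s = seq.fetch(interval)
    return s.count("G") + s.count("C")


def gc_percent(interval: GenomicInterval, seq: GenomeSequence) -> float:
    """100 x GC bases / interval length. N bases count toward length, not GC."""
    return 100.0 * gc_count(interval, seq) / interval.length


def flanked_region(
    gene: GeneModel, flank: int = 1000, chrom_length: int | None = None
) -> GenomicInterval:
    """Gene span extended by ``flank`` bp both sides, clipped to the chromosome."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = gene.span.start - flank
    end = gene.span.end + flank
    if start < 0:
        logger.debug("gene %s: flank clipped at chromosome start", gene.gene_id)
        start = 0
    if chrom_length is not None and end > chrom_length:
        logger.debug("gene %s: flank clipped at chromosome end", gene.gene_id)
        end = chrom_length
    return GenomicInterval(gene.span.chrom, start, end, gene.strand)
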