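"""Per-gene and per-feature occupancy quantification.

Counting uses the any-overlap rule (a fragment counts toward a region if it
shares at least one base with it, half-open abutment excluded), implemented
with sorted-array bisection so whole-annotation scans stay O(n log n).

RPK follows the study's asymmetric definition: the fragment count is taken
over the gene span extended by a flank (default 1 kb) on both sides, while
the denominator is the gene span length alone, in kilobases. Density is
log2(1 + RPK).

Metagene matrices reproduce deepTools computeMatrix semantics: the bin
statistic is the mean of per-base track values, minus-strand windows are
reversed so the left edge is always upstream in the direction of
transcription, and bins falling off a chromosome end are missing (NaN) and
excluded from column means.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    flanked_region,
    gc_count,
    gc_percent,
    introns_of,
)
from .coverage import CoverageTrack, FragmentSet

logger = logging.getLogger(__name__)

NUCLEOSOME_MIN_FRAGMENT = 150


@dataclass(frozen=True)
class OccupancyRecord:
    gene_id: str
    factor: str
    fragment_count: int
    rpk: float
    density: float


def count_fragments_in(frags: FragmentSet, region: GenomicInterval) -> int:
    """Fragments overlapping ``region`` by >= 1 bp."""
    if region.chrom not in frags.by_chrom:
        return 0
    starts, ends = frags.by_chrom[region.chrom]
    n = len(starts)
    if n == 0:
        return 0
    # starts sorted ascending; count fragments with start >= region.end
    right = n - np.searchsorted(starts, region.end, side="left")
    # fragments with end <= region.start
    left = np.count_nonzero(ends <= region.start)
    return int(n - right - left)


class _SortedEnds:
    """Cache of per-chromosome sorted end arrays for repeated counting."""

    def __init__(self, frags: FragmentSet):
        self.starts = {c: s for c, (s, _) in frags.by_chrom.items()}
        self.ends_sorted = {c: np.sort(e) for c, (_, e) in frags.by_chrom.items()}

    def count(self, region: GenomicInterval) -> int:
        if region.chrom not in self.starts:
            return 0
        starts = self.starts[region.chrom]
        ends = self.ends_sorted[region.chrom]
        n = len(starts)
        right = n - np.searchsorted(starts, region.end, side="left")
        left = np.searchsorted(ends, region.start, side="right")
        return int(n - right - left)


def gene_rpk(
    frags: FragmentSet,
    gene: GeneModel,
    flank: int = 1000,
    chrom_length: int | None = None,
    factor: str = "",
    _counter: "_SortedEnds | None" = None,
) -> OccupancyRecord:
    """Fragments in gene +- flank per kilobase of gene length, plus density."""
    if gene.length <= 0:
        raise ValueError(f"gene {gene.gene_id}: zero-length gene")
    region = flanked_region(gene, flank, chrom_length)
    count = (_counter or _SortedEnds(frags)).count(region)
    rpk = count / (gene.length / 1000.0)
    return OccupancyRecord(
        gene_id=gene.gene_id,
        factor=factor or frags.label,
        fragment_count=count,
        rpk=rpk,
        density=math.log2(1.0 + rpk),
    )


def gene_rpk_table(
    frags: FragmentSet,
    genes: list[GeneModel],
    flank: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
    factor: str = "",
) -> pd.DataFrame:
    counter = _SortedEnds(frags)
    rows = []
    for g in genes:
        L = chrom_lengths.get(g.span.chrom) if chrom_lengths else None
        rec = gene_rpk(frags, g, flank, L, factor=factor, _counter=counter)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows)


def feature_rpk(
    frags: FragmentSet, gene: GeneModel, which: str, ordinal: int
) -> float:
    """Any-overlap fragment count per kilobase of one exon or intron.

    ``ordinal`` is 1-based and follows transcription direction. Sub-gene
    features take no flank.
    """
    if which == "exon":
        feats = gene.exons_in_transcription_order()
    elif which == "intron":
        feats = gene.introns_in_transcription_order()
    else:
        raise ValueError("which must be 'exon' or 'intron'")
    if not 1 <= ordinal <= len(feats):
        raise IndexError(
            f"gene {gene.gene_id}: no {which} #{ordinal} (has {len(feats)})"
        )
    feat = feats[ordinal - 1]
    count = count_fragments_in(frags, feat)
    return count / (feat.length / 1000.0)


def nucleosome_occupancy(
    frags: FragmentSet,
    region: GenomicInterval,
    seq: GenomeSequence | None = None,
    per: str = "kb",
    min_fragment_length: int = NUCLEOSOME_MIN_FRAGMENT,
) -> float:
    """Nucleosome-sized (>= 150 bp) fragment density.

    per='kb': count / (region length / 1000); per='kGC': count / (GC bases
    in region / 1000), the GC-normalized occupancy.
    """
    nuc = frags.filter_min_length(min_fragment_length)
    count = count_fragments_in(nuc, region)
    if per == "kb":
        return count / (region.length / 1000.0)
    if per == "kGC":
        if seq is None:
            raise ValueError("per='kGC' requires a genome sequence")
        gc = gc_count(region, seq)
        if gc == 0:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} has zero GC "
                "bases; per-kGC occupancy undefined"
            )
        return count / (gc / 1000.0)
    raise ValueError("per must be 'kb' or 'kGC'")


def eclip_fold_change(ip_count: int, input_count: int) -> float:
    """IP fragments / input fragments on a feature."""
    if input_count <= 0:
        raise ValueError("input fragment count must be > 0")
    return ip_count / input_count


def log_expression(fpkm: float) -> float:
    """Expression score log2(1 + FPKM)."""
    if fpkm < 0:
        raise ValueError("FPKM must be >= 0")
    return math.log2(1.0 + fpkm)


# ---------------------------------------------------------------------------
# metagene matrices


@dataclass
class MetageneMatrix:
    """Genes x bins signal matrix; NaN marks off-chromosome bins."""

    values: np.ndarray
    gene_ids: list[str]
    anchor: str  # "TSS", "TES" or "scale-regions"
    bin_size: int
    upstream: int
    downstream: int
    body_bins: int = 0
    dropped_genes: list[str] | None = None

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def _bin_means(track_values: np.ndarray, start: int, end: int, bin_size: int) -> np.ndarray:
    """Mean per-base value in consecutive bins of [start, end); NaN off-chromosome."""
    L = len(track_values)
    n_bins = (end - start) // bin_size
    out = np.full(n_bins, np.nan)
    for j in range(n_bins):
        s = start + j * bin_size
        e = s + bin_size
        cs, ce = max(s, 0), min(e, L)
        if ce <= cs:
            continue
        if cs != s or ce != e:
            out[j] = np.nan  # partially off-chromosome: mark missing
        else:
            out[j] = track_values[cs:ce].mean()
    return out


def metagene_reference_point(
    track: CoverageTrack,
    genes: list[GeneModel],
    anchor: str = "TSS",
    upstream: int = 2000,
    downstream: int = 2000,
    bin_size: int = 50,
) -> MetageneMatrix:
    """Signal around TSS or TES, strand-oriented (left = upstream)."""
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    if (upstream + downstream) % bin_size or upstream % bin_size:
        raise ValueError("bin_size must divide upstream and downstream")
    rows, ids = [], []
    for g in genes:
        v = track.values[g.span.chrom]
        point = g.tss if anchor == "TSS" else g.tes
        if g.strand != "-":
            row = _bin_means(v, point - upstream, point + downstream, bin_size)
        else:
            row = _bin_means(v, point - downstream, point + upstream, bin_size)[::-1]
        rows.append(row)
        ids.append(g.gene_id)
    return MetageneMatrix(
        values=np.array(rows) if rows else np.empty((0, (upstream + downstream) // bin_size)),
        gene_ids=ids,
        anchor=anchor,
        bin_size=bin_size,
        upstream=upstream,
        downstream=downstream,
    )


def _body_bin_edges(start: int, end: int, body_bins: int) -> np.ndarray:
    """Partition [start, end) into body_bins near-equal spans; the remainder
    is spread over the leftmost bins."""
    L = end - start
    base, rem = divmod(L, body_bins)
    sizes = np.full(body_bins, base, dtype=np.int64)
    sizes[:rem] += 1
    return start + np.concatenate([[0], np.cumsum(sizes)])


def metagene_scale_regions(
    track: CoverageTrack,
    genes: list[GeneModel],
    upstream: int = 1000,
    downstream: int = 1000,
    body_bins: int = 100,
    bin_size: int = 50,
) -> MetageneMatrix:
    """Length-scaled gene-body signal with fixed-width flanks.

    Genes shorter than ``body_bins`` bp cannot be partitioned into
    per-base-or-larger bins and are dropped (recorded on the matrix and
    logged).
    """
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    if upstream % bin_size or downstream % bin_size:
        raise ValueError("bin_size must divide upstream and downstream")
    rows, ids, dropped = [], [], []
    for g in genes:
        if g.length < body_bins:
            dropped.append(g.gene_id)
            continue
        v = track.values[g.span.chrom]
        edges = _body_bin_edges(g.span.start, g.span.end, body_bins)
        body = np.empty(body_bins)
        for j in range(body_bins):
            body[j] = v[edges[j] : edges[j + 1]].mean()
        left = _bin_means(v, g.span.start - upstream, g.span.start, bin_size)
        right = _bin_means(v, g.span.end, g.span.end + downstream, bin_size)
        row = np.concatenate([left, body, right])
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(g.gene_id)
    if dropped:
        logger.warning(
            "metagene_scale_regions: dropped %d genes shorter than %d bp",
            len(dropped), body_bins,
        )
    width = (upstream + downstream) // bin_size + body_bins
    return MetageneMatrix(
        values=np.array(rows) if rows else np.empty((0, width)),
        gene_ids=ids,
        anchor="scale-regions",
        bin_size=bin_size,
        upstream=upstream,
        downstream=downstream,
        body_bins=body_bins,
        dropped_genes=dropped,
    )


def column_mean_profile(matrix: MetageneMatrix) -> np.ndarray:
    """Per-bin mean over genes ('average plot'), ignoring missing cells."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty metagene matrix")
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        return np.nanmean(matrix.values, axis=0)


def write_metagene(matrix: MetageneMatrix, path) -> None:
    """Gzip TSV with a JSON header line describing anchor and binning."""
    header = {
        "anchor": matrix.anchor,
        "bin_size": matrix.bin_size,
        "upstream": matrix.upstream,
        "downstream": matrix.downstream,
        "body_bins": matrix.body_bins,
        "n_genes": len(matrix.gene_ids),
        "dropped_genes": matrix.dropped_genes or [],
    }
    with gzip.open(path, "wt") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def read_metagene(path) -> MetageneMatrix:
    with gzip.open(path, "rt") as fh:
        header = json.loads(fh.readline().lstrip("#"))
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return MetageneMatrix(
        values=np.array(rows),
        gene_ids=ids,
        anchor=header["anchor"],
        bin_size=header["bin_size"],
        upstream=header["upstream"],
        downstream=header["downstream"],
        body_bins=header["body_bins"],
        dropped_genes=header.get("dropped_genes") or [],
    )


# ---------------------------------------------------------------------------
# per-feature tables


def feature_occupancy_table(
    frags: FragmentSet,
    nucleosome_frags: FragmentSet,
    genes: list[GeneModel],
    seq: GenomeSequence,
    max_ordinal: int = 10,
) -> pd.DataFrame:
    """Per exon/intron metrics for the first ``max_ordinal`` features of each
    gene: factor RPK, %GC, nucleosome occupancy per kb and per kGC."""
    factor_counter = _SortedEnds(frags)
    nuc_counter = _SortedEnds(
        nucleosome_frags.filter_min_length(NUCLEOSOME_MIN_FRAGMENT)
    )
    rows = []
    for g in genes:
        for kind, feats in (
            ("exon", g.exons_in_transcription_order()),
            ("intron", g.introns_in_transcription_order()),
        ):
            for ordinal, feat in enumerate(feats[:max_ordinal], start=1):
                count = factor_counter.count(feat)
                kb = feat.length / 1000.0
                gc = gc_count(feat, seq)
                nuc = nuc_counter.count(feat)
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "feature": kind,
                        "ordinal": ordinal,
                        "length": feat.length,
                        "rpk": count / kb,
                        "gc_percent": gc_percent(feat, seq),
                        "nucleosome_per_kb": nuc / kb,
                        "nucleosome_per_kgc": (nuc / (gc / 1000.0)) if gc else np.nan,
                    }
                )
    return pd.DataFrame(rows)
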