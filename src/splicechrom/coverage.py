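"""Fragment ingestion, per-base coverage, normalization, spike calibration.

Two normalized track flavors are produced from raw per-base fragment
coverage:

* ``coverage_normalized`` — each base holds the fraction of total per-base
  counts at that base, scaled by the genome size G. Uniformly distributed
  coverage therefore maps every base to exactly 1, and the track sums to G.
* ``spike_calibrated`` — raw counts multiplied by 10,000 / (mapped spike-in
  genome fragments), enabling quantitative comparison across conditions.

Tracks are held as per-chromosome float vectors and serialized as bedGraph
(0-based half-open, zero runs omitted, equal-value runs merged) with a
metadata header; bigWig output is available when pyBigWig is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotation import GenomeSequence, GenomicInterval


class TrackError(ValueError):
    pass


@dataclass
class FragmentSet:
    """Mapped paired-end fragments (unstranded intervals) plus spike-in count.

    Fragments are stored column-wise per chromosome as (starts, ends) int
    arrays for fast counting; construction sorts by start.
    """

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]
    label: str = ""
    spike_in_count: int = 0

    def __post_init__(self) -> None:
        if self.spike_in_count < 0:
            raise ValueError("spike_in_count must be >= 0")
        clean = {}
        for chrom, (starts, ends) in self.by_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if starts.shape != ends.shape:
                raise ValueError(f"{chrom}: starts/ends length mismatch")
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: all fragment lengths must be > 0")
            order = np.argsort(starts, kind="stable")
            clean[chrom] = (starts[order], ends[order])
        self.by_chrom = clean

    @classmethod
    def from_intervals(
        cls, fragments: list[GenomicInterval], label: str = "", spike_in_count: int = 0
    ) -> "FragmentSet":
        by: dict[str, tuple[list, list]] = {}
        for f in fragments:
            s, e = by.setdefault(f.chrom, ([], []))
            s.append(f.start)
            e.append(f.end)
        return cls(
            {c: (np.array(s), np.array(e)) for c, (s, e) in by.items()},
            label=label,
            spike_in_count=spike_in_count,
        )

    @classmethod
    def from_bed(cls, path, label: str = "", spike_in_count: int = 0) -> "FragmentSet":
        """Read BED3 fragment intervals (as produced from paired-end mapping)."""
        by: dict[str, tuple[list, list]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise TrackError(f"{path} line {lineno}: expected >=3 BED fields")
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise TrackError(f"{path} line {lineno}: {exc}") from exc
                s, e = by.setdefault(chrom, ([], []))
                s.append(start)
                e.append(end)
        return cls(
            {c: (np.array(s), np.array(e)) for c, (s, e) in by.items()},
            label=label,
            spike_in_count=spike_in_count,
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.by_chrom:
                starts, ends = self.by_chrom[chrom]
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    @property
    def n_fragments(self) -> int:
        return sum(len(s) for s, _ in self.by_chrom.values())

    def lengths(self) -> np.ndarray:
        if not self.by_chrom:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([e - s for s, e in self.by_chrom.values()])

    def filter_min_length(self, min_length: int) -> "FragmentSet":
        """Subset to fragments of at least ``min_length`` bp (nucleosome-sized
        fragments for min_length=150)."""
        by = {}
        for chrom, (s, e) in self.by_chrom.items():
            keep = (e - s) >= min_length
            by[chrom] = (s[keep], e[keep])
        return FragmentSet(by, label=self.label, spike_in_count=self.spike_in_count)


MODES = ("raw", "coverage_normalized", "spike_calibrated")


@dataclass
class CoverageTrack:
    """Per-base values per chromosome with a recorded normalization mode."""

    values: dict[str, np.ndarray]
    mode: str = "raw"
    genome_size: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.values = {c: np.asarray(v, dtype=np.float64) for c, v in self.values.items()}
        if not self.genome_size:
            self.genome_size = int(sum(len(v) for v in self.values.values()))

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos])


def coverage_from_fragments(frags: FragmentSet, genome: GenomeSequence) -> CoverageTrack:
    """Raw per-base coverage: value at base b = number of fragments covering b."""
    values = {}
    for chrom, L in genome.lengths.items():
        diff = np.zeros(L + 1, dtype=np.float64)
        if chrom in frags.by_chrom:
            starts, ends = frags.by_chrom[chrom]
            if len(starts) and (starts.min() < 0 or ends.max() > L):
                bad = np.flatnonzero((starts < 0) | (ends > L))
                s, e = starts[bad[0]], ends[bad[0]]
                raise TrackError(
                    f"fragment {chrom}:{s}-{e} extends beyond chromosome "
                    f"bounds [0,{L})"
                )
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
        values[chrom] = np.cumsum(diff[:-1])
    unknown = set(frags.by_chrom) - set(genome.lengths)
    if unknown:
        raise TrackError(f"fragments on chromosomes absent from genome: {sorted(unknown)}")
    return CoverageTrack(values, mode="raw", genome_size=genome.total_size)


def normalize_coverage(track: CoverageTrack) -> CoverageTrack:
    """Fraction-of-counts normalization scaled by genome size.

    value_b = (count_b / T) * G with T the genome-wide sum of per-base
    counts; uniform coverage yields exactly 1 at every base and the
    normalized track sums to G.
    """
    if track.mode != "raw":
        raise TrackError(f"can only normalize a raw track, got mode {track.mode!r}")
    T = track.total()
    if T <= 0:
        raise TrackError("empty track cannot be coverage-normalized (total = 0)")
    G = track.genome_size
    values = {c: v * (G / T) for c, v in track.values.items()}
    return CoverageTrack(values, mode="coverage_normalized", genome_size=G)


def spike_scale_factor(spike_in_count: int) -> float:
    """Spike-in calibration factor: 10,000 / mapped spike-genome fragments."""
    if spike_in_count <= 0:
        raise TrackError("spike-in calibration impossible with zero mapped spike fragments")
    return 10000.0 / spike_in_count


def calibrate_track(track: CoverageTrack, factor: float) -> CoverageTrack:
    """Multiply raw per-base counts by a spike-in scale factor."""
    if factor <= 0:
        raise TrackError("scale factor must be > 0")
    if track.mode != "raw":
        raise TrackError("spike calibration applies to raw counts")
    values = {c: v * factor for c, v in track.values.items()}
    return CoverageTrack(values, mode="spike_calibrated", genome_size=track.genome_size)


# ---------------------------------------------------------------------------
# track I/O


def _runs(v: np.ndarray):
    """Yield (start, end, value) runs of equal value, skipping zero runs."""
    if len(v) == 0:
        return
    change = np.flatnonzero(np.diff(v)) + 1
    bounds = np.concatenate([[0], change, [len(v)]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        val = v[s]
        if val != 0:
            yield int(s), int(e), float(val)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """bedGraph with a JSON metadata header (mode, chromosome sizes).

    Values are rounded to float32 precision; zero-valued runs are omitted
    and equal-value runs merged.
    """
    meta = {
        "mode": track.mode,
        "genome_size": track.genome_size,
        "chrom_sizes": {c: len(v) for c, v in track.values.items()},
    }
    with open(path, "w") as fh:
        fh.write(f"#splicechrom {json.dumps(meta)}\n")
        fh.write("track type=bedGraph\n")
        for chrom, v in track.values.items():
            v32 = v.astype(np.float32).astype(np.float64)
            for s, e, val in _runs(v32):
                fh.write(f"{chrom}\t{s}\t{e}\t{val:.8g}\n")


def read_bedgraph(path) -> CoverageTrack:
    meta = None
    values: dict[str, np.ndarray] = {}
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#splicechrom"):
                meta = json.loads(line.split(None, 1)[1])
                for chrom, L in meta["chrom_sizes"].items():
                    values[chrom] = np.zeros(L, dtype=np.float64)
                    last[chrom] = -1
                continue
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, val = line.split("\t")
            s, e = int(s), int(e)
            if meta is None:
                raise TrackError(f"{path}: missing metadata header line")
            if chrom not in values:
                raise TrackError(f"{path} line {lineno}: unknown chromosome {chrom}")
            if s < last[chrom]:
                raise TrackError(f"{path} line {lineno}: bedGraph not sorted")
            last[chrom] = s
            values[chrom][s:e] = float(val)
    if meta is None:
        raise TrackError(f"{path}: missing metadata header line")
    return CoverageTrack(values, mode=meta["mode"], genome_size=meta["genome_size"])


def write_bigwig(track: CoverageTrack, path) -> None:
    """Optional bigWig output (requires pyBigWig)."""
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    header = [(c, len(v)) for c, v in track.values.items()]
    bw.addHeader(header)
    for chrom, v in track.values.items():
        starts, ends, vals = [], [], []
        for s, e, val in _runs(v.astype(np.float32).astype(np.float64)):
            starts.append(s)
            ends.append(e)
            vals.append(val)
        if starts:
            bw.addEntries([chrom] * len(starts), starts, ends=ends, values=vals)
    bw.close()


def read_sample_sheet(path):
    """Sample-sheet TSV: sample, fragments_path, spike_in_count."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"sample", "fragments_path", "spike_in_count"}
    missing = required - set(df.columns)
    if missing:
        raise TrackError(f"sample sheet {path}: missing columns {sorted(missing)}")
    return df
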