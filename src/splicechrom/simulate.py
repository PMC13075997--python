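"""Synthetic genomes, fragment sets, and PSI tables with planted structure.

The generator emulates the study conditions every pipeline stage is tested
against, without any downloads:

* gene models with ~145-bp exons (truncated normal), longer log-normal
  introns, and an exon-dense planted-high class whose gene lengths stay
  comparable to the other classes;
* per-base sequence with feature-specific GC probability (exons GC-richer
  than introns);
* factor fragment counts negative-binomially dispersed around per-class
  RPK rates, with exon positions oversampled by a configurable enrichment
  fold and a genome-wide background;
* spike-in fragment counts per sample;
* rMATS-style PSI event tables whose p-values come from an explicit
  two-proportion z-test on binomially simulated inclusion/exclusion reads,
  so significance is internally consistent with the planted ΔPSI;
* a second "cell line" PSI table with configurable error concordance.

Every generator draws from ``numpy.random.default_rng([seed, stream])``
with a fixed stream id per product, so a fixed seed yields byte-identical
bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GeneModel, GenomeSequence, GenomicInterval, write_annotation
from .coverage import FragmentSet

logger = logging.getLogger(__name__)

GENE_CLASSES = ("U2AF2_high_active", "U2AF2_low_active", "inactive")


@dataclass
class SimulationConfig:
    """All generator knobs with the default study-scale values."""

    seed: int = 0
    n_genes: int = 400
    genome_size: int = 5_000_000
    chrom_name: str = "chrSim1"

    # planted class structure
    class_proportions: dict = field(
        default_factory=lambda: {
            "U2AF2_high_active": 0.15,
            "U2AF2_low_active": 0.35,
            "inactive": 0.50,
        }
    )
    intronless_fraction: float = 0.06

    # gene architecture
    exon_length_mean: float = 145.0
    exon_length_sd: float = 20.0
    exon_length_min: int = 50
    extra_exons_poisson: dict = field(
        default_factory=lambda: {
            "U2AF2_high_active": 8.0,
            "U2AF2_low_active": 4.0,
            "inactive": 4.0,
        }
    )
    intron_length_logmean: dict = field(
        default_factory=lambda: {
            "U2AF2_high_active": 6.3,  # ~545 bp: exon-dense genes, shorter introns
            "U2AF2_low_active": 7.0,  # ~1100 bp
            "inactive": 7.0,
        }
    )
    intron_length_logsd: float = 0.5
    intron_length_min: int = 80
    intronless_length_logmean: float = 7.1
    intronless_length_logsd: float = 0.4
    min_intergenic_gap: int = 1500
    mean_extra_gap: float = 1500.0

    # sequence composition
    gc_prob_exon: float = 0.55
    gc_prob_intron: float = 0.40
    gc_prob_intergenic: float = 0.40

    # fragment generation (RPK units: fragments per gene kilobase, per replicate)
    u2af2_rpk: dict = field(
        default_factory=lambda: {
            "U2AF2_high_active": 32.0,
            "U2AF2_low_active": 4.0,
            "inactive": 0.4,
        }
    )
    rnapii_rpk: dict = field(
        default_factory=lambda: {
            "U2AF2_high_active": 60.0,
            "U2AF2_low_active": 60.0,
            "inactive": 1.0,
        }
    )
    mnase_rpk: float = 8.0
    exon_enrichment_fold: dict = field(
        default_factory=lambda: {"U2AF2": 3.0, "RNAPIIS2P": 1.0, "MNase": 1.5}
    )
    nucleosomal_fraction: dict = field(
        default_factory=lambda: {"U2AF2": 0.5, "RNAPIIS2P": 0.5, "MNase": 0.85}
    )
    background_per_kb: float = 0.2
    nb_dispersion: float = 0.1  # var = mu + dispersion * mu^2
    n_replicates: int = 3
    flank: int = 1000
    spike_in_mean: int = 10_000

    # RNase condition
    rnase_sensitive_fraction: float = 0.03
    rnase_fold: float = 0.25

    # planted splicing errors (per-class probabilities)
    exon_class_probs: dict = field(
        default_factory=lambda: {
            "U2AF2_high_active": {"skipped": 0.37, "included": 0.10, "MXE": 0.07},
            "U2AF2_low_active": {"skipped": 0.17, "included": 0.07, "MXE": 0.06},
        }
    )
    intron_class_probs: dict = field(
        default_factory=lambda: {
            "U2AF2_high_active": {"retained": 0.15, "removed": 0.05},
            "U2AF2_low_active": {"retained": 0.08, "removed": 0.04},
        }
    )
    delta_psi: float = 0.3
    base_psi: float = 0.5
    psi_depth: int = 200
    n_se_events_per_gene: int = 2
    p_ri_event: float = 0.6
    p_splice_site_event: float = 0.5
    p_null_mxe_event: float = 0.3
    concordance_error: float = 0.65
    concordance_no_error: float = 0.66

    # expression
    fpkm_logmean_active: float = 3.0
    fpkm_logmean_inactive: float = -0.7
    fpkm_logsd: float = 1.0

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


# stream ids, one per independent generator product
_S_GENOME, _S_FRAGMENTS, _S_PSI, _S_EXPR, _S_SPIKE = 1, 2, 3, 4, 5


def _truncated_normal(rng, mean, sd, minimum, size) -> np.ndarray:
    out = np.asarray(np.round(rng.normal(mean, sd, size)), dtype=np.int64)
    while np.any(out < minimum):
        redo = out < minimum
        out[redo] = np.round(rng.normal(mean, sd, int(redo.sum())))
    return out


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=np.float64)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _planted_classes(config: SimulationConfig) -> list[str]:
    """Deterministic per-gene class allocation matching the configured
    proportions exactly (largest-remainder rounding)."""
    props = config.class_proportions
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    n = config.n_genes
    raw = {c: props[c] * n for c in GENE_CLASSES}
    counts = {c: int(np.floor(raw[c])) for c in GENE_CLASSES}
    short = n - sum(counts.values())
    for c in sorted(GENE_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    classes = [c for c in GENE_CLASSES for _ in range(counts[c])]
    return classes


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], pd.DataFrame]:
    """Place non-overlapping genes on one synthetic chromosome and draw the
    per-base sequence with feature-specific GC probability.

    Returns the genome, the gene models, and the truth table recording every
    gene's planted class and structural features.
    """
    rng = config.rng(_S_GENOME)
    classes = _planted_classes(config)
    rng.shuffle(classes)
    n_intronless = int(round(config.intronless_fraction * config.n_genes))
    intronless_idx = set(rng.choice(config.n_genes, size=n_intronless, replace=False).tolist())

    genes: list[GeneModel] = []
    truth_rows = []
    feature_runs: list[tuple[int, int, float]] = []  # (start, end, gc_prob)
    cursor = 0
    for i, cls in enumerate(classes):
        gap = config.min_intergenic_gap + int(rng.exponential(config.mean_extra_gap))
        start = cursor + gap
        strand = "+" if rng.random() < 0.5 else "-"
        if i in intronless_idx:
            length = max(
                config.exon_length_min,
                int(rng.lognormal(config.intronless_length_logmean, config.intronless_length_logsd)),
            )
            exon_lengths = [length]
            intron_lengths = []
        else:
            n_exons = 2 + int(rng.poisson(config.extra_exons_poisson[cls]))
            exon_lengths = list(
                _truncated_normal(
                    rng, config.exon_length_mean, config.exon_length_sd,
                    config.exon_length_min, n_exons,
                )
            )
            intron_lengths = [
                max(config.intron_length_min,
                    int(rng.lognormal(config.intron_length_logmean[cls], config.intron_length_logsd)))
                for _ in range(n_exons - 1)
            ]
        exons = []
        pos = start
        for j, el in enumerate(exon_lengths):
            exons.append(GenomicInterval(config.chrom_name, pos, pos + int(el), strand))
            feature_runs.append((pos, pos + int(el), config.gc_prob_exon))
            pos += int(el)
            if j < len(intron_lengths):
                feature_runs.append((pos, pos + intron_lengths[j], config.gc_prob_intron))
                pos += intron_lengths[j]
        end = pos
        if end > config.genome_size:
            raise ValueError(
                f"genes do not fit in genome of size {config.genome_size}; "
                "increase genome_size or reduce n_genes/gene lengths"
            )
        span = GenomicInterval(config.chrom_name, start, end, strand)
        gene = GeneModel(gene_id=f"SIMG{i:04d}", span=span, exons=exons, category=cls)
        genes.append(gene)
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "gene_class": cls,
                "intronless": i in intronless_idx,
                "n_exons": gene.n_exons,
                "length": gene.length,
                "strand": strand,
            }
        )
        cursor = end

    # sequence: per-base GC probability by feature, intergenic elsewhere
    gc_prob = np.full(config.genome_size, config.gc_prob_intergenic)
    for s, e, p in feature_runs:
        gc_prob[s:e] = p
    is_gc = rng.random(config.genome_size) < gc_prob
    half = rng.random(config.genome_size) < 0.5
    bases = np.where(is_gc, np.where(half, ord("G"), ord("C")), np.where(half, ord("A"), ord("T")))
    seq = bases.astype(np.uint8).tobytes().decode("ascii")
    genome = GenomeSequence({config.chrom_name: seq})

    truth = pd.DataFrame(truth_rows)
    truth = _plant_phenotypes(config, truth)
    return genome, genes, truth


def _plant_phenotypes(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Attach planted RNase sensitivity, splice classes, and expression."""
    rng = config.rng(_S_EXPR)
    n = len(truth)
    cls = truth["gene_class"]
    active = cls != "inactive"

    # RNase-sensitive genes: a fixed fraction of all genes, planted among
    # genes that carry U2AF2 signal (active genes)
    n_sens = int(round(config.rnase_sensitive_fraction * n))
    candidates = np.flatnonzero(active.to_numpy())
    sens_idx = rng.choice(candidates, size=min(n_sens, len(candidates)), replace=False)
    sensitive = np.zeros(n, dtype=bool)
    sensitive[sens_idx] = True
    truth["rnase_sensitive"] = sensitive

    # planted splice classes: only intron-containing active genes are tested
    testable = (active & ~truth["intronless"]).to_numpy()
    exon_class = np.where(testable, "unchanged", "untested").astype(object)
    intron_class = np.where(testable, "unchanged", "untested").astype(object)
    for i in np.flatnonzero(testable):
        probs = config.exon_class_probs.get(cls.iloc[i], {})
        u = rng.random()
        acc = 0.0
        for label, p in probs.items():
            acc += p
            if u < acc:
                exon_class[i] = label
                break
        iprobs = config.intron_class_probs.get(cls.iloc[i], {})
        u = rng.random()
        acc = 0.0
        for label, p in iprobs.items():
            acc += p
            if u < acc:
                intron_class[i] = label
                break
    truth["exon_class"] = exon_class
    truth["intron_class"] = intron_class

    logmean = np.where(active, config.fpkm_logmean_active, config.fpkm_logmean_inactive)
    truth["fpkm"] = np.round(rng.lognormal(logmean, config.fpkm_logsd), 4)
    return truth


# ---------------------------------------------------------------------------
# fragments


def _fragment_positions_for_gene(
    rng, gene: GeneModel, count: int, fold: float, flank: int, genome_size: int
):
    """Sample fragment center positions in gene +- flank with exon bases
    oversampled by ``fold``."""
    segs = []
    weights = []
    region_start = max(0, gene.span.start - flank)
    region_end = min(genome_size, gene.span.end + flank)
    prev = region_start
    for ex in gene.exons:
        if ex.start > prev:
            segs.append((prev, ex.start))
            weights.append(float(ex.start - prev))
        segs.append((ex.start, ex.end))
        weights.append(fold * ex.length)
        prev = ex.end
    if region_end > prev:
        segs.append((prev, region_end))
        weights.append(float(region_end - prev))
    w = np.array(weights)
    seg_idx = rng.choice(len(segs), size=count, p=w / w.sum())
    starts = np.array([segs[j][0] for j in seg_idx])
    lens = np.array([segs[j][1] - segs[j][0] for j in seg_idx])
    return starts + (rng.random(count) * lens).astype(np.int64)


def _fragment_lengths(rng, count: int, nucleosomal_fraction: float) -> np.ndarray:
    nuc = rng.random(count) < nucleosomal_fraction
    lens = np.where(
        nuc,
        np.clip(np.round(rng.normal(170, 15, count)), 150, 400),
        np.clip(np.round(rng.normal(105, 20, count)), 40, 149),
    )
    return lens.astype(np.int64)


def simulate_fragments(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: pd.DataFrame,
    factor: str = "U2AF2",
    condition: str = "control",
    n_replicates: int | None = None,
) -> list[FragmentSet]:
    """One FragmentSet per replicate for the given factor and condition.

    Per-gene fragment counts are negative-binomial around the planted class
    rate (times gene length in kb); positions oversample exons by the
    factor's enrichment fold; lengths come from the nucleosomal /
    subnucleosomal mixture; background fragments are scattered genome-wide;
    the spike-in count is attached per replicate.
    """
    if factor not in ("U2AF2", "RNAPIIS2P", "MNase"):
        raise ValueError(f"unknown factor {factor!r}")
    if condition not in ("control", "rnase"):
        raise ValueError(f"unknown condition {condition!r}")
    n_replicates = n_replicates or config.n_replicates
    # independent, deterministic stream per (factor, condition)
    factors = {"U2AF2": 1, "RNAPIIS2P": 2, "MNase": 3}
    conditions = {"control": 1, "rnase": 2}
    stream_key = factors[factor] * 10 + conditions[condition]
    rng = np.random.default_rng([config.seed, _S_FRAGMENTS, stream_key])
    spike_rng = np.random.default_rng([config.seed, _S_SPIKE, stream_key])

    cls_by_gene = truth.set_index("gene_id")["gene_class"]
    sens_by_gene = truth.set_index("gene_id")["rnase_sensitive"]
    fold = config.exon_enrichment_fold[factor]
    nuc_frac = config.nucleosomal_fraction[factor]
    G = config.genome_size
    chrom = config.chrom_name

    out = []
    for rep in range(1, n_replicates + 1):
        centers = []
        lengths = []
        for gene in genes:
            cls = cls_by_gene[gene.gene_id]
            if factor == "U2AF2":
                rate = config.u2af2_rpk[cls]
                if condition == "rnase" and sens_by_gene[gene.gene_id]:
                    rate *= config.rnase_fold
            elif factor == "RNAPIIS2P":
                rate = config.rnapii_rpk[cls]
            else:
                rate = config.mnase_rpk
            mu = rate * gene.length / 1000.0
            count = int(_nb_draw(rng, np.array([mu]), config.nb_dispersion)[0])
            if count == 0:
                continue
            centers.append(
                _fragment_positions_for_gene(rng, gene, count, fold, config.flank, G)
            )
            lengths.append(_fragment_lengths(rng, count, nuc_frac))
        n_bg = int(rng.poisson(config.background_per_kb * G / 1000.0))
        if n_bg:
            centers.append(rng.integers(0, G, n_bg))
            lengths.append(_fragment_lengths(rng, n_bg, nuc_frac))
        c = np.concatenate(centers) if centers else np.empty(0, dtype=np.int64)
        l = np.concatenate(lengths) if lengths else np.empty(0, dtype=np.int64)
        starts = np.clip(c - l // 2, 0, None)
        ends = np.minimum(starts + l, G)
        starts = np.minimum(starts, ends - 1)  # keep length >= 1 at the edge
        spike = int(spike_rng.poisson(config.spike_in_mean))
        out.append(
            FragmentSet(
                {chrom: (starts, ends)},
                label=f"{factor}_{condition}_rep{rep}",
                spike_in_count=spike,
            )
        )
    return out


# ---------------------------------------------------------------------------
# PSI tables


def two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test."""
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def _psi_event(rng, psi_wt: float, psi_kd: float, depth: int):
    """Simulate inclusion reads at the given true PSIs; return observed
    ΔPSI (WT − KD) and the two-proportion p-value."""
    k_wt = int(rng.binomial(depth, psi_wt))
    k_kd = int(rng.binomial(depth, psi_kd))
    delta = k_wt / depth - k_kd / depth
    return round(delta, 4), two_proportion_p(k_wt, depth, k_kd, depth)


def simulate_psi_table(
    config: SimulationConfig,
    truth: pd.DataFrame,
    exon_class_col: str = "exon_class",
    intron_class_col: str = "intron_class",
    stream: int = 0,
) -> pd.DataFrame:
    """rMATS-style event table consistent with the planted gene classes."""
    rng = np.random.default_rng([config.seed, _S_PSI, stream])
    d, depth = config.delta_psi, config.psi_depth
    base = config.base_psi
    rows = []
    for _, row in truth.iterrows():
        if row[exon_class_col] == "untested" and row[intron_class_col] == "untested":
            continue
        gid = row["gene_id"]

        # SE events: one causal if the gene is planted skipped/included
        causal_cls = row[exon_class_col]
        for j in range(config.n_se_events_per_gene):
            if j == 0 and causal_cls == "skipped":
                wt, kd = base + d / 2, base - d / 2
            elif j == 0 and causal_cls == "included":
                wt, kd = base - d / 2, base + d / 2
            else:
                wt = kd = base
            delta, p = _psi_event(rng, wt, kd, depth)
            rows.append({"gene_id": gid, "event_type": "SE", "delta_psi": delta, "p_value": p})

        # MXE: causal when planted, occasional null otherwise
        if causal_cls == "MXE":
            sign = 1 if rng.random() < 0.5 else -1
            delta, p = _psi_event(rng, base + sign * d / 2, base - sign * d / 2, depth)
            rows.append({"gene_id": gid, "event_type": "MXE", "delta_psi": delta, "p_value": p})
        elif rng.random() < config.p_null_mxe_event:
            delta, p = _psi_event(rng, base, base, depth)
            rows.append({"gene_id": gid, "event_type": "MXE", "delta_psi": delta, "p_value": p})

        # RI events (intron inclusion level)
        icls = row[intron_class_col]
        if icls != "untested" and (icls != "unchanged" or rng.random() < config.p_ri_event):
            if icls == "retained":  # intron stays in KD: KD inclusion higher
                wt, kd = base - d / 2, base + d / 2
            elif icls == "removed":
                wt, kd = base + d / 2, base - d / 2
            else:
                wt = kd = base
            delta, p = _psi_event(rng, wt, kd, depth)
            rows.append({"gene_id": gid, "event_type": "RI", "delta_psi": delta, "p_value": p})

        # null splice-site events
        for et in ("A5SS", "A3SS"):
            if rng.random() < config.p_splice_site_event:
                delta, p = _psi_event(rng, base, base, depth)
                rows.append({"gene_id": gid, "event_type": et, "delta_psi": delta, "p_value": p})
    return pd.DataFrame(rows)


def plant_second_cell_line(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Planted classes for a second cell line with configurable concordance.

    Error genes keep their class with probability ``concordance_error``
    (else become unchanged); unchanged genes stay clean with probability
    ``concordance_no_error`` (else acquire an error class).
    """
    rng = np.random.default_rng([config.seed, _S_PSI, 999])
    out = truth.copy()
    new_exon = []
    for cls in truth["exon_class"]:
        if cls == "untested":
            new_exon.append(cls)
        elif cls in ("skipped", "included", "MXE"):
            new_exon.append(cls if rng.random() < config.concordance_error else "unchanged")
        else:
            if rng.random() < config.concordance_no_error:
                new_exon.append("unchanged")
            else:
                new_exon.append(
                    ["skipped", "included", "MXE"][int(rng.choice(3, p=[0.6, 0.2, 0.2]))]
                )
    out["exon_class"] = new_exon
    return out


# ---------------------------------------------------------------------------
# fixture bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(config: SimulationConfig, outdir, force: bool = False) -> dict:
    """Write the full synthetic bundle (FASTA, BED12, fragment BEDs, sample
    sheet with spike counts, PSI TSVs, FPKM TSV, truth TSV, manifest)."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    (outdir / "fragments").mkdir(parents=True, exist_ok=True)

    genome, genes, truth = simulate_genome(config)
    genome.to_fasta(outdir / "genome.fa")
    write_annotation(genes, outdir / "genes.bed12")

    sheet_rows = []
    for factor, condition in (
        ("U2AF2", "control"),
        ("U2AF2", "rnase"),
        ("RNAPIIS2P", "control"),
        ("MNase", "control"),
    ):
        for fs in simulate_fragments(config, genes, truth, factor, condition):
            rel = f"fragments/{fs.label}.bed"
            fs.to_bed(outdir / rel)
            sheet_rows.append(
                {
                    "sample": fs.label,
                    "factor": factor,
                    "condition": condition,
                    "fragments_path": rel,
                    "spike_in_count": fs.spike_in_count,
                }
            )
    pd.DataFrame(sheet_rows).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)

    psi_a = simulate_psi_table(config, truth, stream=0)
    psi_a.to_csv(outdir / "psi_k562.tsv", sep="\t", index=False)
    truth_b = plant_second_cell_line(config, truth)
    psi_b = simulate_psi_table(config, truth_b, stream=1)
    psi_b.to_csv(outdir / "psi_hepg2.tsv", sep="\t", index=False)
    truth["exon_class_hepg2"] = truth_b["exon_class"]

    truth[["gene_id", "fpkm"]].to_csv(outdir / "fpkm.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)

    files = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_hash": config.config_hash(),
        "files": {f: _sha256(outdir / f) for f in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
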