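"""Stage orchestration: simulate -> coverage -> occupancy -> classify ->
splice -> report.

Each stage reads the previous stage's files from the run directory, writes
its own outputs, and appends an entry (with input/output checksums, dropped
gene counts, and warnings) to ``manifest.json``. Stages are deterministic
given the run seed, so re-running a completed stage reproduces identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import classify as cls
from . import coverage as cov
from . import occupancy as occ
from . import simulate as sim
from . import splicing as spl
from .stats import bonferroni, mann_whitney

logger = logging.getLogger(__name__)

STAGES = ("simulate", "coverage", "occupancy", "classify", "splice", "report")


class ValidationError(ValueError):
    """Configuration or input-file validation failure (exit code 1)."""


@dataclass
class RunConfig:
    """Run-level parameters; file paths are relative to the run directory."""

    outdir: str = "run"
    seed: int = 0
    flank: int = 1000
    activity_threshold: float = 4.0
    k: int = 3
    body_bins: int = 100
    bin_size: int = 50
    metagene_flank: int = 1000
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    adjusted_alpha: float = 0.01  # corrected significance threshold for rank-sum reports
    quantiles: int = 4
    deciles: int = 10
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**data)
        config.validate()
        return config

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.flank < 0 or self.metagene_flank < 0:
            raise ValidationError("flanks must be >= 0")
        if self.body_bins < 1 or self.bin_size < 1:
            raise ValidationError("body_bins and bin_size must be >= 1")
        if self.quantiles < 2 or self.deciles < 2:
            raise ValidationError("quantiles and deciles must be >= 2")

    def sim_config(self) -> sim.SimulationConfig:
        return sim.SimulationConfig(seed=self.seed, **self.simulation)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _append_manifest(outdir: Path, stage: str, outputs: list[Path], info: dict | None = None):
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["stages"][stage] = {
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs if p.exists()},
        **(info or {}),
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(outdir: Path, relpath: str, produced_by: str) -> Path:
    p = outdir / relpath
    if not p.exists():
        raise ValidationError(
            f"missing {relpath}: run the '{produced_by}' stage first"
        )
    return p


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    bundle = outdir / "bundle"
    manifest = sim.write_fixture_bundle(config.sim_config(), bundle, force=True)
    _append_manifest(outdir, "simulate", sorted(bundle.rglob("*.tsv")),
                     {"config_hash": manifest["config_hash"]})
    return manifest


def _load_bundle(config: RunConfig):
    outdir = Path(config.outdir)
    bundle = outdir / "bundle"
    genome = ann.GenomeSequence.from_fasta(_require(outdir, "bundle/genome.fa", "simulate"))
    genes = ann.read_annotation(_require(outdir, "bundle/genes.bed12", "simulate"))
    try:
        sheet = cov.read_sample_sheet(_require(outdir, "bundle/sample_sheet.tsv", "simulate"))
    except cov.TrackError as exc:
        raise ValidationError(str(exc)) from exc
    missing = sorted(set(g.span.chrom for g in genes) - set(genome.lengths))
    if missing:
        raise ValidationError(f"annotation chromosomes absent from FASTA: {missing}")
    return bundle, genome, genes, sheet


def _pooled_fragments(bundle: Path, sheet: pd.DataFrame, factor: str, condition: str) -> cov.FragmentSet:
    sel = sheet[(sheet["factor"] == factor) & (sheet["condition"] == condition)]
    if sel.empty:
        raise ValidationError(f"no samples for factor={factor} condition={condition}")
    by: dict[str, list] = {}
    for _, row in sel.iterrows():
        fs = cov.FragmentSet.from_bed(bundle / row["fragments_path"])
        for chrom, (s, e) in fs.by_chrom.items():
            by.setdefault(chrom, []).append((s, e))
    merged = {
        c: (np.concatenate([s for s, _ in parts]), np.concatenate([e for _, e in parts]))
        for c, parts in by.items()
    }
    return cov.FragmentSet(merged, label=f"{factor}_{condition}_pooled",
                           spike_in_count=int(sel["spike_in_count"].sum()))


def stage_coverage(config: RunConfig) -> list[Path]:
    """Per-sample raw + coverage-normalized tracks; spike-calibrated tracks
    for samples with spike-in counts; pooled normalized track per factor."""
    outdir = Path(config.outdir)
    bundle, genome, genes, sheet = _load_bundle(config)
    trackdir = outdir / "tracks"
    trackdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for _, row in sheet.iterrows():
        fs = cov.FragmentSet.from_bed(
            bundle / row["fragments_path"],
            label=row["sample"],
            spike_in_count=int(row["spike_in_count"]),
        )
        raw = cov.coverage_from_fragments(fs, genome)
        norm = cov.normalize_coverage(raw)
        p = trackdir / f"{row['sample']}.norm.bedgraph"
        cov.write_bedgraph(norm, p)
        outputs.append(p)
        if fs.spike_in_count > 0:
            calib = cov.calibrate_track(raw, cov.spike_scale_factor(fs.spike_in_count))
            p = trackdir / f"{row['sample']}.spike.bedgraph"
            cov.write_bedgraph(calib, p)
            outputs.append(p)
    for factor, condition in sheet[["factor", "condition"]].drop_duplicates().itertuples(index=False):
        pooled = _pooled_fragments(bundle, sheet, factor, condition)
        norm = cov.normalize_coverage(cov.coverage_from_fragments(pooled, genome))
        p = trackdir / f"{factor}_{condition}_pooled.norm.bedgraph"
        cov.write_bedgraph(norm, p)
        outputs.append(p)
    _append_manifest(outdir, "coverage", outputs)
    return outputs


def stage_occupancy(config: RunConfig) -> dict:
    """Per-gene occupancy tables (mean per-replicate counts), the U2AF2
    gene-body metagene matrix for clustering, and the exon/intron feature
    table."""
    outdir = Path(config.outdir)
    bundle, genome, genes, sheet = _load_bundle(config)
    occdir = outdir / "occupancy"
    occdir.mkdir(parents=True, exist_ok=True)
    outputs = []

    tables = {}
    for factor, condition in (("U2AF2", "control"), ("RNAPIIS2P", "control"),
                              ("U2AF2", "rnase")):
        sel = sheet[(sheet["factor"] == factor) & (sheet["condition"] == condition)]
        if sel.empty:
            continue
        per_rep = []
        for _, row in sel.iterrows():
            fs = cov.FragmentSet.from_bed(bundle / row["fragments_path"], label=row["sample"])
            per_rep.append(
                occ.gene_rpk_table(fs, genes, flank=config.flank,
                                   chrom_lengths=genome.lengths, factor=factor)
            )
        counts = np.column_stack([t["fragment_count"].to_numpy() for t in per_rep])
        mean_count = counts.mean(axis=1)
        lengths = np.array([g.length for g in genes])
        rpk = mean_count / (lengths / 1000.0)
        table = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "factor": factor,
                "condition": condition,
                "fragment_count_mean": mean_count,
                "rpk": rpk,
                "density": np.log2(1.0 + rpk),
            }
        )
        for i, t in enumerate(per_rep, 1):
            table[f"count_rep{i}"] = t["fragment_count"].to_numpy()
        name = f"{factor}_{condition}"
        tables[name] = table
        p = occdir / f"occupancy_{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        outputs.append(p)

    # metagene matrix of pooled coverage-normalized U2AF2 signal over
    # intron-containing genes (the clustering input)
    pooled = _pooled_fragments(bundle, sheet, "U2AF2", "control")
    norm = cov.normalize_coverage(cov.coverage_from_fragments(pooled, genome))
    intron_genes = [g for g in genes if g.intron_containing]
    matrix = occ.metagene_scale_regions(
        norm, intron_genes,
        upstream=config.metagene_flank, downstream=config.metagene_flank,
        body_bins=config.body_bins, bin_size=config.bin_size,
    )
    p = occdir / "u2af2_metagene.tsv.gz"
    occ.write_metagene(matrix, p)
    outputs.append(p)

    mnase = _pooled_fragments(bundle, sheet, "MNase", "control")
    feat = occ.feature_occupancy_table(
        cov.FragmentSet(pooled.by_chrom, label="U2AF2"), mnase, genes, genome
    )
    p = occdir / "feature_table.tsv"
    feat.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    _append_manifest(
        outdir, "occupancy", outputs,
        {"dropped_genes_metagene": len(matrix.dropped_genes or []),
         "intronless_genes": len(genes) - len(intron_genes)},
    )
    return {"tables": tables, "metagene": matrix, "features": feat}


def stage_classify(config: RunConfig) -> pd.DataFrame:
    outdir = Path(config.outdir)
    occdir = outdir / "occupancy"
    rnapii = pd.read_csv(_require(outdir, "occupancy/occupancy_RNAPIIS2P_control.tsv", "occupancy"), sep="\t")
    u2_control = pd.read_csv(_require(outdir, "occupancy/occupancy_U2AF2_control.tsv", "occupancy"), sep="\t")
    matrix = occ.read_metagene(_require(outdir, "occupancy/u2af2_metagene.tsv.gz", "occupancy"))

    activity = pd.Series(
        cls.classify_activity(rnapii["density"].to_numpy(), config.activity_threshold),
        index=rnapii["gene_id"],
    )

    # log2(1+x) variance-stabilizes the NB-like signal before clustering:
    # on the raw scale the high-occupancy cluster's variance grows with its
    # mean^2 and splitting it can become the k-means optimum
    log_matrix = np.log2(1.0 + np.nan_to_num(matrix.values))
    km = cls.kmeans(log_matrix, k=config.k, seed=config.seed)
    high_low = cls.assign_high_low(km.labels, log_matrix)
    occupancy = pd.Series(high_low, index=pd.Index(matrix.gene_ids, name="gene_id"))

    rep_cols = [c for c in u2_control.columns if c.startswith("count_rep")]
    rnase_df = None
    rnase_path = occdir / "occupancy_U2AF2_rnase.tsv"
    if rnase_path.exists() and len(rep_cols) >= 2:
        u2_rnase = pd.read_csv(rnase_path, sep="\t")
        diff = cls.differential_enrichment(
            u2_control[rep_cols].to_numpy(),
            u2_rnase[rep_cols].to_numpy(),
            gene_ids=u2_control["gene_id"],
            lfc_threshold=config.lfc_threshold,
            alpha=config.alpha,
        )
        rnase_df = diff.set_index("gene_id")["rnase_label"]

    quart = cls.quantile_split(rnapii["rpk"].to_numpy(), config.quantiles)
    table = pd.DataFrame({"gene_id": rnapii["gene_id"]})
    table["activity"] = activity.reindex(table["gene_id"]).to_numpy()
    table["occupancy"] = occupancy.reindex(table["gene_id"]).fillna("not_tested").to_numpy()
    table["rnase"] = (
        rnase_df.reindex(table["gene_id"]).fillna("not_tested").to_numpy()
        if rnase_df is not None else "not_tested"
    )
    table["rnapii_quartile"] = quart
    # joint class used throughout reporting
    table["gene_class"] = np.where(
        table["activity"] == "inactive",
        "inactive",
        np.where(table["occupancy"] == "U2AF2_high", "U2AF2_high_active", "U2AF2_low_active"),
    )

    classdir = outdir / "classify"
    classdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    p = classdir / "gene_classes.tsv"
    table.to_csv(p, sep="\t", index=False)
    outputs.append(p)
    if rnase_df is not None:
        diffp = classdir / "differential.tsv"
        diff.to_csv(diffp, sep="\t", index=False)
        outputs.append(diffp)
    _append_manifest(outdir, "classify", outputs,
                     {"n_genes": len(table),
                      "n_clustered": len(matrix.gene_ids),
                      "kmeans_iterations": km.n_iter})
    return table


def stage_splice(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    bundle = outdir / "bundle"
    events_a = spl.read_psi_table(_require(outdir, "bundle/psi_k562.tsv", "simulate"))
    classes_a = spl.classify_genes(events_a, alpha=config.alpha)
    summary = spl.summarize(classes_a, events_a, alpha=config.alpha)
    result = {"summary": summary}

    hepg2 = bundle / "psi_hepg2.tsv"
    if hepg2.exists():
        events_b = spl.read_psi_table(hepg2)
        classes_b = spl.classify_genes(events_b, alpha=config.alpha)
        result["concordance"] = spl.concordance(classes_a, classes_b)

    splicedir = outdir / "splice"
    splicedir.mkdir(parents=True, exist_ok=True)
    outputs = []
    p = splicedir / "splice_classes.tsv"
    classes_a.to_csv(p, sep="\t", index=False)
    outputs.append(p)
    if hepg2.exists():
        p2 = splicedir / "splice_classes_hepg2.tsv"
        classes_b.to_csv(p2, sep="\t", index=False)
        outputs.append(p2)
    p3 = splicedir / "summary.json"
    p3.write_text(json.dumps(result, indent=2, sort_keys=True))
    outputs.append(p3)
    _append_manifest(outdir, "splice", outputs, {"n_tested": summary["total_tested"]})
    return result


def stage_report(config: RunConfig) -> dict:
    """Consolidated report: class counts, per-class splice-error rates,
    decile table, concordance, exon/intron occupancy comparison, and (when
    the bundle carries a truth table) planted-recovery metrics."""
    outdir = Path(config.outdir)
    classes = pd.read_csv(_require(outdir, "classify/gene_classes.tsv", "classify"), sep="\t")
    splice = pd.read_csv(_require(outdir, "splice/splice_classes.tsv", "splice"), sep="\t")
    summary = json.loads((outdir / "splice" / "summary.json").read_text())
    feat = pd.read_csv(_require(outdir, "occupancy/feature_table.tsv", "occupancy"), sep="\t")
    fpkm = pd.read_csv(_require(outdir, "bundle/fpkm.tsv", "simulate"), sep="\t")

    report: dict = {"seed": config.seed}
    class_counts = classes["gene_class"].value_counts().to_dict()
    n = len(classes)
    report["gene_classes"] = {
        "counts": class_counts,
        "proportions": {k: round(v / n, 4) for k, v in class_counts.items()},
    }

    # splice-error percentage within each occupancy class (tested genes only)
    merged = splice.merge(classes, on="gene_id")
    tested = merged[merged["exon_class"] != "untested"]
    per_class = {}
    for gcls, sub in tested.groupby("gene_class"):
        err = int(sub["exon_class"].isin(spl.ERROR_EXON_CLASSES).sum())
        per_class[gcls] = {
            "tested": len(sub),
            "error_genes": err,
            "error_percent": spl.percent(err, len(sub)) if len(sub) else None,
            "skipped_percent": spl.percent(int((sub["exon_class"] == "skipped").sum()), len(sub)),
        }
    report["errors_by_class"] = per_class
    report["splice_summary"] = summary["summary"]
    if "concordance" in summary:
        report["concordance"] = summary["concordance"]

    # exon vs intron factor occupancy (rank-sum, Bonferroni over the panel)
    exon_rpk = feat.loc[feat["feature"] == "exon", "rpk"].to_numpy()
    intron_rpk = feat.loc[feat["feature"] == "intron", "rpk"].to_numpy()
    comparisons = {}
    if len(exon_rpk) and len(intron_rpk):
        tests = {
            "u2af2_exon_vs_intron_rpk": mann_whitney(exon_rpk, intron_rpk),
            "nucleosome_exon_vs_intron_per_kb": mann_whitney(
                feat.loc[feat["feature"] == "exon", "nucleosome_per_kb"],
                feat.loc[feat["feature"] == "intron", "nucleosome_per_kb"],
            ),
        }
        adj = bonferroni([t.pvalue for t in tests.values()])
        for (name, t), padj in zip(tests.items(), adj):
            comparisons[name] = {
                "U": t.statistic, "p": t.pvalue, "p_bonferroni": float(padj),
                "significant": bool(padj < config.adjusted_alpha),
                "median_exon": float(np.median(exon_rpk)) if name.startswith("u2af2") else None,
                "median_intron": float(np.median(intron_rpk)) if name.startswith("u2af2") else None,
            }
    report["feature_comparisons"] = comparisons

    active_occ = classes.loc[classes["activity"] == "active", ["gene_id", "occupancy"]]
    try:
        deciles = spl.decile_report(splice, fpkm, active_occ, q=config.deciles)
        report["decile_table"] = json.loads(deciles.to_json(orient="records"))
    except ValueError as exc:
        logger.warning("decile report skipped: %s", exc)

    truth_path = outdir / "bundle" / "truth.tsv"
    if truth_path.exists():
        report["planted_recovery"] = planted_recovery_metrics(
            pd.read_csv(truth_path, sep="\t"), classes, splice,
            pd.read_csv(outdir / "classify" / "differential.tsv", sep="\t")
            if (outdir / "classify" / "differential.tsv").exists() else None,
        )

    reportdir = outdir / "report"
    reportdir.mkdir(parents=True, exist_ok=True)
    p = reportdir / "report.json"
    p.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    tested.to_csv(reportdir / "gene_table.tsv", sep="\t", index=False)
    _append_manifest(outdir, "report", [p, reportdir / "gene_table.tsv"])
    return report


def planted_recovery_metrics(
    truth: pd.DataFrame,
    classes: pd.DataFrame,
    splice: pd.DataFrame,
    differential: pd.DataFrame | None,
) -> dict:
    """Compare recovered labels against the truth table."""
    m = truth.merge(classes, on="gene_id", suffixes=("_true", ""))
    out: dict = {}

    intron_containing = m[~m["intronless"]]
    recovered = intron_containing["gene_class"].value_counts(normalize=True)
    planted = intron_containing["gene_class_true"].value_counts(normalize=True)
    out["class_proportions"] = {
        c: {"planted": round(float(planted.get(c, 0.0)), 4),
            "recovered": round(float(recovered.get(c, 0.0)), 4)}
        for c in sim.GENE_CLASSES
    }
    out["max_class_proportion_error"] = round(
        max(abs(float(planted.get(c, 0)) - float(recovered.get(c, 0))) for c in sim.GENE_CLASSES), 4
    )

    if differential is not None:
        d = truth.merge(differential, on="gene_id")
        flagged = d["rnase_label"] == "rnase_sensitive"
        sens = d["rnase_sensitive"].astype(bool)
        out["rnase"] = {
            "planted": int(sens.sum()),
            "flagged": int(flagged.sum()),
            "sensitivity": round(float((flagged & sens).sum() / sens.sum()), 4) if sens.any() else None,
            "false_positive_rate": round(float((flagged & ~sens).sum() / (~sens).sum()), 4),
        }

    s = truth.merge(splice, on="gene_id", suffixes=("_true", ""))
    tested = s[(s["exon_class_true"] != "untested") & (s["exon_class"] != "untested")]
    if len(tested):
        out["exon_class_accuracy"] = round(
            float((tested["exon_class"] == tested["exon_class_true"]).mean()), 4
        )

    sk = splice.merge(classes, on="gene_id")
    sk = sk[(sk["exon_class"] != "untested") & (sk["activity"] == "active")]
    pct = {}
    for label, sub in sk.groupby("occupancy"):
        if len(sub):
            pct[label] = round(float((sub["exon_class"] == "skipped").mean()) * 100, 2)
    out["percent_skipped_by_occupancy"] = pct
    return out


def run_stage(name: str, config: RunConfig):
    if name not in STAGES:
        raise ValidationError(f"unknown stage {name!r}; expected one of {STAGES}")
    fn = {
        "simulate": stage_simulate,
        "coverage": stage_coverage,
        "occupancy": stage_occupancy,
        "classify": stage_classify,
        "splice": stage_splice,
        "report": stage_report,
    }[name]
    logger.info("stage=%s outdir=%s seed=%d", name, config.outdir, config.seed)
    return fn(config)


def run_all(config: RunConfig) -> dict:
    for name in STAGES:
        result = run_stage(name, config)
    return result
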