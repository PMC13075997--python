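"""PSI-based splicing-error classification.

Consumes rMATS-style event tables (gene, event type, IncLevelDifference,
PValue). ΔPSI is oriented WT − KD throughout: a positive ΔPSI on a
skipped-exon (SE) event means the exon's inclusion is higher in wild type,
i.e. the exon is skipped after knockdown.

Event-level error types: SE and MXE are exon-inclusion errors, RI is an
intron-removal error, A5SS/A3SS are splice-site errors. Gene-level exon
classes use significant events only, with precedence skipped > included >
MXE when a gene carries several significant event types; a gene with no
exon-type events at all is ``untested`` and excluded from denominators.
A5SS/A3SS never affect gene classes — they count only in the event-level
breakdown.

Percentages are reported as integers rounded to nearest, half away from
zero.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .classify import quantile_split
from .stats import bonferroni, mann_whitney

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "MXE", "RI", "A5SS", "A3SS")
EXON_EVENT_TYPES = ("SE", "MXE")

EXON_CLASSES = ("unchanged", "skipped", "included", "MXE", "untested")
INTRON_CLASSES = ("unchanged", "retained", "removed", "untested")
ERROR_EXON_CLASSES = ("skipped", "included", "MXE")


class SpliceTableError(ValueError):
    pass


def round_half_up(x: float) -> int:
    """Nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(count: int, total: int) -> int:
    if total <= 0:
        raise ValueError("total must be > 0")
    return round_half_up(100.0 * count / total)


# ---------------------------------------------------------------------------
# table ingestion


REQUIRED_COLUMNS = ("gene_id", "event_type", "delta_psi", "p_value")


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SpliceTableError(f"missing columns: {sorted(missing)}")
    bad = set(df["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise SpliceTableError(f"unknown event types: {sorted(bad)}")
    if df["delta_psi"].abs().max() > 1 + 1e-9:
        raise SpliceTableError("delta_psi must lie in [-1, 1]")
    if df["p_value"].min() < 0 or df["p_value"].max() > 1:
        raise SpliceTableError("p_value must lie in [0, 1]")
    return df


def read_psi_table(path, orientation: str = "wt_minus_kd") -> pd.DataFrame:
    """Read a TSV with columns gene_id, event_type, delta_psi (or
    IncLevelDifference), p_value (or PValue).

    ``orientation`` declares the sign convention of the input table;
    ``kd_minus_wt`` tables are flipped to the internal WT − KD orientation.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(
        columns={"IncLevelDifference": "delta_psi", "PValue": "p_value", "GeneID": "gene_id"}
    )
    if orientation == "kd_minus_wt":
        df["delta_psi"] = -df["delta_psi"]
    elif orientation != "wt_minus_kd":
        raise ValueError("orientation must be 'wt_minus_kd' or 'kd_minus_wt'")
    return validate_events(df)


def convert_rmats(path, event_type: str, p_column: str = "PValue") -> pd.DataFrame:
    """Convert one raw rMATS ``*.MATS.JC.txt`` table (column layout by name)
    to the standard schema."""
    if event_type not in EVENT_TYPES:
        raise SpliceTableError(f"unknown event type {event_type!r}")
    raw = pd.read_csv(path, sep="\t")
    for col in ("GeneID", "IncLevelDifference", p_column):
        if col not in raw.columns:
            raise SpliceTableError(f"{path}: missing rMATS column {col!r}")
    out = pd.DataFrame(
        {
            "gene_id": raw["GeneID"].str.strip('"'),
            "event_type": event_type,
            "delta_psi": raw["IncLevelDifference"],
            "p_value": raw[p_column],
        }
    ).dropna(subset=["delta_psi", "p_value"])
    return validate_events(out)


# ---------------------------------------------------------------------------
# event- and gene-level classification


def is_significant(p_value: float, alpha: float = 0.05) -> bool:
    """Strict threshold: p < alpha."""
    return p_value < alpha


def error_type(event_type: str) -> str:
    if event_type in ("SE", "MXE"):
        return "exon_inclusion"
    if event_type == "RI":
        return "intron_removal"
    if event_type in ("A5SS", "A3SS"):
        return "splice_site"
    raise SpliceTableError(f"unknown event type {event_type!r}")


def classify_gene_exon(
    events: pd.DataFrame,
    alpha: float = 0.05,
    precedence: tuple[str, ...] = ("skipped", "included", "MXE"),
) -> str:
    """Exon class for one gene's events.

    Among significant events: any SE with ΔPSI > 0 → skipped; any SE with
    ΔPSI < 0 → included; any MXE → MXE (default precedence, configurable);
    otherwise unchanged. No exon-type events at all → untested.
    """
    exon_events = events[events["event_type"].isin(EXON_EVENT_TYPES)]
    if exon_events.empty:
        return "untested"
    sig = exon_events[exon_events["p_value"] < alpha]
    found = {
        "skipped": bool(
            ((sig["event_type"] == "SE") & (sig["delta_psi"] > 0)).any()
        ),
        "included": bool(
            ((sig["event_type"] == "SE") & (sig["delta_psi"] < 0)).any()
        ),
        "MXE": bool((sig["event_type"] == "MXE").any()),
    }
    for cls in precedence:
        if found.get(cls):
            return cls
    return "unchanged"


def classify_gene_intron(events: pd.DataFrame, alpha: float = 0.05) -> str:
    """Intron class for one gene's retained-intron events.

    ΔPSI is the WT − KD intron-inclusion level: significantly negative →
    the intron stays in KD transcripts (retained); positive → removed.
    """
    ri = events[events["event_type"] == "RI"]
    if ri.empty:
        return "untested"
    sig = ri[ri["p_value"] < alpha]
    if ((sig["delta_psi"] < 0)).any():
        return "retained"
    if ((sig["delta_psi"] > 0)).any():
        return "removed"
    return "unchanged"


def classify_genes(events: pd.DataFrame, alpha: float = 0.05,
                   precedence: tuple[str, ...] = ("skipped", "included", "MXE")) -> pd.DataFrame:
    """Per-gene exon and intron classes over an event table."""
    validate_events(events)
    rows = []
    for gid, sub in events.groupby("gene_id", sort=False):
        rows.append(
            {
                "gene_id": gid,
                "exon_class": classify_gene_exon(sub, alpha, precedence),
                "intron_class": classify_gene_intron(sub, alpha),
            }
        )
    return pd.DataFrame(rows)


def summarize(classes: pd.DataFrame, events: pd.DataFrame | None = None,
              alpha: float = 0.05) -> dict:
    """Class counts and integer percentages over tested genes, plus (when the
    event table is given) the error-type breakdown over significant events."""
    if classes.empty:
        raise ValueError("empty class table")
    tested = classes[classes["exon_class"] != "untested"]
    total = len(tested)
    if total == 0:
        raise ValueError("no tested genes")
    counts = {c: int((tested["exon_class"] == c).sum()) for c in EXON_CLASSES if c != "untested"}
    error_count = sum(counts[c] for c in ERROR_EXON_CLASSES)
    out = {
        "total_tested": total,
        "counts": counts,
        "percents": {c: percent(n, total) for c, n in counts.items()},
        "error_genes": error_count,
        "error_percent": percent(error_count, total),
    }
    if events is not None:
        sig = events[events["p_value"] < alpha]
        breakdown = {}
        for et in ("exon_inclusion", "intron_removal", "splice_site"):
            breakdown[et] = int(sum(error_type(t) == et for t in sig["event_type"]))
        n_sig = sum(breakdown.values())
        out["significant_events"] = n_sig
        out["event_breakdown"] = breakdown
        if n_sig:
            out["event_breakdown_percent"] = {
                et: percent(n, n_sig) for et, n in breakdown.items()
            }
    return out


def concordance(classes_a: pd.DataFrame, classes_b: pd.DataFrame) -> dict:
    """Agreement of error status across two tables over shared tested genes.

    Returns percentages of A-error genes also erroring in B and of
    A-no-error genes also clean in B, with the underlying counts.
    """
    a = classes_a[classes_a["exon_class"] != "untested"].set_index("gene_id")
    b = classes_b[classes_b["exon_class"] != "untested"].set_index("gene_id")
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("no shared tested genes between the two tables")
    a_err = a.loc[shared, "exon_class"].isin(ERROR_EXON_CLASSES)
    b_err = b.loc[shared, "exon_class"].isin(ERROR_EXON_CLASSES)
    n_err = int(a_err.sum())
    n_no = int((~a_err).sum())
    err_conc = int((a_err & b_err).sum())
    no_conc = int((~a_err & ~b_err).sum())
    return {
        "shared_genes": int(len(shared)),
        "error_to_error": {"count": err_conc, "of": n_err,
                           "percent": percent(err_conc, n_err) if n_err else None},
        "no_error_to_no_error": {"count": no_conc, "of": n_no,
                                 "percent": percent(no_conc, n_no) if n_no else None},
    }


def decile_report(
    classes: pd.DataFrame,
    fpkm: pd.DataFrame,
    occupancy_labels: pd.DataFrame,
    q: int = 10,
) -> pd.DataFrame:
    """Percent-skipped and median expression per FPKM decile and occupancy
    class, with rank-sum comparisons of expression Bonferroni-corrected over
    deciles.

    ``fpkm``: columns gene_id, fpkm. ``occupancy_labels``: columns gene_id,
    occupancy.
    """
    merged = (
        classes.merge(fpkm, on="gene_id").merge(occupancy_labels, on="gene_id")
    )
    merged = merged[merged["exon_class"] != "untested"].reset_index(drop=True)
    if merged.empty:
        raise ValueError("no overlap between class, FPKM, and occupancy tables")
    merged["decile"] = quantile_split(merged["fpkm"].to_numpy(), q)
    merged["log_expr"] = np.log2(1.0 + merged["fpkm"])
    rows = []
    raw_ps: list[float] = []
    for d in range(q):
        sub = merged[merged["decile"] == d]
        row: dict = {"decile": d + 1, "n_genes": len(sub)}
        groups = {}
        for label, g in sub.groupby("occupancy"):
            groups[label] = g
            tag = label.lower()
            row[f"n_{tag}"] = len(g)
            row[f"pct_skipped_{tag}"] = (
                percent(int((g["exon_class"] == "skipped").sum()), len(g))
                if len(g) else None
            )
            row[f"median_log_expr_{tag}"] = float(g["log_expr"].median()) if len(g) else None
        labels = sorted(groups)
        if len(labels) == 2 and all(len(groups[l]) >= 2 for l in labels):
            res = mann_whitney(
                groups[labels[0]]["log_expr"], groups[labels[1]]["log_expr"]
            )
            row["expr_rank_sum_p"] = res.pvalue
            raw_ps.append(res.pvalue)
        else:
            logger.warning("decile %d: fewer than 2 genes in a class; comparison skipped", d + 1)
            row["expr_rank_sum_p"] = np.nan
        rows.append(row)
    report = pd.DataFrame(rows)
    tested = report["expr_rank_sum_p"].notna()
    adj = np.full(len(report), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = bonferroni(
            report.loc[tested, "expr_rank_sum_p"].to_numpy(), m=int(tested.sum())
        )
    report["expr_rank_sum_p_bonferroni"] = adj
    return report
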