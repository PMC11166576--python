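"""Integration detection and detection-conditioned reporter quantification.

A reporter integration is called present in a cell when its oBC reaches the
UMI threshold (default >=12, sitting in the valley between the chimeric low
mode and the bona fide high mode of the bimodal oBC count distribution).
Expression is then quantified from the matched mBC:

    norm_expr = mBC_UMI / GEx_UMI x mean(GEx_UMI)

with a *true zero* recorded when the oBC is detected but no mBC UMI was
captured. mBC UMIs in cells lacking the matched detected oBC are excluded
(chimera suppression) but tallied as spurious detections.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "detect_integrations",
    "estimate_threshold",
    "quantify_reporters",
    "summarize_cre",
    "per_mbc_summary",
    "compare_to_bulk",
    "unconditioned_quantification",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 12


def detect_integrations(obc_counts: pd.DataFrame, threshold: int = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Boolean integration calls per (cell, oBC).

    Returns the count table with a ``detected`` column
    (``umi_count >= threshold``).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out = obc_counts.rename(columns={"barcode": "obc"}).copy()
    if "obc" not in out.columns:
        raise ValueError("obc_counts must have a 'barcode' or 'obc' column")
    if out.empty:
        return pd.DataFrame(columns=["cell_bc", "obc", "umi_count", "detected"])
    out["detected"] = out["umi_count"] >= threshold
    cols = ["cell_bc", "obc", "umi_count", "detected"]
    return out[[c for c in cols if c in out.columns] + [c for c in out.columns if c not in cols]]


def estimate_threshold(
    obc_counts: pd.DataFrame | np.ndarray,
    default: int = DEFAULT_THRESHOLD,
    bins: int = 40,
) -> int:
    """Data-driven detection threshold from the bimodal log10 count histogram.

    Finds the minimum-density valley between the two dominant modes of the
    smoothed log10(UMI count) histogram. Falls back to ``default`` with a
    warning when the distribution looks unimodal.
    """
    counts = (
        obc_counts["umi_count"].to_numpy()
        if isinstance(obc_counts, pd.DataFrame)
        else np.asarray(obc_counts)
    )
    counts = counts[counts > 0]
    if len(counts) < 100:
        raise ValueError("need >= 100 nonzero counts to estimate a threshold")
    logc = np.log10(counts.astype(float))

    def _fallback() -> int:
        warnings.warn(
            "oBC count distribution looks unimodal; falling back to default threshold",
            stacklevel=3,
        )
        return default

    if logc.max() - logc.min() < 0.5:
        return _fallback()
    try:
        # kernel density on log counts; the bandwidth smooths over the
        # integer-count teeth of the chimeric low mode
        kde = sps.gaussian_kde(logc, bw_method=0.25)
    except np.linalg.LinAlgError:
        return _fallback()
    grid = np.linspace(logc.min(), logc.max(), max(bins * 8, 256))
    dens = kde(grid)
    is_peak = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(is_peak) + 1
    peaks = peaks[dens[peaks] >= 0.01 * dens.max()]
    if len(peaks) < 2:
        return _fallback()
    top2 = sorted(sorted(peaks, key=lambda i: -dens[i])[:2])
    lo, hi = top2
    inner = dens[lo : hi + 1]
    if inner.min() > 0.8 * min(dens[lo], dens[hi]):  # no real valley between modes
        return _fallback()
    mins = np.flatnonzero(inner == inner.min())
    valley = lo + int(mins[len(mins) // 2])
    return max(1, int(np.ceil(10 ** grid[valley])))


def quantify_reporters(
    detections: pd.DataFrame,
    mbc_counts: pd.DataFrame,
    triplet_map: pd.DataFrame,
    cell_table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Detection-conditioned expression table with true zeros.

    Parameters
    ----------
    detections : output of :func:`detect_integrations`.
    mbc_counts : (cell_bc, barcode, umi_count) error-corrected mBC counts.
    triplet_map : (obc, mbc, cre_id), unique oBC and mBC keys.
    cell_table : (cell_bc, gex_umis[, cluster]) for every cell in the counts.

    Returns
    -------
    (expression, qc) : expression has one row per detected oBC occurrence with
    ``cell_bc, cre_id, obc, mbc, mbc_umis, norm_expr`` (plus ``cluster`` when
    available); qc tallies valid vs spurious (unmatched-oBC) mBC detections.
    """
    for col, n in (("obc", triplet_map["obc"]), ("mbc", triplet_map["mbc"])):
        if n.duplicated().any():
            raise ValueError(f"triplet map has duplicate {col} keys")
    cells = cell_table.drop_duplicates("cell_bc").set_index("cell_bc")
    mean_gex = float(cells["gex_umis"].mean())

    det = detections[detections["detected"]].merge(triplet_map, on="obc", how="inner")
    count_cells = set(det["cell_bc"]) | set(mbc_counts["cell_bc"])
    missing = count_cells - set(cells.index)
    if missing:
        raise ValueError(
            f"{len(missing)} cell barcodes in count tables missing from cell_table"
        )

    mbc = mbc_counts.rename(columns={"barcode": "mbc", "umi_count": "mbc_umis"})
    expr = det.merge(mbc[["cell_bc", "mbc", "mbc_umis"]], on=["cell_bc", "mbc"], how="left")
    expr["mbc_umis"] = pd.to_numeric(expr["mbc_umis"]).fillna(0).astype(np.int64)
    gex = cells["gex_umis"].reindex(expr["cell_bc"]).to_numpy(float)
    expr["norm_expr"] = expr["mbc_umis"] / gex * mean_gex
    if "cluster" in cells.columns:
        expr["cluster"] = cells["cluster"].reindex(expr["cell_bc"]).to_numpy()

    # spurious mBC detections: mBC UMIs present without the matched detected oBC
    matched = expr.loc[expr["mbc_umis"] > 0, ["cell_bc", "mbc"]]
    valid_keys = set(map(tuple, matched.to_numpy()))
    observed = mbc.merge(triplet_map[["mbc", "cre_id"]], on="mbc", how="inner")
    observed = observed[observed["mbc_umis"] > 0]
    is_valid = [
        (c, m) in valid_keys for c, m in zip(observed["cell_bc"], observed["mbc"])
    ]
    observed = observed.assign(valid=is_valid)
    per_cre = observed.groupby("cre_id")["valid"].agg(["size", "sum"])
    qc = {
        "mean_gex_umis": mean_gex,
        "n_detection_rows": int(len(expr)),
        "n_mbc_detection_events": int(len(observed)),
        "n_spurious_mbc_events": int((~observed["valid"]).sum()),
        "chimeric_detection_rate": (
            float((~observed["valid"]).mean()) if len(observed) else float("nan")
        ),
        "chimeric_detection_rate_per_cre": {
            str(k): float(1.0 - r["sum"] / r["size"]) for k, r in per_cre.iterrows()
        },
    }
    cols = ["cell_bc", "cre_id", "obc", "mbc", "mbc_umis", "norm_expr"]
    if "cluster" in expr.columns:
        cols.append("cluster")
    return expr[cols], qc


def summarize_cre(
    expr: pd.DataFrame,
    min_cells_per_cluster: int = 5,
    denominator: str = "carriers",
) -> pd.DataFrame:
    """Per-CRE activity and specificity from the expression table.

    Activity is the mean normalized expression in the maximum-expression
    eligible cluster (clusters with fewer than ``min_cells_per_cluster``
    detections are ineligible for the max); specificity is that maximum
    divided by the mean over all detection rows outside the winning cluster
    (``denominator="carriers"``) -- reporter-carrying cells only. A
    specificity of ``inf`` marks zero expression outside the max cluster.
    """
    if "cluster" not in expr.columns:
        raise ValueError("expression table must carry cluster labels")
    if denominator not in ("carriers", "all"):
        raise ValueError("denominator must be 'carriers' or 'all'")
    rows = []
    for cre, g in expr.groupby("cre_id"):
        by_cluster = g.groupby("cluster")["norm_expr"].agg(["mean", "size"])
        eligible = by_cluster[by_cluster["size"] >= min_cells_per_cluster]
        if eligible.empty:
            logger.info("CRE %s: no cluster with >= %d detections; omitted", cre, min_cells_per_cluster)
            continue
        best = eligible["mean"].idxmax()
        activity = float(eligible.loc[best, "mean"])
        rest = g.loc[g["cluster"] != best, "norm_expr"]
        rest_mean = float(rest.mean()) if len(rest) else float("nan")
        if rest_mean == 0.0:
            spec = float("inf")
        elif np.isnan(rest_mean):
            spec = float("nan")
        else:
            spec = activity / rest_mean
        rows.append(
            {
                "cre_id": cre,
                "best_cluster": best,
                "activity": activity,
                "all_cells_mean": float(g["norm_expr"].mean()),
                "specificity": spec,
                "n_detections": int(len(g)),
            }
        )
    return pd.DataFrame(rows)


def per_mbc_summary(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-mBC single-cell summary used for the bulk comparison."""
    g = expr.groupby(["mbc", "cre_id"])
    out = g.agg(
        n_cells=("cell_bc", "nunique"),
        total_mbc_umis=("mbc_umis", "sum"),
        mean_norm_expr=("norm_expr", "mean"),
    ).reset_index()
    return out


def compare_to_bulk(
    single_per_mbc: pd.DataFrame,
    bulk_expr: pd.DataFrame,
    min_cells: int = 5,
    min_mbc_umis: int = 1,
    min_dna_umis: int = 100,
) -> dict:
    """Concordance of single-cell vs bulk per-mBC expression.

    Applies the representation filters (>= ``min_cells`` cells with detected
    integrations, >= ``min_mbc_umis`` captured mBC UMI in total, and >=
    ``min_dna_umis`` bulk DNA UMIs) and reports the R^2 of log-transformed
    values. The log pseudocount is half the smallest positive value observed
    in each arm.
    """
    merged = single_per_mbc.merge(bulk_expr, on="mbc", how="inner")
    keep = (
        (merged["n_cells"] >= min_cells)
        & (merged["total_mbc_umis"] >= min_mbc_umis)
        & (merged["dna_umis"] >= min_dna_umis)
    )
    merged = merged[keep]
    if merged.empty:
        raise ValueError("no mBC passes the bulk-comparison filters")

    def _log(v: np.ndarray) -> np.ndarray:
        pos = v[v > 0]
        pc = 0.5 * pos.min() if len(pos) else 1.0
        return np.log10(v + pc)

    x = _log(merged["expression"].to_numpy(float))
    y = _log(merged["mean_norm_expr"].to_numpy(float))
    r = sps.pearsonr(x, y).statistic if len(merged) > 1 else float("nan")
    return {
        "n_mbc": int(len(merged)),
        "r2_log": float(r**2),
        "mbcs": merged["mbc"].tolist(),
        "table": merged,
    }


def unconditioned_quantification(
    mbc_counts: pd.DataFrame, cell_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-mBC mean normalized expression over cells with any captured counts.

    The one-RNA comparison arm: no oBC conditioning, so chimeric mBC molecules
    inflate the mean for lowly expressed reporters.
    """
    if mbc_counts.empty:
        return pd.DataFrame(columns=["mbc", "n_cells", "mean_norm_expr_unconditioned"])
    cells = cell_table.drop_duplicates("cell_bc").set_index("cell_bc")
    mean_gex = float(cells["gex_umis"].mean())
    m = mbc_counts.rename(columns={"barcode": "mbc", "umi_count": "mbc_umis"}).copy()
    m = m[m["mbc_umis"] > 0]
    gex = cells["gex_umis"].reindex(m["cell_bc"]).to_numpy(float)
    m["norm_expr"] = m["mbc_umis"] / gex * mean_gex
    out = (
        m.groupby("mbc")
        .agg(n_cells=("cell_bc", "nunique"), mean_norm_expr_unconditioned=("norm_expr", "mean"))
        .reset_index()
    )
    return out
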