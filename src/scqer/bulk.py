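"""Bulk MPRA quantification: UMI-normalized RNA/DNA barcode expression.

Expression per mBC is the sample-normalized RNA UMI count divided by the
sample-normalized DNA UMI count; mBCs with too few DNA UMIs (default < 100)
are flagged unquantified. CRE-level expression aggregates member mBCs by the
median. A differentiation time course is classified per CRE into
increasing / decreasing / nonmonotonic / flat with Mann-Kendall-style sign
statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from scqer import counts as _counts

__all__ = ["count_bulk", "bulk_expression", "time_series"]


def count_bulk(reads: pd.DataFrame, valid_mbcs) -> pd.DataFrame:
    """Per-mBC error-corrected UMI and read counts from a bulk library.

    ``reads`` carries (mbc, umi, reads); only mBCs present in ``valid_mbcs``
    (the a priori reporter pool) are counted. UMIs are collapsed per mBC with
    the same Hamming-distance-1 connected-components rule as the single-cell
    stage.
    """
    if reads.empty:
        return pd.DataFrame(columns=["mbc", "umi_count", "read_count"])
    valid = set(valid_mbcs)
    r = reads[reads["mbc"].isin(valid)]
    if r.empty:
        return pd.DataFrame(columns=["mbc", "umi_count", "read_count"])
    recs = r.rename(columns={"mbc": "barcode"}).assign(cell_bc="bulk")
    out = _counts.collapse_umis(recs[["cell_bc", "barcode", "umi", "reads"]])
    return out.rename(columns={"barcode": "mbc"})[["mbc", "umi_count", "read_count"]]


def bulk_expression(
    dna_counts: pd.DataFrame,
    rna_counts: pd.DataFrame,
    triplet_map: pd.DataFrame | None = None,
    min_dna: int = 100,
) -> dict:
    """Normalized RNA/DNA expression per mBC (and per CRE when a map is given).

    Each library's UMI counts are normalized to sum to 1 within the sample;
    expression = norm_rna / norm_dna. mBCs with ``dna_umis < min_dna`` are
    flagged ``quantified = False`` (expression NaN). CRE-level expression is
    the median over its quantified mBCs.
    """
    dna = dna_counts.rename(columns={"umi_count": "dna_umis"})[["mbc", "dna_umis"]]
    rna = rna_counts.rename(columns={"umi_count": "rna_umis"})[["mbc", "rna_umis"]]
    tbl = dna.merge(rna, on="mbc", how="outer").fillna(0)
    tbl[["dna_umis", "rna_umis"]] = tbl[["dna_umis", "rna_umis"]].astype(np.int64)
    td, tr = tbl["dna_umis"].sum(), tbl["rna_umis"].sum()
    if td == 0 or tr == 0:
        raise ValueError("zero total UMIs in DNA or RNA library")
    tbl["norm_dna"] = tbl["dna_umis"] / td
    tbl["norm_rna"] = tbl["rna_umis"] / tr
    tbl["quantified"] = tbl["dna_umis"] >= min_dna
    with np.errstate(divide="ignore", invalid="ignore"):
        expr = np.where(tbl["norm_dna"] > 0, tbl["norm_rna"] / tbl["norm_dna"], np.nan)
    tbl["expression"] = np.where(tbl["quantified"], expr, np.nan)

    out = {"per_mbc": tbl}
    if triplet_map is not None:
        m = tbl.merge(triplet_map[["mbc", "cre_id"]].drop_duplicates(), on="mbc", how="inner")
        per_cre = (
            m[m["quantified"]]
            .groupby("cre_id")["expression"]
            .agg(expression="median", n_mbcs="size")
            .reset_index()
        )
        out["per_cre"] = per_cre
    return out


def _mann_kendall(values: np.ndarray) -> tuple[int, float]:
    """Mann-Kendall S statistic and normal-approximation p-value (no-trend null)."""
    n = len(values)
    s = 0
    for i in range(n - 1):
        s += int(np.sign(values[i + 1 :] - values[i]).sum())
    var = n * (n - 1) * (2 * n + 5) / 18.0
    if var == 0:
        return s, 1.0
    z = (s - np.sign(s)) / np.sqrt(var) if s != 0 else 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return s, float(p)


def _classify_trajectory(values: np.ndarray, alpha: float = 0.05, rel_tol: float = 0.05) -> str:
    v = np.asarray(values, dtype=float)
    scale = np.nanmax(np.abs(v)) if np.nanmax(np.abs(v)) > 0 else 1.0
    if np.nanmax(v) - np.nanmin(v) <= rel_tol * scale:
        return "flat"
    s, p = _mann_kendall(v)
    if p < alpha and s > 0:
        return "increasing"
    if p < alpha and s < 0:
        return "decreasing"
    # peak/valley split: strictly monotone rise then fall (or fall then rise)
    for extremum, first, second in ((np.argmax(v), 1, -1), (np.argmin(v), -1, 1)):
        k = int(extremum)
        if 0 < k < len(v) - 1:
            pre = np.sign(np.diff(v[: k + 1]))
            post = np.sign(np.diff(v[k:]))
            if (pre == first).all() and (post == second).all():
                return "nonmonotonic"
    # fall back on the sign of a clear but sub-threshold trend
    if s > 0 and abs(s) == len(v) * (len(v) - 1) / 2:
        return "increasing"
    if s < 0 and abs(s) == len(v) * (len(v) - 1) / 2:
        return "decreasing"
    return "flat"


def time_series(expression_by_day: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Per-CRE expression trajectory across differentiation days.

    ``expression_by_day`` maps day -> per-CRE expression table (the
    ``per_cre`` output of :func:`bulk_expression`). With >= 3 time points each
    CRE is classified as increasing / decreasing / nonmonotonic / flat; with
    fewer, the trajectory is returned unclassified.
    """
    frames = []
    for day, tbl in sorted(expression_by_day.items()):
        frames.append(tbl[["cre_id", "expression"]].assign(day=day))
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot_table(index="cre_id", columns="day", values="expression")
    classify = wide.shape[1] >= 3
    rows = []
    for cre, traj in wide.iterrows():
        v = traj.to_numpy(float)
        row = {"cre_id": cre, **{f"day_{d}": x for d, x in zip(wide.columns, v)}}
        if classify and not np.isnan(v).any():
            row["class"] = _classify_trajectory(v, alpha=alpha)
        else:
            row["class"] = None
        rows.append(row)
    return pd.DataFrame(rows)
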