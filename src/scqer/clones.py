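"""Clonotype inference and clone-based quality metrics.

Cells descended from one transfected clone share the same set of reporter
integrations, so their detected oBC sets are near-identical up to capture
noise. Exploiting this redundancy:

* :func:`infer_clonotypes` links cells whose detected oBC sets have Jaccard
  similarity >= 0.6, takes connected components as clones, builds a
  majority-vote consensus oBC set per clone, and re-assigns every cell to its
  best-matching consensus.
* :func:`precision_recall` treats consensus sets as ground truth and scans a
  UMI-count threshold, yielding dropout (1 - recall) at a target FDR.
* :func:`ztp_mean` inverts the zero-truncated Poisson mean
  m = lambda / (1 - exp(-lambda)) to estimate per-integration capture.
* :func:`clonal_variability` measures per-(clone, reporter) CV across clonal
  replicate cells, against the Poisson counting floor 1/sqrt(mean).
* :func:`positional_variance` splits reporter expression variance into
  between-clone (positional context) and within-clone components.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "infer_clonotypes",
    "precision_recall",
    "ztp_mean",
    "clonal_variability",
    "positional_variance",
]

logger = logging.getLogger(__name__)


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def infer_clonotypes(
    detections: pd.DataFrame,
    min_jaccard: float = 0.6,
    min_clone_size: int = 2,
    min_assignment_score: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Infer consensus integration clonotypes from oBC co-detections.

    Parameters
    ----------
    detections : detection matrix (``cell_bc, obc, detected``).
    min_jaccard : similarity linking two cells into the clone graph.
    min_clone_size : minimum component size to call a clone.
    min_assignment_score : cells whose best consensus Jaccard falls below this
        are flagged unassigned (doublet-like).

    Returns
    -------
    (clonotypes, assignments) : clonotypes has ``clone_id, consensus_obcs
    (frozenset), size``; assignments has one row per cell with
    ``cell_bc, clone_id (-1 if unassigned), score, assigned``.
    """
    det = detections[detections["detected"]]
    if det.empty:
        raise ValueError("empty detection matrix")
    cell_sets = {c: frozenset(g["obc"]) for c, g in det.groupby("cell_bc")}
    cells = sorted(cell_sets)

    # candidate pairs share at least one oBC (inverted index)
    by_obc: dict[str, list[str]] = {}
    for c, s in cell_sets.items():
        for o in s:
            by_obc.setdefault(o, []).append(c)
    graph = nx.Graph()
    graph.add_nodes_from(cells)
    seen: set[tuple[str, str]] = set()
    for members in by_obc.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if (a, b) in seen:
                    continue
                seen.add((a, b))
                if _jaccard(cell_sets[a], cell_sets[b]) >= min_jaccard:
                    graph.add_edge(a, b)

    clone_rows = []
    consensus_list: list[frozenset] = []
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        if len(comp) < min_clone_size:
            continue
        counts: dict[str, int] = {}
        for c in comp:
            for o in cell_sets[c]:
                counts[o] = counts.get(o, 0) + 1
        consensus = frozenset(o for o, k in counts.items() if k > len(comp) / 2)
        if not consensus:
            continue
        clone_rows.append(
            {
                "clone_id": len(clone_rows),
                "consensus_obcs": consensus,
                "size": len(comp),
            }
        )
        consensus_list.append(consensus)

    if not clone_rows:
        raise ValueError("no clones found at the requested size/similarity")

    # re-assign every cell to the best-matching consensus
    assign_rows = []
    for c in cells:
        scores = [_jaccard(cell_sets[c], cons) for cons in consensus_list]
        best = int(np.argmax(scores))
        score = scores[best]
        ok = score >= min_assignment_score
        assign_rows.append(
            {
                "cell_bc": c,
                "clone_id": clone_rows[best]["clone_id"] if ok else -1,
                "score": score,
                "assigned": ok,
            }
        )
    assignments = pd.DataFrame(assign_rows)
    clonotypes = pd.DataFrame(clone_rows)
    sizes = assignments[assignments["assigned"]].groupby("clone_id").size()
    clonotypes["size"] = clonotypes["clone_id"].map(sizes).fillna(0).astype(int)
    return clonotypes, assignments


def precision_recall(
    raw_obc_counts: pd.DataFrame,
    assignments: pd.DataFrame,
    clonotypes: pd.DataFrame,
    thresholds: np.ndarray | None = None,
    min_clone_cells: int = 3,
    target_fdr: float = 0.01,
) -> dict:
    """Precision-recall of oBC retrieval against consensus clonotypes.

    For each threshold t, an oBC is "detected" in a clone-assigned cell when
    its raw UMI count >= t. True positives are detected consensus oBCs;
    false negatives are consensus oBCs below threshold; false positives are
    detected non-consensus oBCs. Tallies are per (cell, oBC) pair aggregated
    over clones with > 2 cells (``min_clone_cells``).

    Returns a dict with the PR curve table and the recall/dropout at the
    highest-recall threshold achieving FDR <= ``target_fdr``.
    """
    if thresholds is None:
        thresholds = np.unique(
            np.concatenate([[1, 2, 3], np.round(np.geomspace(4, 3000, 40)).astype(int)])
        )
    counts = raw_obc_counts.rename(columns={"barcode": "obc"})
    eligible = clonotypes[clonotypes["size"] >= min_clone_cells]
    if eligible.empty:
        raise ValueError(f"no clones with >= {min_clone_cells} cells")
    cons = dict(zip(eligible["clone_id"], eligible["consensus_obcs"]))
    assigned = assignments[
        assignments["assigned"] & assignments["clone_id"].isin(cons)
    ]

    merged = assigned.merge(counts[["cell_bc", "obc", "umi_count"]], on="cell_bc", how="left")
    is_consensus = np.array(
        [o in cons[cl] for o, cl in zip(merged["obc"], merged["clone_id"])]
    )
    umi = merged["umi_count"].to_numpy(float)
    n_consensus_pairs = int(sum(len(cons[cl]) for cl in assigned["clone_id"]))

    rows = []
    for t in thresholds:
        detected = umi >= t
        tp = int((detected & is_consensus).sum())
        fp = int((detected & ~is_consensus).sum())
        fn = n_consensus_pairs - tp
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / (tp + fn) if tp + fn else float("nan")
        rows.append(
            {
                "threshold": int(t),
                "precision": precision,
                "recall": recall,
                "fdr": 1.0 - precision,
                "dropout": 1.0 - recall,
            }
        )
    curve = pd.DataFrame(rows)
    ok = curve[curve["fdr"] <= target_fdr]
    if ok.empty:
        at_fdr = None
    else:
        at_fdr = ok.loc[ok["recall"].idxmax()].to_dict()
    return {
        "curve": curve,
        "at_target_fdr": at_fdr,
        "n_cells": int(assigned["cell_bc"].nunique()),
        "n_clones": int(len(cons)),
        "n_consensus_pairs": n_consensus_pairs,
    }


def ztp_mean(truncated_counts, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Zero-truncated Poisson rate from truncated counts.

    Solves m = lambda / (1 - exp(-lambda)) for lambda by safeguarded Newton
    iteration, where m is the sample mean of the (all >= 1) counts.
    """
    x = np.asarray(truncated_counts, dtype=float)
    if len(x) == 0 or (x < 1).any():
        raise ValueError("all counts must be >= 1")
    m = float(x.mean())
    if m <= 1.0:
        raise ValueError("sample mean must exceed 1 for a zero-truncated Poisson")

    def f(lam: float) -> float:
        return lam / -np.expm1(-lam) - m

    lo, hi = 1e-12, m  # mean of ZTP(lam) is in (1, ...] and <= lam + 1; lam in (0, m]
    lam = m - 1.0 if m > 1.5 else (m - 1.0)
    lam = min(max(lam, lo), hi)
    for _ in range(max_iter):
        e = -np.expm1(-lam)  # 1 - exp(-lam)
        val = lam / e - m
        if abs(val) < tol:
            return float(lam)
        # derivative of lam / (1 - exp(-lam))
        d = (e - lam * np.exp(-lam)) / (e * e)
        step = val / d if d != 0 else 0.0
        new = lam - step
        if val > 0:
            hi = lam
        else:
            lo = lam
        if not (lo < new < hi) or step == 0.0:
            new = 0.5 * (lo + hi)
        lam = new
    return float(lam)


def clonal_variability(
    expression: pd.DataFrame,
    assignments: pd.DataFrame,
    reporter_col: str = "mbc",
    min_cells: int = 2,
) -> pd.DataFrame:
    """Per-(clone, reporter) mean, sd, CV and the Poisson reference 1/sqrt(mean).

    Expression rows are joined to clone assignments; only (clone, reporter)
    groups with >= ``min_cells`` member cells are reported. CV is sd/mean.
    """
    assigned = assignments[assignments["assigned"]][["cell_bc", "clone_id"]]
    merged = expression.merge(assigned, on="cell_bc", how="inner")
    g = merged.groupby(["clone_id", reporter_col])["norm_expr"]
    stats = g.agg(n_cells="size", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    stats = stats[stats["n_cells"] >= min_cells].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        stats["cv"] = np.where(stats["mean"] > 0, stats["sd"] / stats["mean"], np.nan)
        stats["poisson_cv"] = np.where(
            stats["mean"] > 0, 1.0 / np.sqrt(stats["mean"]), np.nan
        )
    return stats.reset_index(drop=True)


def positional_variance(
    expression: pd.DataFrame,
    assignments: pd.DataFrame,
    reporter_col: str = "mbc",
    min_clones: int = 2,
    min_cells_per_clone: int = 2,
) -> pd.DataFrame:
    """Between-clone (positional) vs within-clone variance share per reporter.

    One-way random-effects decomposition by method of moments on the clone
    grouping: sigma2_between = max(0, (MSB - MSW) / n0) with n0 the effective
    per-clone cell count; the reported share is
    sigma2_between / (sigma2_between + MSW). Reporters observed in fewer than
    ``min_clones`` clones with >= ``min_cells_per_clone`` cells are skipped.
    """
    assigned = assignments[assignments["assigned"]][["cell_bc", "clone_id"]]
    merged = expression.merge(assigned, on="cell_bc", how="inner")
    rows = []
    for rep, g in merged.groupby(reporter_col):
        sizes = g.groupby("clone_id").size()
        good = sizes[sizes >= min_cells_per_clone].index
        g = g[g["clone_id"].isin(good)]
        k = g["clone_id"].nunique()
        if k < min_clones:
            logger.info("reporter %s: insufficient clonal replication; skipped", rep)
            continue
        n_i = g.groupby("clone_id").size().to_numpy(float)
        n = n_i.sum()
        grand = g["norm_expr"].mean()
        means = g.groupby("clone_id")["norm_expr"].mean()
        ssb = float((n_i * (means.to_numpy() - grand) ** 2).sum())
        ssw = float(
            ((g["norm_expr"] - g["clone_id"].map(means)) ** 2).sum()
        )
        msb = ssb / (k - 1)
        msw = ssw / (n - k) if n > k else float("nan")
        n0 = (n - (n_i**2).sum() / n) / (k - 1)
        sigma_b2 = max(0.0, (msb - msw) / n0) if np.isfinite(msw) else float("nan")
        total = sigma_b2 + msw
        rows.append(
            {
                reporter_col: rep,
                "n_clones": int(k),
                "n_cells": int(n),
                "between_var": sigma_b2,
                "within_var": msw,
                "between_share": sigma_b2 / total if total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
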