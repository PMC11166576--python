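"""Bootstrap and permutation tests for CRE activity and specificity.

Integration events (one per detected reporter occurrence, true zeros
included) are the resampling unit throughout.

* :func:`bootstrap_activity` -- B bootstrap resamples of the CRE's events and
  of equally sized samples from the pooled basal-promoter events (minimal +
  no promoter). The null is the distribution of basal max-cluster means; the
  empirical p-value is the probability that the CRE's max-cluster bootstrap
  mean falls below the basal one, averaged over all bootstrap pairs with ties
  counted 1/2 (a rank-sum-style comparison). An unstratified all-cells
  version is computed alongside (more power, no cell-type resolution).
* :func:`permutation_specificity` -- the observed statistic is the fold
  change between the maximum-expression cluster and the rest of cells in a
  bootstrap resample; the null applies the same computation after permuting
  cluster labels.
* :func:`pleiotropy_test` -- same machinery on pairs of clusters vs rest,
  flagging CREs active in two cell types.
* :func:`bh_fdr` + :func:`call_cres` -- Benjamini-Hochberg correction per
  replicate and the all-replicates consensus classification into
  inactive / active_nonspecific / cell_type_specific / pleiotropic_specific.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ActivityResult",
    "SpecificityResult",
    "PleiotropyResult",
    "bootstrap_activity",
    "bh_fdr",
    "permutation_specificity",
    "pleiotropy_test",
    "call_cres",
    "run_replicate",
]

logger = logging.getLogger(__name__)

_B_CHUNK = 2048  # bootstrap block size, bounds the B x n_events weight matrix


@dataclass
class ActivityResult:
    cre_id: str
    p_maxcluster: float
    p_allcells: float
    n_events: int
    B: int
    fdr_maxcluster: float = np.nan
    fdr_allcells: float = np.nan


@dataclass
class SpecificityResult:
    cre_id: str
    fold_change: float
    p_perm: float
    best_cluster: object
    n_events: int
    B: int
    fdr_perm: float = np.nan


@dataclass
class PleiotropyResult:
    cre_id: str
    best_pair: tuple
    pair_fold_change: float
    single_fold_change: float
    pair_over_single_ratio: float
    p_perm: float


def _as_events(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    expr = events["norm_expr"].to_numpy(float)
    clus, _ = pd.factorize(events["cluster"], sort=True)
    return expr, clus


def _eligible_clusters(clus: np.ndarray, n_clusters: int, min_events: int) -> np.ndarray:
    counts = np.bincount(clus, minlength=n_clusters)
    elig = counts >= min_events
    if not elig.any():
        elig = counts > 0
    return elig


def _bootstrap_weights(
    rng: np.random.Generator, n_pool: int, n_draw: int, B: int
) -> np.ndarray:
    """B x n_pool multinomial weights == with-replacement bootstrap of size n_draw."""
    return rng.multinomial(n_draw, np.full(n_pool, 1.0 / n_pool), size=B)


def _cluster_max_means(
    W: np.ndarray, expr: np.ndarray, clus: np.ndarray, n_clusters: int, elig: np.ndarray
) -> np.ndarray:
    """Max over eligible clusters of the weighted per-cluster mean, per bootstrap row."""
    onehot = np.zeros((len(expr), n_clusters))
    onehot[np.arange(len(expr)), clus] = 1.0
    sums = W @ (expr[:, None] * onehot)
    cnts = W @ onehot
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / cnts
    means[:, ~elig] = -np.inf
    means[cnts == 0] = -np.inf
    return means.max(axis=1)


def _empirical_p_below(stat: np.ndarray, null: np.ndarray) -> float:
    """Mean over (b, b') of 1[stat_b < null_b'], ties counted 1/2."""
    null_sorted = np.sort(null)
    lo = np.searchsorted(null_sorted, stat, side="left")
    hi = np.searchsorted(null_sorted, stat, side="right")
    n_gt = len(null_sorted) - hi
    n_eq = hi - lo
    return float(np.mean((n_gt + 0.5 * n_eq) / len(null_sorted)))


def _empirical_p_geq(null: np.ndarray, stat: np.ndarray) -> float:
    """Mean over (b, b') of 1[null_b' >= stat_b] (ties favor the null: conservative)."""
    null_sorted = np.sort(null)
    lo = np.searchsorted(null_sorted, stat, side="left")
    return float(np.mean((len(null_sorted) - lo) / len(null_sorted)))


def bootstrap_activity(
    cre_events: pd.DataFrame,
    basal_events: pd.DataFrame,
    B: int = 10000,
    seed: int | np.random.Generator = 0,
    min_cells_per_cluster: int = 5,
    cre_id: str = "",
) -> ActivityResult:
    """Empirical activity p-values for one CRE against the basal-event pool.

    Per bootstrap, the CRE's events and an equally sized with-replacement
    sample from the basal pool are drawn; the statistic is the maximum
    eligible-cluster mean (and, separately, the unstratified mean).
    ``p = P(CRE statistic < basal statistic)`` over all bootstrap pairs with
    ties counted 1/2. CRE and basal draws are independent.
    """
    if basal_events.empty:
        raise ValueError("basal event pool is empty")
    if B < 100:
        warnings.warn("B < 100 gives a very coarse empirical p-value", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    all_clusters = pd.concat([cre_events["cluster"], basal_events["cluster"]]).unique()
    cat = pd.CategoricalDtype(sorted(all_clusters))
    n_clusters = len(cat.categories)
    ce = cre_events["norm_expr"].to_numpy(float)
    cc = cre_events["cluster"].astype(cat).cat.codes.to_numpy()
    be = basal_events["norm_expr"].to_numpy(float)
    bc = basal_events["cluster"].astype(cat).cat.codes.to_numpy()
    n = len(ce)
    if n == 0:
        raise ValueError("CRE has no integration events")

    elig_cre = _eligible_clusters(cc, n_clusters, min_cells_per_cluster)
    elig_bas = _eligible_clusters(bc, n_clusters, min_cells_per_cluster)

    cre_max = np.empty(B)
    bas_max = np.empty(B)
    cre_all = np.empty(B)
    bas_all = np.empty(B)
    done = 0
    while done < B:
        b = min(_B_CHUNK, B - done)
        Wc = _bootstrap_weights(rng, n, n, b)
        Wb = _bootstrap_weights(rng, len(be), n, b)
        cre_max[done : done + b] = _cluster_max_means(Wc, ce, cc, n_clusters, elig_cre)
        bas_max[done : done + b] = _cluster_max_means(Wb, be, bc, n_clusters, elig_bas)
        cre_all[done : done + b] = (Wc @ ce) / n
        bas_all[done : done + b] = (Wb @ be) / n
        done += b

    return ActivityResult(
        cre_id=cre_id,
        p_maxcluster=_empirical_p_below(cre_max, bas_max),
        p_allcells=_empirical_p_below(cre_all, bas_all),
        n_events=n,
        B=B,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fold_changes(
    W: np.ndarray, expr: np.ndarray, clus: np.ndarray, n_clusters: int, elig: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(fold change, best cluster) of max eligible cluster mean vs rest, per row."""
    onehot = np.zeros((len(expr), n_clusters))
    onehot[np.arange(len(expr)), clus] = 1.0
    sums = W @ (expr[:, None] * onehot)
    cnts = W @ onehot
    tot_sum = sums.sum(axis=1, keepdims=True)
    tot_cnt = cnts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / cnts
    means[:, ~elig] = -np.inf
    means[cnts == 0] = -np.inf
    best = means.argmax(axis=1)
    rows = np.arange(len(W))
    best_mean = means[rows, best]
    rest_sum = (tot_sum.ravel() - sums[rows, best])
    rest_cnt = (tot_cnt.ravel() - cnts[rows, best])
    with np.errstate(invalid="ignore", divide="ignore"):
        rest_mean = np.where(rest_cnt > 0, rest_sum / np.maximum(rest_cnt, 1), np.nan)
        fc = np.where(
            rest_mean > 0,
            best_mean / np.where(rest_mean > 0, rest_mean, 1.0),
            np.where(best_mean > 0, np.inf, 1.0),
        )
    return fc, best


def permutation_specificity(
    cre_events: pd.DataFrame,
    B: int = 10000,
    seed: int | np.random.Generator = 0,
    min_cells_per_cluster: int = 5,
    cre_id: str = "",
) -> SpecificityResult:
    """Cluster-permutation test of cell-type specificity for one CRE.

    Per repeat: a bootstrap resample gives the observed fold change
    (max-cluster mean over rest-of-cells mean); permuting the cluster labels
    of an independent resample gives a null fold change. The empirical p-value
    is the probability that a null fold change is >= an observed one, averaged
    over all (observed, null) pairs. The reported fold change is the median
    observed value; a +inf fold change marks zero expression outside the
    winning cluster.
    """
    expr, clus = _as_events(cre_events)
    n_clusters = int(clus.max()) + 1 if len(clus) else 0
    if n_clusters < 2:
        raise ValueError("need >= 2 clusters represented for a specificity test")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(expr)
    elig = _eligible_clusters(clus, n_clusters, min_cells_per_cluster)

    obs = np.empty(B)
    null = np.empty(B)
    best_all = np.empty(B, dtype=int)
    done = 0
    while done < B:
        b = min(_B_CHUNK, B - done)
        W = _bootstrap_weights(rng, n, n, b)
        fc, best = _fold_changes(W, expr, clus, n_clusters, elig)
        obs[done : done + b] = fc
        best_all[done : done + b] = best
        Wp = _bootstrap_weights(rng, n, n, b)
        perm = rng.permuted(np.tile(clus, (b, 1)), axis=1)
        null[done : done + b] = _fold_changes_rowperm(Wp, expr, perm, n_clusters, elig)
        done += b

    p = _empirical_p_geq(null, obs)  # P(null fold change >= observed one)
    fold = float(np.median(obs))
    categories = pd.factorize(cre_events["cluster"], sort=True)[1]
    best_cluster = categories[int(np.bincount(best_all).argmax())]
    return SpecificityResult(
        cre_id=cre_id,
        fold_change=fold,
        p_perm=p,
        best_cluster=best_cluster,
        n_events=n,
        B=B,
    )


def _fold_changes_rowperm(
    W: np.ndarray, expr: np.ndarray, perm: np.ndarray, n_clusters: int, elig: np.ndarray
) -> np.ndarray:
    """Fold changes where each bootstrap row has its own permuted cluster labels."""
    b, n = perm.shape
    sums = np.zeros((b, n_clusters))
    cnts = np.zeros((b, n_clusters))
    wx = W * expr
    for k in range(n_clusters):
        mask = perm == k
        sums[:, k] = (wx * mask).sum(axis=1)
        cnts[:, k] = (W * mask).sum(axis=1)
    tot_sum = sums.sum(axis=1)
    tot_cnt = cnts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / cnts
    means[:, ~elig] = -np.inf
    means[cnts == 0] = -np.inf
    best = means.argmax(axis=1)
    rows = np.arange(b)
    best_mean = means[rows, best]
    rest_sum = tot_sum - sums[rows, best]
    rest_cnt = tot_cnt - cnts[rows, best]
    with np.errstate(invalid="ignore", divide="ignore"):
        rest_mean = np.where(rest_cnt > 0, rest_sum / np.maximum(rest_cnt, 1), np.nan)
        fc = np.where(
            rest_mean > 0,
            best_mean / np.where(rest_mean > 0, rest_mean, 1.0),
            np.where(best_mean > 0, np.inf, 1.0),
        )
    return fc


def pleiotropy_test(
    cre_events: pd.DataFrame,
    B_pairs: int = 10000,
    B_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    min_cells_per_cluster: int = 5,
    cre_id: str = "",
) -> PleiotropyResult:
    """Pair-of-clusters vs rest fold-change test (bifunctional CREs).

    Per bootstrap the maximum fold change over all cluster pairs (pair mean vs
    rest-of-cells mean) is recorded; the pleiotropy ratio compares its median
    to the median single-cluster fold change. The permutation p-value is the
    probability that a label-permuted resample's best pair fold change is >=
    an observed one.
    """
    expr, clus = _as_events(cre_events)
    n_clusters = int(clus.max()) + 1 if len(clus) else 0
    if n_clusters < 3:
        raise ValueError("pleiotropy test needs >= 3 clusters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(expr)
    elig = _eligible_clusters(clus, n_clusters, min_cells_per_cluster)
    pairs = [
        (i, j)
        for i in range(n_clusters)
        for j in range(i + 1, n_clusters)
        if elig[i] or elig[j]
    ]

    def _pair_fc(W: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b = len(W)
        sums = np.zeros((b, n_clusters))
        cnts = np.zeros((b, n_clusters))
        wx = W * expr
        if labels.ndim == 1:
            onehot = np.zeros((n, n_clusters))
            onehot[np.arange(n), labels] = 1.0
            sums = W @ (expr[:, None] * onehot)
            cnts = W @ onehot
        else:
            for k in range(n_clusters):
                mask = labels == k
                sums[:, k] = (wx * mask).sum(axis=1)
                cnts[:, k] = (W * mask).sum(axis=1)
        tot_sum = sums.sum(axis=1)
        tot_cnt = cnts.sum(axis=1)
        best_fc = np.full(b, -np.inf)
        best_pair = np.zeros(b, dtype=int)
        for pi, (i, j) in enumerate(pairs):
            ps = sums[:, i] + sums[:, j]
            pc = cnts[:, i] + cnts[:, j]
            rs = tot_sum - ps
            rc = tot_cnt - pc
            with np.errstate(invalid="ignore", divide="ignore"):
                pm = np.where(pc > 0, ps / np.maximum(pc, 1), -np.inf)
                rm = np.where(rc > 0, rs / np.maximum(rc, 1), np.nan)
                fc = np.where(
                    rm > 0, pm / np.where(rm > 0, rm, 1.0), np.where(pm > 0, np.inf, 1.0)
                )
            upd = fc > best_fc
            best_fc[upd] = fc[upd]
            best_pair[upd] = pi
        return best_fc, best_pair

    obs_pair = np.empty(B_pairs)
    best_pair_idx = np.empty(B_pairs, dtype=int)
    obs_single = np.empty(B_pairs)
    done = 0
    while done < B_pairs:
        b = min(_B_CHUNK, B_pairs - done)
        W = _bootstrap_weights(rng, n, n, b)
        fc, bp = _pair_fc(W, clus)
        obs_pair[done : done + b] = fc
        best_pair_idx[done : done + b] = bp
        obs_single[done : done + b], _ = _fold_changes(W, expr, clus, n_clusters, elig)
        done += b

    null_pair = np.empty(B_perm)
    done = 0
    while done < B_perm:
        b = min(_B_CHUNK, B_perm - done)
        W = _bootstrap_weights(rng, n, n, b)
        perm = rng.permuted(np.tile(clus, (b, 1)), axis=1)
        null_pair[done : done + b], _ = _pair_fc(W, perm)
        done += b

    p = _empirical_p_geq(null_pair, obs_pair)
    med_pair = float(np.median(obs_pair))
    med_single = float(np.median(obs_single))
    ratio = med_pair / med_single if med_single > 0 and np.isfinite(med_single) else np.nan
    if np.isinf(med_pair) and np.isinf(med_single):
        ratio = 1.0
    categories = pd.factorize(cre_events["cluster"], sort=True)[1]
    bi, bj = pairs[int(np.bincount(best_pair_idx).argmax())]
    return PleiotropyResult(
        cre_id=cre_id,
        best_pair=(categories[bi], categories[bj]),
        pair_fold_change=med_pair,
        single_fold_change=med_single,
        pair_over_single_ratio=float(ratio),
        p_perm=p,
    )


def run_replicate(
    expression: pd.DataFrame,
    basal_cres: list[str],
    B: int = 10000,
    B_perm_pleio: int = 1000,
    seed: int | np.random.Generator = 0,
    min_cells_per_cluster: int = 5,
    run_pleiotropy: bool = True,
) -> dict:
    """All per-CRE tests for one biological replicate.

    Returns a dict with ``activity``, ``specificity`` and (optionally)
    ``pleiotropy`` DataFrames. BH correction is applied across CREs within
    the replicate, separately per test family.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    basal = expression[expression["cre_id"].isin(basal_cres)]
    if basal.empty:
        raise ValueError("basal event pool is empty")
    test_cres = sorted(set(expression["cre_id"]) - set(basal_cres))

    n_clusters_total = expression["cluster"].nunique()
    act_rows, spec_rows, pleio_rows = [], [], []
    for cre in test_cres:
        ev = expression[expression["cre_id"] == cre]
        a = bootstrap_activity(
            ev, basal, B=B, seed=rng, min_cells_per_cluster=min_cells_per_cluster, cre_id=cre
        )
        act_rows.append(a)
        if ev["cluster"].nunique() >= 2:
            s = permutation_specificity(
                ev, B=B, seed=rng, min_cells_per_cluster=min_cells_per_cluster, cre_id=cre
            )
            spec_rows.append(s)
        if run_pleiotropy and n_clusters_total >= 3 and ev["cluster"].nunique() >= 3:
            pl = pleiotropy_test(
                ev,
                B_pairs=B,
                B_perm=B_perm_pleio,
                seed=rng,
                min_cells_per_cluster=min_cells_per_cluster,
                cre_id=cre,
            )
            pleio_rows.append(pl)

    activity = pd.DataFrame([vars(a) for a in act_rows])
    if not activity.empty:
        activity["fdr_maxcluster"] = bh_fdr(activity["p_maxcluster"])
        activity["fdr_allcells"] = bh_fdr(activity["p_allcells"])
    specificity = pd.DataFrame([vars(s) for s in spec_rows])
    if not specificity.empty:
        specificity["fdr_perm"] = bh_fdr(specificity["p_perm"])
    out = {"activity": activity, "specificity": specificity}
    if run_pleiotropy:
        out["pleiotropy"] = pd.DataFrame([vars(p) for p in pleio_rows])
    return out


DEFAULT_RULES = {
    "fdr_maxcluster": 0.10,
    "fdr_allcells": 0.01,
    "min_fold_change": 5.0,
    "fdr_perm": 0.10,
    "pleiotropy_ratio": 3.0,
    "pleiotropy_p": 0.001,
}


def call_cres(per_replicate_results: list[dict], rules: dict | None = None) -> pd.DataFrame:
    """Multi-replicate consensus classification of CREs.

    A CRE is *active* when fdr_maxcluster < 10% in every replicate OR
    fdr_allcells < 1% in every replicate; *cell_type_specific* when
    additionally the fold change is > 5 and the permutation FDR < 10% in every
    replicate; *pleiotropic_specific* when the (median across replicates)
    pair/single fold-change ratio also exceeds 3x with permutation support.
    Reported activity/specificity are medians across replicates.
    """
    rules = {**DEFAULT_RULES, **(rules or {})}
    acts = [r["activity"].set_index("cre_id") for r in per_replicate_results]
    specs = [
        r["specificity"].set_index("cre_id")
        for r in per_replicate_results
        if not r["specificity"].empty
    ]
    pleios = [
        r["pleiotropy"].set_index("cre_id")
        for r in per_replicate_results
        if "pleiotropy" in r and not r["pleiotropy"].empty
    ]

    common = set(acts[0].index)
    for a in acts[1:]:
        common &= set(a.index)
    union = set().union(*(set(a.index) for a in acts))
    if common != union:
        warnings.warn(
            "inconsistent CRE sets across replicates; intersecting", stacklevel=2
        )

    rows = []
    for cre in sorted(common):
        act_max = all(a.loc[cre, "fdr_maxcluster"] < rules["fdr_maxcluster"] for a in acts)
        act_all = all(a.loc[cre, "fdr_allcells"] < rules["fdr_allcells"] for a in acts)
        active = act_max or act_all
        in_spec = all(cre in s.index for s in specs) and specs
        specific = False
        fold_median = np.nan
        if in_spec:
            fcs = [s.loc[cre, "fold_change"] for s in specs]
            fdrs = [s.loc[cre, "fdr_perm"] for s in specs]
            fold_median = float(np.median(fcs))
            specific = (
                active
                and all(fc > rules["min_fold_change"] for fc in fcs)
                and all(f < rules["fdr_perm"] for f in fdrs)
            )
        pleio = False
        ratio_median = np.nan
        if specific and pleios and all(cre in p.index for p in pleios):
            ratios = [p.loc[cre, "pair_over_single_ratio"] for p in pleios]
            pps = [p.loc[cre, "p_perm"] for p in pleios]
            ratio_median = float(np.median(ratios))
            pleio = ratio_median > rules["pleiotropy_ratio"] and all(
                pp <= rules["pleiotropy_p"] for pp in pps
            )
        if not active:
            label = "inactive"
        elif pleio:
            label = "pleiotropic_specific"
        elif specific:
            label = "cell_type_specific"
        else:
            label = "active_nonspecific"
        rows.append(
            {
                "cre_id": cre,
                "class": label,
                "active": active,
                "specific": specific or pleio,
                "median_fold_change": fold_median,
                "median_pleiotropy_ratio": ratio_median,
            }
        )
    return pd.DataFrame(rows)
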