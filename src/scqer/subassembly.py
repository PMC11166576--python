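"""Subassembly calling: oBC-mBC pairs, oBC-CRE alignments, triplet map.

The triplet map used to deconvolve single-cell data is assembled a priori
from two sequencing subassemblies: a saturated oBC-mBC pairing library
(valid pairs have > 500 reads, and any barcode appearing in more than one
surviving pair is conflicted and removed) and a tagmentation-based oBC-CRE
alignment library filtered on strand, median mapping position, per-oBC
unique-CRE read fraction, read count and positional dispersal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["call_pairs", "call_obc_cre", "build_triplets"]


def call_pairs(pair_counts: pd.DataFrame, min_reads: int = 500) -> pd.DataFrame:
    """Valid, unique oBC-mBC pairs from a pair-count table.

    ``pair_counts`` carries (obc, mbc, reads). Pairs with reads strictly
    greater than ``min_reads`` are retained; then any oBC or mBC occurring in
    more than one surviving pair is removed with all its pairs.
    """
    surv = pair_counts[pair_counts["reads"] > min_reads].copy()
    dup_obc = surv["obc"].duplicated(keep=False)
    dup_mbc = surv["mbc"].duplicated(keep=False)
    out = surv[~dup_obc & ~dup_mbc].reset_index(drop=True)
    return out[["obc", "mbc", "reads"]]


def call_obc_cre(
    alignments: pd.DataFrame,
    expected_strand: pd.Series | str = "+",
    min_reads: int = 30,
    min_fraction: float = 0.95,
    pos_window: tuple[float, float] = (30.0, 300.0),
    dispersal_window: tuple[float, float] = (30.0, 300.0),
) -> tuple[pd.DataFrame, dict]:
    """Valid oBC-CRE pairs from per-read alignment summaries.

    ``alignments`` carries one row per aligned read (or per collapsed position
    bin with a ``reads`` column): (obc, cre_id, position, strand[, reads]).
    ``expected_strand`` is either a single strand or a per-CRE Series keyed by
    cre_id (construct cloning orientation).

    Filters, applied in order with per-filter drop diagnostics:

    1. strand: reads on the wrong strand removed;
    2. median mapping position inside ``pos_window`` (inclusive);
    3. per-oBC unique-CRE read fraction > ``min_fraction``;
    4. read count > ``min_reads`` (strict);
    5. positional dispersal p90 - p10 inside ``dispersal_window`` (inclusive).

    Returns (pairs, diagnostics): pairs has (obc, cre_id, reads,
    median_position, dispersal); diagnostics partitions dropped pairs by the
    first failing filter.
    """
    aln = alignments.copy()
    if "reads" not in aln.columns:
        aln["reads"] = 1
    if (aln["position"] < 1).any():
        raise ValueError("positions are 1-based and must be >= 1")
    if isinstance(expected_strand, str):
        exp = pd.Series(expected_strand, index=aln["cre_id"].unique())
    else:
        exp = expected_strand

    diag = {"strand": 0, "median_position": 0, "cre_fraction": 0, "read_count": 0, "dispersal": 0}

    def _wq(g: pd.DataFrame, q: float) -> float:
        # read-weighted quantile with linear interpolation
        pos = np.repeat(g["position"].to_numpy(float), g["reads"].to_numpy(int))
        return float(np.percentile(pos, q))

    pairs = []
    all_keys = aln[["obc", "cre_id"]].drop_duplicates()
    # 1. strand filter on reads; pairs losing all reads drop at "strand"
    ok_strand = aln["strand"] == aln["cre_id"].map(exp)
    aln_s = aln[ok_strand]
    kept_keys = aln_s[["obc", "cre_id"]].drop_duplicates()
    diag["strand"] = len(all_keys) - len(kept_keys)

    per_pair = {
        key: g for key, g in aln_s.groupby(["obc", "cre_id"], sort=True)
    }
    # per-oBC read totals (over surviving reads) for the fraction filter
    obc_totals = aln_s.groupby("obc")["reads"].sum()

    for (obc, cre), g in per_pair.items():
        med = _wq(g, 50)
        if not (pos_window[0] <= med <= pos_window[1]):
            diag["median_position"] += 1
            continue
        reads = int(g["reads"].sum())
        frac = reads / float(obc_totals[obc])
        if not frac > min_fraction:
            diag["cre_fraction"] += 1
            continue
        if not reads > min_reads:
            diag["read_count"] += 1
            continue
        disp = _wq(g, 90) - _wq(g, 10)
        if not (dispersal_window[0] <= disp <= dispersal_window[1]):
            diag["dispersal"] += 1
            continue
        pairs.append(
            {
                "obc": obc,
                "cre_id": cre,
                "reads": reads,
                "median_position": med,
                "dispersal": disp,
            }
        )
    out = pd.DataFrame(pairs, columns=["obc", "cre_id", "reads", "median_position", "dispersal"])
    diag["n_input_pairs"] = int(len(all_keys))
    diag["n_retained"] = int(len(out))
    return out, diag


def build_triplets(
    obc_cre_pairs: pd.DataFrame, obc_mbc_pairs: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join the two subassemblies into the final conflict-free triplet map.

    Joins on oBC, then removes every triplet whose oBC or mBC appears in more
    than one joined triplet. Returns (triplets, per_cre_counts).
    """
    joined = obc_cre_pairs[["obc", "cre_id"]].merge(
        obc_mbc_pairs[["obc", "mbc"]], on="obc", how="inner"
    )
    if joined.empty:
        raise ValueError("empty join between oBC-CRE and oBC-mBC pairs")
    dup_obc = joined["obc"].duplicated(keep=False)
    dup_mbc = joined["mbc"].duplicated(keep=False)
    triplets = joined[~dup_obc & ~dup_mbc].reset_index(drop=True)
    triplets = triplets[["obc", "mbc", "cre_id"]]
    per_cre = (
        triplets.groupby("cre_id").size().rename("n_pairs").reset_index()
    )
    return triplets, per_cre
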