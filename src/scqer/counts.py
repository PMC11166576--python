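"""Raw barcode reads -> error-corrected per-(cell, barcode) UMI counts.

Three stages, in the order they are applied to sequencing data:

1. :func:`validate_reads` -- keep only reads whose flanking constant region
   matches exactly (mBC: ``TCGACAA`` at read positions 16-22 after the 15 nt
   barcode; oBC: ``GCTTTAA`` at positions 17-23 after the 16 nt barcode) and
   whose barcode is not the all-G "empty" read.
2. :func:`filter_chimeric_umis` -- within each (cell, UMI), drop target
   barcodes whose read fraction falls strictly below 0.2 (chimeric
   re-amplification products carry few reads relative to the true target).
3. :func:`collapse_umis` -- per (cell, barcode), count connected components
   of the graph linking UMIs at Hamming distance <= 1: the error-corrected
   molecule count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MODES",
    "DropTally",
    "validate_reads",
    "filter_chimeric_umis",
    "collapse_umis",
    "process_reads",
    "hamming1_components",
    "hamming1_components_bruteforce",
]

#: per-mode barcode span (length) and exact-match constant region that follows it
MODES = {
    "mbc": {"barcode_length": 15, "constant": "TCGACAA"},
    "obc": {"barcode_length": 16, "constant": "GCTTTAA"},
}


@dataclass
class DropTally:
    """Per-stage drop accounting, for QC logging."""

    too_short: int = 0
    constant_mismatch: int = 0
    all_g: int = 0
    chimeric_umi: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "too_short": self.too_short,
            "constant_mismatch": self.constant_mismatch,
            "all_g": self.all_g,
            "chimeric_umi": self.chimeric_umi,
        }
        d.update(self.extra)
        return d


def validate_reads(
    records: pd.DataFrame, mode: str, tally: DropTally | None = None
) -> pd.DataFrame:
    """Validate target reads and extract the barcode.

    Parameters
    ----------
    records : DataFrame with columns ``cell_bc, umi, target_read, reads``.
    mode : ``"obc"`` or ``"mbc"``; fixes barcode span and constant region.

    Returns the surviving records with a ``barcode`` column replacing
    ``target_read``. Reads shorter than the required span, with an inexact
    constant region, or with an all-G barcode are dropped (and tallied).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {sorted(MODES)}")
    spec = MODES[mode]
    blen, const = spec["barcode_length"], spec["constant"]
    span = blen + len(const)

    reads = records["target_read"].astype(str)
    long_enough = reads.str.len() >= span
    barcode = reads.str.slice(0, blen)
    const_ok = reads.str.slice(blen, span) == const
    not_all_g = barcode != "G" * blen

    keep = long_enough & const_ok & not_all_g
    if tally is not None:
        tally.too_short += int((~long_enough).sum())
        tally.constant_mismatch += int((long_enough & ~const_ok).sum())
        tally.all_g += int((long_enough & const_ok & ~not_all_g).sum())

    out = records.loc[keep, [c for c in records.columns if c != "target_read"]].copy()
    out["barcode"] = barcode[keep]
    return out.reset_index(drop=True)


def filter_chimeric_umis(
    records: pd.DataFrame, min_fraction: float = 0.2, tally: DropTally | None = None
) -> pd.DataFrame:
    """Drop (cell, UMI, barcode) rows whose read fraction is below ``min_fraction``.

    For each (cell, UMI), the fraction of reads going to each target barcode is
    computed over all targets sharing that (cell, UMI); rows strictly below the
    threshold are removed (ties at exactly ``min_fraction`` are kept).
    """
    if records.empty:
        return records.copy()
    grp = records.groupby(["cell_bc", "umi"])["reads"]
    frac = records["reads"] / grp.transform("sum")
    keep = frac >= min_fraction
    if tally is not None:
        tally.chimeric_umi += int((~keep).sum())
    return records.loc[keep].reset_index(drop=True)


def _mask_keys(umis: np.ndarray, length: int) -> np.ndarray:
    """(n, length) array of masked keys: UMI with position j blanked."""
    mat = umis.astype(f"S{length}").view(np.uint8).reshape(len(umis), length)
    keys = np.empty((len(umis), length), dtype=f"S{length}")
    for j in range(length):
        m = mat.copy()
        m[:, j] = ord("*")
        keys[:, j] = m.view(f"S{length}").ravel()
    return keys


def hamming1_components(umis: np.ndarray) -> int:
    """Connected components of the Hamming-distance-<=1 graph over distinct UMIs.

    Uses a masked-key index (each UMI keyed by its ``length`` single-position
    wildcards) and union-find, avoiding the all-pairs scan. Two distinct UMIs
    share a masked key iff their Hamming distance is exactly 1; an ``N`` never
    matches any base, i.e. counts as a mismatch to everything.
    """
    umis = np.unique(np.asarray(umis, dtype=str))
    n = len(umis)
    if n == 0:
        return 0
    lengths = np.char.str_len(umis)
    if lengths.min() != lengths.max():
        raise ValueError("UMIs of unequal length within a group: Hamming undefined")
    length = int(lengths[0])

    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    keys = _mask_keys(umis, length)
    base_mat = umis.astype(f"S{length}").view(np.uint8).reshape(n, length)
    n_count = (base_mat == ord("N")).sum(axis=1)
    for j in range(length):
        col = keys[:, j]
        # an N counts as a mismatch to every base (including another N), so a
        # UMI may only link through position j if j is its sole N (if any)
        had_n = base_mat[:, j] == ord("N")
        linkable = (n_count == 0) | (had_n & (n_count == 1))
        order = np.argsort(col)
        sorted_keys = col[order]
        start = 0
        for i in range(1, n + 1):
            if i == n or sorted_keys[i] != sorted_keys[start]:
                if i - start > 1:
                    members = [order[t] for t in range(start, i) if linkable[order[t]]]
                    for a, b in zip(members, members[1:]):
                        ra, rb = find(a), find(b)
                        if ra != rb:
                            parent[ra] = rb
                start = i
    roots = {find(i) for i in range(n)}
    return len(roots)


def hamming1_components_bruteforce(umis) -> int:
    """All-pairs BFS oracle for :func:`hamming1_components` (test reference)."""
    umis = sorted(set(map(str, umis)))
    n = len(umis)
    if n == 0:
        return 0
    if len({len(u) for u in umis}) > 1:
        raise ValueError("UMIs of unequal length within a group: Hamming undefined")

    def hamming(a: str, b: str) -> int:
        return sum(1 for x, y in zip(a, b) if x != y or x == "N")

    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if hamming(umis[i], umis[j]) <= 1:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = 0
    for s in range(n):
        if seen[s]:
            continue
        comps += 1
        stack = [s]
        seen[s] = True
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
    return comps


def collapse_umis(records: pd.DataFrame) -> pd.DataFrame:
    """Per (cell, barcode): error-corrected UMI count and total reads.

    ``umi_count`` is the number of connected components of the Hamming-<=1
    graph over the group's distinct UMI sequences; ``read_count`` is the total
    reads. Output has one row per (cell_bc, barcode), sorted for determinism.
    """
    if records.empty:
        return pd.DataFrame(columns=["cell_bc", "barcode", "umi_count", "read_count"])
    rows = []
    for (cell, bc), g in records.groupby(["cell_bc", "barcode"], sort=True):
        rows.append(
            (cell, bc, hamming1_components(g["umi"].to_numpy()), int(g["reads"].sum()))
        )
    return pd.DataFrame(rows, columns=["cell_bc", "barcode", "umi_count", "read_count"])


def process_reads(
    records: pd.DataFrame,
    mode: str,
    min_fraction: float = 0.2,
    chimera_filter_first: bool = True,
) -> tuple[pd.DataFrame, DropTally]:
    """Full counting stage: validate -> chimera filter -> Hamming collapse.

    ``chimera_filter_first`` keeps the documented order (filter before
    collapse); set False to collapse on unfiltered UMIs for sensitivity
    analysis (the filter is then applied to the validated records only for
    tallying).
    """
    tally = DropTally()
    validated = validate_reads(records, mode, tally)
    if chimera_filter_first:
        filtered = filter_chimeric_umis(validated, min_fraction, tally)
        counts = collapse_umis(filtered)
    else:
        counts = collapse_umis(validated)
        filter_chimeric_umis(validated, min_fraction, tally)  # tally only
    return counts, tally
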