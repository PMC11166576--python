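"""Generative simulator of dual-barcode single-cell reporter experiments.

The simulator emulates the statistical structure of an scQer-style experiment
with known ground truth, producing every input the downstream pipeline
consumes:

* a triplet library linking each oBC to one (CRE, mBC) pair;
* a clonal population: each clone carries a zero-truncated-Poisson number of
  integrations, each with a log-normal positional multiplier;
* per-cell barcode molecules: oBC UMIs at high copy (Poisson around the
  capture mean, the "high mode"), mBC UMIs Poisson around
  activity x positional multiplier x relative transcriptome depth, and
  chimeric low-count molecules injected for barcodes absent from the cell
  (zero-truncated Poisson with mean 1, the "low mode");
* read-level tables with explicit UMI sequences, reads per UMI
  (1 + geometric), read-level barcode-swapping chimeras, and per-base UMI
  substitution errors -- with a sidecar truth table flagging every emitted
  molecule as real or chimeric;
* bulk DNA/RNA MPRA libraries as multinomial draws over integration copy
  number and copy x population-averaged activity.

Fixing ``SimConfig.seed`` fixes all outputs bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "build_library",
    "simulate_population",
    "simulate_cells",
    "simulate_counts",
    "simulate_bulk",
    "random_sequences",
    "ztpoisson",
    "OBC_CONSTANT",
    "MBC_CONSTANT",
]

# constant regions flanking each barcode in the sequencing read
OBC_CONSTANT = "GCTTTAA"  # follows the 16 nt oBC (read positions 17-23)
MBC_CONSTANT = "TCGACAA"  # follows the 15 nt mBC (read positions 16-22)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of the generative model.

    Defaults mirror the benchmark regime of the assay: high-MOI clonal
    integration (zero-truncated Poisson MOI), ~2,500 oBC UMIs captured per
    cell per integration giving >30x separation from the chimeric low mode,
    transcriptome depths log-normal around ``gex_mean``, and log-normal
    per-integration positional multipliers.
    """

    n_cre: int = 10
    pairs_per_cre: int = 20
    n_clusters: int = 3
    cluster_proportions: Sequence[float] | None = None  # uniform when None
    activity_matrix: np.ndarray | None = None  # (n_cre, n_clusters); 1.0 when None
    moi_mean: float = 5.0
    n_clones: int = 100
    positional_sd_log: float = 0.5
    obc_capture_mean: float = 2500.0
    obc_dropout_rate: float = 0.0
    chimera_rate_obc: float = 0.01
    chimera_rate_mbc: float = 0.01
    read_chimera_fraction: float = 0.0
    umi_length: int = 12
    obc_length: int = 16
    mbc_length: int = 15
    cell_bc_length: int = 16
    umi_error_rate: float = 0.0
    reads_per_umi_mean: float = 3.0
    gex_mean: float = 10000.0
    gex_sd_log: float = 0.3
    seed: int = 0
    cre_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.n_cre < 1 or self.pairs_per_cre < 1:
            raise ValueError("n_cre and pairs_per_cre must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple([1.0 / self.n_clusters] * self.n_clusters)
        props = np.asarray(self.cluster_proportions, dtype=float)
        if props.shape != (self.n_clusters,) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError("cluster_proportions must be a probability vector of length n_clusters")
        if self.activity_matrix is None:
            self.activity_matrix = np.ones((self.n_cre, self.n_clusters))
        self.activity_matrix = np.asarray(self.activity_matrix, dtype=float)
        if self.activity_matrix.shape != (self.n_cre, self.n_clusters):
            raise ValueError("activity_matrix must have shape (n_cre, n_clusters)")
        if (self.activity_matrix < 0).any():
            raise ValueError("activity_matrix must be nonnegative")
        for name in (
            "moi_mean",
            "obc_capture_mean",
            "reads_per_umi_mean",
            "gex_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "positional_sd_log",
            "obc_dropout_rate",
            "chimera_rate_obc",
            "chimera_rate_mbc",
            "read_chimera_fraction",
            "umi_error_rate",
            "gex_sd_log",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.cre_names:
            width = max(3, len(str(self.n_cre - 1)))
            self.cre_names = tuple(f"cre_{i:0{width}d}" for i in range(self.n_cre))
        if len(self.cre_names) != self.n_cre:
            raise ValueError("cre_names must have length n_cre")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth of a simulated population.

    Attributes
    ----------
    triplets : pandas.DataFrame
        Columns ``obc, mbc, cre_id`` -- the emitted triplet map.
    integrations : pandas.DataFrame
        One row per clonal integration: ``clone, triplet_idx, obc, mbc,
        cre_id, pos_mult``.
    config : SimConfig
    """

    triplets: pd.DataFrame
    integrations: pd.DataFrame
    config: SimConfig

    def clone_obc_sets(self) -> dict[int, frozenset]:
        return {
            int(c): frozenset(g["obc"])
            for c, g in self.integrations.groupby("clone")
        }


def random_sequences(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n random DNA sequences of the given length, as a str array."""
    arr = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    return _BASES[arr].view(f"S{length}").ravel().astype(str)


def _parity_umis(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n UMI sequences from the distance-2 parity code over {A,C,G,T}.

    The final base is the mod-4 checksum of the others, so any two distinct
    code words differ at >= 2 positions: distinct molecules never merge under
    Hamming-1 collapse, and only sequencing errors create Hamming-1 neighbors.
    """
    digits = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    digits[:, -1] = (-digits[:, :-1].sum(axis=1)) % 4
    return _BASES[digits].view(f"S{length}").ravel().astype(str)


def _distinct_sequences(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n pairwise-distinct random sequences, by rejection sampling."""
    if 4**length < 2 * n:
        raise ValueError(
            f"sequence space 4^{length} too small to draw {n} distinct barcodes"
        )
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        for s in random_sequences(rng, n - len(seqs), length):
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    return np.array(seqs)


def ztpoisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws via inverse-CDF on the truncated support."""
    u = rng.uniform(size=size)
    from scipy import stats as sps

    p0 = np.exp(-mean)
    # invert the truncated CDF: F_trunc(k) = (F(k) - p0) / (1 - p0)
    return sps.poisson.ppf(p0 + u * (1.0 - p0), mean).astype(np.int64)


def build_library(config: SimConfig) -> pd.DataFrame:
    """Build the oBC-CRE-mBC triplet map with pairwise-distinct barcodes.

    Returns a DataFrame with columns ``obc, mbc, cre_id`` and
    ``n_cre * pairs_per_cre`` rows. All oBCs are distinct and all mBCs are
    distinct (each oBC maps to exactly one (CRE, mBC) pair).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cre * config.pairs_per_cre
    obcs = _distinct_sequences(rng, n, config.obc_length)
    mbcs = _distinct_sequences(rng, n, config.mbc_length)
    cre = np.repeat(np.array(config.cre_names), config.pairs_per_cre)
    return pd.DataFrame({"obc": obcs, "mbc": mbcs, "cre_id": cre})


def simulate_population(triplets: pd.DataFrame, config: SimConfig) -> SimTruth:
    """Draw the clonal structure: integration sets and positional multipliers.

    Each clone receives a zero-truncated Poisson(``moi_mean``) number of
    integrations drawn without replacement from the triplet library; each
    integration gets an independent log-normal(0, ``positional_sd_log``)
    positional multiplier.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_triplets = len(triplets)
    mois = np.minimum(
        ztpoisson(rng, config.moi_mean, config.n_clones), n_triplets
    )
    rows = []
    for clone, k in enumerate(mois):
        idx = rng.choice(n_triplets, size=int(k), replace=False)
        rows.append(
            pd.DataFrame(
                {
                    "clone": clone,
                    "triplet_idx": idx,
                    "pos_mult": (
                        np.ones(int(k))
                        if config.positional_sd_log == 0
                        else rng.lognormal(0.0, config.positional_sd_log, int(k))
                    ),
                }
            )
        )
    integ = pd.concat(rows, ignore_index=True)
    integ = integ.join(triplets.reset_index(drop=True), on="triplet_idx")
    return SimTruth(triplets=triplets, integrations=integ, config=config)


# ---------------------------------------------------------------------------
# molecule-level generation
# ---------------------------------------------------------------------------


def _draw_cells(truth: SimTruth, n_cells: int, rng: np.random.Generator) -> pd.DataFrame:
    cfg = truth.config
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    cell_bcs = _distinct_sequences(rng, n_cells, cfg.cell_bc_length)
    clone = rng.integers(0, cfg.n_clones, size=n_cells)
    cluster = rng.choice(cfg.n_clusters, size=n_cells, p=np.asarray(cfg.cluster_proportions))
    gex = np.maximum(
        1, np.round(rng.lognormal(np.log(cfg.gex_mean), cfg.gex_sd_log, n_cells))
    ).astype(np.int64)
    return pd.DataFrame(
        {"cell_bc": cell_bcs, "cluster": cluster, "clone": clone, "gex_umis": gex}
    )


def _draw_molecule_counts(
    truth: SimTruth, cells: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-(cell, barcode) molecule counts for both libraries, plus expected truth.

    Returns ``(obc_mols, mbc_mols, expected)`` where the molecule frames have
    columns ``cell_idx, barcode, n_umis, real`` and ``expected`` carries the
    per-(cell, CRE) expected mBC count
    (sum over integrations of activity x pos_mult x gex / gex_mean).
    """
    cfg = truth.config
    integ = truth.integrations
    cre_index = {name: i for i, name in enumerate(cfg.cre_names)}
    act = cfg.activity_matrix

    # expand integrations to cells via clone assignment
    merged = cells.reset_index(names="cell_idx").merge(integ, on="clone", how="inner")
    rel_depth = merged["gex_umis"].to_numpy() / cfg.gex_mean
    cre_idx = merged["cre_id"].map(cre_index).to_numpy()
    clus = merged["cluster"].to_numpy()
    lam_mbc = act[cre_idx, clus] * merged["pos_mult"].to_numpy() * rel_depth

    obc_n = rng.poisson(cfg.obc_capture_mean, size=len(merged))
    if cfg.obc_dropout_rate > 0:
        # capture dropout: the whole integration's oBC fails to be captured
        obc_n = obc_n * (rng.uniform(size=len(merged)) >= cfg.obc_dropout_rate)
    mbc_n = rng.poisson(lam_mbc)

    obc_mols = pd.DataFrame(
        {
            "cell_idx": merged["cell_idx"].to_numpy(),
            "barcode": merged["obc"].to_numpy(),
            "n_umis": obc_n,
            "real": True,
        }
    )
    mbc_mols = pd.DataFrame(
        {
            "cell_idx": merged["cell_idx"].to_numpy(),
            "barcode": merged["mbc"].to_numpy(),
            "n_umis": mbc_n,
            "real": True,
        }
    )

    expected = (
        pd.DataFrame(
            {
                "cell_idx": merged["cell_idx"].to_numpy(),
                "cell_bc": merged["cell_bc"].to_numpy(),
                "cre_id": merged["cre_id"].to_numpy(),
                "expected_mbc": lam_mbc,
            }
        )
        .groupby(["cell_idx", "cell_bc", "cre_id"], as_index=False)["expected_mbc"]
        .sum()
    )

    # chimeric molecules: per cell, each absent barcode fires independently
    n_triplets = len(truth.triplets)
    present = {
        lib: merged.groupby("cell_idx")[col].agg(set)
        for lib, col in (("obc", "obc"), ("mbc", "mbc"))
    }
    chim_frames = {"obc": [], "mbc": []}
    all_bc = {"obc": truth.triplets["obc"].to_numpy(), "mbc": truth.triplets["mbc"].to_numpy()}
    rates = {"obc": cfg.chimera_rate_obc, "mbc": cfg.chimera_rate_mbc}
    for lib in ("obc", "mbc"):
        rate = rates[lib]
        if rate <= 0:
            continue
        for cell_idx in cells.index.to_numpy():
            have = present[lib].get(cell_idx, set())
            n_absent = n_triplets - len(have)
            if n_absent <= 0:
                continue
            n_events = rng.binomial(n_absent, min(rate, 1.0))
            if n_events == 0:
                continue
            pool = all_bc[lib]
            picks: list[str] = []
            while len(picks) < n_events:
                cand = pool[rng.integers(0, n_triplets, size=n_events - len(picks))]
                picks.extend(b for b in cand if b not in have and b not in picks)
            chim_frames[lib].append(
                pd.DataFrame(
                    {
                        "cell_idx": cell_idx,
                        "barcode": picks,
                        "n_umis": ztpoisson(rng, 1.0, n_events),
                        "real": False,
                    }
                )
            )
    if chim_frames["obc"]:
        obc_mols = pd.concat([obc_mols, *chim_frames["obc"]], ignore_index=True)
    if chim_frames["mbc"]:
        mbc_mols = pd.concat([mbc_mols, *chim_frames["mbc"]], ignore_index=True)
    return obc_mols, mbc_mols, expected


def simulate_counts(
    truth: SimTruth, n_cells: int, config: SimConfig | None = None
) -> dict:
    """Simulate directly at the error-corrected count level.

    Skips UMI-sequence and read emission: the returned tables are what a
    noiseless counting stage would produce (chimeric molecules included as
    real low-count entries). Useful for statistics-level experiments where
    read-level noise channels are off.

    Returns a dict with ``cells``, ``obc_counts``, ``mbc_counts``,
    ``expected`` (per-(cell, CRE) expected mBC count) and ``truth_flags``.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    cells = _draw_cells(truth, n_cells, rng)
    obc_mols, mbc_mols, expected = _draw_molecule_counts(truth, cells, rng)

    def _to_counts(mols: pd.DataFrame) -> pd.DataFrame:
        mols = mols[mols["n_umis"] > 0]
        out = (
            mols.groupby(["cell_idx", "barcode"], as_index=False)["n_umis"]
            .sum()
            .rename(columns={"n_umis": "umi_count"})
        )
        out["cell_bc"] = cells["cell_bc"].to_numpy()[out["cell_idx"]]
        out["read_count"] = out["umi_count"]  # 1 read per UMI at the count level
        return out[["cell_bc", "barcode", "umi_count", "read_count"]]

    flags = pd.concat(
        [obc_mols.assign(library="obc"), mbc_mols.assign(library="mbc")],
        ignore_index=True,
    )
    flags["cell_bc"] = cells["cell_bc"].to_numpy()[flags["cell_idx"]]
    return {
        "cells": cells,
        "obc_counts": _to_counts(obc_mols),
        "mbc_counts": _to_counts(mbc_mols),
        "expected": expected,
        "truth_flags": flags[["cell_bc", "library", "barcode", "n_umis", "real"]],
    }


def _emit_reads(
    mols: pd.DataFrame,
    cells: pd.DataFrame,
    constant: str,
    all_barcodes: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand molecule counts to a read table with explicit UMI sequences.

    Returns (read_table, sidecar). The read table has columns
    ``cell_bc, umi, target_read, reads``; the sidecar flags each emitted UMI
    with its pre-error sequence and real/chimeric status.
    """
    mols = mols[mols["n_umis"] > 0].reset_index(drop=True)
    n_mol = int(mols["n_umis"].sum())
    cell_idx = np.repeat(mols["cell_idx"].to_numpy(), mols["n_umis"].to_numpy())
    barcode = np.repeat(mols["barcode"].to_numpy(), mols["n_umis"].to_numpy())
    real = np.repeat(mols["real"].to_numpy(), mols["n_umis"].to_numpy())
    umis = _parity_umis(rng, n_mol, cfg.umi_length)
    # distinct molecules within a (cell, barcode) group carry distinct UMIs
    key = pd.DataFrame({"c": cell_idx, "b": barcode, "u": umis})
    dup = key.duplicated().to_numpy()
    while dup.any():
        umis[dup] = _parity_umis(rng, int(dup.sum()), cfg.umi_length)
        key["u"] = umis
        dup = key.duplicated().to_numpy()
    # reads per UMI: geometric on {1, 2, ...} with the configured mean
    if cfg.reads_per_umi_mean > 1.0:
        reads = rng.geometric(1.0 / cfg.reads_per_umi_mean, size=n_mol)
    else:
        reads = np.ones(n_mol, dtype=np.int64)

    cell_bc = cells["cell_bc"].to_numpy()[cell_idx]
    rows = {
        "cell_bc": [cell_bc],
        "umi": [umis],
        "barcode": [barcode],
        "reads": [reads.astype(np.int64)],
        "real": [real],
        "true_umi": [umis],
    }

    # read-level chimeras: some reads re-emitted under a wrong barcode,
    # same (cell, UMI)
    if cfg.read_chimera_fraction > 0:
        n_chim = rng.binomial(reads, min(cfg.read_chimera_fraction, 1.0))
        sel = n_chim > 0
        if sel.any():
            wrong = all_barcodes[rng.integers(0, len(all_barcodes), size=int(sel.sum()))]
            # avoid re-emitting under the same barcode
            same = wrong == barcode[sel]
            while same.any():
                wrong[same] = all_barcodes[rng.integers(0, len(all_barcodes), size=int(same.sum()))]
                same = wrong == barcode[sel]
            rows["cell_bc"].append(cell_bc[sel])
            rows["umi"].append(umis[sel])
            rows["barcode"].append(wrong)
            rows["reads"].append(n_chim[sel].astype(np.int64))
            rows["real"].append(np.zeros(int(sel.sum()), dtype=bool))
            rows["true_umi"].append(umis[sel])

    tbl = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})

    # per-read UMI substitution errors: erroneous reads split off the UMI
    if cfg.umi_error_rate > 0:
        p_read_err = 1.0 - (1.0 - cfg.umi_error_rate) ** cfg.umi_length
        n_err = rng.binomial(tbl["reads"].to_numpy(), p_read_err)
        tbl["reads"] = tbl["reads"].to_numpy() - n_err
        err_sel = n_err > 0
        if err_sel.any():
            src = tbl.loc[err_sel]
            rep = np.repeat(src.index.to_numpy(), n_err[err_sel])
            err = tbl.loc[rep].copy().reset_index(drop=True)
            err["reads"] = 1
            # corrupt one or more bases of each erroneous read's UMI
            u = err["umi"].to_numpy().astype(f"S{cfg.umi_length}")
            mat = u.view(np.uint8).reshape(len(err), cfg.umi_length).copy()
            n_sub = np.maximum(1, rng.binomial(cfg.umi_length, cfg.umi_error_rate, len(err)))
            for i in range(len(err)):
                pos = rng.choice(cfg.umi_length, size=int(n_sub[i]), replace=False)
                mat[i, pos] = _BASES[
                    (np.searchsorted(_BASES, mat[i, pos]) + rng.integers(1, 4, int(n_sub[i]))) % 4
                ]
            err["umi"] = mat.view(f"S{cfg.umi_length}").ravel().astype(str)
            tbl = pd.concat([tbl[tbl["reads"] > 0], err], ignore_index=True)
        else:
            tbl = tbl[tbl["reads"] > 0].reset_index(drop=True)

    tbl = (
        tbl.groupby(["cell_bc", "umi", "barcode", "real", "true_umi"], as_index=False)[
            "reads"
        ].sum()
    )
    read_tbl = tbl[["cell_bc", "umi", "barcode", "reads"]].copy()
    read_tbl["target_read"] = read_tbl.pop("barcode") + constant
    sidecar = tbl[["cell_bc", "barcode", "umi", "true_umi", "real", "reads"]].copy()
    return read_tbl[["cell_bc", "umi", "target_read", "reads"]], sidecar


def simulate_cells(
    truth: SimTruth, n_cells: int, config: SimConfig | None = None
) -> dict:
    """Simulate read-level oBC and mBC tables for ``n_cells`` cells.

    Returns a dict with ``cells`` (cell_bc, cluster, clone, gex_umis),
    ``obc_reads`` / ``mbc_reads`` (cell_bc, umi, target_read, reads),
    ``obc_sidecar`` / ``mbc_sidecar`` truth tables, and ``expected``
    per-(cell, CRE) expected mBC counts.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    cells = _draw_cells(truth, n_cells, rng)
    obc_mols, mbc_mols, expected = _draw_molecule_counts(truth, cells, rng)
    obc_reads, obc_side = _emit_reads(
        obc_mols, cells, OBC_CONSTANT, truth.triplets["obc"].to_numpy(), cfg, rng
    )
    mbc_reads, mbc_side = _emit_reads(
        mbc_mols, cells, MBC_CONSTANT, truth.triplets["mbc"].to_numpy(), cfg, rng
    )
    return {
        "cells": cells,
        "obc_reads": obc_reads,
        "mbc_reads": mbc_reads,
        "obc_sidecar": obc_side,
        "mbc_sidecar": mbc_side,
        "expected": expected,
    }


def simulate_bulk(
    truth: SimTruth,
    depth_dna: int,
    depth_rna: int,
    config: SimConfig | None = None,
    umi_length: int = 10,
) -> dict:
    """Simulate bulk MPRA DNA and RNA libraries.

    DNA UMIs are multinomial over integration copy numbers (each clone
    contributes its integrations with equal population weight); RNA UMIs are
    multinomial over copy x positional multiplier x population-averaged
    activity. Read-level tables carry explicit pseudo-UMIs and reads.

    Returns a dict with ``dna_reads``/``rna_reads`` (mbc, umi, reads),
    ``dna_counts``/``rna_counts`` (mbc, umi_count) and ``expected`` per-mBC
    expected RNA/DNA expression ratio.
    """
    cfg = config or truth.config
    if depth_dna < 1 or depth_rna < 1:
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    integ = truth.integrations
    cre_index = {name: i for i, name in enumerate(cfg.cre_names)}
    props = np.asarray(cfg.cluster_proportions)
    mean_act = cfg.activity_matrix @ props  # population-averaged activity per CRE

    per_mbc = integ.groupby("mbc").agg(
        copies=("clone", "size"),
        rna_weight=("pos_mult", "sum"),  # placeholder, fixed below
    )
    act = mean_act[integ["cre_id"].map(cre_index).to_numpy()]
    rna_w = (
        pd.Series(act * integ["pos_mult"].to_numpy(), index=integ["mbc"].to_numpy())
        .groupby(level=0)
        .sum()
    )
    per_mbc["rna_weight"] = rna_w.reindex(per_mbc.index).fillna(0.0)

    dna_p = per_mbc["copies"].to_numpy(float)
    dna_p /= dna_p.sum()
    rna_p = per_mbc["rna_weight"].to_numpy(float)
    if rna_p.sum() <= 0:
        raise ValueError("all activities are zero; RNA library would be empty")
    rna_p /= rna_p.sum()

    dna_n = rng.multinomial(depth_dna, dna_p)
    rna_n = rng.multinomial(depth_rna, rna_p)

    def _reads(counts: np.ndarray) -> pd.DataFrame:
        mbc = np.repeat(per_mbc.index.to_numpy(), counts)
        umis = random_sequences(rng, int(counts.sum()), umi_length)
        if cfg.reads_per_umi_mean > 1.0:
            reads = rng.geometric(1.0 / cfg.reads_per_umi_mean, len(mbc))
        else:
            reads = np.ones(len(mbc), dtype=np.int64)
        return pd.DataFrame({"mbc": mbc, "umi": umis, "reads": reads.astype(np.int64)})

    expected = pd.DataFrame(
        {
            "mbc": per_mbc.index,
            "expected_expression": np.where(dna_p > 0, rna_p / np.where(dna_p > 0, dna_p, 1.0), np.nan),
        }
    )
    return {
        "dna_reads": _reads(dna_n),
        "rna_reads": _reads(rna_n),
        "dna_counts": pd.DataFrame({"mbc": per_mbc.index, "umi_count": dna_n}),
        "rna_counts": pd.DataFrame({"mbc": per_mbc.index, "umi_count": rna_n}),
        "expected": expected,
    }
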