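"""Integration detection and detection-conditioned quantification."""

import numpy as np
import pandas as pd
import pytest

from scqer import quant, sim
from tests.conftest import expression_from, simulate_pipeline_inputs


def _counts(rows):
    return pd.DataFrame(rows, columns=["cell_bc", "barcode", "umi_count"])


class TestDetectIntegrations:
    def test_thresholding(self):
        det = quant.detect_integrations(_counts([("c", "o1", 2500), ("c", "o2", 3)]), 12)
        assert det.set_index("obc")["detected"].to_dict() == {"o1": True, "o2": False}

    def test_boundary_is_inclusive(self):
        det = quant.detect_integrations(_counts([("c", "o1", 12), ("c", "o2", 11)]), 12)
        assert det.set_index("obc")["detected"].to_dict() == {"o1": True, "o2": False}

    def test_empty_table(self):
        det = quant.detect_integrations(_counts([]), 12)
        assert det.empty

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            quant.detect_integrations(_counts([("c", "o", 5)]), 0)


class TestEstimateThreshold:
    def test_valley_of_bimodal_mixture(self, rng):
        low = rng.poisson(1.0, 2000) + 1
        high = rng.poisson(2500.0, 2000)
        thr = quant.estimate_threshold(np.concatenate([low, high]))
        assert 5 <= thr <= 100

    def test_unimodal_falls_back_with_warning(self, rng):
        with pytest.warns(UserWarning, match="unimodal"):
            thr = quant.estimate_threshold(rng.poisson(2500.0, 1000) + 1)
        assert thr == 12

    def test_deterministic_given_counts(self, rng):
        x = np.concatenate([rng.poisson(1.0, 500) + 1, rng.poisson(2000.0, 500)])
        assert quant.estimate_threshold(x) == quant.estimate_threshold(x)

    def test_needs_enough_counts(self):
        with pytest.raises(ValueError):
            quant.estimate_threshold(np.array([5] * 50))


class TestQuantifyReporters:
    triplets = pd.DataFrame(
        {"obc": ["o1", "o2"], "mbc": ["m1", "m2"], "cre_id": ["creA", "creB"]}
    )

    def _cells(self):
        return pd.DataFrame(
            {
                "cell_bc": ["c1", "c2"],
                "gex_umis": [5000, 15000],  # mean 10,000
                "cluster": ["k0", "k1"],
            }
        )

    def test_normalization_formula(self):
        det = quant.detect_integrations(_counts([("c1", "o1", 100)]), 12)
        mbc = _counts([("c1", "m1", 2)])
        expr, _ = quant.quantify_reporters(det, mbc, self.triplets, self._cells())
        # 2 / 5000 * 10000 = 4.0
        assert expr.iloc[0]["norm_expr"] == pytest.approx(4.0)

    def test_true_zero_for_detected_but_silent(self):
        det = quant.detect_integrations(_counts([("c1", "o1", 100)]), 12)
        expr, _ = quant.quantify_reporters(det, _counts([]), self.triplets, self._cells())
        assert len(expr) == 1
        assert expr.iloc[0]["mbc_umis"] == 0 and expr.iloc[0]["norm_expr"] == 0.0

    def test_unmatched_mbc_excluded_and_tallied(self):
        det = quant.detect_integrations(_counts([("c1", "o1", 100)]), 12)
        mbc = _counts([("c1", "m1", 2), ("c2", "m1", 3), ("c1", "m2", 1)])
        expr, qc = quant.quantify_reporters(det, mbc, self.triplets, self._cells())
        assert len(expr) == 1  # only the detected (c1, o1) row
        assert qc["n_spurious_mbc_events"] == 2
        assert qc["chimeric_detection_rate"] == pytest.approx(2 / 3)

    def test_missing_cell_errors(self):
        det = quant.detect_integrations(_counts([("c9", "o1", 100)]), 12)
        with pytest.raises(ValueError, match="missing from cell_table"):
            quant.quantify_reporters(det, _counts([]), self.triplets, self._cells())

    def test_duplicate_triplet_keys_rejected(self):
        bad = pd.DataFrame({"obc": ["o1", "o1"], "mbc": ["m1", "m2"], "cre_id": ["a", "b"]})
        det = quant.detect_integrations(_counts([("c1", "o1", 100)]), 12)
        with pytest.raises(ValueError, match="duplicate"):
            quant.quantify_reporters(det, _counts([]), bad, self._cells())

    def test_chimeric_mbc_does_not_change_conditioned_rows(self):
        det = quant.detect_integrations(_counts([("c1", "o1", 100)]), 12)
        mbc = _counts([("c1", "m1", 2)])
        base, _ = quant.quantify_reporters(det, mbc, self.triplets, self._cells())
        noisy = pd.concat([mbc, _counts([("c2", "m2", 1), ("c2", "m1", 4)])])
        with_chim, _ = quant.quantify_reporters(det, noisy, self.triplets, self._cells())
        pd.testing.assert_frame_equal(base, with_chim)


class TestSummarizeCre:
    def _expr(self, rows):
        return pd.DataFrame(rows, columns=["cre_id", "cell_bc", "cluster", "norm_expr"])

    def test_activity_and_specificity(self):
        rows = [("A", f"c{i}", "k0", 4.0) for i in range(6)] + [
            ("A", f"d{i}", "k1", 1.0) for i in range(6)
        ]
        out = quant.summarize_cre(self._expr(rows))
        r = out.iloc[0]
        assert r["activity"] == 4.0 and r["best_cluster"] == "k0"
        assert r["specificity"] == pytest.approx(4.0)

    def test_uniform_expression_specificity_one(self):
        rows = [("A", f"c{i}", f"k{i % 2}", 2.0) for i in range(12)]
        assert quant.summarize_cre(self._expr(rows)).iloc[0]["specificity"] == pytest.approx(1.0)

    def test_infinite_specificity_sentinel(self):
        rows = [("A", f"c{i}", "k0", 3.0) for i in range(6)] + [
            ("A", f"d{i}", "k1", 0.0) for i in range(6)
        ]
        spec = quant.summarize_cre(self._expr(rows)).iloc[0]["specificity"]
        assert np.isinf(spec) and spec > 1e12  # caps any threshold

    def test_small_clusters_ineligible_for_max(self):
        rows = [("A", "c0", "k9", 100.0)] + [("A", f"c{i}", "k0", 2.0) for i in range(1, 8)]
        r = quant.summarize_cre(self._expr(rows), min_cells_per_cluster=5).iloc[0]
        assert r["best_cluster"] == "k0" and r["activity"] == 2.0

    def test_specificity_scale_invariance(self):
        rows = [("A", f"c{i}", "k0", 4.0) for i in range(6)] + [
            ("A", f"d{i}", "k1", 1.0) for i in range(6)
        ]
        base = quant.summarize_cre(self._expr(rows)).iloc[0]["specificity"]
        scaled_rows = [(a, b, c, 7.3 * v) for a, b, c, v in rows]
        scaled = quant.summarize_cre(self._expr(scaled_rows)).iloc[0]["specificity"]
        assert scaled == pytest.approx(base)


class TestCompareToBulk:
    def test_perfectly_proportional_gives_r2_one(self):
        single = pd.DataFrame(
            {
                "mbc": list("abcde"),
                "n_cells": 10,
                "total_mbc_umis": 50,
                "mean_norm_expr": [1.0, 2.0, 4.0, 8.0, 16.0],
            }
        )
        bulk = pd.DataFrame(
            {"mbc": list("abcde"), "expression": [0.5, 1.0, 2.0, 4.0, 8.0], "dna_umis": 500}
        )
        rep = quant.compare_to_bulk(single, bulk)
        assert rep["r2_log"] == pytest.approx(1.0)
        assert rep["n_mbc"] == 5

    def test_representation_filters(self):
        single = pd.DataFrame(
            {
                "mbc": ["a", "b", "c"],
                "n_cells": [4, 5, 5],  # a: too few cells
                "total_mbc_umis": [10, 0, 10],  # b: no mBC UMI
                "mean_norm_expr": [1.0, 1.0, 1.0],
            }
        )
        bulk = pd.DataFrame({"mbc": ["a", "b", "c"], "expression": 1.0, "dna_umis": [500, 500, 99]})
        with pytest.raises(ValueError, match="no mBC passes"):
            quant.compare_to_bulk(single, bulk)  # c: dna < 100 -- all fail

    def test_simulated_concordance(self):
        cfg, triplets, truth, data = simulate_pipeline_inputs(
            seed=21,
            n_cells=800,
            n_cre=5,
            pairs_per_cre=6,
            positional_sd_log=0.0,
            activity_matrix=np.tile([20.0, 5.0, 1.0, 0.3, 60.0], (3, 1)).T,
        )
        det, expr, _ = expression_from(data, triplets)
        single = quant.per_mbc_summary(expr)
        bres = sim.simulate_bulk(truth, 300_000, 300_000, cfg)
        bulk_tbl = (
            bres["dna_counts"]
            .rename(columns={"umi_count": "dna_umis"})
            .merge(bres["rna_counts"].rename(columns={"umi_count": "rna_umis"}), on="mbc")
        )
        bulk_tbl["expression"] = (
            bulk_tbl["rna_umis"] / bulk_tbl["rna_umis"].sum()
        ) / (bulk_tbl["dna_umis"] / bulk_tbl["dna_umis"].sum())
        rep = quant.compare_to_bulk(single, bulk_tbl)
        assert rep["r2_log"] >= 0.95


class TestUnconditioned:
    def test_agrees_with_conditioned_when_no_chimeras(self):
        cfg, triplets, truth, data = simulate_pipeline_inputs(
            seed=22,
            n_cells=300,
            chimera_rate_obc=0.0,
            chimera_rate_mbc=0.0,
            activity_matrix=np.full((6, 3), 5.0),
        )
        det, expr, _ = expression_from(data, triplets)
        unc = quant.unconditioned_quantification(data["mbc_counts"], data["cells"])
        cond = (
            expr[expr["mbc_umis"] > 0]
            .groupby("mbc")["norm_expr"]
            .mean()
            .rename("cond")
            .reset_index()
        )
        m = cond.merge(unc, on="mbc")
        assert np.allclose(m["cond"], m["mean_norm_expr_unconditioned"])

    def test_upward_bias_for_silent_cres_with_chimeras(self):
        act = np.zeros((6, 3))
        act[:2] = 5.0
        cfg, triplets, truth, data = simulate_pipeline_inputs(
            seed=23, n_cells=800, chimera_rate_mbc=0.02, activity_matrix=act
        )
        det, expr, _ = expression_from(data, triplets)
        cond = expr.groupby("cre_id")["norm_expr"].mean()
        unc = quant.unconditioned_quantification(data["mbc_counts"], data["cells"])
        unc_cre = (
            unc.merge(triplets[["mbc", "cre_id"]], on="mbc")
            .groupby("cre_id")["mean_norm_expr_unconditioned"]
            .mean()
        )
        silent = [c for c in cond.index if c not in ("cre_000", "cre_001")]
        assert (unc_cre[silent] > cond[silent]).all()
        assert (cond[silent] == 0).all()

    def test_empty_counts(self):
        cells = pd.DataFrame({"cell_bc": ["c"], "gex_umis": [1000]})
        out = quant.unconditioned_quantification(
            pd.DataFrame(columns=["cell_bc", "barcode", "umi_count"]), cells
        )
        assert out.empty
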