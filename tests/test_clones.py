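"""Clonotype inference, precision-recall, capture estimation, clonal noise."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from scqer import clones, quant
from tests.conftest import expression_from, simulate_pipeline_inputs


def _detections(cell_sets):
    rows = [
        {"cell_bc": cell, "obc": o, "umi_count": 100, "detected": True}
        for cell, obcs in cell_sets.items()
        for o in obcs
    ]
    return pd.DataFrame(rows)


class TestInferClonotypes:
    def test_majority_vote_consensus(self):
        det = _detections({"c1": "abc", "c2": "abc", "c3": "abd"})
        ct, asn = clones.infer_clonotypes(det, min_jaccard=0.5)
        assert len(ct) == 1
        assert ct.iloc[0]["consensus_obcs"] == frozenset("abc")  # c: 2/3 > 50%, d: 1/3
        assert asn["assigned"].all() and (asn["clone_id"] == 0).all()

    def test_disjoint_cells_form_no_clone(self):
        det = _detections({"c1": "ab", "c2": "cd"})
        with pytest.raises(ValueError, match="no clones"):
            clones.infer_clonotypes(det, min_clone_size=2)

    def test_two_separate_clones(self):
        det = _detections({"c1": "abc", "c2": "abc", "c3": "xyz", "c4": "xyz"})
        ct, asn = clones.infer_clonotypes(det)
        assert len(ct) == 2
        assert set(map(tuple, (sorted(s) for s in ct["consensus_obcs"]))) == {
            tuple("abc"),
            tuple("xyz"),
        }

    def test_cell_order_invariance(self):
        sets = {"c1": "abcd", "c2": "abcd", "c3": "abce", "c4": "wxyz", "c5": "wxyz"}
        det = _detections(sets)
        ct1, asn1 = clones.infer_clonotypes(det, min_jaccard=0.5)
        det_rev = _detections(dict(reversed(list(sets.items()))))
        ct2, asn2 = clones.infer_clonotypes(det_rev, min_jaccard=0.5)
        key = lambda ct: sorted(tuple(sorted(s)) for s in ct["consensus_obcs"])
        assert key(ct1) == key(ct2)
        m = asn1.merge(asn2, on="cell_bc")
        assert (m["assigned_x"] == m["assigned_y"]).all()

    def test_empty_detections_error(self):
        with pytest.raises(ValueError):
            clones.infer_clonotypes(_detections({}).reindex(columns=["cell_bc", "obc", "detected"]))

    def test_simulation_recovery(self):
        cfg, triplets, truth, data = simulate_pipeline_inputs(
            seed=31, n_cells=1000, n_cre=10, pairs_per_cre=20, n_clones=100
        )
        det = quant.detect_integrations(data["obc_counts"], 12)
        ct, asn = clones.infer_clonotypes(det)
        m = asn[asn["assigned"]].merge(data["cells"], on="cell_bc")
        assert adjusted_rand_score(m["clone"], m["clone_id"]) >= 0.95


class TestPrecisionRecall:
    def test_hand_counted_recall(self):
        # 3 cells assigned to a clone with consensus {a,b,c,d}; each detects {a,b,c}
        ct = pd.DataFrame(
            {"clone_id": [0], "consensus_obcs": [frozenset("abcd")], "size": [3]}
        )
        asn = pd.DataFrame(
            {"cell_bc": ["c1", "c2", "c3"], "clone_id": 0, "score": 1.0, "assigned": True}
        )
        counts = pd.DataFrame(
            [(c, o, 100) for c in ["c1", "c2", "c3"] for o in "abc"],
            columns=["cell_bc", "obc", "umi_count"],
        )
        pr = clones.precision_recall(counts, asn, ct, thresholds=np.array([1]))
        row = pr["curve"].iloc[0]
        assert row["recall"] == pytest.approx(0.75)
        assert row["precision"] == pytest.approx(1.0)

    def test_threshold_zero_limit(self):
        ct = pd.DataFrame({"clone_id": [0], "consensus_obcs": [frozenset("ab")], "size": [3]})
        asn = pd.DataFrame(
            {"cell_bc": ["c1", "c2", "c3"], "clone_id": 0, "score": 1.0, "assigned": True}
        )
        # every cell sees both consensus oBCs plus one stray barcode
        counts = pd.DataFrame(
            [(c, o, 1) for c in ["c1", "c2", "c3"] for o in "abz"],
            columns=["cell_bc", "obc", "umi_count"],
        )
        pr = clones.precision_recall(counts, asn, ct, thresholds=np.array([0]))
        row = pr["curve"].iloc[0]
        assert row["recall"] == pytest.approx(1.0)
        assert row["precision"] == pytest.approx(2 / 3)  # consensus fraction of seen barcodes

    def test_requires_large_enough_clones(self):
        ct = pd.DataFrame({"clone_id": [0], "consensus_obcs": [frozenset("ab")], "size": [2]})
        asn = pd.DataFrame({"cell_bc": ["c1"], "clone_id": 0, "score": 1.0, "assigned": True})
        counts = pd.DataFrame([("c1", "a", 5)], columns=["cell_bc", "obc", "umi_count"])
        with pytest.raises(ValueError):
            clones.precision_recall(counts, asn, ct)

    def test_recovers_injected_dropout(self):
        """2% oBC capture dropout is read back off the PR curve at 1% FDR."""
        cfg, triplets, truth, data = simulate_pipeline_inputs(
            seed=32,
            n_cells=2000,
            n_cre=10,
            pairs_per_cre=20,
            n_clones=100,
            obc_capture_mean=100,
            obc_dropout_rate=0.02,
        )
        det = quant.detect_integrations(data["obc_counts"], 12)
        ct, asn = clones.infer_clonotypes(det)
        pr = clones.precision_recall(data["obc_counts"], asn, ct)
        est = pr["at_target_fdr"]["dropout"]
        assert est == pytest.approx(0.02, abs=0.01)

    def test_noise_free_pr_is_perfect(self):
        cfg, triplets, truth, data = simulate_pipeline_inputs(
            seed=33, n_cells=400, chimera_rate_obc=0.0, chimera_rate_mbc=0.0
        )
        det = quant.detect_integrations(data["obc_counts"], 12)
        ct, asn = clones.infer_clonotypes(det)
        pr = clones.precision_recall(
            data["obc_counts"], asn, ct, thresholds=np.array([2, 5, 12])
        )
        assert (pr["curve"]["precision"] == 1.0).all()
        assert (pr["curve"]["recall"] == 1.0).all()


class TestZtpMean:
    def test_closed_form_at_lambda_one(self):
        m = 1.0 / -np.expm1(-1.0)  # 1.581977...
        assert clones.ztp_mean([m, m]) == pytest.approx(1.0, abs=1e-8)

    def test_large_lambda_limit(self):
        assert clones.ztp_mean([2500.0, 2500.0]) == pytest.approx(2500.0, rel=1e-9)

    def test_boundary_mean_one_errors(self):
        with pytest.raises(ValueError):
            clones.ztp_mean([1, 1, 1])

    def test_counts_below_one_rejected(self):
        with pytest.raises(ValueError):
            clones.ztp_mean([0, 2, 3])

    @pytest.mark.parametrize("lam", [1.0, 2.5, 10.0])
    def test_recovers_rate_from_samples(self, lam):
        from scqer.sim import ztpoisson

        x = ztpoisson(np.random.default_rng(2024), lam, 10_000)
        assert clones.ztp_mean(x) == pytest.approx(lam, rel=0.02)


class TestClonalVariability:
    def _frames(self, values_by_cell, clone=0):
        expr = pd.DataFrame(
            {
                "cell_bc": list(values_by_cell),
                "mbc": "m1",
                "norm_expr": list(values_by_cell.values()),
            }
        )
        asn = pd.DataFrame(
            {
                "cell_bc": list(values_by_cell),
                "clone_id": clone,
                "score": 1.0,
                "assigned": True,
            }
        )
        return expr, asn

    def test_constant_counts_cv_zero(self):
        expr, asn = self._frames({f"c{i}": 4.0 for i in range(5)})
        out = clones.clonal_variability(expr, asn)
        assert out.iloc[0]["cv"] == 0.0

    def test_poisson_counts_cv_near_half(self, rng):
        vals = rng.poisson(4.0, 1000).astype(float)
        expr, asn = self._frames({f"c{i}": v for i, v in enumerate(vals)})
        out = clones.clonal_variability(expr, asn)
        assert out.iloc[0]["cv"] == pytest.approx(0.5, rel=0.1)
        assert out.iloc[0]["poisson_cv"] == pytest.approx(1 / np.sqrt(out.iloc[0]["mean"]))

    def test_poisson_floor_not_undershot(self, rng):
        """At the pure counting limit, CV does not fall below 1/sqrt(mean)."""
        for lam in (1.0, 4.0, 16.0):
            vals = rng.poisson(lam, 1000).astype(float)
            expr, asn = self._frames({f"c{i}": v for i, v in enumerate(vals)})
            out = clones.clonal_variability(expr, asn).iloc[0]
            # sampling error on CV at n=1000 is ~2-3%
            assert out["cv"] >= out["poisson_cv"] * 0.9

    def test_min_cells_filter(self):
        expr, asn = self._frames({"c1": 4.0})
        assert clones.clonal_variability(expr, asn).empty


class TestPositionalVariance:
    def _build(self, clone_means, within_sd, cells_per_clone, rng):
        rows = []
        asn_rows = []
        i = 0
        for cl, mu in enumerate(clone_means):
            for _ in range(cells_per_clone):
                rows.append({"cell_bc": f"c{i}", "mbc": "m1", "norm_expr": mu + rng.normal(0, within_sd)})
                asn_rows.append({"cell_bc": f"c{i}", "clone_id": cl, "score": 1.0, "assigned": True})
                i += 1
        return pd.DataFrame(rows), pd.DataFrame(asn_rows)

    def test_identical_clone_means_share_near_zero(self, rng):
        expr, asn = self._build([5.0] * 30, 1.0, 10, rng)
        out = clones.positional_variance(expr, asn)
        assert out.iloc[0]["between_share"] < 0.15

    def test_constructed_fifty_fifty_split(self, rng):
        clone_means = rng.normal(0.0, 1.0, 80)  # between-variance 1
        expr, asn = self._build(clone_means, 1.0, 12, rng)  # within-variance 1
        out = clones.positional_variance(expr, asn)
        assert out.iloc[0]["between_share"] == pytest.approx(0.5, abs=0.1)

    def test_single_clone_skipped(self, rng):
        expr, asn = self._build([3.0], 0.5, 8, rng)
        assert clones.positional_variance(expr, asn).empty
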