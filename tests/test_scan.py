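import numpy as np
import pytest
import statsmodels.api as sm

from splicemod.config import AnalysisConfig
from splicemod.datatypes import ExpressionMatrix, PsiMatrix, TFTargetMap, TripletVectors
from splicemod.scan import correct_fdr, fit_triplet, scan_all
from splicemod.simulate import SimulationConfig, simulate_dataset, simulate_triplet_vectors

CFG = AnalysisConfig(min_samples_gene=10, min_samples_triplet=10)


def _tv(x_tf, y, x_m, psi_raw=None):
    n = len(x_tf)
    psi_raw = psi_raw if psi_raw is not None else np.full(n, 0.5)
    return TripletVectors(sample_ids=[f"S{i}" for i in range(n)],
                          x_tf=x_tf, y_target=y, x_m=x_m,
                          psi_raw=psi_raw, n=n)


class TestFitTriplet:
    def test_exact_interpolation(self):
        rng = np.random.default_rng(1)
        x_tf = rng.normal(8, 2, 50)
        x_m = rng.uniform(0.1, 3, 50)
        y = 2.0 + 0.5 * x_tf  # no modulator terms, no noise
        res = fit_triplet(_tv(x_tf, y, x_m))
        assert res.beta == pytest.approx((2.0, 0.5, 0.0, 0.0), abs=1e-10)

    def test_matches_statsmodels(self):
        tv = simulate_triplet_vectors(80, (1.0, 0.8, -0.4, 0.6), seed=3)
        res = fit_triplet(tv)
        X = sm.add_constant(np.column_stack(
            [tv.x_tf, tv.x_m, tv.x_tf * tv.x_m]))
        ref = sm.OLS(tv.y_target, X).fit()
        assert res.beta == pytest.approx(tuple(ref.params), rel=1e-9)
        assert res.se3 == pytest.approx(ref.bse[3], rel=1e-9)
        assert res.t3 == pytest.approx(ref.tvalues[3], rel=1e-9)
        assert res.p3 == pytest.approx(ref.pvalues[3], rel=1e-9)

    def test_constant_modulator_unfit(self):
        rng = np.random.default_rng(2)
        x_tf = rng.normal(8, 2, 40)
        res = fit_triplet(_tv(x_tf, 2 + x_tf + rng.normal(size=40),
                              np.full(40, 1.0)))
        assert res.status == "unfit"
        assert "rank" in res.reason

    def test_skipped_vectors_pass_through(self):
        tv = _tv(np.ones(3), np.ones(3), np.ones(3))
        tv.status, tv.reason = "skipped", "too small"
        res = fit_triplet(tv, "G", "T", "E")
        assert res.status == "skipped" and res.reason == "too small"

    def test_sign_follows_beta3(self):
        tv = simulate_triplet_vectors(200, (0, 1, 0, 2.0), noise_sd=0.5, seed=9)
        assert fit_triplet(tv).sign == "positive"
        tv = simulate_triplet_vectors(200, (0, 1, 0, -2.0), noise_sd=0.5, seed=9)
        assert fit_triplet(tv).sign == "negative"

    def test_planted_effects_rank_first(self):
        # 5 of 100 triplets carry a strong interaction; they must have the
        # 5 smallest p-values
        rng = np.random.default_rng(11)
        pvals, planted = [], []
        for i in range(100):
            b3 = 1.5 if i < 5 else 0.0
            tv = simulate_triplet_vectors(400, (1.0, 1.0, 0.2, b3),
                                          noise_sd=1.0, rng=rng)
            pvals.append(fit_triplet(tv).p3)
            planted.append(b3 != 0)
        order = np.argsort(pvals)
        assert set(order[:5]) == {0, 1, 2, 3, 4}


class TestScanAll:
    def test_cardinality_full_cross(self, small_expr, small_psi):
        pairs = TFTargetMap({(tf, g) for tf in ("TF1", "TF2")
                             for g in ("TF1", "TF2", "G1")})
        results = scan_all(small_expr, small_psi, pairs, config=CFG)
        assert len(results) == 2 * 3 * 2
        keys = [r.key for r in results]
        assert keys == sorted(keys, key=lambda k: (k[1], k[0], k[2]))

    def test_missing_target_skipped_with_reason(self, small_expr, small_psi):
        pairs = TFTargetMap({("TF1", "ABSENT")})
        results = scan_all(small_expr, small_psi, pairs, config=CFG)
        assert len(results) == 2
        assert all(r.status == "skipped" for r in results)
        assert "absent" in results[0].reason

    def test_gene_sample_floor_enforced(self, small_expr, small_psi, small_pairs):
        cfg = CFG.replace(min_samples_gene=11)  # more than the 10 samples
        results = scan_all(small_expr, small_psi, small_pairs, config=cfg)
        assert all(r.status == "skipped" for r in results)
        assert "min_samples_gene" in results[0].reason

    def test_empty_pairs_warns(self, small_expr, small_psi, caplog):
        with caplog.at_level("WARNING"):
            results = scan_all(small_expr, small_psi, TFTargetMap(set()),
                               config=CFG)
        assert results == []
        assert "empty" in caplog.text

    def test_order_invariance(self):
        expr, psi, pairs, _ = simulate_dataset(SimulationConfig(
            n_samples=60, n_tfs=2, n_targets_per_tf=4, n_events=2,
            missing_rate=0.02, seed=21))
        cfg = CFG.replace(min_samples_gene=5)
        base = scan_all(expr, psi, pairs, config=cfg)
        rng = np.random.default_rng(0)
        expr2 = ExpressionMatrix(
            expr.data.iloc[rng.permutation(expr.shape[0]),
                           rng.permutation(expr.shape[1])])
        psi2 = PsiMatrix(psi.data.iloc[::-1, ::-1], event_gene=psi.event_gene)
        shuffled = scan_all(expr2, psi2, pairs, config=cfg)
        assert [r.key for r in base] == [r.key for r in shuffled]
        for a, b in zip(base, shuffled):
            assert a.n == b.n
            assert a.beta == pytest.approx(b.beta, rel=1e-12, nan_ok=True)
            assert a.p3 == pytest.approx(b.p3, rel=1e-12, nan_ok=True)


class TestCorrectFdr:
    def _results(self, pvals):
        out = []
        for i, p in enumerate(pvals):
            r = fit_triplet(simulate_triplet_vectors(
                20, (0, 1, 0, 0), seed=i))
            r.p3 = p
            out.append(r)
        return out

    def test_bh_hand_computation(self):
        res = correct_fdr(self._results([0.01, 0.02, 0.03, 0.9]), alpha=0.05)
        assert [r.q3 for r in res] == pytest.approx([0.04, 0.04, 0.04, 0.9])
        assert [r.significant for r in res] == [True, True, True, False]

    def test_all_ones_nothing_significant(self):
        res = correct_fdr(self._results([1.0] * 5))
        assert not any(r.significant for r in res)

    def test_single_pvalue_identity(self):
        res = correct_fdr(self._results([0.04]))
        assert res[0].q3 == pytest.approx(0.04)
        assert res[0].significant

    def test_pvalue_mode(self):
        res = correct_fdr(self._results([0.005, 0.02]), mode="pvalue",
                          pvalue_threshold=0.01)
        assert [r.significant for r in res] == [True, False]

    def test_skip_records_excluded_from_correction(self):
        res = self._results([0.01, 0.02])
        res[0].status = "skipped"
        out = correct_fdr(res)
        assert np.isnan(out[0].q3) and not out[0].significant
        assert out[1].q3 == pytest.approx(0.02)

    def test_per_tf_grouping(self):
        res = self._results([0.01, 0.04, 0.9, 0.9])
        for r, tf in zip(res, ["A", "B", "B", "B"]):
            r.tf_id = tf
        joint = [r.q3 for r in correct_fdr(res)]
        assert joint == pytest.approx([0.04, 0.08, 0.9, 0.9])
        per_tf = [r.q3 for r in correct_fdr(res, per_tf=True)]
        assert per_tf == pytest.approx([0.01, 0.12, 0.9, 0.9])
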