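"""Empirical p-values, Fisher combination and independence diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spip.core import TargetScoreList
from spip.integrate import (
    PredictionMatrix,
    bin_series,
    calibration_check,
    channel_distance_matrix,
    empirical_pvalue,
    fisher_combine,
    mi_distance,
    spip_integrate,
)


def _tsl(scores, method="m", higher=True):
    return TargetScoreList(method=method, scores=dict(scores), higher_is_better=higher)


class TestEmpiricalPvalue:
    def test_strict_maximum_gets_two_over_n_plus_one(self):
        n = 10
        scores = {f"t{i}": float(i) for i in range(n)}
        pv = empirical_pvalue(_tsl(scores))
        assert pv["t9"] == pytest.approx(2 / (n + 1))

    def test_minimum_gets_one(self):
        scores = {f"t{i}": float(i) for i in range(10)}
        pv = empirical_pvalue(_tsl(scores))
        assert pv["t0"] == pytest.approx(1.0)

    def test_identical_scores_all_one_with_flag(self):
        with pytest.warns(UserWarning, match="identical"):
            pv = empirical_pvalue(_tsl({"a": 1.0, "b": 1.0, "c": 1.0}))
        assert set(pv.values()) == {1.0}

    def test_monotone_in_score(self, rng):
        scores = {f"t{i}": float(s) for i, s in enumerate(rng.normal(size=50))}
        pv = empirical_pvalue(_tsl(scores))
        ranked = sorted(scores, key=scores.get)
        pvals = [pv[t] for t in ranked]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_lower_is_better_orientation_flips(self):
        scores = {f"t{i}": float(i) for i in range(10)}
        pv = empirical_pvalue(_tsl(scores, higher=False))
        assert pv["t0"] == pytest.approx(2 / 11)
        assert pv["t9"] == pytest.approx(1.0)

    def test_calibrated_on_iid_continuous_scores(self):
        # over 100 seeded replicates the KS rejection rate at alpha = 0.01
        # stays within its binomial expectation
        rejections = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            scores = {f"t{i}": float(s) for i, s in enumerate(r.uniform(size=200))}
            pv = np.array(list(empirical_pvalue(_tsl(scores)).values()))
            if stats.kstest(pv, "uniform").pvalue < 0.01:
                rejections += 1
        # Binomial(100, 0.01): P(X > 5) < 1e-4
        assert rejections <= 5


class TestFisherCombine:
    def test_single_p_is_identity(self):
        for p in (0.001, 0.05, 0.5, 1.0):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-12)

    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_closed_form_for_two_pvalues(self):
        # for k = 2, P(combined) = u (1 - ln u) with u = p1 p2
        for p1, p2 in [(0.05, 0.05), (0.3, 0.7), (0.01, 0.9)]:
            u = p1 * p2
            assert fisher_combine([p1, p2]) == pytest.approx(
                u * (1 - math.log(u)), abs=1e-10
            )

    def test_exchangeability(self, rng):
        ps = list(rng.uniform(0.01, 1.0, size=6))
        base = fisher_combine(ps)
        for _ in range(5):
            assert fisher_combine(list(rng.permutation(ps))) == pytest.approx(base)

    def test_zero_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            fisher_combine([1.5])
        with pytest.raises(ValueError):
            fisher_combine([])


class TestSpipIntegrate:
    def test_single_channel_passthrough(self):
        pm = PredictionMatrix.from_channels({"GECO": {"a": 0.2, "b": 0.9}})
        out = spip_integrate(pm)
        got = dict(zip(out.table["target"], out.table["p_spip"]))
        assert got["a"] == pytest.approx(0.2)
        assert got["b"] == pytest.approx(0.9)

    def test_identical_channels_reinforce(self):
        pm = PredictionMatrix.from_channels(
            {"GECO": {"a": 0.05}, "DORA": {"a": 0.05}, "GOSS": {"a": 0.05}}
        )
        out = spip_integrate(pm)
        assert out.table["p_spip"].iloc[0] <= 0.05

    def test_matches_straight_line_reference(self, rng):
        channels = ["dCOCITE", "iCOCITE", "MLNN", "GECO", "DORA", "GOSS"]
        targets = [f"t{i}" for i in range(30)]
        data = {}
        for c in channels:
            col = {}
            for t in targets:
                if rng.random() < 0.7:
                    col[t] = float(rng.uniform(0.001, 1.0))
            data[c] = col
        pm = PredictionMatrix.from_channels(data)
        out = spip_integrate(pm)
        got = dict(zip(out.table["target"], out.table["p_spip"]))
        from spip.integrate import CHANNEL_APPROACH

        for t in targets:
            per_app = {}
            for c in channels:
                if t in data[c]:
                    per_app.setdefault(CHANNEL_APPROACH[c], []).append(data[c][t])
            if not per_app:
                assert t not in got
                continue
            stage1 = [fisher_combine(ps) for ps in per_app.values()]
            assert got[t] == pytest.approx(fisher_combine(stage1), rel=1e-12)

    def test_flat_mode_combines_all_channels_once(self):
        pm = PredictionMatrix.from_channels(
            {"GECO": {"a": 0.1}, "MLNN": {"a": 0.2}, "dCOCITE": {"a": 0.3}}
        )
        flat = spip_integrate(pm, mode="flat")
        assert flat.table["p_spip"].iloc[0] == pytest.approx(
            fisher_combine([0.1, 0.2, 0.3])
        )

    def test_zero_channel_target_excluded(self):
        df = pd.DataFrame({"GECO": [0.5, np.nan]}, index=["a", "b"])
        out = spip_integrate(PredictionMatrix(df))
        assert list(out.table["target"]) == ["a"]

    def test_output_sorted_with_deterministic_ties(self):
        pm = PredictionMatrix.from_channels(
            {"GECO": {"b": 0.5, "a": 0.5, "c": 0.1}}
        )
        out = spip_integrate(pm)
        assert list(out.table["target"]) == ["c", "a", "b"]

    def test_uniform_independent_channels_give_uniform_output(self):
        # the integration step itself preserves the null
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            data = {
                c: {f"t{i}": float(p) for i, p in enumerate(r.uniform(size=300))}
                for c in ["dCOCITE", "MLNN", "GECO", "DORA"]
            }
            out = spip_integrate(PredictionMatrix.from_channels(data))
            if stats.kstest(out.table["p_spip"], "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= 2

    def test_invalid_matrix_values_rejected(self):
        df = pd.DataFrame({"GECO": [0.0]}, index=["a"])
        with pytest.raises(ValueError):
            PredictionMatrix(df)


class TestCalibrationCheck:
    def test_uniform_sample_passes(self):
        r = np.random.default_rng(7)
        report = calibration_check(r.uniform(size=500))
        assert report["pass"]

    def test_concentrated_sample_fails(self):
        r = np.random.default_rng(7)
        report = calibration_check(r.uniform(0, 0.2, size=500))
        assert not report["pass"]
        assert report["z_p"] < 0.05

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            calibration_check([0.5] * 29)


class TestMiDistance:
    def test_identical_series_distance_zero(self):
        x = [0, 1, 2, 0, 1, 2, 0, 1]
        assert mi_distance(x, x) == pytest.approx(0.0)

    def test_product_joint_distance_one(self):
        x = [0, 0, 1, 1] * 4
        y = [0, 1, 0, 1] * 4
        assert mi_distance(x, y) == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # joint counts (10, 5; 5, 10): plug-in I, H and D by direct arithmetic
        x = [0] * 15 + [1] * 15
        y = [0] * 10 + [1] * 5 + [0] * 5 + [1] * 10
        n = 30.0
        pxy = np.array([[10, 5], [5, 10]]) / n
        H = -np.sum(pxy * np.log(pxy))
        px = pxy.sum(axis=1)
        py = pxy.sum(axis=0)
        I = np.sum(pxy * np.log(pxy / np.outer(px, py)))
        assert mi_distance(x, y) == pytest.approx(1 - I / H)

    def test_symmetry(self, rng):
        x = rng.integers(0, 3, size=100)
        y = rng.integers(0, 4, size=100)
        assert mi_distance(x, y) == pytest.approx(mi_distance(y, x))

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(20):
            x = rng.integers(0, 3, size=200)
            y = rng.integers(0, 3, size=200)
            z = rng.integers(0, 3, size=200)
            dxy = mi_distance(x, y)
            dyz = mi_distance(y, z)
            dxz = mi_distance(x, z)
            assert dxz <= dxy + dyz + 1e-9

    def test_constant_series_signalled(self):
        with pytest.raises(ValueError, match="degenerate"):
            mi_distance([1] * 10, [1] * 10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mi_distance([1, 2], [1, 2, 3])


class TestChannelDiagnostics:
    def test_equal_frequency_bins_are_balanced(self, rng):
        v = rng.uniform(size=1000)
        bins = bin_series(v, bins=10)
        counts = np.bincount(bins)
        assert len(counts) == 10
        assert counts.min() >= 80

    def test_fixture_distance_matrix_is_metric_like(self, default_run):
        dm = channel_distance_matrix(default_run.matrix, bins=8)
        assert (dm.values.diagonal() == 0).all()
        sub = dm.dropna(how="all").dropna(axis=1, how="all")
        assert np.allclose(sub.values, sub.values.T, equal_nan=True)
        vals = sub.values[~np.isnan(sub.values)]
        assert vals.min() >= 0 and vals.max() <= 1 + 1e-9
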