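"""Ratio traces, sign-restricted AUC, correlation screening, normalisation,
and the linear circuit decomposition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antagonav.calcium_metrics import (
    AUCResult,
    CalciumTrace,
    auc_response,
    correlation_screen,
    dual_vs_sum,
    fit_linear_combination,
    normalize_unit_interval,
    ratio_trace,
)


def _trace(gcamp, reference, fs=2.0, stim=30.0):
    t = np.arange(len(gcamp)) / fs
    return CalciumTrace(times=t, gcamp=np.asarray(gcamp, float),
                        reference=np.asarray(reference, float),
                        stim_onset=stim, epochs={"pre": (0.0, stim)})


class TestRatioTrace:
    def test_constant_channels(self):
        n = 200
        rt = ratio_trace(_trace(np.full(n, 2.0), np.ones(n)))
        assert np.allclose(rt.R, 2.0)
        assert np.allclose(rt.dRR0, 0.0)

    def test_step_doubling_gives_unit_drr0(self):
        n = 400
        g = np.where(np.arange(n) / 2.0 >= 100.0, 4.0, 2.0)
        rt = ratio_trace(_trace(g, np.ones(n)))
        # plateaus away from the step edge; SG window is 13 samples
        assert np.allclose(rt.dRR0[:180], 0.0, atol=1e-9)
        assert np.allclose(rt.dRR0[220:], 1.0, atol=1e-9)

    def test_order1_filter_preserves_linear_ramp_interior(self):
        n = 300
        t = np.arange(n) / 2.0
        g = 2.0 + 0.01 * t
        ref = 1.0 + 0.002 * t
        rt = ratio_trace(_trace(g, ref))
        interior = slice(13, n - 13)
        assert np.allclose(rt.R[interior], (g / ref)[interior], rtol=1e-12)

    def test_invariant_under_common_rescaling(self):
        n = 200
        rng = np.random.default_rng(0)
        g = 2.0 + 0.1 * rng.random(n)
        ref = 1.0 + 0.05 * rng.random(n)
        a = ratio_trace(_trace(g, ref))
        b = ratio_trace(_trace(3.7 * g, 3.7 * ref))
        assert np.allclose(a.dRR0, b.dRR0)

    def test_even_filter_length_rejected(self):
        with pytest.raises(ValueError):
            ratio_trace(_trace(np.ones(50), np.ones(50)), filter_length=12)

    def test_nonpositive_channel_rejected(self):
        with pytest.raises(ValueError):
            _trace(np.zeros(50), np.ones(50))


class TestAUC:
    def _times(self):
        return np.arange(0.0, 400.0, 0.5)

    def test_flat_trace_zero_in_both_modes(self):
        t = self._times()
        v = np.full(t.size, 1.5)
        for mode in ("suppression", "excitation"):
            assert auc_response(t, v, 200.0, mode=mode).auc == 0.0

    def test_suppression_step_has_rectangle_area(self):
        t = self._times()
        v = np.ones(t.size)
        v[(t >= 200.0) & (t <= 260.0)] -= 0.5  # 60-s dip of depth 0.5
        res = auc_response(t, v, 200.0, mode="suppression")
        assert res.auc == pytest.approx(-30.0, abs=0.3)
        assert res.auc <= 0.0

    def test_excitation_mode_ignores_suppression(self):
        t = self._times()
        v = np.ones(t.size)
        v[(t >= 200.0) & (t <= 260.0)] -= 0.5
        assert auc_response(t, v, 200.0, mode="excitation").auc == 0.0

    def test_auc_scales_linearly_with_deviation(self):
        t = self._times()
        rng = np.random.default_rng(1)
        v = 1.0 + 0.2 * rng.standard_normal(t.size)
        a1 = auc_response(t, v, 200.0, mode="excitation", baseline=1.0).auc
        a3 = auc_response(t, 1.0 + 3 * (v - 1.0), 200.0, mode="excitation",
                          baseline=1.0).auc
        assert a3 == pytest.approx(3 * a1, rel=1e-9)

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 100.0, 0.5)
        with pytest.raises(ValueError):
            auc_response(t, np.ones(t.size), 50.0)


class TestCorrelationScreen:
    def test_reference_selects_itself(self, rng):
        ref = rng.standard_normal(500)
        selected, table = correlation_screen({"self": ref}, ref)
        assert selected == ["self"]
        assert table["self"] == pytest.approx(1.0)

    def test_exact_negation_not_selected(self, rng):
        ref = rng.standard_normal(500)
        selected, table = correlation_screen({"neg": -ref}, ref)
        assert selected == []
        assert table["neg"] == pytest.approx(-1.0)

    def test_constructed_correlations_straddle_cutoff(self, rng):
        n = 2000
        ref = rng.standard_normal(n)
        z1 = (ref - ref.mean()) / ref.std()
        raw = rng.standard_normal(n)
        raw -= raw @ z1 / (z1 @ z1) * z1      # orthogonalise
        z2 = (raw - raw.mean()) / raw.std()
        cands = {}
        for r in (0.6, 0.5):
            c = r * z1 + np.sqrt(1 - r**2) * z2
            assert np.corrcoef(c, ref)[0, 1] == pytest.approx(r, abs=1e-6)
            cands[f"r{r}"] = c
        selected, table = correlation_screen(cands, ref, cutoff=0.55)
        assert selected == ["r0.6"]
        assert table["r0.5"] == pytest.approx(0.5, abs=1e-6)

    def test_zero_variance_candidate_flagged(self, rng):
        ref = rng.standard_normal(100)
        with pytest.warns(UserWarning):
            selected, table = correlation_screen({"flat": np.ones(100)}, ref)
        assert selected == []
        assert np.isnan(table["flat"])


class TestNormalize:
    def test_extremes_map_to_unit_interval(self, rng):
        x = rng.standard_normal(100)
        y, degenerate = normalize_unit_interval(x)
        assert not degenerate
        assert y.min() == 0.0 and y.max() == 1.0

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        x = np.array([0.0, 0.3, 1.0, -2.0, 0.7])
        y0, _ = normalize_unit_interval(x)
        y1, _ = normalize_unit_interval(a * x + b)
        assert np.allclose(y0, y1, atol=1e-9)

    def test_constant_series_degenerate(self):
        y, degenerate = normalize_unit_interval(np.full(10, 3.3))
        assert degenerate and np.all(y == 0.0)


class TestCircuitFit:
    def test_noiseless_composition_recovered_exactly(self, rng):
        awa = rng.random(300)
        phd = rng.random(300)
        ava = -0.7 * awa + 0.1 * phd - 0.2
        fit = fit_linear_combination(ava, {"AWA": awa, "PHD": phd})
        assert fit.coefficients == pytest.approx([-0.7, 0.1], abs=1e-12)
        assert fit.intercept == pytest.approx(-0.2, abs=1e-12)
        assert fit.residual_rms < 1e-12

    def test_orthonormal_regressors_identity(self):
        q, _ = np.linalg.qr(np.random.default_rng(3).standard_normal((50, 2)))
        fit = fit_linear_combination(q[:, 0], {"a": q[:, 0], "b": q[:, 1]})
        assert fit.coefficients == pytest.approx([1.0, 0.0], abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_noisy_recovery_within_tolerance(self, rng):
        awa = rng.random(600)
        phd = rng.random(600)
        ava = -0.7 * awa + 0.1 * phd - 0.2 + 0.05 * rng.standard_normal(600)
        fit = fit_linear_combination(ava, {"AWA": awa, "PHD": phd})
        assert fit.coefficients[0] == pytest.approx(-0.7, abs=0.05)
        assert fit.coefficients[1] == pytest.approx(0.1, abs=0.05)

    def test_residual_orthogonal_to_design(self, rng):
        X = rng.standard_normal((200, 2))
        y = rng.standard_normal(200)
        fit = fit_linear_combination(y, {"a": X[:, 0], "b": X[:, 1]})
        resid = y - X @ fit.coefficients - fit.intercept
        assert abs(resid @ X[:, 0]) < 1e-8 * 200
        assert abs(resid @ X[:, 1]) < 1e-8 * 200
        assert abs(resid.sum()) < 1e-8 * 200

    def test_collinear_design_rejected(self, rng):
        x = rng.random(100)
        with pytest.raises(np.linalg.LinAlgError):
            fit_linear_combination(x, {"a": x, "b": 2 * x})


class TestDualVsSum:
    def _auc(self, v, mode="excitation"):
        return AUCResult(baseline=0.0, auc=v, mode=mode, window=(0.0, 120.0))

    def test_zero_singles(self):
        rec = dual_vs_sum(self._auc(0.0), self._auc(0.0), self._auc(5.0))
        assert rec["sum"] == 0.0 and rec["difference"] == 5.0

    def test_additive_traces_have_zero_difference(self):
        rec = dual_vs_sum(self._auc(2.0), self._auc(3.0), self._auc(5.0))
        assert rec["difference"] == pytest.approx(0.0)

    def test_subadditive_ratio_recovered(self):
        rec = dual_vs_sum(self._auc(2.0), self._auc(4.0), self._auc(3.0))
        assert rec["ratio"] == pytest.approx(0.5)

    def test_mismatched_modes_rejected(self):
        with pytest.raises(ValueError):
            dual_vs_sum(self._auc(1.0), self._auc(1.0, "suppression"),
                        self._auc(1.0))
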