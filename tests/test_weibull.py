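"""Tests for the Weibull curve family and the dual-component grid fit."""

import numpy as np
import pytest
from scipy import integrate, optimize

from megbeta.weibull import (
    ComponentGrid,
    component_auc,
    fit_two_component,
    predicted_integrative_timecourse,
    sample_times_ms,
    weibull_pdf,
    weibull_peak,
)

COARSE = ComponentGrid(
    local_scale_step=(450.0 - 283.0) / 4,
    integrative_scale_step=(1700.0 - 500.0) / 4,
    integrative_shape_step=1.0,
)


class TestPdf:
    def test_zero_at_origin(self):
        assert weibull_pdf(0.0, 400.0, 3.0) == 0.0

    def test_closed_form_at_scale(self):
        # f(a) = (b/a) e^-1
        assert weibull_pdf(1.0, 1.0, 3.0) == pytest.approx(3.0 / np.e)
        assert weibull_pdf(800.0, 800.0, 2.0) == pytest.approx(
            2.0 / 800.0 / np.e
        )

    @pytest.mark.parametrize("a,b", [(400.0, 3.0), (800.0, 2.0), (1200.0, 4.0)])
    def test_integrates_to_one(self, a, b):
        val, _ = integrate.quad(lambda t: weibull_pdf(t, a, b), 0, 10 * a)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            weibull_pdf(1.0, -1.0, 3.0)
        with pytest.raises(ValueError):
            weibull_pdf(1.0, 400.0, 0.5)
        with pytest.raises(ValueError):
            weibull_pdf(-1.0, 400.0, 3.0)


class TestPeak:
    @pytest.mark.parametrize("a,b", [(400.0, 3.0), (800.0, 2.0), (1200.0, 4.0)])
    def test_matches_numeric_maximization(self, a, b):
        res = optimize.minimize_scalar(
            lambda t: -weibull_pdf(t, a, b), bounds=(1.0, 3 * a),
            method="bounded",
        )
        assert weibull_peak(a, b) == pytest.approx(res.x, rel=1e-5)

    def test_known_values(self):
        assert weibull_peak(400.0, 3.0) == pytest.approx(349.43, abs=0.01)
        assert weibull_peak(800.0, 2.0) == pytest.approx(565.69, abs=0.01)

    def test_peak_before_scale(self):
        for a, b in [(300.0, 2.0), (900.0, 3.0), (1700.0, 4.0)]:
            assert weibull_peak(a, b) < a

    def test_shape_below_one_rejected(self):
        with pytest.raises(ValueError):
            weibull_peak(400.0, 1.0)


def _series_from(grid, i_loc, i_int, i_shape, cl, ci, intercept=0.0):
    t = sample_times_ms()
    a_loc = grid.local_scales()[i_loc]
    a_int = grid.integrative_scales()[i_int]
    b_int = grid.integrative_shapes()[i_shape]
    return (intercept + cl * weibull_pdf(t, a_loc, 3.0)
            + ci * weibull_pdf(t, a_int, b_int)), (a_loc, a_int, b_int)


class TestFit:
    def test_noise_free_exact_recovery(self):
        grid = ComponentGrid()
        y, (a_loc, a_int, b_int) = _series_from(grid, 7, 30, 2, -150.0, 400.0,
                                                intercept=0.3)
        dec = fit_two_component(y, grid)
        assert dec.local.a == a_loc
        assert dec.integrative.a == a_int
        assert dec.integrative.b == b_int
        assert dec.local.coefficient == pytest.approx(-150.0, abs=1e-6)
        assert dec.integrative.coefficient == pytest.approx(400.0, abs=1e-6)
        assert dec.intercept == pytest.approx(0.3, abs=1e-9)
        assert dec.flags == ()

    def test_local_only_series(self):
        grid = ComponentGrid()
        t = sample_times_ms()
        y = -200.0 * weibull_pdf(t, grid.local_scales()[3], 3.0)
        dec = fit_two_component(y, grid)
        assert dec.ssr == pytest.approx(0.0, abs=1e-12)
        assert abs(dec.integrative.coefficient) < 1e-6
        assert abs(component_auc(dec, "integrative")) < 1e-6
        assert dec.local.coefficient == pytest.approx(-200.0, rel=1e-6)

    def test_brute_force_loop_oracle(self, rng):
        y = rng.normal(size=900) - 0.5 * np.linspace(0, 1, 900)
        dec = fit_two_component(y, COARSE)
        t = sample_times_ms()
        best = (np.inf, None)
        for a_loc in COARSE.local_scales():
            for a_int in COARSE.integrative_scales():
                for b_int in COARSE.integrative_shapes():
                    if weibull_peak(a_int, b_int) <= weibull_peak(a_loc, 3.0):
                        continue
                    X = np.column_stack([
                        weibull_pdf(t, a_loc, 3.0),
                        weibull_pdf(t, a_int, b_int),
                        np.ones(900),
                    ])
                    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                    if beta[0] >= 0:
                        continue
                    ssr = float(np.sum((y - X @ beta) ** 2))
                    if ssr < best[0]:
                        best = (ssr, (a_loc, a_int, b_int, *beta))
        ssr, (a_loc, a_int, b_int, cl, ci, c0) = best
        assert dec.ssr == pytest.approx(ssr, rel=1e-9)
        assert (dec.local.a, dec.integrative.a, dec.integrative.b) == (
            a_loc, a_int, b_int
        )
        assert dec.local.coefficient == pytest.approx(cl)
        assert dec.integrative.coefficient == pytest.approx(ci)
        assert dec.intercept == pytest.approx(c0)

    def test_selected_ssr_is_minimal(self, rng):
        """Exhaustiveness: no admissible pair beats the selected SSR."""
        y = rng.normal(size=900)
        dec = fit_two_component(y, COARSE)
        t = sample_times_ms()
        for a_loc in COARSE.local_scales():
            for a_int in COARSE.integrative_scales():
                for b_int in COARSE.integrative_shapes():
                    if weibull_peak(a_int, b_int) <= weibull_peak(a_loc, 3.0):
                        continue
                    X = np.column_stack([
                        weibull_pdf(t, a_loc, 3.0),
                        weibull_pdf(t, a_int, b_int),
                        np.ones(900),
                    ])
                    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                    if beta[0] >= 0:
                        continue
                    ssr = float(np.sum((y - X @ beta) ** 2))
                    assert dec.ssr <= ssr + 1e-9

    def test_shift_changes_only_intercept(self, rng):
        y = rng.normal(size=900)
        d0 = fit_two_component(y, COARSE)
        d1 = fit_two_component(y + 2.5, COARSE)
        assert d1.intercept == pytest.approx(d0.intercept + 2.5)
        assert d1.local.coefficient == pytest.approx(d0.local.coefficient)
        assert d1.integrative.coefficient == pytest.approx(
            d0.integrative.coefficient
        )
        assert d1.ssr == pytest.approx(d0.ssr)

    def test_scaling_equivariance(self, rng):
        y = rng.normal(size=900)
        d0 = fit_two_component(y, COARSE)
        d3 = fit_two_component(3.0 * y, COARSE)
        assert d3.local.coefficient == pytest.approx(3 * d0.local.coefficient)
        assert d3.ssr == pytest.approx(9 * d0.ssr)

    def test_constraint_unsatisfied_flag(self):
        single = ComponentGrid(
            local_scale_bounds=(283.0, 283.0),
            integrative_scale_bounds=(1700.0, 1700.0),
            integrative_shape_bounds=(3.0, 3.0),
        )
        t = sample_times_ms()
        y = +100.0 * weibull_pdf(t, 283.0, 3.0)  # positive local deflection
        dec = fit_two_component(y, single)
        assert "constraint_unsatisfied" in dec.flags
        assert dec.local.coefficient > 0

    def test_constant_series_degenerate(self):
        dec = fit_two_component(np.full(900, 1.2))
        assert "degenerate" in dec.flags
        assert dec.intercept == pytest.approx(1.2)
        assert dec.local.coefficient == 0.0

    def test_nonfinite_rejected(self):
        y = np.zeros(900)
        y[3] = np.inf
        with pytest.raises(ValueError, match="finite"):
            fit_two_component(y)


class TestAUC:
    def test_zero_coefficient(self):
        grid = ComponentGrid()
        y, _ = _series_from(grid, 2, 10, 1, -50.0, 0.0)
        dec = fit_two_component(y, grid)
        assert abs(component_auc(dec, "integrative")) < 1e-6

    def test_quadrature_oracle(self):
        val, _ = integrate.quad(lambda t: weibull_pdf(t, 400.0, 3.0), 0, 1500)
        from megbeta.weibull import _component_auc

        assert _component_auc(-2.0, 400.0, 3.0) == pytest.approx(-2 * val,
                                                                 rel=1e-8)

    def test_linearity(self):
        from megbeta.weibull import _component_auc

        one = _component_auc(1.0, 900.0, 3.0)
        assert _component_auc(2.0, 900.0, 3.0) == pytest.approx(2 * one)


class TestPredictedIntegrative:
    def test_zero_coefficient_zero_series(self):
        grid = ComponentGrid()
        y, _ = _series_from(grid, 2, 10, 1, -50.0, 0.0)
        dec = fit_two_component(y, grid)
        assert np.allclose(predicted_integrative_timecourse(dec), 0.0,
                           atol=1e-9)

    def test_pointwise_oracle(self):
        grid = ComponentGrid()
        y, (a_loc, a_int, b_int) = _series_from(grid, 4, 25, 3, -80.0, 120.0)
        dec = fit_two_component(y, grid)
        t = sample_times_ms()
        expected = 120.0 * weibull_pdf(t, a_int, b_int)
        assert np.allclose(predicted_integrative_timecourse(dec), expected,
                           atol=1e-6)

    def test_peak_sample_matches_mode(self):
        grid = ComponentGrid()
        y, (_, a_int, b_int) = _series_from(grid, 4, 25, 3, -80.0, 120.0)
        dec = fit_two_component(y, grid)
        series = predicted_integrative_timecourse(dec)
        peak_ms = sample_times_ms()[np.argmax(series)]
        assert peak_ms == pytest.approx(weibull_peak(a_int, b_int), abs=1.0)


class TestGrid:
    def test_bounds_honored(self):
        g = ComponentGrid()
        assert g.local_scales().min() >= 283.0
        assert g.local_scales().max() <= 450.0
        assert g.integrative_scales().min() >= 500.0
        assert g.integrative_scales().max() <= 1700.0
        assert g.integrative_shapes().min() >= 2.0
        assert g.integrative_shapes().max() <= 4.0

    def test_pairing_rule_enforced(self):
        from megbeta.weibull import _GridCache

        cache = _GridCache(COARSE, 900)
        peaks_loc = np.array([weibull_peak(a, 3.0) for a in cache.a_loc])
        peaks_int = np.array(
            [weibull_peak(a, b) for a, b in zip(cache.a_int, cache.b_int)]
        )
        i, j = np.where(cache.admissible)
        assert np.all(peaks_int[j] > peaks_loc[i])
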