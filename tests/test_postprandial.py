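import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rumenadapt as ra
from rumenadapt.errors import InfeasibleParametersError, InsufficientDataError
from rumenadapt.postprandial import evaluate_quadratic

TIMES = np.array([0.0, 1.0, 2.0, 4.0, 6.0])


def normal_equations(t, y):
    """Independent oracle: direct solve of the 3x3 normal equations."""
    X = np.column_stack([t**2, t, np.ones_like(t)])
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitQuadratic:
    def test_exact_interpolation_of_generating_coefficients(self):
        y = evaluate_quadratic(-1, 6, 10, TIMES)
        fit = ra.fit_quadratic(TIMES, y)
        assert (fit.a, fit.b, fit.c) == pytest.approx((-1, 6, 10), rel=1e-12)
        assert fit.rss < 1e-18

    def test_matches_normal_equations_oracle_under_noise(self, rng):
        for _ in range(200):
            coef = rng.uniform(-5, 5, size=3)
            y = evaluate_quadratic(*coef, TIMES) + rng.normal(0, 0.5, TIMES.size)
            fit = ra.fit_quadratic(TIMES, y)
            expect = normal_equations(TIMES, y)
            assert np.allclose([fit.a, fit.b, fit.c], expect, rtol=1e-9, atol=1e-12)

    def test_three_points_interpolate(self, rng):
        y = rng.normal(size=3)
        fit = ra.fit_quadratic([0, 1, 2], y)
        assert fit.rss == pytest.approx(0, abs=1e-20)

    def test_too_few_distinct_times(self):
        with pytest.raises(InsufficientDataError):
            ra.fit_quadratic([0, 1], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            ra.fit_quadratic([0, 1, 1], [1.0, 2.0, 2.0])


class TestReparametrise:
    def test_symmetric_parabola_full_recovery(self):
        sv = ra.reparametrise(ra.QuadraticFit(-1, 6, 10, 0, 5))
        assert (sv.v0, sv.t_peak, sv.A, sv.v_last) == (10, 3, 9, 10)
        assert sv.R == pytest.approx(100)

    def test_asymmetric_parabola(self):
        sv = ra.reparametrise(ra.QuadraticFit(-1, 4, 10, 0, 5))
        assert (sv.v0, sv.t_peak, sv.A, sv.v_last) == (10, 2, 4, -2)
        assert sv.R == pytest.approx(25)

    def test_upward_parabola_endpoint_maximum(self):
        with pytest.warns(UserWarning, match="R.*undefined"):
            sv = ra.reparametrise(ra.QuadraticFit(1, -2, 10, 0, 5))
        assert sv.t_peak == 6
        assert sv.A == pytest.approx(24)
        assert sv.v_last == pytest.approx(34)
        assert np.isnan(sv.R)

    def test_complement_recovery_definition(self):
        sv = ra.reparametrise(
            ra.QuadraticFit(-1, 4, 10, 0, 5), recovery_definition="complement"
        )
        # (max - v_last) / (max - v0) x 100 = 16/4 x 100
        assert sv.R == pytest.approx(400)

    def test_amplitude_invariant_to_baseline_shift(self):
        sv1 = ra.reparametrise(ra.QuadraticFit(-1, 4, 10, 0, 5))
        sv2 = ra.reparametrise(ra.QuadraticFit(-1, 4, 17, 0, 5))
        assert sv2.v0 - sv1.v0 == pytest.approx(7)
        assert sv2.A == pytest.approx(sv1.A)

    def test_ph_scale_downward_deviation(self):
        # concave-up pH dip: minimum inside the window
        sv = ra.reparametrise(ra.QuadraticFit(0.1, -0.6, 6.5, 0, 5),
                              direction="down")
        assert sv.t_peak == pytest.approx(3.0)
        assert sv.A == pytest.approx(6.5 - evaluate_quadratic(0.1, -0.6, 6.5, 3.0))
        assert sv.A > 0


class TestInverseReparametrise:
    @pytest.mark.parametrize(
        "triple, expected",
        [((10, 9, 100), (-1, 6, 10)), ((10, 4, 25), (-1, 4, 10))],
    )
    def test_known_coefficient_recovery(self, triple, expected):
        assert ra.inverse_reparametrise(*triple) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        v0=st.floats(min_value=1e-8, max_value=1e-5),
        A=st.floats(min_value=1e-8, max_value=1e-5),
        R=st.floats(min_value=1.0, max_value=100.0),
    )
    def test_round_trip_identity(self, v0, A, R):
        a, b, c = ra.inverse_reparametrise(v0, A, R)
        sv = ra.reparametrise(ra.QuadraticFit(a, b, c, 0, 5))
        assert sv.v0 == pytest.approx(v0, rel=1e-9)
        assert sv.A == pytest.approx(A, rel=1e-9)
        assert sv.R == pytest.approx(R, rel=1e-9)
        assert 0 < sv.t_peak < 6

    def test_degenerate_amplitude_rejected(self):
        with pytest.raises(InfeasibleParametersError):
            ra.inverse_reparametrise(10, 0, 50)
        with pytest.raises(InfeasibleParametersError):
            ra.inverse_reparametrise(-1, 4, 50)


class TestThresholdVars:
    def test_toy_roots(self):
        # -t^2 + 6t crosses the level 5 at t = 1 and t = 5
        tv = ra.derive_threshold_vars(
            ra.QuadraticFit(-1, 6, 0, 0, 5), theta_ph=-np.log10(5)
        )
        assert tv.dur == pytest.approx(4)
        assert tv.amp_ac == pytest.approx(4)

    def test_curve_below_threshold(self):
        tv = ra.derive_threshold_vars(
            ra.QuadraticFit(-1, 6, 0, 0, 5), theta_ph=-np.log10(20)
        )
        assert tv.dur == 0
        assert tv.amp_ac == pytest.approx(9 - 20)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        a=st.floats(min_value=-2, max_value=2),
        b=st.floats(min_value=-5, max_value=5),
        c=st.floats(min_value=0.1, max_value=20),
        theta1=st.floats(min_value=0.5, max_value=1.5),
        dtheta=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_raising_threshold_never_increases_dur(self, a, b, c, theta1, dtheta):
        fit = ra.QuadraticFit(a, b, c, 0, 5)
        lo = ra.derive_threshold_vars(fit, theta_ph=theta1)
        hi = ra.derive_threshold_vars(fit, theta_ph=theta1 - dtheta)  # lower pH = higher [H+]
        assert hi.dur <= lo.dur + 1e-12
        assert hi.amp_ac <= lo.amp_ac + 1e-12


class TestFitAll:
    def test_reference_design_yields_72_rows(self, descriptors):
        assert len(descriptors) == 72
        assert (descriptors["A"] >= 0).all()

    def test_short_day_excluded_with_warning(self, default_cohort, caplog):
        meas, _ = default_cohort
        ann = ra.annotate_schedule(meas)
        mask = (ann["animal_id"] == "goat1") & (ann["day_label"] == 1) & (
            ann["time_h"] > 2
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="rumenadapt.postprandial"):
            out = ra.fit_all(ann[~mask])
        assert len(out) == 71
        assert any("excluding" in rec.message for rec in caplog.records)

    def test_noise_free_cohort_recovers_ground_truth(self):
        params = ra.default_params(seed=7, meas_noise_cv=0.0)
        meas, truth = ra.generate_cohort(params)
        desc = ra.fit_all(ra.annotate_schedule(meas))
        merged = desc.merge(truth, on=["animal_id", "day_label"],
                            suffixes=("_fit", "_true"))
        for var in ("v0", "A", "R"):
            err = np.abs(merged[f"{var}_fit"] / merged[f"{var}_true"] - 1)
            assert err.max() < 1e-9


class TestSpearman:
    def test_monotone_invariance_and_sign(self, rng):
        x = rng.normal(size=30)
        tab = pd.DataFrame({"x": x, "up": np.exp(x), "down": -x})
        rho, _ = ra.spearman_matrix(tab, ["x", "up", "down"])
        assert rho.loc["x", "up"] == pytest.approx(1.0)
        assert rho.loc["x", "down"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)

    def test_matches_rank_pearson_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        tab = pd.DataFrame({"x": x, "y": y})
        rho, _ = ra.spearman_matrix(tab, ["x", "y"])
        rx = pd.Series(x).rank()
        ry = pd.Series(y).rank()
        expect = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(expect, rel=1e-12)

    def test_constant_column_flagged_missing(self, rng):
        tab = pd.DataFrame({"x": rng.normal(size=10), "k": np.ones(10)})
        rho, _ = ra.spearman_matrix(tab, ["x", "k"])
        assert np.isnan(rho.loc["x", "k"])

    def test_descriptor_screen_on_cohort(self, descriptors):
        rho, p = ra.spearman_matrix(descriptors)
        # amplitude descriptors measure the same deviation
        assert rho.loc["A", "amp_ac"] > 0.8
        assert p.loc["A", "amp_ac"] < 1e-6
        pd.testing.assert_frame_equal(rho, rho.T)
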