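"""Settling physics: worked examples, fit oracles, and consistency laws."""

import numpy as np
import pytest

from aggsink import biophysics as bp
from aggsink.biophysics import (
    DensityGradient,
    GradientExceededError,
    SettlingTrial,
    assign_density_layer,
    compare_fits,
    drag_coefficient,
    ecd_from_area,
    excess_density,
    fit_power_law,
    fractal_dimension,
    porosity,
    reynolds,
    settling_velocity,
    sphere_volume,
    stokes_velocity,
)


class TestGeometry:
    @pytest.mark.parametrize(
        "area, expected",
        [(np.pi, 2.0), (3.0, 1.9544), (12.0, 3.9088)],
    )
    def test_ecd_from_area(self, area, expected):
        assert ecd_from_area(area) == pytest.approx(expected, abs=1e-4)

    def test_ecd_rejects_nonpositive_area(self):
        with pytest.raises(ValueError):
            ecd_from_area(0.0)

    def test_sphere_volume_and_cubic_scaling(self):
        assert sphere_volume(1.0) == pytest.approx(0.5236, abs=1e-4)
        assert sphere_volume(2.0) / sphere_volume(1.0) == pytest.approx(8.0)


class TestSettlingVelocity:
    @pytest.mark.parametrize("time_s, expected", [(60.0, 216.0), (150.0, 86.4)])
    def test_stopwatch_conversion(self, time_s, expected):
        # 15 cm / t s in cm/s, times 864 (m d-1 per cm s-1)
        assert settling_velocity(SettlingTrial(15.0, time_s)) == pytest.approx(expected)

    def test_doubling_time_halves_velocity(self):
        u1 = settling_velocity(SettlingTrial(15.0, 40.0))
        u2 = settling_velocity(SettlingTrial(15.0, 80.0))
        assert u1 == pytest.approx(2 * u2)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            settling_velocity(SettlingTrial(15.0, 0.0))


class TestStokes:
    @pytest.mark.parametrize(
        "u, d, expected",
        [(201.0, 2.4, 0.8), (144.0, 2.4, 0.6)],
    )
    def test_excess_density_table_means(self, u, d, expected):
        """Mean settling velocities and diameters reproduce the reported Δρ."""
        assert round(excess_density(u, d), 1) == expected

    def test_zero_velocity_gives_zero_excess_density(self):
        assert excess_density(0.0, 2.4) == 0.0

    def test_stokes_round_trip(self):
        """Δρ → implied Stokes velocity reproduces the input U exactly."""
        u = 201.0
        drho = excess_density(u, 2.4)
        assert stokes_velocity(drho, 2.4) == pytest.approx(u, rel=1e-9)

    @pytest.mark.parametrize(
        "drho, rho_s, expected",
        [(0.6, 1.258, 0.9995), (1.3, 1.284, 0.9990)],
    )
    def test_porosity_worked_examples(self, drho, rho_s, expected):
        assert round(porosity(drho, rho_s), 4) == expected

    def test_porosity_boundary_and_error(self):
        assert porosity(0.0, 1.258) == 1.0
        with pytest.raises(ValueError):
            porosity(1300.0, 1.2)  # Δρ above ρs: φ < 0 impossible

    def test_reynolds_worked_example_and_linearity(self):
        re = reynolds(2.4, 201.0)
        assert re == pytest.approx(5.15, abs=0.01)
        assert reynolds(2.4, 0.0) == 0.0
        assert reynolds(2.4, 402.0) == pytest.approx(2 * re)

    def test_drag_coefficient(self):
        assert drag_coefficient(1.0) == pytest.approx(24 + 3 + 0.4)
        assert drag_coefficient(5.15) == pytest.approx(6.90, abs=0.01)
        assert drag_coefficient(1e6) == pytest.approx(0.4, abs=0.01)
        with pytest.raises(ValueError):
            drag_coefficient(0.0)


def _normal_equations_loglog(d, u):
    """Independent OLS oracle: solve X'Xb = X'y on log10-transformed data."""
    x, y = np.log10(d), np.log10(u)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return 10.0 ** beta[0], beta[1]


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        d = np.linspace(0.5, 5.0, 20)
        fit = fit_power_law(d, 2.0 * d**1.5)
        assert fit.a == pytest.approx(2.0, rel=1e-12)
        assert fit.b == pytest.approx(1.5, rel=1e-12)

    def test_constant_velocity_gives_zero_exponent(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_power_law(d, np.full(4, 7.0))
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_loglog_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0.5, 5.0, 40)
        u = 3.0 * d**1.4 * rng.lognormal(0.0, 0.2, 40)
        fit = fit_power_law(d, u)
        a_ref, b_ref = _normal_equations_loglog(d, u)
        assert fit.a == pytest.approx(a_ref, rel=1e-10)
        assert fit.b == pytest.approx(b_ref, rel=1e-10)

    def test_nonlinear_ls_improves_natural_space_ss(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(1.0, 5.0, 30)
        u = 50.0 * d**1.37 + rng.normal(0.0, 10.0, 30)
        u = np.abs(u)
        nl = fit_power_law(d, u, method="nonlinear_ls")
        ols = fit_power_law(d, u, method="loglog_ols")
        ss_ols_natural = float(np.sum((u - ols.predict(d)) ** 2))
        assert nl.residual_ss <= ss_ols_natural + 1e-9

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0, 3.0], [1.0, -2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0], [1.0, 2.0])


class TestFractalDimension:
    def test_noiseless_slopes(self):
        d = np.geomspace(0.5, 5.0, 12)
        assert fractal_dimension(d, 60 * d**1.37).d3 == pytest.approx(2.37, abs=1e-9)
        assert fractal_dimension(d, np.full(12, 100.0)).d3 == pytest.approx(1.0, abs=1e-9)
        assert fractal_dimension(d, 10 * d**2).d3 == pytest.approx(3.0, abs=1e-9)

    def test_scale_invariance(self):
        """Rescaling d by c and U by c^b leaves D3 unchanged."""
        rng = np.random.default_rng(11)
        d = rng.uniform(1.0, 5.0, 30)
        u = 40 * d**1.5 * rng.lognormal(0, 0.1, 30)
        base = fractal_dimension(d, u).d3
        b = 1.5
        for c in (0.1, 3.0, 10.0):
            assert fractal_dimension(c * d, c**b * u).d3 == pytest.approx(base, rel=1e-9)


class TestCompareFits:
    def test_identical_groups_not_different(self):
        d = np.geomspace(1.0, 5.0, 12)
        u = 60 * d**1.37 * np.random.default_rng(0).lognormal(0, 0.1, 12)
        res = compare_fits((d, u), (d, u))
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_ss_never_below_separate(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            d1 = rng.uniform(1, 5, 10)
            d2 = rng.uniform(1, 5, 10)
            u1 = 50 * d1**1.3 * rng.lognormal(0, 0.3, 10)
            u2 = 40 * d2**1.7 * rng.lognormal(0, 0.3, 10)
            res = compare_fits((d1, u1), (d2, u2))
            assert res.ss_pooled >= res.ss_separate - 1e-12

    def test_power_to_separate_treatment_exponents(self):
        """Exponents 1.37 vs 1.64 at n=12 each and low noise are detected
        (p < 0.05) in at least 90% of 100 simulations."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d1, d2 = rng.uniform(1.1, 4.9, 12), rng.uniform(1.1, 4.9, 12)
            u1 = 60 * d1**1.37 * rng.lognormal(0, 0.05, 12)
            u2 = 34 * d2**1.64 * rng.lognormal(0, 0.05, 12)
            if compare_fits((d1, u1), (d2, u2)).p_value < 0.05:
                hits += 1
        assert hits >= 90

    def test_reported_degrees_of_freedom(self):
        d = np.geomspace(1, 5, 12)
        rng = np.random.default_rng(1)
        res = compare_fits(
            (d, 60 * d**1.37 * rng.lognormal(0, 0.1, 12)),
            (d, 34 * d**1.64 * rng.lognormal(0, 0.1, 12)),
        )
        assert (res.df_num, res.df_den) == (2, 20)


class TestDensityGradient:
    def test_measured_layer_density_returned(self):
        grad = DensityGradient()
        assert assign_density_layer(3, grad, measured_layer_density=1.284) == 1.284
        assert assign_density_layer(2, grad, measured_layer_density=1.251) == 1.251

    def test_nominal_density_fallback(self):
        grad = DensityGradient()
        assert assign_density_layer(0, grad) == grad.layer_densities[0]

    def test_item_below_densest_layer_flagged(self):
        with pytest.raises(GradientExceededError):
            assign_density_layer(6, DensityGradient())

    def test_gradient_must_increase(self):
        with pytest.raises(ValueError):
            DensityGradient(layer_densities=(1.3, 1.2))
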