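"""Settling physics and aggregate structure.

Single sinking aggregates are characterised by their equivalent circular
diameter *d*, settling velocity *U*, and a set of quantities derived from
Stokes' law:

* excess density        Δρ = 18 U ν / (g d²)        (cgs, reported mg cm⁻³)
* porosity              φ  = 1 − Δρ / ρ_s
* Reynolds number       Re = d U / ν
* drag coefficient      C_D = 24/Re + 6/(1 + √Re) + 0.4
* fractal dimension     U ∝ d^(D₃ − 1), D₃ = log–log slope + 1

Settling velocities come from timed settling trials over a fixed distance;
the solid hydrated density ρ_s is read off a density gradient. Power-law
size~velocity fits can be made in log space (OLS, the estimator behind D₃)
or by nonlinear least squares for display purposes, and two treatments'
fits are compared with an extra-sum-of-squares F-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .constants import CM_S_TO_M_D, MM_TO_CM, DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "DensityGradient",
    "GradientExceededError",
    "PowerLawFit",
    "SettlingTrial",
    "assign_density_layer",
    "compare_fits",
    "drag_coefficient",
    "ecd_from_area",
    "excess_density",
    "fit_power_law",
    "fractal_dimension",
    "porosity",
    "reynolds",
    "settling_velocity",
    "sphere_volume",
    "stokes_velocity",
]


# ---------------------------------------------------------------------------
# geometry


def ecd_from_area(area):
    """Equivalent circular diameter from a cross-sectional area.

    d = 2 √(A/π), in whatever length unit ``area`` is squared in.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    out = 2.0 * np.sqrt(area / np.pi)
    return out.item() if out.ndim == 0 else out


def sphere_volume(d):
    """Volume of a sphere of diameter ``d``: (π/6) d³."""
    d = np.asarray(d, dtype=float)
    out = (np.pi / 6.0) * d**3
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# settling trials


@dataclass(frozen=True)
class SettlingTrial:
    """One timed settling run: distance settled (cm) and elapsed time (s)."""

    distance_cm: float = 15.0
    time_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise ValueError("settling distance must be positive")


def settling_velocity(trial: SettlingTrial) -> float:
    """Settling velocity in m d⁻¹ from a stopwatch trial (distance/time)."""
    if not trial.time_s > 0:
        raise ValueError("settling time must be positive")
    return trial.distance_cm / trial.time_s * CM_S_TO_M_D


# ---------------------------------------------------------------------------
# Stokes-law quantities


def excess_density(
    velocity_m_d,
    diameter_mm,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Excess density Δρ (mg cm⁻³) from Stokes' law, Δρ = 18 U ν / (g d²).

    Parameters are in field units (m d⁻¹, mm); the computation is cgs.
    """
    u = np.asarray(velocity_m_d, dtype=float) / CM_S_TO_M_D
    d = np.asarray(diameter_mm, dtype=float) * MM_TO_CM
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    if np.any(u < 0):
        raise ValueError("settling velocity must be non-negative")
    drho_g = 18.0 * u * constants.kinematic_viscosity / (constants.gravity * d**2)
    out = drho_g * 1000.0  # g cm⁻³ -> mg cm⁻³
    return out.item() if out.ndim == 0 else out


def stokes_velocity(
    excess_density_mg_cm3,
    diameter_mm,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Invert Stokes' law: U (m d⁻¹) implied by Δρ (mg cm⁻³) and d (mm)."""
    drho = np.asarray(excess_density_mg_cm3, dtype=float) / 1000.0
    d = np.asarray(diameter_mm, dtype=float) * MM_TO_CM
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    u = drho * constants.gravity * d**2 / (18.0 * constants.kinematic_viscosity)
    out = u * CM_S_TO_M_D
    return out.item() if out.ndim == 0 else out


def porosity(excess_density_mg_cm3, solid_density_g_cm3):
    """Porosity φ = 1 − Δρ/ρ_s.

    Δρ is given in mg cm⁻³ (as reported), ρ_s in g cm⁻³; the mg→g
    conversion happens here. The aggregate volume cancels algebraically.
    """
    drho = np.asarray(excess_density_mg_cm3, dtype=float) / 1000.0
    rho_s = np.asarray(solid_density_g_cm3, dtype=float)
    if np.any(drho < 0):
        raise ValueError("excess density must be non-negative")
    if np.any(rho_s <= 0):
        raise ValueError("solid density must be positive")
    if np.any(drho > rho_s):
        raise ValueError("excess density exceeds solid density (porosity < 0)")
    out = 1.0 - drho / rho_s
    return out.item() if out.ndim == 0 else out


def reynolds(
    diameter_mm,
    velocity_m_d,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Particle Reynolds number Re = d U / ν (cgs-converted inputs)."""
    d = np.asarray(diameter_mm, dtype=float) * MM_TO_CM
    u = np.asarray(velocity_m_d, dtype=float) / CM_S_TO_M_D
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = d * u / constants.kinematic_viscosity
    return out.item() if out.ndim == 0 else out


def drag_coefficient(re):
    """Empirical drag coefficient C_D = 24/Re + 6/(1 + Re^0.5) + 0.4."""
    re = np.asarray(re, dtype=float)
    if np.any(re <= 0):
        raise ValueError("Reynolds number must be positive")
    out = 24.0 / re + 6.0 / (1.0 + np.sqrt(re)) + 0.4
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# density gradient


class GradientExceededError(ValueError):
    """Raised when an item settled below the densest gradient layer."""


@dataclass(frozen=True)
class DensityGradient:
    """Ascending densities (g cm⁻³) of the viscous gradient layers, top→bottom."""

    layer_densities: tuple = (1.18, 1.22, 1.26, 1.30, 1.34, 1.38)

    def __post_init__(self) -> None:
        dens = tuple(float(x) for x in self.layer_densities)
        if len(dens) < 1 or any(b <= a for a, b in zip(dens, dens[1:])):
            raise ValueError("layer densities must be strictly increasing")
        object.__setattr__(self, "layer_densities", dens)

    def __len__(self) -> int:
        return len(self.layer_densities)


def assign_density_layer(
    layer_index: int,
    gradient: DensityGradient,
    measured_layer_density: float | None = None,
) -> float:
    """Mass density of an item that settled into ``layer_index`` (0-based).

    Returns the layer's measured density if one was recorded (the density
    meter reading of the sub-sampled layer), else the gradient's nominal
    density for that layer. An index beyond the densest layer means the item
    sank through the whole gradient and its density exceeds the gradient.
    """
    if layer_index < 0:
        raise ValueError("layer index must be non-negative")
    if layer_index >= len(gradient):
        raise GradientExceededError(
            f"item settled below layer {len(gradient) - 1}: density exceeds gradient"
        )
    if measured_layer_density is not None:
        if measured_layer_density <= 0:
            raise ValueError("measured layer density must be positive")
        return float(measured_layer_density)
    return gradient.layer_densities[layer_index]


# ---------------------------------------------------------------------------
# power-law fits


@dataclass(frozen=True)
class PowerLawFit:
    """U = a·d^b fit summary.

    ``residual_ss`` is the residual sum of squares in the fitting space:
    log₁₀ units for ``loglog_ols``, natural units for ``nonlinear_ls``.
    ``stderr_b`` is the OLS standard error of the exponent (log fits only).
    """

    a: float
    b: float
    residual_ss: float
    n: int
    method: str
    stderr_b: float = float("nan")

    def predict(self, d):
        d = np.asarray(d, dtype=float)
        out = self.a * d**self.b
        return out.item() if out.ndim == 0 else out


def _validate_fit_inputs(d, u) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float)
    u = np.asarray(u, dtype=float)
    if d.shape != u.shape or d.ndim != 1:
        raise ValueError("d and U must be 1-D arrays of equal length")
    if d.size < 3:
        raise ValueError("at least 3 points are required for a fit")
    if np.any(d <= 0) or np.any(u <= 0):
        raise ValueError("power-law fits require strictly positive data")
    return d, u


def fit_power_law(
    d: Sequence[float],
    u: Sequence[float],
    method: Literal["loglog_ols", "nonlinear_ls"] = "loglog_ols",
) -> PowerLawFit:
    """Fit U = a·d^b.

    ``loglog_ols`` regresses log₁₀U on log₁₀d (the estimator used for the
    fractal dimension). ``nonlinear_ls`` minimises the untransformed sum of
    squares, initialised from the log fit (the display-curve convention).
    """
    d, u = _validate_fit_inputs(d, u)
    x, y = np.log10(d), np.log10(u)
    res = stats.linregress(x, y)
    a0, b0 = 10.0**res.intercept, res.slope
    if method == "loglog_ols":
        resid = y - (res.intercept + res.slope * x)
        return PowerLawFit(
            a=a0,
            b=b0,
            residual_ss=float(resid @ resid),
            n=d.size,
            method=method,
            stderr_b=float(res.stderr),
        )
    if method == "nonlinear_ls":
        popt, _ = optimize.curve_fit(
            lambda dd, a, b: a * dd**b, d, u, p0=[a0, b0], maxfev=10000
        )
        resid = u - popt[0] * d ** popt[1]
        return PowerLawFit(
            a=float(popt[0]),
            b=float(popt[1]),
            residual_ss=float(resid @ resid),
            n=d.size,
            method=method,
        )
    raise ValueError(f"unknown fit method {method!r}")


@dataclass(frozen=True)
class FractalDimensionResult:
    d3: float
    stderr: float
    fit: PowerLawFit = field(repr=False)


def fractal_dimension(d: Sequence[float], u: Sequence[float]) -> FractalDimensionResult:
    """Three-dimensional fractal number D₃ from U ∝ d^(D₃−1).

    D₃ is the slope of the log–log size~velocity regression plus one; its
    standard error is the OLS slope standard error. D₃ = 3 is a solid
    sphere, D₃ = 1 size-independent settling.
    """
    fit = fit_power_law(d, u, method="loglog_ols")
    return FractalDimensionResult(d3=fit.b + 1.0, stderr=fit.stderr_b, fit=fit)


@dataclass(frozen=True)
class FitComparison:
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    ss_pooled: float
    ss_separate: float


def compare_fits(
    group1: tuple[Sequence[float], Sequence[float]],
    group2: tuple[Sequence[float], Sequence[float]],
    method: Literal["loglog_ols", "nonlinear_ls"] = "loglog_ols",
) -> FitComparison:
    """Extra-sum-of-squares F-test: one pooled power curve vs. two curves.

    The null model fits a single U = a·d^b to both groups combined; the
    alternative fits each group separately (two extra parameters). Residual
    sums of squares are taken in the chosen fitting space.
    """
    (d1, u1), (d2, u2) = group1, group2
    fit1 = fit_power_law(d1, u1, method=method)
    fit2 = fit_power_law(d2, u2, method=method)
    pooled = fit_power_law(
        np.concatenate([np.asarray(d1, float), np.asarray(d2, float)]),
        np.concatenate([np.asarray(u1, float), np.asarray(u2, float)]),
        method=method,
    )
    ss_sep = fit1.residual_ss + fit2.residual_ss
    ss_pool = pooled.residual_ss
    n = fit1.n + fit2.n
    df_num = 2  # two extra parameters in the separate-curves model
    df_den = n - 4
    if df_den <= 0:
        raise ValueError("not enough points to compare fits")
    if ss_sep <= 0:
        raise ValueError("degenerate (perfect) separate fits; F undefined")
    f = ((ss_pool - ss_sep) / df_num) / (ss_sep / df_den)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df_num, df_den))
    return FitComparison(
        f_statistic=float(f),
        p_value=p,
        df_num=df_num,
        df_den=df_den,
        ss_pooled=float(ss_pool),
        ss_separate=float(ss_sep),
    )
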