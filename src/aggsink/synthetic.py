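"""Seeded synthetic-data generators.

Every input the analysis pipeline consumes can be simulated here with the
statistical structure the analysis assumes:

* aggregate populations with power-law (or log-uniform) size distributions
  and settling velocities U = a·d^(D₃−1)·ε, ε lognormal — so the log–log
  slope estimator targets a known fractal dimension;
* shadowgraph-style image stacks (dark discs on a light background, with
  optional illumination gradient and Gaussian noise) plus ground-truth
  detection tables;
* stained RGB micrographs with blue-dominant polymer particles and
  red-dominant cell bodies, exercising the channel-subtraction step;
* two-point O₂ drawdown assays with paired control vials;
* stopwatch settling trials;
* stage-structured cell censuses for the aggregate and ambient-water
  compartments, with stage-dependent, overdispersed bacterial loads.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import biophysics
from .census import CellCensus, INFECTED_STAGES, STAGES
from .constants import CM_S_TO_M_D, DEFAULT_CONSTANTS, PhysicalConstants, RESPIRATORY_QUOTIENT, CARBON_MOLAR_MASS

__all__ = [
    "CensusParams",
    "PopulationParams",
    "SceneParams",
    "generate_aggregate_population",
    "generate_cell_census",
    "generate_image_sequence",
    "generate_o2_assays",
    "generate_settling_trials",
    "generate_stained_micrograph",
    "match_detections_to_truth",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class PopulationParams:
    """Generating truth for a population of sinking aggregates.

    Settling follows U = velocity_scale_a · d^(D3_true − 1) · ε with ε
    lognormal (sd of ln ε = ``velocity_noise_sd``). Diameters are drawn
    from ``d_range`` (mm) either log-uniformly or from a power law with
    the given exponent. POC is proportional to the Stokes-implied solid
    volume V·(1 − φ).
    """

    n_aggregates: int = 12
    d_range: tuple = (1.1, 4.9)
    size_dist: Literal["power_law", "log_uniform"] = "log_uniform"
    power_exponent: float = -3.0
    D3_true: float = 2.37
    velocity_scale_a: float = 60.0  # m d⁻¹ at d = 1 mm
    velocity_noise_sd: float = 0.1
    mass_density: float = 1.284  # g cm⁻³ (solid hydrated density)
    poc_per_volume: float = 1480.0  # µg C per mm³ solid volume
    resp_rate: float = 0.16  # d⁻¹, carbon-specific
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_aggregates < 1:
            problems.append("n_aggregates must be at least 1")
        if not (0 < self.d_range[0] < self.d_range[1]):
            problems.append("d_range must be positive and increasing")
        if not (1.0 <= self.D3_true <= 3.0):
            problems.append("D3_true must lie in [1, 3]")
        if self.velocity_noise_sd < 0:
            problems.append("velocity_noise_sd must be non-negative")
        if self.velocity_scale_a <= 0:
            problems.append("velocity_scale_a must be positive")
        if self.mass_density <= 0:
            problems.append("mass_density must be positive")
        if self.poc_per_volume <= 0:
            problems.append("poc_per_volume must be positive")
        if self.resp_rate < 0:
            problems.append("resp_rate must be non-negative")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for synthetic frames.

    ``pixel_scale`` is length per pixel (mm px⁻¹ for shadowgraph frames,
    µm px⁻¹ for micrographs). Intensities are floats in [0, 1]; particles
    are darker than the background by ``blob_intensity``.
    """

    image_shape: tuple = (512, 512)
    pixel_scale: float = 0.04
    background: float = 0.8
    blob_intensity: float = 0.5
    background_gradient: float = 0.0
    noise_sd: float = 0.0
    channel_mode: Literal["shadowgraph_gray", "stained_rgb"] = "shadowgraph_gray"

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.noise_sd > 0 and self.blob_intensity <= 3 * self.noise_sd:
            logger.warning(
                "blob_intensity %.3g is not >3x noise_sd %.3g; detection may degrade",
                self.blob_intensity, self.noise_sd,
            )


@dataclass(frozen=True)
class CensusParams:
    """Generating truth for paired aggregate/ambient cell censuses.

    ``stage_mix`` is the ambient-water stage composition. In the aggregate
    compartment, infected-stage fractions are scaled by
    ``aggregate_enrichment`` (so the prevalence ratio equals the
    parameter) and the uninfected stages shrink to fill the remainder.
    Per-cell bacterial loads are negative binomial with stage-specific
    means and a common dispersion (smaller = wider).
    """

    n_cells: int = 10_000
    stage_mix: dict = field(
        default_factory=lambda: {
            "non": 0.55, "early": 0.08, "mature": 0.15, "post": 0.19, "decaying": 0.03,
        }
    )
    bacteria_mean_per_stage: dict = field(
        default_factory=lambda: {
            "non": 6.5, "early": 9.9, "mature": 9.6, "post": 16.1, "decaying": 24.2,
        }
    )
    bacteria_dispersion: float = 2.0
    aggregate_enrichment: float = 71.0 / 42.0
    seed: int = 0

    def __post_init__(self) -> None:
        mix = self.stage_mix
        if set(mix) != set(STAGES):
            raise ValueError(f"stage_mix must cover exactly the stages {STAGES}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("stage_mix must sum to 1")
        if any(v < 0 for v in mix.values()):
            raise ValueError("stage fractions must be non-negative")
        if any(v < 0 for v in self.bacteria_mean_per_stage.values()):
            raise ValueError("bacterial means must be non-negative")
        if self.bacteria_dispersion <= 0:
            raise ValueError("bacteria_dispersion must be positive")
        if self.aggregate_enrichment <= 0:
            raise ValueError("aggregate_enrichment must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")


# ---------------------------------------------------------------------------
# aggregate population


def _sample_diameters(params: PopulationParams, rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.d_range
    u = rng.random(params.n_aggregates)
    if params.size_dist == "log_uniform":
        return lo * (hi / lo) ** u
    if params.size_dist == "power_law":
        a = params.power_exponent
        if np.isclose(a, -1.0):
            return lo * (hi / lo) ** u
        lo_p, hi_p = lo ** (a + 1.0), hi ** (a + 1.0)
        return (lo_p + u * (hi_p - lo_p)) ** (1.0 / (a + 1.0))
    raise ValueError(f"unknown size distribution {params.size_dist!r}")


def generate_aggregate_population(
    params: PopulationParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Draw a population of aggregates with known generating truth.

    Each row carries the measured-equivalent quantities (d, A, V, U) and
    the derived ground truth (Δρ from Stokes, φ, Re, C_D, POC, k). The
    same seed yields an identical table.
    """
    rng = np.random.default_rng(params.seed)
    d = _sample_diameters(params, rng)
    eps = rng.lognormal(mean=0.0, sigma=params.velocity_noise_sd, size=d.size) \
        if params.velocity_noise_sd > 0 else np.ones_like(d)
    u = params.velocity_scale_a * d ** (params.D3_true - 1.0) * eps
    area = np.pi / 4.0 * d**2
    volume = biophysics.sphere_volume(d)
    drho = biophysics.excess_density(u, d, constants)
    phi = biophysics.porosity(drho, params.mass_density)
    solid_volume = volume * (1.0 - phi)
    poc = params.poc_per_volume * solid_volume
    re = biophysics.reynolds(d, u, constants)
    return pd.DataFrame(
        {
            "aggregate_id": np.arange(d.size),
            "d_mm": d,
            "area_mm2": area,
            "volume_mm3": volume,
            "u_m_d": u,
            "excess_density_mg_cm3": drho,
            "porosity": phi,
            "reynolds": re,
            "drag_coefficient": biophysics.drag_coefficient(re),
            "mass_density_g_cm3": np.full(d.size, params.mass_density),
            "poc_ug": poc,
            "resp_rate_per_day": np.full(d.size, params.resp_rate),
        }
    )


# ---------------------------------------------------------------------------
# image rendering


def _rasterize_disc(frame: np.ndarray, cy: float, cx: float, r_px: float, depth: float) -> int:
    """Darken pixels whose center lies inside the disc; return the pixel count."""
    r_int = int(np.ceil(r_px)) + 1
    y0, y1 = max(0, int(cy) - r_int), min(frame.shape[0], int(cy) + r_int + 1)
    x0, x1 = max(0, int(cx) - r_int), min(frame.shape[1], int(cx) + r_int + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    frame[y0:y1, x0:x1][inside] -= depth
    return int(inside.sum())


def _place_blobs(
    radii_px: np.ndarray,
    shape: tuple,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Random non-overlapping centers (rejection sampling), blobs fully in frame."""
    ys, xs = np.empty(radii_px.size), np.empty(radii_px.size)
    overlapped = False
    for i, r in enumerate(radii_px):
        ok = False
        for _ in range(max_tries):
            y = rng.uniform(r + 1, shape[0] - r - 1)
            x = rng.uniform(r + 1, shape[1] - r - 1)
            if all(
                (y - ys[j]) ** 2 + (x - xs[j]) ** 2 > (r + radii_px[j] + 2) ** 2
                for j in range(i)
            ):
                ok = True
                break
        if not ok:
            overlapped = True
        ys[i], xs[i] = y, x
    return ys, xs, overlapped


def generate_image_sequence(
    population: pd.DataFrame,
    scene: SceneParams,
    max_per_frame: int = 4,
    seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a population as a shadowgraph-style frame stack plus truth table.

    Aggregates are distributed over frames (at most ``max_per_frame`` per
    frame, placed without overlap), rendered as dark discs of the true
    cross-sectional radius. The truth table records, per aggregate, the
    frame, centroid, rasterized pixel area, and the scaled area/ECD. An
    empty population yields a single pure-background frame and an empty
    truth table.
    """
    rng = np.random.default_rng(seed)
    shape = scene.image_shape
    radii_px = population["d_mm"].to_numpy() / 2.0 / scene.pixel_scale if len(population) else np.array([])
    too_big = np.flatnonzero(2 * radii_px + 4 > min(shape))
    if too_big.size:
        bad = population.iloc[too_big[0]]
        raise ValueError(
            f"aggregate {int(bad['aggregate_id'])} (d = {bad['d_mm']:.3g} mm) "
            f"does not fit in a {shape} frame at {scene.pixel_scale} per px"
        )
    n = len(population)
    n_frames = max(1, int(np.ceil(n / max_per_frame)))
    frame_of = np.repeat(np.arange(n_frames), max_per_frame)[:n]

    stack = np.empty((n_frames, *shape), dtype=float)
    truth_rows = []
    for f in range(n_frames):
        frame = np.full(shape, scene.background, dtype=float)
        if scene.background_gradient:
            frame += scene.background_gradient * np.linspace(-0.5, 0.5, shape[1])[None, :]
        members = np.flatnonzero(frame_of == f)
        ys, xs, overlapped = _place_blobs(radii_px[members], shape, rng)
        if overlapped:
            logger.warning("frame %d: could not place all blobs without overlap", f)
        for (m, y, x) in zip(members, ys, xs):
            n_px = _rasterize_disc(frame, y, x, radii_px[m], scene.blob_intensity)
            area = n_px * scene.pixel_scale**2
            truth_rows.append(
                {
                    "aggregate_id": int(population["aggregate_id"].iloc[m]),
                    "frame": f,
                    "centroid_row": y,
                    "centroid_col": x,
                    "radius_px": radii_px[m],
                    "area_px": n_px,
                    "area": area,
                    "ecd": biophysics.ecd_from_area(area),
                }
            )
        if scene.noise_sd > 0:
            frame += rng.normal(0.0, scene.noise_sd, size=shape)
        stack[f] = frame
    truth = pd.DataFrame(
        truth_rows,
        columns=["aggregate_id", "frame", "centroid_row", "centroid_col",
                 "radius_px", "area_px", "area", "ecd"],
    )
    return stack, truth


def generate_stained_micrograph(
    n_polymer: int,
    n_cells: int,
    scene: SceneParams,
    polymer_radius_px: tuple = (4.0, 10.0),
    cell_radius_px: tuple = (4.0, 8.0),
    seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a stained-filter RGB micrograph plus truth table.

    Polymer particles are blue-dominant (R − B ≈ 0 after subtraction),
    cell bodies red-dominant (high R − B), and the background warm
    (intermediate R − B), so channel subtraction leaves polymer as the
    only dark phase. The truth table flags each blob as polymer or cell.
    """
    if scene.channel_mode != "stained_rgb":
        raise ValueError("generate_stained_micrograph requires channel_mode='stained_rgb'")
    rng = np.random.default_rng(seed)
    shape = scene.image_shape
    # warm background: R-B clearly positive but below the cell signal
    rgb = np.empty((*shape, 3), dtype=float)
    rgb[..., 0] = scene.background
    rgb[..., 1] = scene.background
    rgb[..., 2] = scene.background - 0.2
    radii = np.concatenate([
        rng.uniform(*polymer_radius_px, size=n_polymer),
        rng.uniform(*cell_radius_px, size=n_cells),
    ])
    kinds = ["polymer"] * n_polymer + ["cell"] * n_cells
    ys, xs, overlapped = _place_blobs(radii, shape, rng)
    if overlapped:
        logger.warning("stained micrograph: blob overlap exceeded the placement limit")
    rows = []
    for kind, y, x, r in zip(kinds, ys, xs, radii):
        if kind == "polymer":
            # blue-stained: depress R and G, keep B high
            n_px = _rasterize_disc(rgb[..., 0], y, x, r, scene.blob_intensity)
            _rasterize_disc(rgb[..., 1], y, x, r, scene.blob_intensity / 2.0)
        else:
            # chlorophyll-red: depress B and G, keep R high
            n_px = _rasterize_disc(rgb[..., 2], y, x, r, scene.blob_intensity)
            _rasterize_disc(rgb[..., 1], y, x, r, scene.blob_intensity / 2.0)
        area = n_px * scene.pixel_scale**2
        rows.append(
            {
                "kind": kind,
                "frame": 0,
                "centroid_row": y,
                "centroid_col": x,
                "radius_px": r,
                "area_px": n_px,
                "area": area,
                "ecd": biophysics.ecd_from_area(area),
            }
        )
    if scene.noise_sd > 0:
        rgb += rng.normal(0.0, scene.noise_sd, size=rgb.shape)
    truth = pd.DataFrame(rows, columns=["kind", "frame", "centroid_row", "centroid_col",
                                        "radius_px", "area_px", "area", "ecd"])
    return np.clip(rgb, 0.0, 1.0), truth


# ---------------------------------------------------------------------------
# assays, trials, censuses


def generate_o2_assays(
    population: pd.DataFrame,
    vial_volume_ml: float = 5.9,
    duration_h: float = 24.0,
    o2_start: float = 300.0,
    control_drift_frac: float = 0.0,
    noise_sd: float = 0.0,
    n_controls: int = 3,
    rq: float = RESPIRATORY_QUOTIENT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Forward-model two-point O₂ assays for each aggregate, plus controls.

    End O₂ = start − drawdown − drift + noise, where the drawdown follows
    the aggregate's carbon-specific rate k (CO₂ production k·POC/M_C,
    times RQ for O₂, accumulated over the incubation in the vial volume)
    and drift = ``control_drift_frac``·start affects all vials alike.
    Control vials carry drift (and noise) only. A drawdown exceeding the
    start concentration is an anoxia error.
    """
    if vial_volume_ml <= 0 or duration_h <= 0:
        raise ValueError("vial volume and duration must be positive")
    rng = np.random.default_rng(seed)
    duration_d = duration_h / 24.0
    vial_l = vial_volume_ml / 1000.0
    drift = control_drift_frac * o2_start
    rows = []
    for _, agg in population.iterrows():
        co2_umol_d = agg["resp_rate_per_day"] * agg["poc_ug"] / CARBON_MOLAR_MASS
        o2_umol_d = co2_umol_d * rq
        drawdown = o2_umol_d * duration_d / vial_l
        end = o2_start - drawdown - drift
        if end < 0:
            raise ValueError(
                f"aggregate {int(agg['aggregate_id'])}: O2 drawdown {drawdown:.1f} "
                f"µmol/L exceeds the start concentration (anoxia)"
            )
        rows.append(
            {
                "aggregate_id": int(agg["aggregate_id"]),
                "o2_start": o2_start,
                "o2_end": end + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
                "vial_volume_ml": vial_volume_ml,
                "duration_h": duration_h,
                "poc_ug": agg["poc_ug"],
                "is_control": False,
            }
        )
    for c in range(n_controls):
        rows.append(
            {
                "aggregate_id": -1 - c,
                "o2_start": o2_start,
                "o2_end": o2_start - drift + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
                "vial_volume_ml": vial_volume_ml,
                "duration_h": duration_h,
                "poc_ug": np.nan,
                "is_control": True,
            }
        )
    return pd.DataFrame(rows)


def generate_settling_trials(
    population: pd.DataFrame,
    distance_cm: float = 15.0,
    timing_noise_sd_s: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stopwatch settling trials: time = distance / U, plus truncated noise.

    Timing noise is Gaussian truncated so that every recorded time stays
    positive.
    """
    if distance_cm <= 0:
        raise ValueError("settling distance must be positive")
    rng = np.random.default_rng(seed)
    u_cm_s = population["u_m_d"].to_numpy() / CM_S_TO_M_D
    t0 = distance_cm / u_cm_s
    if timing_noise_sd_s > 0:
        noise = sps.truncnorm.rvs(
            a=-t0 / timing_noise_sd_s + 1e-9, b=np.inf,
            scale=timing_noise_sd_s, size=t0.size, random_state=rng,
        )
    else:
        noise = np.zeros_like(t0)
    return pd.DataFrame(
        {
            "aggregate_id": population["aggregate_id"].to_numpy(),
            "distance_cm": distance_cm,
            "time_s": t0 + noise,
        }
    )


def _aggregate_stage_mix(params: CensusParams) -> dict:
    """Aggregate-compartment stage mix under prevalence-ratio enrichment."""
    mix = params.stage_mix
    e = params.aggregate_enrichment
    p_inf = sum(mix[s] for s in INFECTED_STAGES)
    if e * p_inf > 1.0:
        raise ValueError(
            f"enrichment {e:.3g} with ambient prevalence {p_inf:.3g} "
            "would make uninfected fractions negative"
        )
    uninfected = [s for s in STAGES if s not in INFECTED_STAGES]
    p_non = sum(mix[s] for s in uninfected)
    scale_non = (1.0 - e * p_inf) / p_non if p_non > 0 else 0.0
    out = {}
    for s in STAGES:
        out[s] = mix[s] * (e if s in INFECTED_STAGES else scale_non)
    return out


def generate_cell_census(params: CensusParams) -> tuple[CellCensus, CellCensus]:
    """Paired (aggregate, ambient) censuses with overdispersed bacterial loads.

    Stage counts are multinomial; per-cell bacteria are negative binomial
    with the stage's mean and the common dispersion r (variance
    m + m²/r). The aggregate compartment's expected prevalence is
    ``aggregate_enrichment`` times the ambient prevalence.
    """
    rng = np.random.default_rng(params.seed)
    mixes = {"aggregate": _aggregate_stage_mix(params), "ambient": params.stage_mix}
    out = []
    for compartment in ("aggregate", "ambient"):
        mix = mixes[compartment]
        probs = np.array([mix[s] for s in STAGES])
        counts = rng.multinomial(params.n_cells, probs)
        bacteria = {}
        r = params.bacteria_dispersion
        for s, c in zip(STAGES, counts):
            m = params.bacteria_mean_per_stage[s]
            if c == 0:
                bacteria[s] = np.array([], dtype=int)
            elif m == 0:
                bacteria[s] = np.zeros(c, dtype=int)
            else:
                bacteria[s] = rng.negative_binomial(n=r, p=r / (r + m), size=c)
        out.append(
            CellCensus(
                counts={s: int(c) for s, c in zip(STAGES, counts)},
                bacteria=bacteria,
                compartment=compartment,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# truth matching


def match_detections_to_truth(
    truth: pd.DataFrame,
    detections: pd.DataFrame,
    max_distance_px: float = 5.0,
) -> pd.DataFrame:
    """Greedy nearest-centroid match of truth blobs to detections per frame.

    Returns the truth table with matched detection columns (NaN where a
    blob went undetected). Used by round-trip tests and recall/precision
    scoring.
    """
    rows = []
    for f, tgroup in truth.groupby("frame"):
        dgroup = detections[detections["frame"] == f]
        dpos = dgroup[["centroid_row", "centroid_col"]].to_numpy()
        taken: set = set()
        for _, t in tgroup.iterrows():
            row = dict(t)
            row["det_area"] = np.nan
            row["det_ecd"] = np.nan
            if len(dgroup):
                dist = np.hypot(dpos[:, 0] - t["centroid_row"],
                                dpos[:, 1] - t["centroid_col"])
                order = np.argsort(dist)
                for k in order:
                    if k in taken:
                        continue
                    if dist[k] <= max_distance_px + t["radius_px"]:
                        taken.add(k)
                        row["det_area"] = dgroup["area"].iloc[k]
                        row["det_ecd"] = dgroup["ecd"].iloc[k]
                    break
            rows.append(row)
    return pd.DataFrame(rows)
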