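"""Image-based particle quantification.

Reimplements the ImageJ-style workflow used for both stained-polymer
micrographs (TEP/CSP on filters) and shadowgraph frames of suspended
aggregates:

    flatten background → (R − B channel subtraction for RGB) →
    invert + global threshold → connected-component measurement →
    size filter → concentration conversion

Particles are reported by cross-sectional area A and equivalent circular
diameter ECD = 2√(A/π). The pipeline order is fixed; each step is also
exposed separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from skimage import filters, measure, segmentation

from .biophysics import ecd_from_area

__all__ = [
    "ImagingConfig",
    "analyze_image",
    "analyze_stack",
    "binarize",
    "extract_particles",
    "filter_particles",
    "flatten_background",
    "subtract_channels",
    "to_concentration",
]

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["id", "frame", "area", "ecd", "centroid_row", "centroid_col"]


@dataclass(frozen=True)
class ImagingConfig:
    """Configuration of the particle-analysis pipeline.

    ``pixel_scale`` is length per pixel in ``unit``; areas come out in
    ``unit``². The lower ECD cutoff is a closed bound: a particle exactly at
    ``min_ecd`` is kept (particles *below* the cutoff are excluded).
    For filter micrographs, ``imaged_area_fraction`` is the
    fraction of the filter covered by the imaged fields and
    ``filtered_volume_ml`` the volume drawn through the filter; for
    suspension imaging ``imaged_volume_l`` is the optically sampled volume.

    With ``threshold_method='fixed'``, ``threshold`` is in original
    intensity units: pixels darker than it are foreground (equivalent to
    inverting and thresholding, but stable across frames whose maxima
    differ).
    """

    pixel_scale: float = 1.0
    unit: str = "um"
    threshold_method: Literal["otsu", "fixed"] = "otsu"
    threshold: float | None = None
    min_ecd: float = 0.0
    max_ecd: float | None = None
    connectivity: Literal[4, 8] = 8
    exclude_border: bool = False
    imaged_volume_l: float | None = None
    imaged_area_fraction: float | None = None
    filtered_volume_ml: float | None = None
    flatten_degree: int = 2
    smooth_sigma: float = 0.0  # Gaussian denoise before thresholding; 0 = off

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.min_ecd < 0:
            raise ValueError("min_ecd must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_method == "fixed" and self.threshold is None:
            raise ValueError("fixed threshold_method requires a threshold value")


def flatten_background(image: np.ndarray, degree: int = 2) -> np.ndarray:
    """Remove low-frequency illumination, preserving the mean intensity.

    The background is modelled as a low-order (default quadratic)
    polynomial surface fitted to the whole frame by least squares and
    subtracted; the original mean is restored exactly. Unlike a blur-based
    estimate, the surface cannot dent locally around dark particles, so no
    halo artefacts are introduced. A constant image is returned unchanged.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("flatten_background expects a single-channel image")
    if degree < 1:
        raise ValueError("degree must be at least 1")
    if np.ptp(img) == 0:
        return img.copy()
    ny, nx = img.shape
    y = np.linspace(-1.0, 1.0, ny)[:, None]
    x = np.linspace(-1.0, 1.0, nx)[None, :]
    terms = [np.ones_like(img)]
    for total in range(1, degree + 1):
        for py in range(total + 1):
            terms.append((y**py * x ** (total - py)) * np.ones_like(img))
    A = np.stack([t.ravel() for t in terms], axis=1)
    coef, *_ = np.linalg.lstsq(A, img.ravel(), rcond=None)
    bg = (A @ coef).reshape(img.shape)
    out = img - bg
    out += img.mean() - out.mean()
    return out


def subtract_channels(rgb_image: np.ndarray) -> np.ndarray:
    """Pixelwise max(R − B, 0).

    Removes chlorophyll-related (red-dominant) areas from stained-filter
    micrographs, leaving blue-stained polymer darker than the background.
    """
    img = np.asarray(rgb_image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("subtract_channels expects an RGB (…, 3) image")
    return np.clip(img[..., 0] - img[..., 2], 0.0, None)


def binarize(image: np.ndarray, config: ImagingConfig) -> np.ndarray:
    """Invert then apply one global threshold; foreground = particles.

    Particles are darker than the background, so the image is reversed and
    pixels above one global threshold become foreground. Otsu runs on the
    inverted image (shift-equivariant, so masks are invariant to adding a
    constant); a fixed threshold is given in original intensity units and
    keeps pixels darker than it. Otsu on a single-valued image is an
    explicit error rather than a silent empty mask.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("binarize expects a single-channel image")
    if config.threshold_method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("degenerate single-valued image: Otsu threshold undefined")
        inverted = img.max() - img
        thresh = filters.threshold_otsu(inverted)
        logger.debug("Otsu threshold (inverted space): %.6g", thresh)
        return inverted > thresh
    if config.threshold_method == "fixed":
        thresh = float(config.threshold)
        logger.debug("fixed threshold (original space): %.6g", thresh)
        return img < thresh
    raise ValueError(f"unknown threshold method {config.threshold_method!r}")  # pragma: no cover


def extract_particles(
    mask: np.ndarray,
    config: ImagingConfig,
    frame: int = 0,
) -> pd.DataFrame:
    """Measure connected components of a binary mask.

    A = pixel count · pixel_scale²; ECD = 2√(A/π). Centroids are in pixel
    coordinates (row, col).
    """
    mask = np.asarray(mask, dtype=bool)
    if config.exclude_border:
        mask = segmentation.clear_border(mask)
    conn = 1 if config.connectivity == 4 else 2
    labels = measure.label(mask, connectivity=conn)
    props = measure.regionprops(labels)
    rows = []
    for i, p in enumerate(props):
        area = p.area * config.pixel_scale**2
        rows.append(
            {
                "id": i,
                "frame": frame,
                "area": area,
                "ecd": ecd_from_area(area),
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
            }
        )
    out = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    out.attrs["unit"] = config.unit
    return out


def filter_particles(detections: pd.DataFrame, config: ImagingConfig) -> pd.DataFrame:
    """Apply the ECD size window: keep min_ecd ≤ ECD (≤ max_ecd). Idempotent."""
    unit = detections.attrs.get("unit")
    if unit is not None and unit != config.unit:
        raise ValueError(f"unit mismatch: detections in {unit!r}, config in {config.unit!r}")
    keep = detections["ecd"] >= config.min_ecd
    if config.max_ecd is not None:
        keep &= detections["ecd"] <= config.max_ecd
    out = detections.loc[keep].reset_index(drop=True)
    out.attrs.update(detections.attrs)
    return out


def to_concentration(count: int, config: ImagingConfig) -> float:
    """Particle count → concentration.

    Suspension imaging: count / imaged_volume_l (# L⁻¹). Filter
    micrographs: the imaged fields cover ``imaged_area_fraction`` of the
    filter, so the whole-filter count is count / fraction, divided by the
    filtered volume (# mL⁻¹).
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if config.imaged_volume_l is not None:
        if config.imaged_volume_l <= 0:
            raise ValueError("imaged volume must be positive")
        return count / config.imaged_volume_l
    if config.filtered_volume_ml is not None:
        if config.filtered_volume_ml <= 0:
            raise ValueError("filtered volume must be positive")
        if not config.imaged_area_fraction or config.imaged_area_fraction <= 0:
            raise ValueError("filter micrographs require a positive imaged_area_fraction")
        return count / config.imaged_area_fraction / config.filtered_volume_ml
    raise ValueError("config declares neither imaged_volume_l nor filtered_volume_ml")


def analyze_image(
    image: np.ndarray,
    config: ImagingConfig,
    frame: int = 0,
) -> pd.DataFrame:
    """Run the fixed pipeline on one frame: flatten → [R−B] → binarize → extract → filter."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = subtract_channels(img)
    img = flatten_background(img, degree=config.flatten_degree)
    if config.smooth_sigma > 0:
        img = filters.gaussian(img, sigma=config.smooth_sigma, preserve_range=True)
    mask = binarize(img, config)
    det = extract_particles(mask, config, frame=frame)
    return filter_particles(det, config)


def analyze_stack(stack: Iterable[np.ndarray], config: ImagingConfig) -> pd.DataFrame:
    """Analyze a sequence of frames; detection ids are unique across frames."""
    frames = []
    offset = 0
    for k, image in enumerate(stack):
        det = analyze_image(image, config, frame=k)
        det["id"] += offset
        offset += len(det)
        frames.append(det)
    if not frames:
        out = pd.DataFrame(columns=DETECTION_COLUMNS)
    else:
        out = pd.concat(frames, ignore_index=True)
    out.attrs["unit"] = config.unit
    return out
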