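"""Aggregate size spectra.

Detections (equivalent circular diameters, mm) are binned into geometric
size classes whose upper edge is a fixed ratio (default 1.3) times the
lower edge. Per bin:

* N(d)  — number concentration, # L⁻¹
* n(d)  — size spectrum, N(d)/Δd, # L⁻¹ mm⁻¹
* nVd   — volume spectrum, n(d) · V_agg · Δd, mm³ L⁻¹

where Δd is the bin width and V_agg the mean volume of single aggregates
in that bin (from the bin's empirical members, assuming spherical
geometry). Empty bins plot as log₁₀ = −1.0 by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biophysics import sphere_volume

__all__ = [
    "SizeBinGrid",
    "build_bins",
    "cumulative_volume",
    "log_transform_spectrum",
    "number_spectrum",
    "size_spectrum",
    "volume_spectrum",
]

logger = logging.getLogger(__name__)

#: Sentinel for log₁₀ of an empty bin.
LOG_EMPTY_SENTINEL = -1.0


@dataclass(frozen=True)
class SizeBinGrid:
    """Contiguous geometric size classes (mm)."""

    edges: tuple  # n_bins + 1 strictly increasing edges
    ratio: float

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] <= 0:
            raise ValueError("bin edges must be positive")
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def lower_edges(self) -> np.ndarray:
        return np.asarray(self.edges[:-1])

    @property
    def upper_edges(self) -> np.ndarray:
        return np.asarray(self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        """Δd per bin, from the exact (unrounded) edges."""
        return self.upper_edges - self.lower_edges


def build_bins(lower_anchor: float = 0.35, ratio: float = 1.3, n_bins: int = 11) -> SizeBinGrid:
    """Geometric grid: edges lower_anchor·ratio^k, k = 0…n_bins.

    The default anchors the smallest class at 0.35–0.46 mm and spans eleven
    classes up to 6.27 mm.
    """
    if lower_anchor <= 0:
        raise ValueError("lower_anchor must be positive")
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    edges = lower_anchor * ratio ** np.arange(n_bins + 1)
    return SizeBinGrid(edges=tuple(edges), ratio=ratio)


def number_spectrum(
    ecd_mm,
    bins: SizeBinGrid,
    sample_volume_l: float,
) -> pd.DataFrame:
    """Bin detections and compute N(d) and n(d) = N(d)/Δd.

    Bin membership is lower-closed/upper-open. Detections outside every bin
    are counted, logged, and recorded in ``DataFrame.attrs['n_out_of_range']``
    — never silently dropped. The mean single-aggregate volume per bin
    (``v_agg_mm3``) is carried along for the volume spectrum.
    """
    if sample_volume_l <= 0:
        raise ValueError("sample volume must be positive")
    ecd = np.asarray(ecd_mm, dtype=float)
    edges = np.asarray(bins.edges)
    idx = np.searchsorted(edges, ecd, side="right") - 1
    in_range = (idx >= 0) & (idx < bins.n_bins)
    n_out = int((~in_range).sum())
    if n_out:
        logger.warning("%d detections outside the bin grid (%.3g–%.3g mm)",
                       n_out, edges[0], edges[-1])
    counts = np.bincount(idx[in_range], minlength=bins.n_bins)
    v = sphere_volume(ecd)
    v_sums = np.bincount(idx[in_range], weights=np.asarray(v)[in_range],
                         minlength=bins.n_bins)
    with np.errstate(invalid="ignore"):
        v_agg = np.where(counts > 0, v_sums / np.maximum(counts, 1), 0.0)
    widths = bins.widths
    table = pd.DataFrame(
        {
            "d_lower_mm": bins.lower_edges,
            "d_upper_mm": bins.upper_edges,
            "delta_d_mm": widths,
            "count": counts,
            "N_per_l": counts / sample_volume_l,
            "n_per_l_mm": counts / sample_volume_l / widths,
            "v_agg_mm3": v_agg,
        }
    )
    table.attrs["sample_volume_l"] = float(sample_volume_l)
    table.attrs["n_out_of_range"] = n_out
    return table


def volume_spectrum(spectrum: pd.DataFrame, bins: SizeBinGrid) -> pd.DataFrame:
    """Add the volume spectrum nVd = n(d) · V_agg · Δd to a number spectrum."""
    if len(spectrum) != bins.n_bins:
        raise ValueError("spectrum table does not match the bin grid")
    out = spectrum.copy()
    out["nVd_mm3_l"] = out["n_per_l_mm"] * out["v_agg_mm3"] * out["delta_d_mm"]
    out.attrs.update(spectrum.attrs)
    return out


def size_spectrum(ecd_mm, bins: SizeBinGrid, sample_volume_l: float) -> pd.DataFrame:
    """Number + volume spectrum in one call."""
    return volume_spectrum(number_spectrum(ecd_mm, bins, sample_volume_l), bins)


def log_transform_spectrum(values):
    """log₁₀ of spectrum values with the empty-bin sentinel.

    Zeros map to exactly −1.0 (the plotting convention for absent size
    classes); negative values are an error.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("spectrum values must be non-negative")
    out = np.full(x.shape, LOG_EMPTY_SENTINEL)
    pos = x > 0
    out[pos] = np.log10(x[pos])
    return out.item() if out.ndim == 0 else out


def cumulative_volume(ecd_mm, sample_volume_l: float) -> float:
    """Cumulative aggregate volume concentration, Σ (π/6)·ECD³ / volume (mm³ L⁻¹)."""
    if sample_volume_l <= 0:
        raise ValueError("sample volume must be positive")
    ecd = np.asarray(ecd_mm, dtype=float)
    if ecd.size == 0:
        return 0.0
    return float(np.sum(sphere_volume(ecd)) / sample_volume_l)
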