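"""Trilinear decomposition of large-strain load-displacement branches.

A 40%-strain shear loop leaves the low-stiffness neutral zone (NZ) and
enters stiffer compressive (CZ) and tensile (TZ) shear zones.  The NZ
borders are located at the extrema of the second derivative of load with
respect to displacement (the points of maximal compliance change): the
curve is resampled onto a uniform displacement grid, smoothed and
differentiated with a Savitzky-Golay filter (order 3, window defaulting to
10% of the resampled branch — wide enough that second-derivative extrema
survive load-cell noise), the extrema are searched within the central 80%
of the sweep to avoid end-ramp artifacts, and an OLS line is fitted within
each zone excluding a one-window guard band around each border.  Loading
and unloading branches are fitted separately and never averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .types import Geometry
from .waveform import WaveformRecord

__all__ = ["TrilinearFit", "DegenerateFitError", "trilinear_fit", "fit_cycle"]


class DegenerateFitError(ValueError):
    """The branch shows no usable compliance change (e.g., a straight line)."""


@dataclass(frozen=True)
class TrilinearFit:
    nz_stiffness_n_mm: float
    cz_stiffness_n_mm: float
    tz_stiffness_n_mm: float
    breakpoint_low_mm: float
    breakpoint_high_mm: float
    nz_length_mm: float
    r_squared: tuple[float, float, float]  # (CZ, NZ, TZ) zone fits
    curve: str = "loading"

    def stiffness_kpa(self, geometry: Geometry) -> tuple[float, float, float]:
        """Zone stiffnesses as shear moduli (kPa) under the nominal geometry."""
        scale = geometry.height_mm / geometry.area_mm2 * 1000.0
        return (
            self.nz_stiffness_n_mm * scale,
            self.cz_stiffness_n_mm * scale,
            self.tz_stiffness_n_mm * scale,
        )

    def nz_length_strain_pct(self, geometry: Geometry) -> float:
        return self.nz_length_mm / geometry.height_mm * 100.0


def _zone_slope(x: np.ndarray, f: np.ndarray, lo: float, hi: float):
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 3:
        raise DegenerateFitError("zone contains too few samples for a line fit")
    fit = linregress(x[mask], f[mask])
    return float(fit.slope), float(fit.rvalue**2)


def trilinear_fit(
    displacement_mm: np.ndarray,
    load_n: np.ndarray,
    smooth_frac: float = 0.10,
    polyorder: int = 3,
    central_frac: float = 0.8,
    n_grid: int = 601,
    curve: str = "loading",
    min_curvature_ratio: float = 0.05,
) -> TrilinearFit:
    """Fit NZ/CZ/TZ lines to one monotone load-displacement branch.

    ``min_curvature_ratio`` is the degeneracy gate: the slope change implied
    by the second-derivative extrema must exceed this fraction of the mean
    absolute slope, otherwise the branch is effectively linear and a
    :class:`DegenerateFitError` is raised.
    """
    x = np.asarray(displacement_mm, dtype=float)
    f = np.asarray(load_n, dtype=float)
    if x.size < 20:
        raise ValueError("branch too short for a trilinear fit")
    order = np.argsort(x)
    x, f = x[order], f[order]
    xg = np.linspace(x[0], x[-1], n_grid)
    fg = np.interp(xg, x, f)
    dx = xg[1] - xg[0]
    window = int(round(smooth_frac * n_grid))
    window = max(window, polyorder + 2)
    if window % 2 == 0:
        window += 1
    fs = savgol_filter(fg, window, polyorder)
    d1 = savgol_filter(fg, window, polyorder, deriv=1, delta=dx)
    d2 = savgol_filter(fg, window, polyorder, deriv=2, delta=dx)

    span = xg[-1] - xg[0]
    margin = 0.5 * (1.0 - central_frac) * span
    central = (xg >= xg[0] + margin) & (xg <= xg[-1] - margin)
    idx_central = np.flatnonzero(central)
    d2c = d2[idx_central]
    i_max = idx_central[int(np.argmax(d2c))]
    i_min = idx_central[int(np.argmin(d2c))]
    if d2[i_max] <= 0 or d2[i_min] >= 0:
        raise DegenerateFitError(
            "second derivative lacks a sign-separated max/min pair"
        )
    # degeneracy gate: compliance change must be material, not smoothing noise
    slope_scale = float(np.mean(np.abs(d1))) + 1e-30
    guard = window * dx
    slope_change = (d2[i_max] - d2[i_min]) * guard
    if slope_change < min_curvature_ratio * slope_scale:
        raise DegenerateFitError(
            "no material compliance change detected (branch is nearly linear)"
        )
    bp_a, bp_b = xg[i_max], xg[i_min]
    bp_low, bp_high = (bp_a, bp_b) if bp_a < bp_b else (bp_b, bp_a)
    if bp_high - bp_low <= guard:
        raise DegenerateFitError("breakpoints are not separated beyond the guard band")

    cz_slope, cz_r2 = _zone_slope(xg, fs, xg[0], bp_low - guard)
    nz_slope, nz_r2 = _zone_slope(xg, fs, bp_low + guard, bp_high - guard)
    tz_slope, tz_r2 = _zone_slope(xg, fs, bp_high + guard, xg[-1])
    return TrilinearFit(
        nz_stiffness_n_mm=nz_slope,
        cz_stiffness_n_mm=cz_slope,
        tz_stiffness_n_mm=tz_slope,
        breakpoint_low_mm=float(bp_low),
        breakpoint_high_mm=float(bp_high),
        nz_length_mm=float(bp_high - bp_low),
        r_squared=(cz_r2, nz_r2, tz_r2),
        curve=curve,
    )


def fit_cycle(
    record: WaveformRecord, seg_label: str | None = None, **kwargs
) -> dict[str, TrilinearFit]:
    """Split one full cycle into loading/unloading branches and fit both.

    If ``seg_label`` is given, that segment's final cycle is used; otherwise
    the whole record is treated as one cycle.  The loading branch runs from
    the displacement minimum to the maximum.
    """
    if seg_label is not None:
        seg = record.segment(seg_label)
        fs = record.sampling_rate_hz
        n_period = int(round(fs / seg.frequency_hz)) if seg.frequency_hz else seg.n
        sl = np.s_[seg.end - n_period : seg.end]
        disp, load = record.displacement_mm[sl], record.load_n[sl]
    else:
        disp, load = record.displacement_mm, record.load_n
    i_min = int(np.argmin(disp))
    i_max = int(np.argmax(disp))
    order = np.arange(disp.size)
    # rotate the cycle so it starts at the displacement minimum
    rot = np.roll(order, -i_min)
    disp_r, load_r = disp[rot], load[rot]
    i_max_r = int(np.argmax(disp_r))
    fits = {}
    fits["loading"] = trilinear_fit(
        disp_r[: i_max_r + 1], load_r[: i_max_r + 1], curve="loading", **kwargs
    )
    fits["unloading"] = trilinear_fit(
        disp_r[i_max_r:], load_r[i_max_r:], curve="unloading", **kwargs
    )
    return fits
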