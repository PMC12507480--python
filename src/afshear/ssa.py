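"""Static shear analysis: per-step equilibrium stress, the static shear
modulus (slope of equilibrium stress vs. strain), and stress relaxation.

The staircase protocol applies equal unidirectional strain steps, each held
long enough for the tissue to relax.  "End of hold" values are trailing
means over a short window (10 s by default) to suppress load-cell noise;
equilibrium stresses are referenced to the end of the pre-step rest so any
residual offset cancels.  The modulus is the unconstrained OLS slope across
the step points, in kPa, with the intercept kept for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .waveform import ProtocolSegment, WaveformRecord

__all__ = [
    "SSAResult",
    "equilibrium_stress",
    "shear_modulus",
    "stress_relaxation",
    "analyze_ssa",
]


@dataclass(frozen=True)
class SSAResult:
    strain_levels: tuple[float, ...]  # net strain, dimensionless
    equilibrium_stress_kpa: tuple[float, ...]
    peak_stress_kpa: tuple[float, ...]
    relaxation_kpa: tuple[float, ...]
    modulus_kpa: float
    intercept_kpa: float
    r_squared: float


def _hold_segments(record: WaveformRecord) -> list[ProtocolSegment]:
    holds = [s for s in record.segments if s.label.endswith("-hold")]
    holds.sort(key=lambda s: s.start)
    return holds


def _ramp_for(record: WaveformRecord, hold: ProtocolSegment) -> ProtocolSegment | None:
    label = hold.label.replace("-hold", "-ramp")
    try:
        return record.segment(label)
    except KeyError:
        return None


def _trailing_mean(
    record: WaveformRecord, seg: ProtocolSegment, window_s: float
) -> float:
    fs = record.sampling_rate_hz
    n_win = int(round(window_s * fs))
    if n_win > seg.n:
        n_win = seg.n  # hold shorter than the averaging window: shrink
    return float(np.mean(record.load_n[seg.end - n_win : seg.end]))


def equilibrium_stress(
    record: WaveformRecord, window_s: float = 10.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-step equilibrium stresses referenced to the rest baseline.

    Returns ``(net_strains, equilibrium_stress_kpa, baseline_load_n)``.  The
    baseline is the trailing mean load of the rest segment; each step's
    equilibrium load is the trailing mean of its hold.
    """
    try:
        rest = record.segment("rest")
    except KeyError as exc:
        raise ValueError("record has no rest segment") from exc
    holds = _hold_segments(record)
    if not holds:
        raise ValueError("record has no step-hold segments")
    baseline = _trailing_mean(record, rest, window_s)
    area = record.geometry.area_mm2
    height = record.geometry.height_mm
    strains = []
    stresses = []
    for hold in holds:
        eq_load = _trailing_mean(record, hold, window_s)
        stresses.append((eq_load - baseline) / area * 1000.0)
        strains.append(float(np.mean(record.displacement_mm[hold.end - 5 : hold.end])) / height)
    return np.asarray(strains), np.asarray(stresses), baseline


def shear_modulus(
    equilibrium_stress_kpa: np.ndarray, strains: np.ndarray
) -> tuple[float, float, float]:
    """OLS slope of equilibrium stress on strain: ``(G_kpa, intercept, r2)``."""
    strains = np.asarray(strains, dtype=float)
    stress = np.asarray(equilibrium_stress_kpa, dtype=float)
    if strains.size < 2:
        raise ValueError("need at least two (strain, stress) points")
    fit = sstats.linregress(strains, stress)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def stress_relaxation(
    record: WaveformRecord, window_s: float = 10.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-step ``(net_strains, peak_stress, relaxation)`` in kPa.

    Peak stress is the maximum over ramp plus hold, relative to the rest
    baseline; relaxation is peak minus the end-of-hold equilibrium value.
    """
    try:
        rest = record.segment("rest")
        baseline = _trailing_mean(record, rest, window_s)
    except KeyError:
        baseline = 0.0
    holds = _hold_segments(record)
    if not holds:
        raise ValueError("record has no step-hold segments")
    area = record.geometry.area_mm2
    height = record.geometry.height_mm
    strains, peaks, relax = [], [], []
    for hold in holds:
        ramp = _ramp_for(record, hold)
        start = ramp.start if ramp is not None else hold.start
        peak_load = float(np.max(record.load_n[start : hold.end]))
        eq_load = _trailing_mean(record, hold, window_s)
        peaks.append((peak_load - baseline) / area * 1000.0)
        relax.append((peak_load - eq_load) / area * 1000.0)
        strains.append(float(np.mean(record.displacement_mm[hold.end - 5 : hold.end])) / height)
    return np.asarray(strains), np.asarray(peaks), np.asarray(relax)


def analyze_ssa(record: WaveformRecord, window_s: float = 10.0) -> SSAResult:
    """Full static analysis of one staircase recording."""
    strains, eq_stress, _ = equilibrium_stress(record, window_s)
    g, intercept, r2 = shear_modulus(eq_stress, strains)
    strains2, peaks, relax = stress_relaxation(record, window_s)
    return SSAResult(
        strain_levels=tuple(strains.tolist()),
        equilibrium_stress_kpa=tuple(eq_stress.tolist()),
        peak_stress_kpa=tuple(peaks.tolist()),
        relaxation_kpa=tuple(relax.tolist()),
        modulus_kpa=g,
        intercept_kpa=intercept,
        r_squared=r2,
    )
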