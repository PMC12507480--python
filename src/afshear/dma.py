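"""Dynamic shear analysis: hysteresis, FFT phase shift, and moduli.

Each frequency block is reduced to its final commanded period.  The phase
lag delta between load and displacement is read off the fundamental FFT bin
after DC balance (mean removal) and amplitude normalisation; stress and
strain amplitudes come from the same fundamental-bin magnitudes.  The
component moduli are then

    loss      = (sigma0 / eps0) * sin(delta)
    storage   = (sigma0 / eps0) * cos(delta)
    |G*|      = sqrt(storage^2 + loss^2) = sigma0 / eps0

Note on naming: the source equations for these quantities label the
sin-delta term G' and the cos-delta term G'', the reverse of the usual
prime convention.  Fields here are named by physical role (storage = in
phase, loss = quadrature); the arithmetic is identical either way.

Hysteresis is the enclosed area of the load-displacement loop (shoelace
formula, displacement in metres so N*m = J), reported in microjoules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .waveform import (
    ProtocolSegment,
    WaveformRecord,
    final_period,
    segment_dma,
    to_stress_strain,
)

__all__ = [
    "DMACycleResult",
    "hysteresis",
    "phase_shift",
    "moduli",
    "analyze_dma",
]

#: Strain amplitude above which the response departs from a pure sinusoid
#: and the phase estimate is flagged unreliable (large-strain loops are
#: processed for hysteresis and trilinear fitting only).
PHASE_RELIABLE_STRAIN = 0.15


@dataclass(frozen=True)
class DMACycleResult:
    """Per-frequency dynamic results for one recording."""

    frequency_hz: float
    hysteresis_uj: float
    tan_delta: float
    g_storage_kpa: float
    g_loss_kpa: float
    g_dynamic_kpa: float
    sigma0_kpa: float
    eps0: float
    phase_reliable: bool = True


class OpenLoopError(ValueError):
    """The supplied window does not close onto itself within tolerance."""


class WeakFundamentalError(ValueError):
    """Fundamental-bin power too low for a reliable phase estimate."""


def hysteresis(
    load_n: np.ndarray,
    displacement_mm: np.ndarray,
    closure_tol: float = 0.05,
) -> float:
    """Dissipated energy (microjoules) of one closed load-displacement cycle.

    Signed shoelace area of the loop polygon with displacement converted to
    metres; the absolute value is returned.  If the window endpoints differ
    by more than ``closure_tol`` of the sweep range the loop is not closed
    and an :class:`OpenLoopError` is raised.
    """
    x = np.asarray(displacement_mm, dtype=float) * 1e-3  # m
    f = np.asarray(load_n, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for a loop")
    span = np.ptp(x)
    if span > 0 and abs(x[0] - x[-1]) > closure_tol * span:
        raise OpenLoopError(
            f"loop endpoints differ by {abs(x[0] - x[-1]):.3g} m "
            f"(> {closure_tol:.0%} of sweep)"
        )
    # cyclic shoelace: A = 0.5 * sum x_i (f_{i+1} - f_{i-1})
    area_j = 0.5 * np.sum(x * (np.roll(f, -1) - np.roll(f, 1)))
    return abs(float(area_j)) * 1e6


def _fundamental(
    channel: np.ndarray, frequency_hz: float, fs: float
) -> tuple[complex, float, float]:
    """Fundamental-bin coefficient, its power fraction, and amplitude."""
    y = np.asarray(channel, dtype=float)
    y = y - np.mean(y)  # DC balance
    scale = np.max(np.abs(y))
    if scale > 0:
        y = y / scale  # normalisation (phase-invariant)
    n = y.size
    spec = np.fft.rfft(y)
    k = int(round(frequency_hz * n / fs))
    if k < 1 or k >= spec.size:
        raise ValueError("window does not resolve the fundamental frequency")
    total = float(np.sum(np.abs(spec[1:]) ** 2))
    frac = float(np.abs(spec[k]) ** 2 / total) if total > 0 else 0.0
    amplitude = 2.0 * np.abs(spec[k]) / n * (scale if scale > 0 else 1.0)
    return spec[k] * (scale if scale > 0 else 1.0), frac, amplitude


def phase_shift(
    window: WaveformRecord,
    frequency_hz: float,
    min_power_frac: float = 0.2,
) -> tuple[float, float]:
    """tan(delta) and delta from the fundamental FFT bins of one window.

    The window must contain an integer number of periods at
    ``frequency_hz``.  delta is the phase of load minus the phase of
    displacement, wrapped into [0, pi/2).  If the fundamental carries less
    than ``min_power_frac`` of the non-DC load power the estimate is
    rejected as unreliable.
    """
    fs = window.sampling_rate_hz
    c_load, frac_load, _ = _fundamental(window.load_n, frequency_hz, fs)
    c_disp, frac_disp, _ = _fundamental(window.displacement_mm, frequency_hz, fs)
    if frac_disp < min_power_frac or frac_load < min_power_frac:
        raise WeakFundamentalError(
            f"fundamental bin carries only {min(frac_load, frac_disp):.1%} of "
            "channel power; phase estimate unreliable"
        )
    delta = math.atan2(
        math.sin(np.angle(c_load) - np.angle(c_disp)),
        math.cos(np.angle(c_load) - np.angle(c_disp)),
    )
    delta = abs(delta)
    if delta >= math.pi / 2.0:  # amplitude sign flip: fold back
        delta = math.pi - delta
    return math.tan(delta), delta


def moduli(
    sigma0_kpa: float, eps0: float, tan_delta: float
) -> tuple[float, float, float]:
    """(loss, storage, dynamic) moduli in kPa from amplitudes and tan(delta)."""
    if eps0 <= 0 or sigma0_kpa <= 0:
        raise ValueError("amplitudes must be positive")
    ratio = sigma0_kpa / eps0
    delta = math.atan(tan_delta)
    return ratio * math.sin(delta), ratio * math.cos(delta), ratio


def analyze_dma(
    record: WaveformRecord,
    min_power_frac: float = 0.2,
) -> list[DMACycleResult]:
    """Full dynamic analysis of one recording.

    Preconditioning is excluded; each remaining frequency block contributes
    one result computed on its final commanded period.
    """
    results: list[DMACycleResult] = []
    for seg in segment_dma(record):
        if seg.label == "precondition":
            continue
        window = final_period(record, seg)
        h_uj = hysteresis(window.load_n, window.displacement_mm)
        trace = to_stress_strain(window)
        fs = window.sampling_rate_hz
        _, _, sigma0 = _fundamental(trace.stress_kpa, seg.frequency_hz, fs)
        _, _, eps0 = _fundamental(trace.strain, seg.frequency_hz, fs)
        tan_d, _ = phase_shift(window, seg.frequency_hz, min_power_frac)
        g_loss, g_storage, g_dyn = moduli(sigma0, eps0, tan_d)
        results.append(
            DMACycleResult(
                frequency_hz=seg.frequency_hz,
                hysteresis_uj=h_uj,
                tan_delta=tan_d,
                g_storage_kpa=g_storage,
                g_loss_kpa=g_loss,
                g_dynamic_kpa=g_dyn,
                sigma0_kpa=sigma0,
                eps0=eps0,
                phase_reliable=eps0 <= PHASE_RELIABLE_STRAIN,
            )
        )
    return results
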