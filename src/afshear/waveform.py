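"""Waveform data model, CSV round-tripping, protocol segmentation, and
stress/strain conversion.

A recording is a triple of equal-length channels (time, displacement, load)
plus specimen geometry and an ordered list of labelled segments.  Files are
written as plain CSV (``time_s, displacement_mm, load_N``) with a JSON
sidecar carrying geometry, segmentation and provenance so that a recording
survives a write/read round trip without loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Geometry

__all__ = [
    "ProtocolSegment",
    "WaveformRecord",
    "StressStrainTrace",
    "read_waveform",
    "write_waveform",
    "segment_dma",
    "final_period",
    "to_stress_strain",
]

CSV_COLUMNS = ("time_s", "displacement_mm", "load_N")


@dataclass(frozen=True)
class ProtocolSegment:
    """A labelled half-open index range ``[start, end)`` of a recording."""

    label: str
    start: int
    end: int
    kind: str = "sinusoid"
    frequency_hz: float | None = None
    hold_s: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment must be non-empty")

    @property
    def n(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "start": self.start,
            "end": self.end,
            "kind": self.kind,
            "frequency_hz": self.frequency_hz,
            "hold_s": self.hold_s,
        }


@dataclass
class WaveformRecord:
    """Time-stamped displacement/load channels with geometry and annotation."""

    time_s: np.ndarray
    displacement_mm: np.ndarray
    load_n: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)
    segments: list[ProtocolSegment] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.load_n = np.asarray(self.load_n, dtype=float)
        n = self.time_s.size
        if self.displacement_mm.size != n or self.load_n.size != n:
            raise ValueError("channels must have equal length")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        for ch in (self.time_s, self.displacement_mm, self.load_n):
            if np.any(~np.isfinite(ch)):
                raise ValueError("channels must be finite (no missing samples)")

    @property
    def sampling_rate_hz(self) -> float:
        dt = np.median(np.diff(self.time_s))
        return 1.0 / dt

    def segment(self, label: str) -> ProtocolSegment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(f"no segment labelled {label!r}")

    def slice(self, seg: ProtocolSegment) -> "WaveformRecord":
        sl = np.s_[seg.start : seg.end]
        return WaveformRecord(
            time_s=self.time_s[sl],
            displacement_mm=self.displacement_mm[sl],
            load_n=self.load_n[sl],
            geometry=self.geometry,
            segments=[],
            meta=dict(self.meta),
        )


@dataclass
class StressStrainTrace:
    """Shear stress (kPa) and shear strain (dimensionless) versus time."""

    time_s: np.ndarray
    strain: np.ndarray
    stress_kpa: np.ndarray


def to_stress_strain(record: WaveformRecord) -> StressStrainTrace:
    """Normalise load and displacement by the nominal geometry.

    sigma [kPa] = load [N] / area [mm^2] * 1000;  eps = displacement / height.
    """
    geo = record.geometry
    if geo.area_mm2 <= 0 or geo.height_mm <= 0:
        raise ValueError("geometry area and height must be positive")
    return StressStrainTrace(
        time_s=record.time_s,
        strain=record.displacement_mm / geo.height_mm,
        stress_kpa=record.load_n / geo.area_mm2 * 1000.0,
    )


def write_waveform(record: WaveformRecord, path: str | Path) -> Path:
    """Write CSV channels plus a JSON sidecar (same stem, ``.json``)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": record.time_s,
            "displacement_mm": record.displacement_mm,
            "load_N": record.load_n,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")  # lossless for float64
    sidecar = {
        "geometry": record.geometry.to_dict(),
        "segments": [s.to_dict() for s in record.segments],
        "meta": record.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_waveform(path: str | Path) -> WaveformRecord:
    """Read a CSV recording; the JSON sidecar is optional (defaults applied)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    geometry = Geometry()
    segments: list[ProtocolSegment] = []
    meta: dict = {}
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if "geometry" in sidecar:
            geometry = Geometry.from_dict(sidecar["geometry"])
        segments = [ProtocolSegment(**s) for s in sidecar.get("segments", [])]
        meta = sidecar.get("meta", {})
    return WaveformRecord(
        time_s=df["time_s"].to_numpy(),
        displacement_mm=df["displacement_mm"].to_numpy(),
        load_n=df["load_N"].to_numpy(),
        geometry=geometry,
        segments=segments,
        meta=meta,
    )


def _detect_frequency_blocks(record: WaveformRecord) -> list[ProtocolSegment]:
    """Fallback segmentation from displacement zero crossings.

    Consecutive upward zero crossings give cycle periods; runs of similar
    periods (within 20%) are grouped into frequency blocks.
    """
    d = record.displacement_mm - np.mean(record.displacement_mm)
    up = np.flatnonzero((d[:-1] <= 0) & (d[1:] > 0))
    if up.size < 3:
        raise ValueError("too few zero crossings to detect frequency blocks")
    # sub-sample refinement of crossing positions
    frac = -d[up] / (d[up + 1] - d[up])
    xs = up + frac
    periods = np.diff(xs)
    segments: list[ProtocolSegment] = []
    fs = record.sampling_rate_hz
    run_start = 0
    for i in range(1, periods.size + 1):
        end_run = i == periods.size or not (
            0.8 < periods[i] / periods[run_start] < 1.25
        )
        if end_run:
            block = periods[run_start:i]
            if block.size >= 2:  # need at least 2 full cycles to call it a block
                period = float(np.median(block))
                start = int(round(xs[run_start]))
                stop = int(round(xs[i]))
                freq = fs / period
                segments.append(
                    ProtocolSegment(
                        label=f"{freq:.3g}Hz",
                        start=start,
                        end=stop,
                        kind="sinusoid",
                        frequency_hz=freq,
                    )
                )
            run_start = i
    return segments


def segment_dma(record: WaveformRecord) -> list[ProtocolSegment]:
    """Return the sinusoidal frequency blocks of a DMA recording.

    Annotated records are trusted verbatim (idempotent); unannotated
    recordings fall back to zero-crossing period detection.  Blocks shorter
    than one full period are dropped.
    """
    if record.segments:
        segs = [
            s for s in record.segments if s.kind == "sinusoid" and s.frequency_hz
        ]
    else:
        segs = _detect_frequency_blocks(record)
    fs = record.sampling_rate_hz
    usable = []
    for s in segs:
        n_period = int(round(fs / s.frequency_hz))
        if s.n >= n_period:
            usable.append(s)
    return usable


def final_period(record: WaveformRecord, seg: ProtocolSegment) -> WaveformRecord:
    """The last complete commanded period of a frequency block.

    The window endpoint is the block end (the commanded sinusoid completes
    an integer number of cycles there), so the final period is simply the
    trailing ``fs / f`` samples — located from the drive, not from noisy
    load zero crossings.
    """
    if seg.frequency_hz is None:
        raise ValueError("segment has no nominal frequency")
    fs = record.sampling_rate_hz
    n_period = int(round(fs / seg.frequency_hz))
    if seg.n < n_period:
        raise ValueError(
            f"block {seg.label!r} is shorter than one full period; unusable"
        )
    window = ProtocolSegment(
        label=f"{seg.label}-final",
        start=seg.end - n_period,
        end=seg.end,
        kind="sinusoid",
        frequency_hz=seg.frequency_hz,
    )
    return record.slice(window)
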