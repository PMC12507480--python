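"""Core domain types shared across the mechanical and imaging pipelines.

Units convention used throughout the package:

* displacement and specimen dimensions: millimetres
* load: newtons
* stress and moduli: kilopascals (1 kPa = 1e-3 N/mm^2)
* strain: dimensionless (displacement / nominal specimen height)
* time: seconds
* image distances: micrometres; pixel coordinates are (row, column)
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "Geometry",
    "ViscoParams",
    "ProtocolSegmentSpec",
    "DisplacementProtocol",
    "LamellaeParams",
    "GroupConfig",
    "CohortConfig",
    "CohortSample",
]


@dataclass(frozen=True)
class Geometry:
    """Nominal cube geometry used for stress/strain normalisation.

    The strain denominator is the nominal (pre-mount) specimen height, not
    the clamped gap: a +/-0.5 mm sweep on a 5 mm cube is 10% shear strain
    even though the clamps close to a 4.5 mm gap (~10% compressive
    pre-strain).
    """

    width_mm: float = 5.0
    depth_mm: float = 5.0
    height_mm: float = 5.0
    gap_mm: float = 4.5

    def __post_init__(self) -> None:
        for name in ("width_mm", "depth_mm", "height_mm", "gap_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def area_mm2(self) -> float:
        """Sheared cross-section (clamp contact area)."""
        return self.width_mm * self.depth_mm

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(**d)


@dataclass(frozen=True)
class ViscoParams:
    """Generalized-Maxwell (Prony series) material parameters.

    The relaxation function is ``G(t) = g_eq + sum_i g_i * exp(-t / tau_i)``
    which is non-increasing whenever every branch modulus is non-negative.
    ``g_eq`` is the ground-truth counterpart of the statically measured
    shear modulus; the branches set the rate-dependent (storage/loss)
    behaviour.
    """

    g_eq_kpa: float
    branches: tuple[tuple[float, float], ...] = ()  # (g_i kPa, tau_i s)
    noise_sd_n: float = 0.01  # load-cell resolution, N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_eq_kpa <= 0:
            raise ValueError("equilibrium modulus must be positive")
        for g_i, tau_i in self.branches:
            if g_i < 0:
                raise ValueError("branch moduli must be non-negative")
            if tau_i <= 0:
                raise ValueError("relaxation times must be positive")
        if self.noise_sd_n < 0:
            raise ValueError("noise_sd_n must be non-negative")

    def relaxation(self, t: np.ndarray) -> np.ndarray:
        """Relaxation modulus G(t) in kPa for t >= 0."""
        t = np.asarray(t, dtype=float)
        g = np.full_like(t, self.g_eq_kpa)
        for g_i, tau_i in self.branches:
            g = g + g_i * np.exp(-t / tau_i)
        return g


@dataclass(frozen=True)
class ProtocolSegmentSpec:
    """One building block of a displacement-controlled protocol.

    ``kind`` is one of ``sinusoid`` (amplitude + frequency + cycles),
    ``step-hold`` (ramp by ``amplitude_mm`` at ``ramp_rate_mm_s`` then hold
    for ``hold_s``) or ``rest`` (hold the current displacement for
    ``hold_s``).
    """

    label: str
    kind: str
    amplitude_mm: float = 0.0
    frequency_hz: float | None = None
    cycles: int | None = None
    hold_s: float | None = None
    ramp_rate_mm_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoid", "step-hold", "rest"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "sinusoid":
            if not self.frequency_hz or self.frequency_hz <= 0:
                raise ValueError("sinusoid requires a positive frequency")
            if not self.cycles or self.cycles < 1:
                raise ValueError("sinusoid requires cycles >= 1")
        if self.kind in ("step-hold", "rest"):
            if self.hold_s is None or self.hold_s < 0:
                raise ValueError(f"{self.kind} requires hold_s >= 0")
        if self.kind == "step-hold":
            if not self.ramp_rate_mm_s or self.ramp_rate_mm_s <= 0:
                raise ValueError("step-hold requires a positive ramp rate")

    @property
    def duration_s(self) -> float:
        if self.kind == "sinusoid":
            return self.cycles / self.frequency_hz
        ramp = 0.0
        if self.kind == "step-hold":
            ramp = abs(self.amplitude_mm) / self.ramp_rate_mm_s
        return ramp + self.hold_s

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DisplacementProtocol:
    """An ordered sequence of displacement segments plus a sampling rate."""

    segments: tuple[ProtocolSegmentSpec, ...]
    sampling_rate_hz: float = 100.0
    name: str = "protocol"

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        fmax = max(
            (s.frequency_hz for s in self.segments if s.frequency_hz), default=0.0
        )
        if fmax and self.sampling_rate_hz < 50 * fmax:
            raise ValueError(
                f"sampling rate {self.sampling_rate_hz} Hz is below 50x the "
                f"highest drive frequency ({fmax} Hz)"
            )

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def waveform(self) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, int]]]:
        """Render the commanded displacement.

        Returns ``(time_s, displacement_mm, spans)`` where ``spans`` is a
        list of ``(label, start_index, end_index)`` half-open index ranges,
        one per segment.
        """
        fs = self.sampling_rate_hz
        dt = 1.0 / fs
        chunks: list[np.ndarray] = []
        spans: list[tuple[str, int, int]] = []
        level = 0.0  # displacement carried across segments
        idx = 0
        for seg in self.segments:
            n = int(round(seg.duration_s * fs))
            t_rel = np.arange(n) * dt
            if seg.kind == "sinusoid":
                d = level + seg.amplitude_mm * np.sin(
                    2.0 * np.pi * seg.frequency_hz * t_rel
                )
                # sinusoid returns to its baseline level
            elif seg.kind == "rest":
                d = np.full(n, level)
            else:  # step-hold
                ramp_t = abs(seg.amplitude_mm) / seg.ramp_rate_mm_s
                frac = np.clip(t_rel / ramp_t, 0.0, 1.0) if ramp_t > 0 else np.ones(n)
                d = level + seg.amplitude_mm * frac
                level = level + seg.amplitude_mm
            chunks.append(d)
            spans.append((seg.label, idx, idx + n))
            idx += n
        disp = np.concatenate(chunks) if chunks else np.empty(0)
        time = np.arange(disp.size) * dt
        return time, disp, spans

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sampling_rate_hz": self.sampling_rate_hz,
            "segments": [s.to_dict() for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisplacementProtocol":
        segs = tuple(ProtocolSegmentSpec(**s) for s in d["segments"])
        return cls(
            segments=segs,
            sampling_rate_hz=d.get("sampling_rate_hz", 100.0),
            name=d.get("name", "protocol"),
        )


@dataclass(frozen=True)
class LamellaeParams:
    """Parameters of the layered speckle image generator.

    Thickness values are perpendicular inter-boundary distances in
    micrometres.  ``bright_dark_contrast`` is the Michelson-like contrast
    between adjacent bands on a [0, 1] intensity scale; speckle is
    multiplicative gamma noise with unit mean and coefficient of variation
    ``1/sqrt(speckle_shape)``.
    """

    mean_thickness_um: float = 324.67
    sd_thickness_um: float = 26.0
    undulation_amplitude_um: float = 15.0
    undulation_period_um: float = 1500.0
    tilt_deg: float = 0.0
    bright_dark_contrast: float = 0.5
    speckle_shape: float = 4.0
    pixel_size_xy_um: float = 10.23
    image_size_px: int = 440

    def __post_init__(self) -> None:
        if self.mean_thickness_um <= 2.0 * self.pixel_size_xy_um:
            raise ValueError(
                "mean thickness must exceed twice the pixel size to be resolvable"
            )
        if not (0.0 < self.bright_dark_contrast <= 1.0):
            raise ValueError("contrast must lie in (0, 1]")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if self.sd_thickness_um < 0:
            raise ValueError("sd_thickness_um must be non-negative")
        if self.pixel_size_xy_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass(frozen=True)
class GroupConfig:
    """Per-group marginal distributions (means/SDs) of the true quantities."""

    label: str
    n: int
    g1_mean_kpa: float
    g1_sd_kpa: float
    g2_mean_kpa: float
    g2_sd_kpa: float
    thickness_mean_um: float
    thickness_sd_um: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        for name in ("g1_sd_kpa", "g2_sd_kpa", "thickness_sd_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Printed summary statistics used as generator defaults: non-degenerated
#: (organ-donor control) versus degenerated surgical tissue; moduli for the
#: radial (G1) and circumferential (G2) shear orientations, and mean
#: lamellar thickness.
DEFAULT_NON_DD = GroupConfig(
    label="non-DD",
    n=13,
    g1_mean_kpa=83.0,
    g1_sd_kpa=41.3,
    g2_mean_kpa=226.2,
    g2_sd_kpa=81.9,
    thickness_mean_um=324.67,
    thickness_sd_um=26.76,
)
DEFAULT_DD = GroupConfig(
    label="DD",
    n=30,
    g1_mean_kpa=23.7,
    g1_sd_kpa=22.1,
    g2_mean_kpa=52.2,
    g2_sd_kpa=36.8,
    thickness_mean_um=600.23,
    thickness_sd_um=198.58,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator configuration.

    ``rank_rho`` couples lamellar thickness to the moduli through a Gaussian
    copula (negative by default: thicker lamellae co-occur with lower
    moduli).  With ``stratified=True`` the per-group marginals are sampled
    at mid-rank quantiles (then randomly permuted), which pins cohort
    moments at their configured values while preserving the marginal shape;
    set it to ``False`` for fully random i.i.d. draws.
    """

    groups: tuple[GroupConfig, ...] = (DEFAULT_NON_DD, DEFAULT_DD)
    rank_rho: float = -0.7
    seed: int = 0
    stratified: bool = True
    modulus_floor_kpa: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rank_rho <= 1.0:
            raise ValueError("rank_rho must lie in [-1, 1]")
        if self.modulus_floor_kpa <= 0:
            raise ValueError("modulus_floor_kpa must be positive")


@dataclass
class CohortSample:
    """One simulated cube: a disc contributes one cube per shear orientation."""

    sample_id: str
    group: str
    orientation: str  # "G1" (radial) or "G2" (circumferential)
    true_g_eq_kpa: float
    true_thickness_um: float
    metadata: dict = field(default_factory=dict)
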