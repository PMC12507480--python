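"""Synthetic cohort generator: mechanical waveforms, layered OCT-like
images, and whole cohorts with known ground truth.

The mechanical model is a linear generalized-Maxwell (Prony) solid.  Its
single-branch special case is the standard linear (Zener) solid, for which
every reported quantity has a closed form:

    G'(w)  = G_eq + sum_i G_i (w tau_i)^2 / (1 + (w tau_i)^2)
    G''(w) =        sum_i G_i (w tau_i)   / (1 + (w tau_i)^2)
    tan(delta) = G'' / G'

so estimator output can be checked against an independent oracle.  Real
annulus fibrosus is nonlinear at large strain; that is deliberately not
modelled here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .types import (
    CohortConfig,
    CohortSample,
    DisplacementProtocol,
    Geometry,
    GroupConfig,
    LamellaeParams,
    ProtocolSegmentSpec,
    ViscoParams,
)
from .waveform import ProtocolSegment, WaveformRecord

__all__ = [
    "make_dma_protocol",
    "make_ssa_protocol",
    "simulate_response",
    "zener_storage_loss",
    "zener_tan_delta",
    "zener_for_tan_delta",
    "generate_lamellae_image",
    "SyntheticOCT",
    "generate_cohort",
]

#: Frequency blocks in acquisition order (the protocol figure's order); the
#: analysis uses only the final period of each block, so order does not
#: affect estimates.
DEFAULT_DMA_FREQS = (0.1, 1.0, 0.01)
SUPPORTED_DMA_STRAINS = (0.0, 10.0, 40.0)


def make_dma_protocol(
    strain_pct: float,
    geometry: Geometry | None = None,
    freqs: tuple[float, ...] = DEFAULT_DMA_FREQS,
    sampling_rate_hz: float = 100.0,
    precondition_cycles: int = 20,
    cycles_per_freq: int = 5,
) -> DisplacementProtocol:
    """Dynamic protocol: 20 preconditioning cycles at 1 Hz, then 5-cycle
    blocks at each requested frequency.

    Amplitude is strain_pct/100 x nominal height: 10% on a 5 mm cube is
    +/-0.5 mm, 40% is +/-2.0 mm.
    """
    geometry = geometry or Geometry()
    if strain_pct not in SUPPORTED_DMA_STRAINS:
        raise ValueError(
            f"unsupported strain {strain_pct}%: protocol families are defined "
            f"for {SUPPORTED_DMA_STRAINS}"
        )
    if not set(freqs) <= {0.01, 0.1, 1.0}:
        raise ValueError("DMA frequencies must be drawn from {0.01, 0.1, 1} Hz")
    amplitude = strain_pct / 100.0 * geometry.height_mm
    segments = [
        ProtocolSegmentSpec(
            label="precondition",
            kind="sinusoid",
            amplitude_mm=amplitude,
            frequency_hz=1.0,
            cycles=precondition_cycles,
        )
    ]
    for f in freqs:
        segments.append(
            ProtocolSegmentSpec(
                label=f"{f:g}Hz",
                kind="sinusoid",
                amplitude_mm=amplitude,
                frequency_hz=f,
                cycles=cycles_per_freq,
            )
        )
    return DisplacementProtocol(
        segments=tuple(segments),
        sampling_rate_hz=sampling_rate_hz,
        name=f"dma-{strain_pct:g}pct",
    )


def make_ssa_protocol(
    strain_pct: float = 10.0,
    step_pct: float = 2.5,
    hold_s: float = 1200.0,
    geometry: Geometry | None = None,
    sampling_rate_hz: float = 100.0,
    rest_s: float = 900.0,
    ramp_rate_mm_s: float = 0.2,
    precondition_cycles: int = 5,
) -> DisplacementProtocol:
    """Static staircase protocol.

    Five preconditioning cycles at the step amplitude, a rest, then equal
    unidirectional steps (0.2 mm/s ramps) each followed by a hold.  The
    standard variant is 2.5% steps held 20 min up to 10% net strain; the
    large-strain variant uses 10% steps held 5 min up to 40%.
    """
    geometry = geometry or Geometry()
    n_steps_f = strain_pct / step_pct
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9 or n_steps < 1:
        raise ValueError(
            f"total strain {strain_pct}% is not a whole multiple of the "
            f"step {step_pct}%"
        )
    if hold_s <= 0:
        raise ValueError("hold_s must be positive")
    step_mm = step_pct / 100.0 * geometry.height_mm
    segments = [
        ProtocolSegmentSpec(
            label="precondition",
            kind="sinusoid",
            amplitude_mm=step_mm,
            frequency_hz=1.0,
            cycles=precondition_cycles,
        ),
        ProtocolSegmentSpec(label="rest", kind="rest", hold_s=rest_s),
    ]
    for k in range(1, n_steps + 1):
        segments.append(
            ProtocolSegmentSpec(
                label=f"step{k}-ramp",
                kind="step-hold",
                amplitude_mm=step_mm,
                hold_s=0.0,
                ramp_rate_mm_s=ramp_rate_mm_s,
            )
        )
        segments.append(
            ProtocolSegmentSpec(label=f"step{k}-hold", kind="rest", hold_s=hold_s)
        )
    return DisplacementProtocol(
        segments=tuple(segments),
        sampling_rate_hz=sampling_rate_hz,
        name=f"ssa-{strain_pct:g}pct",
    )


# ---------------------------------------------------------------------------
# Zener / Prony closed forms (the independent frequency-domain oracle)


def zener_storage_loss(
    params: ViscoParams, frequency_hz: float
) -> tuple[float, float]:
    """Closed-form storage and loss moduli (kPa) at a drive frequency."""
    w = 2.0 * math.pi * frequency_hz
    gp = params.g_eq_kpa
    gpp = 0.0
    for g_i, tau_i in params.branches:
        x = w * tau_i
        gp += g_i * x * x / (1.0 + x * x)
        gpp += g_i * x / (1.0 + x * x)
    return gp, gpp


def zener_tan_delta(params: ViscoParams, frequency_hz: float) -> float:
    gp, gpp = zener_storage_loss(params, frequency_hz)
    return gpp / gp


def zener_for_tan_delta(
    g_eq_kpa: float,
    frequency_hz: float,
    tan_delta: float,
    noise_sd_n: float = 0.01,
    seed: int = 0,
) -> ViscoParams:
    """Single-branch parameterisation hitting a target loss tangent.

    The branch is placed at its loss peak (w tau = 1), where
    tan(delta) = (G1/2) / (G_eq + G1/2), giving
    G1 = 2 t G_eq / (1 - t).
    """
    if not 0.0 < tan_delta < 1.0:
        raise ValueError("target tan(delta) must lie in (0, 1)")
    tau = 1.0 / (2.0 * math.pi * frequency_hz)
    g1 = 2.0 * tan_delta * g_eq_kpa / (1.0 - tan_delta)
    return ViscoParams(
        g_eq_kpa=g_eq_kpa,
        branches=((g1, tau),),
        noise_sd_n=noise_sd_n,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Time-domain simulation


def simulate_response(
    params: ViscoParams,
    protocol: DisplacementProtocol,
    geometry: Geometry | None = None,
    rng: np.random.Generator | None = None,
) -> WaveformRecord:
    """Simulate the measured load under a displacement-controlled protocol.

    The Boltzmann superposition integral is evaluated exactly for
    piecewise-linear strain: each Maxwell branch obeys
    ``dq/dt = -q/tau + G_i deps/dt`` and is advanced with the exponential
    integrator ``q[n] = a q[n-1] + G_i (tau/dt)(1-a) deps[n]``, ``a =
    exp(-dt/tau)``, implemented as a first-order recursive filter.  Load is
    stress x shear area plus additive Gaussian noise of SD ``noise_sd_n``
    (the load-cell resolution).
    """
    geometry = geometry or Geometry()
    time_s, disp, spans = protocol.waveform()
    dt = 1.0 / protocol.sampling_rate_hz
    strain = disp / geometry.height_mm
    d_eps = np.diff(strain, prepend=0.0)  # strain starts from rest at zero
    stress = params.g_eq_kpa * strain
    for g_i, tau_i in params.branches:
        a = math.exp(-dt / tau_i)
        b0 = g_i * (tau_i / dt) * (1.0 - a)
        stress = stress + signal.lfilter([b0], [1.0, -a], d_eps)
    load = stress * geometry.area_mm2 / 1000.0  # kPa * mm^2 -> N
    if params.noise_sd_n > 0:
        rng = rng if rng is not None else np.random.default_rng(params.seed)
        load = load + rng.normal(0.0, params.noise_sd_n, size=load.size)
    fs = protocol.sampling_rate_hz
    segments = []
    for label, start, end in spans:
        spec = next(s for s in protocol.segments if s.label == label)
        segments.append(
            ProtocolSegment(
                label=label,
                start=start,
                end=end,
                kind=spec.kind,
                frequency_hz=spec.frequency_hz,
                hold_s=spec.hold_s,
            )
        )
    return WaveformRecord(
        time_s=time_s,
        displacement_mm=disp,
        load_n=load,
        geometry=geometry,
        segments=segments,
        meta={
            "protocol": protocol.name,
            "sampling_rate_hz": fs,
            "g_eq_kpa": params.g_eq_kpa,
            "branches": list(map(list, params.branches)),
            "noise_sd_n": params.noise_sd_n,
            "seed": params.seed,
        },
    )


# ---------------------------------------------------------------------------
# Layered speckle images


@dataclass
class SyntheticOCT:
    """A generated image plus its ground truth.

    ``all_boundary_rows`` holds every band border as row coordinates per
    column (shape ``n_borders x width``, top to bottom), including borders
    outside the visible window; ``band_thickness_um[i]`` is the
    perpendicular ground-truth thickness of the layer below border ``i``.
    ``boundaries`` / ``layer_thickness_um`` expose only the borders visible
    across the full width and the layers bounded by two visible borders —
    the inclusion rule of the measurement pipeline.
    """

    image: np.ndarray  # float32, multiplicative-speckle intensity
    pixel_size_um: float
    all_boundary_rows: np.ndarray
    band_thickness_um: np.ndarray
    first_band_bright: bool
    bright_mask: np.ndarray

    @property
    def _visible_idx(self) -> list[int]:
        n_rows = self.image.shape[0]
        return [
            i
            for i in range(self.all_boundary_rows.shape[0])
            if self.all_boundary_rows[i].min() > 0.5
            and self.all_boundary_rows[i].max() < n_rows - 1.5
        ]

    @property
    def boundaries(self) -> list[np.ndarray]:
        return [self.all_boundary_rows[i] for i in self._visible_idx]

    @property
    def layer_thickness_um(self) -> np.ndarray:
        idx = self._visible_idx
        th = [
            self.band_thickness_um[a]
            for a, b in zip(idx[:-1], idx[1:])
            if b == a + 1
        ]
        return np.asarray(th, dtype=float)

    @property
    def true_mean_thickness_um(self) -> float:
        return float(np.mean(self.layer_thickness_um))

    def crop(self, size_px: int = 400) -> "SyntheticOCT":
        """Central crop of image, mask and ground truth (top-left biased)."""
        h, w = self.image.shape
        if h < size_px or w < size_px:
            raise ValueError("image smaller than requested crop")
        r0 = (h - size_px) // 2
        c0 = (w - size_px) // 2
        return SyntheticOCT(
            image=self.image[r0 : r0 + size_px, c0 : c0 + size_px],
            pixel_size_um=self.pixel_size_um,
            all_boundary_rows=self.all_boundary_rows[:, c0 : c0 + size_px] - r0,
            band_thickness_um=self.band_thickness_um,
            first_band_bright=self.first_band_bright,
            bright_mask=self.bright_mask[r0 : r0 + size_px, c0 : c0 + size_px],
        )


def generate_lamellae_image(
    params: LamellaeParams, seed: int | np.random.Generator = 0
) -> SyntheticOCT:
    """Alternating bright/dark bands with gamma speckle and known boundaries.

    Band centre-line spacings are drawn from the configured thickness
    distribution (truncated at twice the pixel size); boundaries share a
    common sinusoidal undulation and linear tilt, so the perpendicular
    thickness of a band equals its vertical spacing times the cosine of the
    local boundary slope.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.image_size_px
    if n < 400:
        raise ValueError("image_size_px must be at least 400 (crop margin included)")
    px = params.pixel_size_xy_um
    min_th = 2.0 * px
    tilt = math.radians(params.tilt_deg)
    # draw enough bands to cover the image with margin
    vert_factor = 1.0 / max(math.cos(tilt), 0.2)
    n_bands = int(math.ceil(n * px * vert_factor / max(params.mean_thickness_um - 3 * params.sd_thickness_um, min_th))) + 4
    th = rng.normal(params.mean_thickness_um, params.sd_thickness_um, size=n_bands)
    th = np.clip(th, min_th, None)  # perpendicular thickness, um
    vert_spacing_px = th / px * vert_factor
    # stagger the first boundary randomly above the top edge
    y0 = -vert_spacing_px[0] * rng.uniform(0.2, 1.0)
    edges = y0 + np.concatenate([[0.0], np.cumsum(vert_spacing_px)])
    cols = np.arange(n)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    und = np.zeros(n)
    if params.undulation_amplitude_um > 0:
        und = (params.undulation_amplitude_um / px) * np.sin(
            2.0 * math.pi * cols * px / params.undulation_period_um + phase
        )
    slope_rows = math.tan(tilt) * (cols - n / 2.0)
    boundary_rows = edges[:, None] + und[None, :] + slope_rows[None, :]

    first_bright = bool(rng.integers(0, 2))
    c = params.bright_dark_contrast
    bright_level, dark_level = 0.5 * (1.0 + c), 0.5 * (1.0 - c)
    rows = np.arange(n, dtype=float)
    # band index of each pixel: number of boundaries above its centre
    band_idx = (rows[None, :, None] > boundary_rows[:, None, :]).sum(axis=0)
    is_bright = (band_idx % 2 == 1) == first_bright
    img = np.where(is_bright, bright_level, dark_level).astype(np.float32)
    if np.isfinite(params.speckle_shape):
        speckle = rng.gamma(
            params.speckle_shape, 1.0 / params.speckle_shape, size=img.shape
        )
        img = img * speckle.astype(np.float32)
    img = np.clip(img, 0.0, 2.0)
    return SyntheticOCT(
        image=img,
        pixel_size_um=px,
        all_boundary_rows=boundary_rows,
        band_thickness_um=th,
        first_band_bright=first_bright,
        bright_mask=is_bright,
    )


# ---------------------------------------------------------------------------
# Cohort construction


def _marginal(mean: float, sd: float, floor: float) -> stats.rv_continuous:
    """Truncated-normal marginal bounded below (moduli/thickness are positive)."""
    if sd == 0:
        return None
    a = (floor - mean) / sd
    return stats.truncnorm(a, np.inf, loc=mean, scale=sd)


def _sample_marginal(
    dist, mean: float, u: np.ndarray
) -> np.ndarray:
    if dist is None:
        return np.full(u.shape, mean)
    return dist.ppf(u)


def generate_cohort(config: CohortConfig) -> list[CohortSample]:
    """Draw per-sample true moduli and lamellar thickness.

    A Gaussian copula couples thickness to the moduli with latent
    correlation ``rank_rho`` (both orientations share the modulus latent, so
    G1 and G2 are comonotone within a sample, as for two cubes of one
    disc).  With ``stratified=True`` the modulus latent takes mid-rank
    normal scores (randomly permuted), pinning cohort moments while leaving
    ranks, coupling and all downstream noise random.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.rank_rho
    samples: list[CohortSample] = []
    for group in config.groups:
        n = group.n
        if config.stratified:
            z_mod = stats.norm.ppf((np.arange(n) + 0.5) / n)
            rng.shuffle(z_mod)
        else:
            z_mod = rng.normal(size=n)
        z_th = rho * z_mod + math.sqrt(max(1.0 - rho * rho, 0.0)) * rng.normal(size=n)
        u_mod = stats.norm.cdf(z_mod)
        u_th = stats.norm.cdf(z_th)
        floor = config.modulus_floor_kpa
        g1 = _sample_marginal(
            _marginal(group.g1_mean_kpa, group.g1_sd_kpa, floor), group.g1_mean_kpa, u_mod
        )
        g2 = _sample_marginal(
            _marginal(group.g2_mean_kpa, group.g2_sd_kpa, floor), group.g2_mean_kpa, u_mod
        )
        th_floor = 25.0  # um, resolvability floor for the image generator
        th = _sample_marginal(
            _marginal(group.thickness_mean_um, group.thickness_sd_um, th_floor),
            group.thickness_mean_um,
            u_th,
        )
        for k in range(n):
            base = f"{group.label}-{k + 1:02d}"
            meta = {"disc": base, "pfirrmann": None}
            samples.append(
                CohortSample(
                    sample_id=f"{base}-G1",
                    group=group.label,
                    orientation="G1",
                    true_g_eq_kpa=float(g1[k]),
                    true_thickness_um=float(th[k]),
                    metadata=dict(meta),
                )
            )
            samples.append(
                CohortSample(
                    sample_id=f"{base}-G2",
                    group=group.label,
                    orientation="G2",
                    true_g_eq_kpa=float(g2[k]),
                    true_thickness_um=float(th[k]),
                    metadata=dict(meta),
                )
            )
    return samples


#: Default loss-tangent targets: the control-group radial values at the
#: three tested frequencies.  Soft tissue shows a nearly flat loss tangent
#: across decades, which a single Maxwell branch cannot reproduce; a branch
#: per tested decade can.
DEFAULT_TAN_DELTA_TARGETS = ((0.01, 0.18), (0.1, 0.16), (1.0, 0.16))


def default_branches_for(
    g_eq_kpa: float,
    tan_delta_targets: tuple[tuple[float, float], ...] = DEFAULT_TAN_DELTA_TARGETS,
) -> tuple[tuple[float, float], ...]:
    """Prony ladder with one branch per target frequency.

    Branch times are placed at the loss peaks (tau_j = 1/(2 pi f_j)) and the
    branch moduli solve the linear system that makes the closed-form loss
    tangent hit every ``(frequency, tan_delta)`` target exactly.  All branch
    times are well under two minutes, so 20-minute holds fully relax.
    """
    fs = [f for f, _ in tan_delta_targets]
    ts = [t for _, t in tan_delta_targets]
    taus = [1.0 / (2.0 * math.pi * f) for f in fs]
    m = len(fs)
    a = np.zeros((m, m))
    rhs = np.zeros(m)
    for i, f in enumerate(fs):
        for j, tau in enumerate(taus):
            x = 2.0 * math.pi * f * tau
            a[i, j] = x / (1.0 + x * x) - ts[i] * x * x / (1.0 + x * x)
        rhs[i] = ts[i] * g_eq_kpa
    g = np.linalg.solve(a, rhs)
    if np.any(g < 0):
        raise ValueError("loss-tangent targets require a negative branch modulus")
    return tuple((float(gi), float(tau)) for gi, tau in zip(g, taus))
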