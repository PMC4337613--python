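"""Synthetic ground-truth generators.

Every downstream stage of the pipeline is exercised on data produced here,
with known ground truth and no external downloads:

* :func:`simulate_lattice` — localizations drawn from evenly spaced rings
  (period ~190 nm, the spacing of the axonal membrane periodic skeleton)
  wrapped around a neurite axis, with per-localization Gaussian precision,
  Poisson labeling, uniform background, and an optional exponential density
  decay toward the distal end.
* :func:`simulate_irregular` — the dendrite-like negative control: identical
  marginal density but axial positions drawn from a smooth (ring-free)
  distribution, so its periodicity score should be ~0.
* :func:`simulate_live_series` — a frame-stamped live-cell stream; an
  optional uniform phase drift translates the lattice over time.
* :func:`simulate_frap` — FRAP traces with a mobile fraction, half-time
  recovery kinetics and acquisition photobleaching.
* :func:`simulate_polarity_image` — a two-compartment intensity image (axon
  stripe vs dendrite stripe on a background) with Poisson noise.

All generators are pure functions of their configuration, including the
seed: the same config yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError
from .frap import FrapTrace
from .geometry import NeuriteTrace
from .io import Image2D
from .localizations import LocalizationTable

__all__ = [
    "LatticeConfig",
    "LiveSeriesConfig",
    "FrapSimConfig",
    "PolarityImageConfig",
    "PolarityImage",
    "simulate_lattice",
    "simulate_irregular",
    "simulate_live_series",
    "simulate_frap",
    "simulate_polarity_image",
    "frap_preset",
    "polarity_preset",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Parameters of the periodic-lattice localization generator.

    Lengths are nm except ``density_decay_length_um`` (µm, converted on use;
    ``inf`` means uniform occupancy along the axon).
    """

    period_nm: float = 190.0
    ring_jitter_nm: float = 10.0
    loc_precision_nm: float = 10.0
    locs_per_ring: float = 30.0
    neurite_radius_nm: float = 80.0
    background_fraction: float = 0.10
    density_decay_length_um: float = math.inf
    phase_nm: float | None = None  # None -> drawn uniform in [0, period)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.period_nm > 0:
            raise InvalidArgumentError("period_nm must be > 0")
        if not 0 <= self.background_fraction < 1:
            raise InvalidArgumentError("background_fraction must be in [0, 1)")
        if not self.locs_per_ring > 0:
            raise InvalidArgumentError("locs_per_ring must be > 0")
        for name in ("neurite_radius_nm", "density_decay_length_um"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        # precision/jitter may be 0 so the noiseless comb limit is expressible
        if self.ring_jitter_nm < 0 or self.loc_precision_nm < 0:
            raise InvalidArgumentError("ring_jitter_nm and loc_precision_nm must be >= 0")


@dataclass(frozen=True)
class LiveSeriesConfig:
    """Frame-stamped live-cell stream: timing plus an underlying lattice."""

    n_frames: int = 400
    frame_rate_hz: float = 1.0
    phase_drift_nm_per_s: float = 0.0
    lattice: LatticeConfig = field(default_factory=LatticeConfig)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise InvalidArgumentError("n_frames must be >= 1")
        if not self.frame_rate_hz > 0:
            raise InvalidArgumentError("frame_rate_hz must be > 0")


@dataclass(frozen=True)
class FrapSimConfig:
    """FRAP trace generator parameters (times in s, intensities relative).

    The noiseless bleached-ROI intensity follows

        I(t) = B(t) * [(1 - bleach_depth)
                       + bleach_depth * mobile_fraction * (1 - 2**(-t'/t_half))]

    for t' = t - t_bleach >= 0, and I(t) = B(t) before the bleach, where
    B(t) = exp(-acq_bleach_rate_per_s * t) is the acquisition-photobleaching
    envelope that is also emitted as the reference trace.
    """

    mobile_fraction: float = 0.75
    recovery_halftime_s: float = 60.0
    bleach_depth: float = 0.9
    acq_bleach_rate_per_s: float = 0.0
    noise_sd: float = 0.0
    pre_bleach_s: float = 10.0
    post_bleach_s: float = 600.0
    sample_interval_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mobile_fraction <= 1:
            raise InvalidArgumentError("mobile_fraction must be in [0, 1]")
        if not self.recovery_halftime_s > 0:
            raise InvalidArgumentError("recovery_halftime_s must be > 0")
        if not 0 < self.bleach_depth <= 1:
            raise InvalidArgumentError("bleach_depth must be in (0, 1]")
        if self.acq_bleach_rate_per_s < 0 or self.noise_sd < 0:
            raise InvalidArgumentError("rates and noise must be >= 0")
        if not self.sample_interval_s > 0:
            raise InvalidArgumentError("sample_interval_s must be > 0")
        if self.pre_bleach_s < 2 * self.sample_interval_s:
            raise InvalidArgumentError("need at least 2 pre-bleach samples")


@dataclass(frozen=True)
class PolarityImageConfig:
    """Two-compartment intensity image: one axon stripe, one dendrite stripe.

    Stripe intensities are signal *added on top of* ``background_intensity``,
    so background subtraction recovers the configured axon/dendrite ratio
    exactly in the noiseless case.  Stripes are horizontal row bands
    (half-open pixel ranges) and must not overlap.
    """

    axon_intensity: float = 200.0
    dendrite_intensity: float = 100.0
    background_intensity: float = 10.0
    poisson_noise: bool = True
    image_shape_px: tuple[int, int] = (200, 200)
    axon_rows_px: tuple[int, int] = (40, 90)
    dendrite_rows_px: tuple[int, int] = (110, 160)
    pixel_size_nm: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("axon_intensity", "dendrite_intensity", "background_intensity"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        h = self.image_shape_px[0]
        for name in ("axon_rows_px", "dendrite_rows_px"):
            r0, r1 = getattr(self, name)
            if not (0 <= r0 < r1 <= h):
                raise InvalidArgumentError(f"{name} must fit inside the image")
        a0, a1 = self.axon_rows_px
        d0, d1 = self.dendrite_rows_px
        if max(a0, d0) < min(a1, d1):
            raise InvalidArgumentError("axon and dendrite stripes must not overlap")


def _ring_grid(trace: NeuriteTrace, cfg: LatticeConfig, rng: np.random.Generator):
    """Ring ideal positions, occupancies and the drawn phase."""
    length = trace.length_nm
    if length < 2 * cfg.period_nm:
        raise InvalidArgumentError("trace must span at least two lattice periods")
    phase = float(rng.uniform(0.0, cfg.period_nm)) if cfg.phase_nm is None else float(cfg.phase_nm)
    ideal = np.arange(phase, length + 1e-9, cfg.period_nm)
    occupancy = np.exp(-ideal / (cfg.density_decay_length_um * 1000.0))
    return ideal, occupancy, phase


def _place_on_rings(trace: NeuriteTrace, s: np.ndarray, cfg: LatticeConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """3D positions on circles of ``neurite_radius_nm`` normal to the axis,
    plus isotropic localization noise."""
    center = trace.point_at(s)
    _, n1, n2 = trace.frames_at(s)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=s.size)
    pos = center + cfg.neurite_radius_nm * (np.cos(theta)[:, None] * n1
                                            + np.sin(theta)[:, None] * n2)
    if cfg.loc_precision_nm > 0:
        pos = pos + rng.normal(0.0, cfg.loc_precision_nm, size=pos.shape)
    return pos


def _background(trace: NeuriteTrace, cfg: LatticeConfig, expected_signal: float,
                rng: np.random.Generator) -> np.ndarray:
    """Uniform background in the trace bounding box padded by the neurite
    envelope; count drawn so the expected background share is
    ``background_fraction`` of all localizations."""
    if cfg.background_fraction == 0:
        return np.empty((0, 3))
    lam = expected_signal * cfg.background_fraction / (1.0 - cfg.background_fraction)
    n_bg = int(rng.poisson(lam))
    pad = cfg.neurite_radius_nm + 3.0 * cfg.loc_precision_nm
    lo = trace.vertices.min(axis=0) - pad
    hi = trace.vertices.max(axis=0) + pad
    return rng.uniform(lo, hi, size=(n_bg, 3))


def simulate_lattice(trace: NeuriteTrace, cfg: LatticeConfig) -> LocalizationTable:
    """Draw localizations from a periodic ring lattice wrapped on ``trace``.

    Ring centers sit at arc-length positions ``phase + k * period_nm`` (each
    jittered by ``ring_jitter_nm``); ring k contributes
    ``Poisson(locs_per_ring * exp(-s_k / decay))`` localizations on a circle
    normal to the axis, each blurred by the localization precision.
    ``truth_ring`` records the generating ring index (-1 for background).
    """
    rng = np.random.default_rng(cfg.seed)
    ideal, occupancy, _ = _ring_grid(trace, cfg, rng)
    jitter = rng.normal(0.0, cfg.ring_jitter_nm, size=ideal.size) if cfg.ring_jitter_nm > 0 else 0.0
    centers = ideal + jitter
    counts = rng.poisson(cfg.locs_per_ring * occupancy)
    ring_idx = np.repeat(np.arange(ideal.size), counts)
    s = np.repeat(centers, counts)
    pos = _place_on_rings(trace, s, cfg, rng)
    bg = _background(trace, cfg, float(cfg.locs_per_ring * occupancy.sum()), rng)
    xyz = np.vstack([pos, bg])
    labels = np.concatenate([ring_idx, np.full(bg.shape[0], -1, dtype=np.int64)])
    return LocalizationTable.from_arrays(xyz[:, 0], xyz[:, 1], xyz[:, 2],
                                         frame=1, truth_ring=labels)


def simulate_irregular(trace: NeuriteTrace, cfg: LatticeConfig) -> LocalizationTable:
    """Dendrite-like control: same marginal density, no ring structure.

    Axial positions are drawn from the smooth density proportional to
    ``exp(-s / decay)`` on ``[0, L]`` (uniform when decay is infinite); the
    expected localization count per µm matches :func:`simulate_lattice` for
    the same config.  All ground-truth labels are -1.
    """
    rng = np.random.default_rng(cfg.seed)
    _, occupancy, _ = _ring_grid(trace, cfg, rng)
    expected_signal = float(cfg.locs_per_ring * occupancy.sum())
    n_sig = int(rng.poisson(expected_signal))
    length = trace.length_nm
    u = rng.uniform(0.0, 1.0, size=n_sig)
    if math.isinf(cfg.density_decay_length_um):
        s = u * length
    else:
        d = cfg.density_decay_length_um * 1000.0
        s = -d * np.log1p(-u * (1.0 - math.exp(-length / d)))
    pos = _place_on_rings(trace, s, cfg, rng)
    bg = _background(trace, cfg, expected_signal, rng)
    xyz = np.vstack([pos, bg])
    return LocalizationTable.from_arrays(xyz[:, 0], xyz[:, 1], xyz[:, 2],
                                         frame=1, truth_ring=-1)


def simulate_live_series(trace: NeuriteTrace, cfg: LiveSeriesConfig) -> LocalizationTable:
    """Frame-stamped stream from a (possibly drifting) lattice.

    Each localization gets a frame uniform over ``[1, n_frames]``; at frame f
    the whole lattice is translated along the axis by
    ``phase_drift_nm_per_s * (f - 1) / frame_rate_hz``.  Zero drift matches
    :func:`simulate_lattice` in distribution.
    """
    if cfg.n_frames < 2:
        raise InvalidArgumentError("live series needs n_frames >= 2")
    lat = cfg.lattice
    rng = np.random.default_rng(lat.seed)
    ideal, occupancy, _ = _ring_grid(trace, lat, rng)
    jitter = rng.normal(0.0, lat.ring_jitter_nm, size=ideal.size) if lat.ring_jitter_nm > 0 else 0.0
    centers = ideal + jitter
    counts = rng.poisson(lat.locs_per_ring * occupancy)
    ring_idx = np.repeat(np.arange(ideal.size), counts)
    s0 = np.repeat(centers, counts)
    frames = rng.integers(1, cfg.n_frames + 1, size=s0.size)
    shift = cfg.phase_drift_nm_per_s * (frames - 1) / cfg.frame_rate_hz
    pos = _place_on_rings(trace, s0 + shift, lat, rng)
    bg = _background(trace, lat, float(lat.locs_per_ring * occupancy.sum()), rng)
    bg_frames = rng.integers(1, cfg.n_frames + 1, size=bg.shape[0])
    xyz = np.vstack([pos, bg])
    return LocalizationTable.from_arrays(
        xyz[:, 0], xyz[:, 1], xyz[:, 2],
        frame=np.concatenate([frames, bg_frames]),
        truth_ring=np.concatenate([ring_idx, np.full(bg.shape[0], -1, dtype=np.int64)]),
    )


def simulate_frap(cfg: FrapSimConfig) -> FrapTrace:
    """Simulate a FRAP recording at fixed sampling (bleach at t = pre_bleach_s)."""
    t = np.arange(0.0, cfg.pre_bleach_s + cfg.post_bleach_s + 1e-9, cfg.sample_interval_s)
    t_bleach = cfg.pre_bleach_s
    envelope = np.exp(-cfg.acq_bleach_rate_per_s * t)
    roi = envelope.copy()
    post = t >= t_bleach
    tp = t[post] - t_bleach
    roi[post] = envelope[post] * (
        (1.0 - cfg.bleach_depth)
        + cfg.bleach_depth * cfg.mobile_fraction * (1.0 - 2.0 ** (-tp / cfg.recovery_halftime_s))
    )
    reference = envelope.copy()
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        roi = roi + rng.normal(0.0, cfg.noise_sd, size=roi.size)
        reference = reference + rng.normal(0.0, cfg.noise_sd, size=reference.size)
        roi = np.clip(roi, 0.0, None)
        reference = np.clip(reference, 1e-9, None)
    return FrapTrace(t_s=t, roi=roi, reference=reference, t_bleach_s=t_bleach)


def frap_preset(name: str) -> FrapSimConfig:
    """Named FRAP regimes observed for the spectrin lattice in live neurons.

    ``high_expression`` — excess unincorporated spectrin dominates: fast,
    75% recovery by 5 min (mobile fraction 0.75, half-time 25 s, full bleach
    depth, so the recovery fraction at 300 s equals the mobile fraction to 3
    decimals).  ``low_expression`` — lattice-incorporated spectrin only:
    essentially no recovery (mobile fraction 0).
    """
    presets = {
        "high_expression": FrapSimConfig(
            mobile_fraction=0.75, recovery_halftime_s=25.0, bleach_depth=1.0,
            post_bleach_s=600.0,
        ),
        "low_expression": FrapSimConfig(
            mobile_fraction=0.0, recovery_halftime_s=60.0, bleach_depth=0.9,
            post_bleach_s=1800.0,
        ),
    }
    try:
        return presets[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown FRAP preset {name!r}; choose from {sorted(presets)}") from None


@dataclass(frozen=True)
class PolarityImage:
    """Synthetic two-compartment image plus its ground-truth masks."""

    image: Image2D
    axon_mask: np.ndarray
    dendrite_mask: np.ndarray
    background_mask: np.ndarray


def simulate_polarity_image(cfg: PolarityImageConfig) -> PolarityImage:
    """Render the axon/dendrite stripe image and its boolean masks.

    With ``poisson_noise`` off, background-subtracted masked means equal the
    configured stripe intensities exactly.
    """
    h, w = cfg.image_shape_px
    mean = np.full((h, w), cfg.background_intensity, dtype=float)
    axon = np.zeros((h, w), dtype=bool)
    dend = np.zeros((h, w), dtype=bool)
    axon[cfg.axon_rows_px[0]:cfg.axon_rows_px[1], :] = True
    dend[cfg.dendrite_rows_px[0]:cfg.dendrite_rows_px[1], :] = True
    mean[axon] += cfg.axon_intensity
    mean[dend] += cfg.dendrite_intensity
    if cfg.poisson_noise:
        rng = np.random.default_rng(cfg.seed)
        pixels = rng.poisson(mean).astype(float)
    else:
        pixels = mean
    return PolarityImage(
        image=Image2D(pixels, pixel_size_nm=cfg.pixel_size_nm),
        axon_mask=axon,
        dendrite_mask=dend,
        background_mask=~(axon | dend),
    )


def polarity_preset(name: str) -> PolarityImageConfig:
    """``wild_type`` — ~2x axon enrichment of spectrin; ``ankyrin_b_ko`` —
    dendrite signal raised to the axonal level (ratio ~1)."""
    presets = {
        "wild_type": PolarityImageConfig(axon_intensity=200.0, dendrite_intensity=100.0,
                                         background_intensity=10.0),
        "ankyrin_b_ko": PolarityImageConfig(axon_intensity=200.0, dendrite_intensity=200.0,
                                            background_intensity=10.0),
    }
    try:
        return presets[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown polarity preset {name!r}; choose from {sorted(presets)}") from None
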