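"""Spatial periodicity scoring along a neurite.

The 1D localization density ρ(s) along the arc-length coordinate is binned
(:func:`density_profile`), and periodicity is scored two ways:

* autocorrelation — the normalized, mean-subtracted, fixed-denominator
  estimator

      ac(l) = Σ_s (ρ(s) − ρ̄)(ρ(s+l) − ρ̄) / (N · var(ρ)),

  which guarantees ac(0) = 1.  The periodicity score (*autocorrelation
  amplitude*) is the value at the first peak minus the mean of the two
  flanking valleys; for a perfectly periodic density it approaches 2, for a
  structureless density it is ~0.

* Fourier — the dominant spatial period is the reciprocal of the frequency
  maximizing spectral power inside a search band, with Hann windowing,
  zero-padding and quadratic peak interpolation for sub-bin resolution.

Robustness utilities reproduce the field's standard controls: curve
averaging over segments, random subsampling of localizations, and
periodicity-versus-distance profiles along the axon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DegenerateInputError, InvalidArgumentError
from .geometry import NeuriteTrace, project_onto_trace
from .localizations import LocalizationTable

__all__ = [
    "DensityProfile",
    "AutocorrResult",
    "SpectrumResult",
    "density_profile",
    "autocorrelation",
    "autocorr_amplitude",
    "dominant_period",
    "average_autocorrelation",
    "subsample_robustness",
    "periodicity_vs_distance",
    "profile_from_localizations",
]

DEFAULT_BIN_NM = 10.0
DEFAULT_PEAK_BAND_NM = (130.0, 260.0)
DEFAULT_FOURIER_BAND_NM = (100.0, 400.0)


@dataclass(frozen=True)
class DensityProfile:
    """Binned 1D localization counts along arc length (half-open bins)."""

    bin_size_nm: float
    s0_nm: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not self.bin_size_nm > 0:
            raise InvalidArgumentError("bin_size_nm must be > 0")
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1:
            raise InvalidArgumentError("counts must be 1D")
        if np.any(c < 0):
            raise InvalidArgumentError("counts must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_centers_nm(self) -> np.ndarray:
        return self.s0_nm + (np.arange(self.n_bins) + 0.5) * self.bin_size_nm


@dataclass(frozen=True)
class AutocorrResult:
    """Autocorrelation curve over non-negative lags plus the periodicity score."""

    lags_nm: np.ndarray
    ac: np.ndarray
    bin_size_nm: float
    amplitude: float = np.nan
    first_peak_lag_nm: float = np.nan


@dataclass(frozen=True)
class SpectrumResult:
    """Power spectrum of the density profile and its dominant period."""

    frequency_per_nm: np.ndarray
    power: np.ndarray
    dominant_period_nm: float
    peak_power: float
    low_confidence: bool
    band_nm: tuple[float, float] = field(default=DEFAULT_FOURIER_BAND_NM, compare=False)


def density_profile(
    positions,
    bin_size_nm: float = DEFAULT_BIN_NM,
    s_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Histogram arc-length positions into half-open bins [edge, edge+bin).

    Without an explicit range the bins start at 0 (or the floor of the
    minimum position if negative) and cover the maximum; positions falling
    outside an explicit range are dropped.
    """
    if not bin_size_nm > 0:
        raise InvalidArgumentError("bin_size_nm must be > 0")
    pos = np.asarray(positions, dtype=float)
    if s_range is None:
        if pos.size == 0:
            return DensityProfile(bin_size_nm, 0.0, np.zeros(1))
        s0 = min(0.0, np.floor(pos.min() / bin_size_nm) * bin_size_nm)
        n = int(np.floor((pos.max() - s0) / bin_size_nm)) + 1
    else:
        s0, s1 = float(s_range[0]), float(s_range[1])
        if not s1 > s0:
            raise InvalidArgumentError("range must have positive extent")
        n = int(np.ceil((s1 - s0) / bin_size_nm - 1e-9))
        pos = pos[(pos >= s0) & (pos < s0 + n * bin_size_nm)]
    idx = np.floor((pos - s0) / bin_size_nm).astype(int)
    counts = np.bincount(idx, minlength=n).astype(float)[:n]
    return DensityProfile(bin_size_nm, s0, counts)


def profile_from_localizations(
    locs: LocalizationTable,
    trace: NeuriteTrace,
    bin_size_nm: float = DEFAULT_BIN_NM,
    max_lateral_nm: float = 400.0,
    s_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Project a localization table onto a trace and bin it in one call."""
    proj = project_onto_trace(locs, trace, max_lateral_nm)
    if s_range is None:
        s_range = (0.0, trace.length_nm)
    return density_profile(proj.s_nm, bin_size_nm, s_range)


def autocorrelation(
    profile: DensityProfile,
    max_lag_nm: float = 1000.0,
    peak_band_nm: tuple[float, float] = DEFAULT_PEAK_BAND_NM,
) -> AutocorrResult:
    """Normalized autocorrelation of the density profile up to ``max_lag_nm``.

    Uses the biased (fixed-N denominator) estimator so that ac(0) = 1 exactly
    and |ac| is bounded.  The amplitude score and first-peak lag are attached
    when the lag range covers the peak band (NaN otherwise).
    """
    rho = profile.counts
    max_lag_bins = int(np.floor(max_lag_nm / profile.bin_size_nm))
    if rho.size < 2 * max_lag_bins:
        raise InvalidArgumentError(
            f"profile has {rho.size} bins; need >= {2 * max_lag_bins} for max_lag {max_lag_nm} nm")
    d = rho - rho.mean()
    var = float(np.mean(d * d))
    if var <= 0:
        raise DegenerateInputError("constant density profile: autocorrelation undefined")
    full = signal.correlate(d, d, mode="full", method="fft")
    ac = full[rho.size - 1: rho.size + max_lag_bins] / (rho.size * var)
    ac[0] = 1.0  # exact by construction; clamp FFT rounding
    lags = np.arange(max_lag_bins + 1) * profile.bin_size_nm
    result = AutocorrResult(lags_nm=lags, ac=ac, bin_size_nm=profile.bin_size_nm)
    try:
        amp, peak = autocorr_amplitude(result, peak_band_nm)
    except InvalidArgumentError:
        return result
    return AutocorrResult(lags_nm=lags, ac=ac, bin_size_nm=profile.bin_size_nm,
                          amplitude=amp, first_peak_lag_nm=peak)


def autocorr_amplitude(
    ac: AutocorrResult,
    period_band_nm: tuple[float, float] = DEFAULT_PEAK_BAND_NM,
) -> tuple[float, float]:
    """Periodicity score: first-peak value minus the mean of the two first valleys.

    The first peak is the maximum of ac over the period search band; the two
    valleys are the minima on (0, peak_lag) and (peak_lag, 2*peak_lag).  Ties
    resolve to the smallest lag.  Returns ``(amplitude, first_peak_lag_nm)``.
    """
    lo, hi = period_band_nm
    if not 0 < lo < hi:
        raise InvalidArgumentError("period band must satisfy 0 < lo < hi")
    lags, vals = ac.lags_nm, ac.ac
    if lags[-1] < 1.5 * hi:
        raise InvalidArgumentError(
            f"autocorrelation covers lags up to {lags[-1]} nm; need >= {1.5 * hi} nm")
    in_band = (lags >= lo) & (lags <= hi)
    band_vals = vals[in_band]
    peak_rel = int(np.argmax(band_vals))  # argmax takes the first (smallest lag) on ties
    peak_idx = int(np.flatnonzero(in_band)[peak_rel])
    peak_lag = float(lags[peak_idx])
    peak_val = float(vals[peak_idx])
    before = (lags > 0) & (lags < peak_lag)
    after = (lags > peak_lag) & (lags <= 2 * peak_lag)
    valley1 = float(np.min(vals[before])) if np.any(before) else 0.0
    valley2 = float(np.min(vals[after])) if np.any(after) else 0.0
    amplitude = peak_val - 0.5 * (valley1 + valley2)
    return amplitude, peak_lag


def dominant_period(
    profile: DensityProfile,
    band_nm: tuple[float, float] = DEFAULT_FOURIER_BAND_NM,
    window: str | None = "hann",
    pad_factor: int = 4,
    snr_threshold: float = 50.0,
) -> SpectrumResult:
    """Dominant spatial period of the profile inside a period search band.

    The mean-subtracted profile is Hann-windowed by default, zero-padded to
    at least ``pad_factor`` times its length, and the power-spectrum maximum
    inside the band is refined by quadratic interpolation of the three
    surrounding points.  A peak weaker than ``snr_threshold`` times the
    median off-DC power is flagged ``low_confidence``; the default 50 sits
    between the extreme-value ceiling of a structureless (shot-noise)
    profile (peak/median < ~20) and the weakest periodic profiles the
    generators produce (> ~400).
    """
    rho = profile.counts
    lo, hi = band_nm
    if not 0 < lo < hi:
        raise InvalidArgumentError("band must satisfy 0 < lo < hi")
    if rho.size * profile.bin_size_nm < 2 * hi:
        raise InvalidArgumentError("profile shorter than twice the upper band edge")
    d = rho - rho.mean()
    if not np.any(d):
        raise DegenerateInputError("all-zero (constant) profile has no spectrum")
    if window == "hann":
        d = d * signal.windows.hann(d.size)
    elif window is not None:
        raise InvalidArgumentError(f"unknown window {window!r}")
    nfft = int(2 ** np.ceil(np.log2(pad_factor * d.size)))
    spec = np.fft.rfft(d, n=nfft)
    power = np.abs(spec) ** 2
    freq = np.fft.rfftfreq(nfft, d=profile.bin_size_nm)
    in_band = (freq >= 1.0 / hi) & (freq <= 1.0 / lo)
    if not np.any(in_band):
        raise InvalidArgumentError("search band contains no frequency samples")
    band_idx = np.flatnonzero(in_band)
    k = int(band_idx[np.argmax(power[band_idx])])
    # quadratic (parabolic) interpolation around the maximum
    if 0 < k < power.size - 1:
        a, b, c = power[k - 1], power[k], power[k + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f_star = freq[k] + delta * (freq[1] - freq[0])
    peak_power = float(power[k])
    median_power = float(np.median(power[1:]))
    return SpectrumResult(
        frequency_per_nm=freq,
        power=power,
        dominant_period_nm=float(1.0 / f_star),
        peak_power=peak_power,
        low_confidence=bool(peak_power < snr_threshold * median_power),
        band_nm=(lo, hi),
    )


def average_autocorrelation(
    results: list[AutocorrResult],
    period_band_nm: tuple[float, float] = DEFAULT_PEAK_BAND_NM,
) -> AutocorrResult:
    """Pointwise mean of autocorrelation curves over their shared lag range.

    All inputs must share a bin size; the amplitude score is recomputed on
    the averaged curve (averaging first suppresses noise in the valleys, so
    this is not the mean of the per-curve amplitudes).
    """
    if not results:
        raise InvalidArgumentError("need at least one autocorrelation result")
    bin_sizes = {r.bin_size_nm for r in results}
    if len(bin_sizes) != 1:
        raise InvalidArgumentError(f"mixed bin sizes: {sorted(bin_sizes)}")
    n = min(r.ac.size for r in results)
    mean_ac = np.mean([r.ac[:n] for r in results], axis=0)
    lags = results[0].lags_nm[:n]
    out = AutocorrResult(lags_nm=lags, ac=mean_ac, bin_size_nm=results[0].bin_size_nm)
    try:
        amp, peak = autocorr_amplitude(out, period_band_nm)
    except InvalidArgumentError:
        return out
    return AutocorrResult(lags_nm=lags, ac=mean_ac, bin_size_nm=out.bin_size_nm,
                          amplitude=amp, first_peak_lag_nm=peak)


def subsample_robustness(
    locs: LocalizationTable,
    trace: NeuriteTrace,
    target_counts,
    n_reps: int = 100,
    seed: int = 0,
    *,
    bin_size_nm: float = DEFAULT_BIN_NM,
    max_lateral_nm: float = 400.0,
    max_lag_nm: float = 1000.0,
    period_band_nm: tuple[float, float] = DEFAULT_PEAK_BAND_NM,
) -> pd.DataFrame:
    """Sensitivity of the amplitude score to the number of localizations.

    For each target count, ``n_reps`` random subsets are drawn without
    replacement from the table, the profile → autocorrelation → amplitude
    chain is recomputed on the fixed full-trace bin grid, and the mean and sd
    of the amplitude are tabulated.  The full-count amplitude is included as
    the reference row (sd 0).
    """
    if n_reps < 1:
        raise InvalidArgumentError("n_reps must be >= 1")
    n_total = len(locs)
    targets = sorted({int(t) for t in target_counts}, reverse=True)
    for t in targets:
        if t > n_total or t < 1:
            raise InvalidArgumentError(f"target count {t} outside [1, {n_total}]")
    proj = project_onto_trace(locs, trace, max_lateral_nm)
    s_kept = np.full(n_total, np.nan)
    s_kept[proj.kept_index] = proj.s_nm
    s_range = (0.0, trace.length_nm)

    def amp_of(indices: np.ndarray) -> float:
        s = s_kept[indices]
        prof = density_profile(s[~np.isnan(s)], bin_size_nm, s_range)
        return autocorrelation(prof, max_lag_nm, period_band_nm).amplitude

    full_amp = amp_of(np.arange(n_total))
    rng = np.random.default_rng(seed)
    rows = [{"target_count": n_total, "mean_amplitude": full_amp,
             "sd_amplitude": 0.0, "n_reps": 1, "is_reference": True}]
    for t in targets:
        if t == n_total:
            continue
        amps = np.array([amp_of(rng.choice(n_total, size=t, replace=False))
                         for _ in range(n_reps)])
        rows.append({"target_count": t, "mean_amplitude": float(amps.mean()),
                     "sd_amplitude": float(amps.std(ddof=1)) if n_reps > 1 else 0.0,
                     "n_reps": n_reps, "is_reference": False})
    return pd.DataFrame(rows)


def periodicity_vs_distance(
    locs: LocalizationTable,
    trace: NeuriteTrace,
    segment_length_um: float = 10.0,
    *,
    bin_size_nm: float = DEFAULT_BIN_NM,
    period_band_nm: tuple[float, float] = DEFAULT_PEAK_BAND_NM,
    max_lateral_nm: float = 400.0,
    min_count: int = 100,
) -> pd.DataFrame:
    """Amplitude score per consecutive axonal segment, proximal to distal.

    The trace is tiled into non-overlapping half-open segments
    [k·L, (k+1)·L); per-segment amplitude and localization count are
    reported.  Segments with fewer than ``min_count`` localizations (or a
    degenerate profile) are flagged via ``low_count``/NaN, never dropped.
    """
    seg_nm = segment_length_um * 1000.0
    if seg_nm > trace.length_nm + 1e-6:
        raise InvalidArgumentError("segment longer than the trace")
    n_seg = int(np.floor(trace.length_nm / seg_nm + 1e-9))
    proj = project_onto_trace(locs, trace, max_lateral_nm)
    max_lag_nm = 1.5 * period_band_nm[1]
    rows = []
    for k in range(n_seg):
        s0, s1 = k * seg_nm, (k + 1) * seg_nm
        sel = proj.s_nm[(proj.s_nm >= s0) & (proj.s_nm < s1)]
        prof = density_profile(sel, bin_size_nm, (s0, s1))
        try:
            amp = autocorrelation(prof, max_lag_nm, period_band_nm).amplitude
        except DegenerateInputError:
            amp = np.nan
        rows.append({
            "segment_center_s_nm": 0.5 * (s0 + s1),
            "amplitude": amp,
            "n_locs": int(sel.size),
            "low_count": bool(sel.size < min_count),
        })
    return pd.DataFrame(rows)
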