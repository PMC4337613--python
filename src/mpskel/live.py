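"""Live-cell lattice stability analysis.

A live-cell localization stream is segregated into time windows by camera
frame; the dominant spatial period of each window reports whether the
lattice spacing changes over time, and the cross-correlation between an
early reference window and later windows reports whether the lattice
*translates* (a nonzero peak lag is a phase shift of the periodic pattern).
A static lattice shows constant period and zero phase shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DegenerateInputError, InvalidArgumentError
from .geometry import NeuriteTrace
from .localizations import LocalizationTable
from .periodicity import (
    DEFAULT_BIN_NM,
    DEFAULT_FOURIER_BAND_NM,
    SpectrumResult,
    dominant_period,
    profile_from_localizations,
)

__all__ = [
    "TimeWindowSet",
    "CrossCorrResult",
    "split_time_windows",
    "window_spectra",
    "window_cross_correlation",
    "window_phase_shifts",
]


@dataclass(frozen=True)
class TimeWindowSet:
    """Contiguous, non-overlapping frame windows covering [1, n_frames].

    ``bounds[i] = (start, end)`` is half-open over frames: window i holds
    frames ``start < f <= end``.  ``tables[i]`` is the per-window
    localization subset; per-window counts sum to the input total.
    """

    bounds: tuple[tuple[int, int], ...]
    tables: tuple[LocalizationTable, ...]
    n_frames: int

    @property
    def n_windows(self) -> int:
        return len(self.bounds)

    def center_time_s(self, i: int, frame_rate_hz: float) -> float:
        """Wall-clock center of window i, counting frame 1 as t = 0."""
        start, end = self.bounds[i]
        return ((start + 1 + end) / 2.0 - 1.0) / frame_rate_hz


def split_time_windows(
    locs: LocalizationTable,
    n_windows: int | None = None,
    window_frames: int | None = None,
    n_frames: int | None = None,
) -> TimeWindowSet:
    """Partition a stream into equal-frame time windows.

    Give either ``n_windows`` (equal windows, remainder frames assigned to
    the earliest windows) or ``window_frames`` (fixed-size chunks, last one
    possibly shorter).  ``n_frames`` defaults to the largest frame stamp.
    """
    if (n_windows is None) == (window_frames is None):
        raise InvalidArgumentError("give exactly one of n_windows or window_frames")
    if n_frames is None:
        if len(locs) == 0:
            raise InvalidArgumentError("cannot infer n_frames from an empty table")
        n_frames = int(locs.frame.max())
    if n_windows is not None:
        if n_windows < 2:
            raise InvalidArgumentError("need n_windows >= 2")
        if n_windows > n_frames:
            raise InvalidArgumentError(f"{n_windows} windows exceed {n_frames} frames")
        base, rem = divmod(n_frames, n_windows)
        sizes = [base + (1 if i < rem else 0) for i in range(n_windows)]
    else:
        if window_frames < 1:
            raise InvalidArgumentError("window_frames must be >= 1")
        sizes = [window_frames] * (n_frames // window_frames)
        if n_frames % window_frames:
            sizes.append(n_frames % window_frames)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    bounds = tuple((int(edges[i]), int(edges[i + 1])) for i in range(len(sizes)))
    tables = tuple(
        locs.take(np.flatnonzero((locs.frame > lo) & (locs.frame <= hi)))
        for lo, hi in bounds
    )
    return TimeWindowSet(bounds=bounds, tables=tables, n_frames=n_frames)


def window_spectra(
    windows: TimeWindowSet,
    trace: NeuriteTrace,
    bin_size_nm: float = DEFAULT_BIN_NM,
    band_nm: tuple[float, float] = DEFAULT_FOURIER_BAND_NM,
    max_lateral_nm: float = 400.0,
) -> list[SpectrumResult | None]:
    """Dominant-period spectrum per time window.

    An empty window yields ``None`` (flagged, not a hard error) so a sparse
    stream does not abort the whole analysis.
    """
    out: list[SpectrumResult | None] = []
    for table in windows.tables:
        if len(table) == 0:
            out.append(None)
            continue
        prof = profile_from_localizations(table, trace, bin_size_nm, max_lateral_nm)
        try:
            out.append(dominant_period(prof, band_nm))
        except DegenerateInputError:
            out.append(None)
    return out


@dataclass(frozen=True)
class CrossCorrResult:
    """Cross-correlation between two windows' density profiles.

    Positive ``peak_lag_nm`` means the second (later) window's pattern is
    shifted toward larger arc length relative to the reference.
    """

    lags_nm: np.ndarray
    cc: np.ndarray
    peak_lag_nm: float
    bin_size_nm: float


def _profile_deviation(table, trace, bin_size_nm, max_lateral_nm):
    prof = profile_from_localizations(table, trace, bin_size_nm, max_lateral_nm)
    d = prof.counts - prof.counts.mean()
    sd = float(np.sqrt(np.mean(d * d)))
    if sd <= 0:
        raise DegenerateInputError("window profile is constant; cross-correlation undefined")
    return d, sd


def window_cross_correlation(
    reference: LocalizationTable,
    other: LocalizationTable,
    trace: NeuriteTrace,
    bin_size_nm: float = DEFAULT_BIN_NM,
    max_lag_nm: float = 600.0,
    max_lateral_nm: float = 400.0,
) -> CrossCorrResult:
    """Pearson-normalized cross-correlation of two windows on a shared grid.

        cc(l) = Σ_s (ρ₁(s) − ρ̄₁)(ρ₂(s + l) − ρ̄₂) / (N · sd(ρ₁) · sd(ρ₂))

    The phase shift is the lag maximizing cc over [−max_lag, +max_lag]
    (smallest |lag| on ties).  A window against itself reduces exactly to
    the unit-normalized autocorrelation.
    """
    if len(reference) == 0 or len(other) == 0:
        raise InvalidArgumentError("both windows must contain localizations")
    d1, sd1 = _profile_deviation(reference, trace, bin_size_nm, max_lateral_nm)
    d2, sd2 = _profile_deviation(other, trace, bin_size_nm, max_lateral_nm)
    n = d1.size
    max_lag_bins = int(np.floor(max_lag_nm / bin_size_nm))
    if max_lag_bins >= n:
        raise InvalidArgumentError("max_lag exceeds the profile extent")
    full = signal.correlate(d2, d1, mode="full", method="fft")  # index N-1+l holds lag l
    sel = full[n - 1 - max_lag_bins: n + max_lag_bins] / (n * sd1 * sd2)
    lag_bins = np.arange(-max_lag_bins, max_lag_bins + 1)
    order = np.lexsort((lag_bins, np.abs(lag_bins), -sel))  # ties -> smallest |lag|
    peak = int(order[0])
    return CrossCorrResult(
        lags_nm=lag_bins * bin_size_nm,
        cc=sel,
        peak_lag_nm=float(lag_bins[peak] * bin_size_nm),
        bin_size_nm=bin_size_nm,
    )


def window_phase_shifts(
    windows: TimeWindowSet,
    trace: NeuriteTrace,
    bin_size_nm: float = DEFAULT_BIN_NM,
    max_lag_nm: float = 600.0,
    max_lateral_nm: float = 400.0,
    reference: int = 0,
) -> pd.DataFrame:
    """Phase shift of every window relative to a reference window."""
    rows = []
    ref_table = windows.tables[reference]
    for i in range(windows.n_windows):
        res = window_cross_correlation(ref_table, windows.tables[i], trace,
                                       bin_size_nm, max_lag_nm, max_lateral_nm)
        rows.append({
            "window": i,
            "frame_start": windows.bounds[i][0] + 1,
            "frame_end": windows.bounds[i][1],
            "peak_lag_nm": res.peak_lag_nm,
            "cc_peak": float(res.cc.max()),
            "n_locs": len(windows.tables[i]),
        })
    return pd.DataFrame(rows)
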