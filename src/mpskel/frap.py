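"""FRAP turnover analysis.

Fluorescence recovery after photobleaching reports molecular exchange between
a bleached region and the surrounding pool.  The workflow here follows the
standard ratio method: the unbleached reference region calibrates acquisition
photobleaching, the corrected bleached-region trace is normalized to its
pre-bleach mean, and the recovery fraction

    R(t) = corrected(t) / mean(corrected, pre-bleach)

is read off at the requested times.  A single-exponential recovery model with
half-time parameterization,

    R(t) = R0 + M * (1 - 2**(-(t - t_bleach) / t_half)),

is provided for parameter-recovery studies: ``M`` estimates the mobile
fraction and ``t_half`` the recovery half-time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, FitError, InvalidArgumentError

__all__ = ["FrapTrace", "FrapFit", "bleach_correct", "recovery_fraction", "fit_recovery"]


@dataclass(frozen=True)
class FrapTrace:
    """Bleached-ROI and reference-ROI intensity time series.

    ``t_s`` is time from the start of the recording (s), strictly increasing;
    the bleach event happens at ``t_bleach_s``.  At least two samples must
    precede the bleach so the pre-bleach baseline is an average, not a single
    noisy frame.  Intensities are in arbitrary units and must be >= 0.
    """

    t_s: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    t_bleach_s: float

    def __post_init__(self) -> None:
        for name in ("t_s", "roi", "reference"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t_s.size == self.roi.size == self.reference.size):
            raise InvalidArgumentError("t_s, roi and reference must share a length")
        if self.t_s.size < 3:
            raise InvalidArgumentError("need at least 3 samples")
        if np.any(np.diff(self.t_s) <= 0):
            raise InvalidArgumentError("sample times must be strictly increasing")
        if np.any(self.roi < 0) or np.any(self.reference < 0):
            raise InvalidArgumentError("intensities must be >= 0")
        if int(np.sum(self.t_s < self.t_bleach_s)) < 2:
            raise InvalidArgumentError("need at least 2 pre-bleach samples")

    @property
    def pre_bleach(self) -> np.ndarray:
        return self.t_s < self.t_bleach_s

    def corrected(self) -> np.ndarray:
        return bleach_correct(self)

    def recovery(self) -> np.ndarray:
        """Recovery-fraction series R(t) at every sample."""
        corr = bleach_correct(self)
        return corr / float(np.mean(corr[self.pre_bleach]))


def bleach_correct(trace: FrapTrace) -> np.ndarray:
    """Divide out acquisition photobleaching using the reference region.

    corrected(t) = roi(t) * mean(reference, pre-bleach) / reference(t).

    A constant reference leaves the ROI trace untouched; a shared exponential
    decay is removed exactly.
    """
    if np.any(trace.reference <= 0):
        raise DataError("reference trace contains non-positive samples; cannot calibrate")
    ref_pre = float(np.mean(trace.reference[trace.pre_bleach]))
    return trace.roi * ref_pre / trace.reference


def recovery_fraction(trace: FrapTrace, times_s) -> np.ndarray:
    """Recovery fraction R at the requested times *after the bleach*.

    ``times_s`` counts from the bleach event (so 300 means 5 minutes of
    recovery).  Values between samples are obtained by linear interpolation;
    a query at a sample point returns the exact ratio.
    """
    times = trace.t_bleach_s + np.atleast_1d(np.asarray(times_s, dtype=float))
    if np.any(times <= trace.t_bleach_s):
        raise InvalidArgumentError("requested times must be positive (after the bleach)")
    if np.any(times > trace.t_s[-1]):
        raise InvalidArgumentError("requested time outside the recorded range")
    return np.interp(times, trace.t_s, trace.recovery())


@dataclass(frozen=True)
class FrapFit:
    mobile_fraction_est: float
    halftime_est_s: float
    r0_est: float
    residual_rms: float
    n_samples: int = field(default=0, compare=False)


def _model(t_post: np.ndarray, r0: float, m: float, t_half: float) -> np.ndarray:
    return r0 + m * (1.0 - 2.0 ** (-t_post / t_half))


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Least-squares single-exponential fit of the post-bleach recovery."""
    post = trace.t_s > trace.t_bleach_s
    if int(np.sum(post)) < 10:
        raise InvalidArgumentError("need at least 10 post-bleach samples to fit")
    r = trace.recovery()[post]
    t_post = trace.t_s[post] - trace.t_bleach_s
    r0_guess = float(r[0])
    m_guess = float(np.clip(r[-1] - r[0], 1e-3, 1.0))
    tau_guess = float(max(t_post[-1] / 4.0, t_post[0]))
    try:
        popt, _ = curve_fit(
            _model, t_post, r,
            p0=(r0_guess, m_guess, tau_guess),
            bounds=([0.0, 0.0, 1e-6], [2.0, 1.5, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - rare non-convergence
        raise FitError(f"recovery fit did not converge: {exc}") from exc
    resid = r - _model(t_post, *popt)
    return FrapFit(
        mobile_fraction_est=float(popt[1]),
        halftime_est_s=float(popt[2]),
        r0_est=float(popt[0]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_samples=int(t_post.size),
    )
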