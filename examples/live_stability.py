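"""Probe lattice stability in a simulated live-cell localization stream.

A 400 s stream (1 Hz) is split into four time windows.  For a static
lattice the per-window dominant periods agree and the cross-correlation
peak between the first and later windows sits at lag 0; imposing a 1 nm/s
drift translates the pattern, and the recovered phase shift grows by
100 nm per window (the 100 s window-center spacing times the drift).
"""

from mpskel import (
    LatticeConfig,
    LiveSeriesConfig,
    make_trace,
    simulate_live_series,
    split_time_windows,
    window_phase_shifts,
    window_spectra,
)

trace = make_trace(30.0, 0.0)
for label, drift in (("static lattice", 0.0), ("1 nm/s drift", 1.0)):
    cfg = LiveSeriesConfig(
        n_frames=400, frame_rate_hz=1.0, phase_drift_nm_per_s=drift,
        # per-window density matched to the fixed-cell default (30 locs/ring/window)
        lattice=LatticeConfig(locs_per_ring=120.0, seed=2),
    )
    stream = simulate_live_series(trace, cfg)
    windows = split_time_windows(stream, n_windows=4)
    periods = [s.dominant_period_nm for s in window_spectra(windows, trace)]
    shifts = window_phase_shifts(windows, trace)
    print(f"{label}:")
    print("  window periods [nm]:", ", ".join(f"{p:.1f}" for p in periods))
    print("  phase shift vs window 1 [nm]:",
          ", ".join(f"{v:.0f}" for v in shifts.peak_lag_nm))

print("\nPeriods stay at 190 nm in both cases (translation preserves frequency);")
print("only the drifting lattice accumulates a phase shift.")
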