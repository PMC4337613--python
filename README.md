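# mpskel

Quantification of the **membrane periodic skeleton** (MPS) — the lattice of
actin rings spaced ~190 nm apart and connected by spectrin tetramers that
lines the axons of neurons — from single-molecule localization microscopy
(STORM/SMLM) data, plus the companion live-cell, FRAP and polarity analyses
used to characterize its assembly and stability.

The package is aimed at microscopists and image analysts who have
localization tables (one row per detected molecule, x/y/z in nm plus a
camera-frame stamp) and neurite traces, and want reproducible, tested
implementations of the standard MPS readouts:

- **Periodicity scoring.** Localizations are projected onto the neurite
  axis; the binned 1D density ρ(s) is autocorrelated with the normalized,
  fixed-denominator estimator

  ```
  AC(l) = Σ_s (ρ(s) − ρ̄)(ρ(s + l) − ρ̄) / (N · var ρ),      AC(0) = 1
  ```

  and the *amplitude* score is AC at the first peak (~190 nm) minus the
  mean of the two flanking valleys — ~0 for an irregular distribution,
  approaching 2 for a perfect lattice.  The dominant period is found
  independently by FFT (Hann window, 4× zero-padding, parabolic peak
  interpolation) inside a 100–400 nm search band.
- **Robustness controls**: curve averaging over segments, random
  subsampling of localizations, and periodicity-versus-distance profiles.
- **Live-cell stability**: a frame-stamped stream is split into time
  windows; per-window spectra test whether the spacing changes, and the
  cross-correlation peak lag between windows measures lattice phase shift.
- **FRAP turnover**: reference-region bleach calibration, recovery
  fraction R(t) relative to the pre-bleach intensity, and a
  single-exponential fit `R(t) = R₀ + M·(1 − 2^(−t/t½))` of the mobile
  fraction M.
- **Axon/dendrite polarity**: masked mean intensity ratio from
  conventional fluorescence images, with optional background subtraction.
- **Synthetic ground truth**: generators for ring-lattice and irregular
  point clouds, drifting live-cell streams, FRAP traces and two-compartment
  images, so the whole pipeline is testable end to end with known answers.

## Worked example

```python
from mpskel import (LatticeConfig, autocorrelation, dominant_period,
                    make_trace, profile_from_localizations,
                    simulate_irregular, simulate_lattice)

trace = make_trace(length_um=30.0, curvature=0.0)
cfg = LatticeConfig(seed=1)          # 190 nm rings, 30 locs/ring, 10% background

locs = simulate_lattice(trace, cfg)  # axon-like
prof = profile_from_localizations(locs, trace, bin_size_nm=10.0)
ac = autocorrelation(prof)
spec = dominant_period(prof)
print(len(locs), ac.amplitude, ac.first_peak_lag_nm, spec.dominant_period_nm)
```

prints (see `examples/periodicity_basics.py` for the full script):

```
  lattice: n=5241  amplitude=0.787  first_peak=190 nm  period=190.0 nm
irregular: n=5465  amplitude=0.053  (no confident spectral peak)
```

The lattice's amplitude of 0.79 is ~15× the irregular control's 0.05, and
both period estimators land on the generator's 190 nm ring spacing — the
axon-versus-dendrite contrast the score is designed to capture.  The other
scripts under `examples/` walk through subsampling robustness, live-cell
stability, FRAP turnover, polarity and the developmental time course, each
printing and explaining its numbers.

A thin CLI wraps the same functions for shell use:

```bash
mps simulate lattice --seed 1 --out run/
mps analyze periodicity --locs run/localizations.csv --trace run/trace.csv --out run/analysis/
mps demo --seed 1 --out report/
```

## Documentation

`docs/methods.md` describes the models, estimators, parameter defaults and
their rationale, the numerical choices, and what the synthetic generators
do and do not emulate about real SMLM data.
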