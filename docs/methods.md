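# Methods

This note documents the models and estimators implemented in `mpskel`, the
defaults and why they were chosen, and the limits of what the synthetic
generators demonstrate.

## The structure being quantified

The axonal membrane periodic skeleton is a quasi-one-dimensional lattice:
actin rings wrap the axon circumference at ~190 nm spacing and adjacent
rings are connected by spectrin tetramers (the spacing matches the tetramer
length).  In SMLM data the structure appears as a periodic modulation of
localization density along the axon shaft; dendrites show at most isolated
patches, so a good periodicity score must separate a long-range lattice
from an irregular distribution of equal density.

All analysis is done in the neurite's arc-length coordinate *s*:
localizations are assigned the arc length of their nearest point on a
polyline trace (lateral gate 400 nm by default, generous relative to a
typical ≤ 0.5 µm neurite diameter) and binned into half-open 10 nm bins.
The 10 nm default bin is ~1/19 of the period: fine enough that peak-lag
quantization is ≤ 5% of the period, coarse enough that bins are not empty
at realistic densities.  Internally every length is nanometers and every
time seconds; config fields whose natural magnitude is ≥ 1 µm take µm and
convert on ingest.

## Periodicity estimators

**Autocorrelation.**  For binned density ρ over N bins,

    AC(l) = Σ_s (ρ(s) − ρ̄)(ρ(s + l) − ρ̄) / (N · var ρ).

The biased (fixed-N) denominator guarantees AC(0) = 1 and |AC| ≤ 1, at the
cost of a mild taper at large lags — irrelevant below ~1 µm lag on ≥ 10 µm
segments.  Computation uses FFT correlation; a direct O(n²) summation
serves as the test oracle (agreement to 1e−10).  Degenerate (constant)
profiles raise a typed error rather than returning NaN so batch pipelines
can skip and log.

**Amplitude score.**  The first peak is the AC maximum inside a
configurable period band, default 130–260 nm around the expected ~190 nm;
the two flanking valleys are the minima on (0, peak) and (peak, 2·peak),
and the score is `AC(peak) − mean(valleys)`.  Ties resolve to the smallest
lag so results are deterministic.  The band is a search window, not a
constraint on the data: a structureless profile still gets a score (~0).

**Fourier period.**  The mean-subtracted profile is Hann-windowed,
zero-padded to ≥ 4× its length (next power of two) and the power maximum
inside a 100–400 nm period band is refined by parabolic interpolation of
the three surrounding samples; this yields ≤ 2 nm period resolution on a
30 µm profile.  A result is flagged *low confidence* when the peak power is
below 50× the median off-DC power.  The factor was calibrated against the
null: the maximum of the ~10³ effective exponential-distributed power
samples in the band reaches ~10–20× the median for pure shot noise, while
the weakest periodic profiles the generators produce exceed 400×.

**Averaging, subsampling, distance profiles.**  Averaged autocorrelation is
the pointwise mean over the shared lag range (amplitude recomputed on the
averaged curve, which suppresses valley noise).  Subsampling robustness
draws subsets without replacement and repeats the full profile →
autocorrelation → amplitude chain on the fixed full-trace grid; the
full-count amplitude is tabulated as the reference row.  The
periodicity-versus-distance table tiles the trace into consecutive
half-open segments; low-count or degenerate segments are flagged, never
dropped.  Note the amplitude is *not* count-invariant in principle: shot
noise enters the variance normalization, so halving the localizations
lowers the score by ~10–15% at default densities — the subsampling table
quantifies exactly this.

## Live-cell stability

Streams are split into equal-frame windows (remainder frames go to the
earliest windows; frame-based partition avoids dependence on wall-clock
metadata).  Per-window spectra use the same Fourier estimator, so a pure
translation of the lattice leaves them unchanged.  The phase shift between
windows is the peak lag of the Pearson-normalized cross-correlation of
their density profiles (positive lag = later pattern shifted distally);
the self-case reduces exactly to the autocorrelation.  The analysis
correlates 1D profiles rather than rendered 2D images; for a quasi-1D
lattice the phase information is the same.

Two design points matter for drift measurements:

- *Window density.*  The per-window localization density should match what
  one would accept for a fixed-cell analysis.  The live-series studies in
  the examples, demo and acceptance suite therefore use
  `locs_per_ring = 120` for four-window analyses, i.e. 30 localizations
  per ring per window — the same density as the fixed-cell default.
- *Within-window smear.*  A drifting lattice is smeared by
  drift × window-duration inside each window; once the smear approaches
  the 190 nm period, ring identity is lost and the comb ambiguity (peaks
  at the true shift ± k·190 nm) can win.  The drift-calibration study
  therefore uses 200 s movies (50 s windows), keeping the smear ≤ 100 nm
  at the largest tested drift of 2 nm/s.  With per-ring position jitter
  breaking the comb symmetry, recovered shift is linear in imposed shift
  with unit slope.

## FRAP

The ratio method calibrates acquisition photobleaching: with pre-bleach
reference mean R̄₀,

    corrected(t) = roi(t) · R̄₀ / reference(t),
    R(t) = corrected(t) / mean(corrected, pre-bleach).

A reference sharing the ROI's bleaching envelope is removed exactly.  The
baseline is the mean over all pre-bleach samples (≥ 2 required) rather
than a single frame, which would be needlessly noise-sensitive.  Recovery
times are counted from the bleach event.  The fit model is a
single-exponential with half-time parameterization,
`R(t) = R₀ + M·(1 − 2^(−t/t½))`, via least squares; multi-component or
reaction–diffusion FRAP models are out of scope.

Two presets encode the observed expression regimes:

- `high_expression`: mobile fraction 0.75, half-time 25 s, full bleach
  depth — the freely exchanging pool dominates, and R(300 s) = 0.7498,
  i.e. 75% recovery at 5 min to three decimals.  The half-time is set well
  below 300 s *and* the bleach depth to 1.0 deliberately: with partial
  bleach depth d < 1, R(∞) = (1 − d) + d·M ≠ M, so no half-time choice
  makes the 5-minute raw recovery equal the mobile fraction.  Since the
  recovery fraction is defined as the raw ratio to the pre-bleach
  intensity (not bleach-depth-normalized), the preset that reproduces the
  75%/5 min regime as ground truth must bleach fully.
- `low_expression`: mobile fraction 0 (bleach depth 0.9) — lattice-locked
  spectrin, essentially no recovery after 30 min.

## Polarity

The axon/dendrite enrichment is the ratio of masked mean intensities,
after subtracting the background-mask mean when one is supplied (default
ON with a background mask, OFF without; recorded in the result).  Masks
are inputs — compartment identification (e.g. MAP2 staining) is out of
scope.  In the synthetic image, stripe intensities are signal *added on
top of* the background level; consequently background-subtracted masked
means equal the configured intensities exactly in the noiseless case and
the wild-type preset (axon 200, dendrite 100 over background 10) has a
true ratio of exactly 2.  This additive convention is what makes the
background-subtracted ratio invariant to a constant offset.

## Synthetic generators: what they emulate, and what not

The lattice generator draws ring centers at `phase + k·190 nm` (phase
uniform by default so bins never align accidentally; fixable for tests),
jitters each ring's axial position (default sd 10 nm), places
`Poisson(30 × occupancy)` localizations per ring on an 80 nm-radius circle
normal to the axis, blurs each by an isotropic 10 nm localization
precision, and adds 10% uniform background in the padded bounding box.
Occupancy decays exponentially toward the distal end with a configurable
e-folding length (`inf` = uniform) — young neurons are emulated by short
decay lengths.  The irregular control matches the marginal density exactly
but draws axial positions from the smooth decay law, so its amplitude is
~0.05.  Ring jitter and localization precision are conventions (real
acquisitions do not report them per se); 10 nm is a typical SMLM lateral
precision and keeps the comb well resolved.  Rings are circles of
positions, not filled disks — lateral structure is irrelevant to the 1D
analyses.

Not modeled: fluorophore blinking/photophysics and camera-frame image
formation, the alternation of spectrin rings with actin–adducin rings
(two-color structure), stage drift, and localization-precision
heterogeneity.  Passing tests therefore demonstrate correctness of the
estimators on data satisfying the stated statistical model, not robustness
to every instrumental artifact of real recordings.

## Reproducibility and problem sizes

Every generator is a pure function of its config including the seed; the
pipeline derives per-stage seeds from one master seed by hashing the stage
name into a `SeedSequence`, so adding a stage never perturbs another
stage's stream.  All writers emit a JSON sidecar with software version and
optional config hash/seed.  The Monte-Carlo studies in the test and
acceptance suites use 30 µm axons (~158 rings, ~5×10³ localizations) with
20–50 seeds per claim and 50–100 subsampling repetitions — sizes at which
every statistic under test is stable to well inside its asserted
tolerance, while a full run completes in about a minute on one CPU.

## Known limitations

- Traces are inputs; there is no automated neurite tracing, drift
  correction, or axon/dendrite classification.
- The amplitude's absolute value depends on localization density, bin
  size and background fraction; comparisons are meaningful within a fixed
  analysis configuration (the subsampling table quantifies the density
  dependence).
- Cross-correlation phase shifts are unambiguous only while |true shift|
  is resolvable against the comb ambiguity (ring jitter plus finite
  window smear, see above); very fast drifts need shorter time windows.
- The FRAP fitter assumes a single well-mixed mobile pool.
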