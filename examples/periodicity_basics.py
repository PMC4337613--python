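"""Score the periodicity of a synthetic spectrin lattice vs an irregular control.

Builds a 30 µm straight axon, draws localizations from a 190 nm ring lattice
and from a structureless (dendrite-like) control, and prints the two
periodicity readouts: the autocorrelation amplitude (first peak minus the
mean of its flanking valleys; ~0 for no structure, approaching 2 for a
perfect lattice) and the FFT dominant period.
"""

from mpskel import (
    LatticeConfig,
    autocorrelation,
    dominant_period,
    make_trace,
    profile_from_localizations,
    simulate_irregular,
    simulate_lattice,
)

trace = make_trace(length_um=30.0, curvature=0.0)
cfg = LatticeConfig(seed=1)  # 190 nm period, 30 locs/ring, 10% background

for name, generator in (("lattice", simulate_lattice), ("irregular", simulate_irregular)):
    locs = generator(trace, cfg)
    profile = profile_from_localizations(locs, trace, bin_size_nm=10.0)
    ac = autocorrelation(profile)
    line = f"{name:>9}: n={len(locs)}  amplitude={ac.amplitude:.3f}"
    spec = dominant_period(profile)
    if spec.low_confidence:
        line += "  (no confident spectral peak)"
    else:
        line += f"  first_peak={ac.first_peak_lag_nm:.0f} nm  period={spec.dominant_period_nm:.1f} nm"
    print(line)

print("\nThe lattice scores an order of magnitude above the control and its")
print("recovered period matches the generator's 190 nm ring spacing.")
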