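"""Quantify spectrin turnover from FRAP traces.

Two regimes are simulated: a high-expression cell where excess spectrin is
freely exchanging (mobile fraction 0.75, fast recovery) and a low-expression
cell where spectrin is locked in the lattice (no recovery).  The analysis
calibrates acquisition photobleaching with the unbleached reference region,
then reports the recovery fraction relative to the pre-bleach intensity and
a single-exponential fit of the mobile fraction.
"""

import dataclasses

from mpskel import fit_recovery, frap_preset, recovery_fraction, simulate_frap

for name, t_query in (("high_expression", 300.0), ("low_expression", 1800.0)):
    cfg = dataclasses.replace(frap_preset(name), acq_bleach_rate_per_s=0.001)
    trace = simulate_frap(cfg)
    r = recovery_fraction(trace, t_query)[0]
    print(f"{name:>16}: recovery fraction at {t_query / 60:.0f} min = {r:.3f}")

noisy = dataclasses.replace(frap_preset("high_expression"), noise_sd=0.02, seed=3)
fit = fit_recovery(simulate_frap(noisy))
print(f"\nFit on a noisy high-expression trace: mobile fraction "
      f"{fit.mobile_fraction_est:.3f} (truth 0.75), half-time "
      f"{fit.halftime_est_s:.1f} s (truth 25 s).")
print("The high-expression regime recovers 75% within 5 minutes; the")
print("lattice-incorporated pool shows essentially no recovery after 30 min.")
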