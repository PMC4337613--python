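"""Synthetic developmental time course of lattice propagation.

During development the periodic skeleton originates near the cell body and
extends distally.  Cohorts with increasing occupancy decay lengths stand in
for increasingly mature neurons; the amplitude-versus-distance table shows
the periodicity front advancing.
"""

from mpskel import run_development_course

table = run_development_course(decay_lengths_um=(5.0, 15.0, None),
                               n_neurons=3, segment_length_um=5.0, seed=0)
for cohort, block in table.groupby("cohort"):
    amps = ", ".join(f"{v:.2f}" for v in block.mean_amplitude)
    print(f"{cohort:>12}: amplitude per 5 µm segment (proximal→distal): {amps}")

print("\nShort-decay cohorts (young neurons) lose periodicity within ~10 µm;")
print("the uniform cohort (mature) stays periodic along the whole axon.")
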