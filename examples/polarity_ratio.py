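"""Measure axon/dendrite intensity polarity on synthetic two-compartment images.

Wild-type neurons concentrate spectrin about twofold in axons; the
ankyrin-B-knockout preset raises the dendritic level to the axonal one.
The ratio is computed from masked mean intensities after subtracting the
background-mask mean.
"""

from mpskel import CompartmentMasks, intensity_ratio, polarity_preset, simulate_polarity_image

for name in ("wild_type", "ankyrin_b_ko"):
    sim = simulate_polarity_image(polarity_preset(name))
    masks = CompartmentMasks(sim.axon_mask, sim.dendrite_mask, sim.background_mask)
    res = intensity_ratio(sim.image, masks)
    rel = res.relative
    print(f"{name:>13}: axon/dendrite ratio = {res.ratio:.3f} "
          f"(relative intensity axon {rel[0]:.2f} : dendrite {rel[1]:.2f})")

print("\nA ratio of ~2 reproduces the wild-type axonal enrichment; ~1 means the")
print("compartments are indistinguishable, as after ankyrin-B loss.")
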