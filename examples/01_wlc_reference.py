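"""Simulate planar worm-like chains and recover the persistence length.

Chains are grown at one bead per base pair (0.34 nm) with harmonic
Boltzmann bend angles at lb = 56 nm, resampled at an AFM-like 7 nm link
length, and the persistence length is re-estimated from the bend-angle
variance between adjacent links (with the chord-averaging correction).
"""

import numpy as np

import wormtrace as wt

rng = np.random.default_rng(0)
model = wt.EnergyModel(kind="harmonic", lb=56.0)

chains = [wt.sample_chain(model, 4363, 0.34, rng) for _ in range(100)]
contours = [wt.resample_with_stride(c, 7.0) for c in chains]
sample = wt.collect_angles(contours, separation_links=1)
est = wt.estimate_lb(sample, "variance", rng=np.random.default_rng(0), n_boot=500)

print(f"chains:               {len(chains)} x {chains[0].n_beads} beads "
      f"({chains[0].contour_length:.0f} nm each)")
print(f"resampled link:       l0 = {contours[0].l0:.2f} nm (stride {contours[0].stride} bp)")
print(f"angles measured:      {len(sample)} at L = {sample.separation:.2f} nm")
print(f"estimated lb:         {est.lb:.1f} +/- {est.stderr:.1f} nm  (generating value 56)")
# The estimate uses the effective separation (k - 1/3) l0: link directions
# average the underlying tangent over one link, so the naive L/<theta^2>
# would read ~1.5x too stiff at adjacent-link separation.
print(f"naive L/<theta^2>:    {sample.separation / np.mean(sample.angles**2):.1f} nm "
      "(chord-averaging bias, for comparison)")
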