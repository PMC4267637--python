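"""The double-helix width as irreducible tracing noise.

The centerline of an AFM image of B-DNA cannot be localized better than the
2 nm envelope of the double helix.  Emulating that limit by shifting contour
vertices along interior-angle bisectors (uniform within +/- amplitude/2)
shows why the apparent persistence length collapses at the one-helical-turn
scale while longer-scale estimates barely move: the injected angle noise
scales as 1/l0^2.
"""

import wormtrace as wt
from wormtrace.pipeline import ExperimentConfig, run_noise_experiment

cfg = ExperimentConfig(
    seed=11, n_molecules=200, n_beads=4363, lb_nm=56.0,
    l0_nm=(3.5, 7.0, 10.5, 14.0), noise_amplitudes_nm=(0.0, 1.0, 2.0),
    n_boot=0,
)
df = run_noise_experiment(cfg)["estimates"]

print("apparent lb (nm) vs bisector-shift amplitude, 200 molecules at lb = 56 nm")
print("  l0 [nm]   clean   a=1 nm   a=2 nm")
for l0 in cfg.l0_nm:
    row = [df[(df.l0_nm == l0) & (df.amplitude_nm == a)].lb_nm.iloc[0]
           for a in (0.0, 1.0, 2.0)]
    print(f"  {l0:7.1f}   {row[0]:5.1f}   {row[1]:6.1f}   {row[2]:6.1f}")
print("A ~1-2 nm shift amplitude wrecks the 3.5 nm estimate but leaves the "
      ">=10.5 nm scales close to 56 nm.")
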