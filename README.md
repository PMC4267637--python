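# wormtrace

Does short DNA bend smoothly or kink?  AFM can answer this by measuring
bend angles between tangents of surface-adsorbed molecules down to one
helical turn (3.5 nm) — but at that scale the answer is limited by the
measurement itself: the tracing algorithm, the pixel grid, and the 2 nm
width of the double helix.  `wormtrace` is a library for running that whole
argument *in silico*:

* **Polymer models** — planar discrete chains at one bead per base pair
  (0.34 nm), sampled in equilibrium from either the harmonic worm-like
  chain (WLC; bend-angle variance `L/lb` in the planar convention) or a
  kinkable sub-elastic potential, quadratic below a 2° flex angle and
  concave beyond it.
* **Virtual AFM** — chains rendered as tip-broadened height ridges with
  seeded background noise and an optional helical centerline undulation
  (the height-maximum line of B-DNA wanders inside its 2 nm envelope), with
  ground truth attached to every image.
* **Tracing** — the sub-pixel prediction–correction tracer (height-weighted
  correction integral over a 10 nm perpendicular segment, three iterations,
  exact chord stepping) plus a centerline refinement stage (half-pixel
  perpendicular height maxima, acute-angle pruning, re-stepping) and
  bundle-spread diagnostics.
* **Bend statistics** — non-overlapping tangent-angle samples, `-ln P(θ)`
  tables, WLC-linearized coordinates (`-ln P` vs `θ²`), persistence-length
  estimators with molecule-level bootstrap errors, including the chord
  correction (`<θ²> = (k - 1/3)·l0/lb` between links `k` apart) without
  which resampled or traced contours read ~50% too stiff.
* **Pipeline** — seeded end-to-end experiments: simulate → resample →
  (render → trace → refine) → measure → estimate, plus the bisector-shift
  width-noise experiment, all bit-reproducible from a YAML config and seed.

It is aimed at people analyzing filament images (AFM or otherwise) who
want oracle-backed tests of their tracing and statistics, and at anyone
who wants to see concretely why single-base-pair kinkability is invisible
beyond one helical turn and why the shortest length scales are dominated
by the width of the molecule.

## Worked example

Simulate 100 full-length molecules (4363 bp) at `lb = 56 nm`, resample
them at an AFM-like 7 nm link and re-estimate the persistence length from
adjacent-link bend angles:

```bash
python examples/01_wlc_reference.py
```

```
chains:               100 x 4363 beads (1483 nm each)
resampled link:       l0 = 7.14 nm (stride 21 bp)
angles measured:      20600 at L = 7.14 nm
estimated lb:         56.2 +/- 0.6 nm  (generating value 56)
naive L/<theta^2>:    84.2 nm (chord-averaging bias, for comparison)
```

The estimate recovers the generating stiffness to 0.4%; the last line
shows what ignoring the chord correction would report.  The other example
scripts each demonstrate one capability and print what the numbers mean:

* `examples/02_kink_model_clt.py` — the kinkable potential is strongly
  non-Gaussian per base pair (linearized R² ≈ 0.94) but near-Gaussian at
  one helical turn (R² ≈ 0.997): the central-limit reason kinks are
  undetectable beyond a turn.
* `examples/03_virtual_afm_tracing.py` — renders a molecule, traces it
  back to within ~0.05 px of ground truth, raw and refined.
* `examples/04_width_noise.py` — bisector-shift noise of 1–2 nm amplitude
  collapses the apparent `lb` at 3.5 nm (56 → 28/12 nm) while ≥ 10.5 nm
  scales stay near 56 nm: the double-helix width as irreducible
  measurement noise.

There is also a thin CLI for batch work (`wormtrace simulate | render |
trace | angles | fit | experiment`); run `wormtrace --help`.

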