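# Methods

`wormtrace` is a virtual twin of an AFM bending-statistics experiment on
short DNA: it simulates planar chains from an explicit bending potential,
renders them as tip-broadened height images, re-measures them with a
sub-pixel contour tracer, and asks whether the recovered bend-angle
statistics behave like a smoothly bending elastic rod (worm-like chain,
WLC) or like a kinkable one.  This note records the models, the numerical
choices and their rationale, and what the synthetic data can and cannot
show.

## Chain models

Chains are planar, discretized at one bead per base pair (step
`a = 0.34 nm`) and *phantom* (no excluded volume; self-crossings are legal
and only matter when a chain is rendered into a single-molecule image).
Configurations are generated by cumulative turning of a unit tangent with
i.i.d. bend angles drawn from `P(theta) ∝ exp(-E(theta)/kT)` on
`(-pi, pi)`; this equilibrium sampling is exact for a chain whose energy is
a sum of independent per-joint terms, so no dynamical integrator is needed.

**Planar WLC convention.**  For the harmonic model
`E = kT·lb·theta²/(2a)`, so the bend angle between tangents separated by
contour length `L` is Gaussian with `<theta²> = L/lb` and
`<cos theta> = exp(-L/(2·lb))`.  This is the standard convention for
polymers equilibrated in 2D on a surface; the 3D persistence length enters
nowhere.  Reference stiffness throughout: `lb = 56 nm` (ensembles), with
`lb = 50 nm` used for single-joint discrete-model checks.

**Kinkable (sub-elastic) model.**  The alternative potential is quadratic,
`q·theta²`, below a flex angle `theta0` and concave above it:

    E(theta) = q·theta0² - (q/k)·theta0·(theta0 - pi)·[1 - ((theta - pi)/(theta0 - pi))^(2k)],   theta >= theta0

with defaults `theta0 = 2°`, `k = 2`, `q = 110 kcal/mol`.  The two branches
meet at `q·theta0²` and the concave branch rises monotonically to
`q·theta0² + (q/k)·theta0·(pi - theta0)` at `theta = pi` (about 6.1
kcal/mol, i.e. ~10 kT), so bends beyond a negligible `theta0` concentrate
into kinks rather than spreading along the chain.  Energies are converted
to Boltzmann weights with `kT = 0.593 kcal/mol` (298 K); the potential is
evaluated on `|theta|` and the planar angle distribution is symmetric.
Sampling is inverse-CDF on a tabulated grid of 1e-4 rad (deterministic
given a seeded generator, no rejection loop).  Note that with these
parameters and this convention the per-bp mean-square angle corresponds to
an effective persistence length of ~15 nm; the model is used here for the
*shape* of its statistics (kinked vs Gaussian), which is insensitive to
that scale.

**Central-limit behavior.**  Per base pair the kinkable distribution is
strongly non-Gaussian (a straight-line fit of `-ln P` against `theta²`
gives R² ≈ 0.94); summed over one helical turn (10 bp, 3.4 nm) it is
near-Gaussian (R² ≈ 0.997).  This is the quantitative reason single-bp
kinkability cannot be detected at or beyond the one-turn scale.

## Resampling and the chord correction

Digitized AFM contours have link lengths `l0 >> 1 bp`, which biases
short-length statistics relative to the underlying chain.  Simulated
chains are therefore resampled by keeping every `m`-th bead,
`m = round(l0/a)` (`m = 10, 21, 41` for `l0 = 3.5, 7, 14 nm`); the
resampled contour records the exact contour stride `m·a` as its link
length, and downstream statistics treat traced and resampled contours
identically.

A link of a resampled or traced contour is a *chord* of the underlying
curve, and a chord direction averages the underlying tangent over one
link.  For a WLC this gives the angle between chords `k` links apart the
variance `(k - 1/3)·l0/lb` — not `k·l0/lb`.  Estimators in this package
therefore use the effective separation

    L_eff = (k - 1/3)·l0  (+ l0/(3m²) exactly, when the stride m is known),

which recovers the generating `lb` from chord data to <1% at all link
lengths tested (the naive `L/<theta²>` would read 50% too stiff at
adjacent-link separation — measured 84 nm for a 56 nm ensemble at
`l0 = 7 nm`).  For angle samples drawn directly from the per-joint model
(`m = 1`) no correction applies, and the formula reduces to `k·l0` as it
must.

## Angle statistics

Angles are measured between links `i` and `i + k` with `i` advancing by
`k`, tiling the contour into fragments so each angle is counted once;
a contour with `n` links yields `floor((n-1)/k)` angles.  Distributions
are histogrammed on `|theta|` (default bin width 0.05 rad; per-bp-scale
distributions need ~0.02 rad to be resolved), normalized over populated
bins, and reported as `-ln P`.  "Linearized" views plot `-ln P` against
`theta²`, where the planar WLC reference

    -ln P(theta) = lb·theta²/(2·L) + ln Z,   Z = sqrt(2·pi·L/lb)·erf(pi·sqrt(lb/(2L)))

is a straight line of slope `lb/(2L)`.

Two `lb` estimators are provided: `variance` (`lb = L_eff/<theta²>`) and
`slope-fit` (count-weighted least squares of `-ln P` vs `theta²` over
`|theta| <= 60°`, bins with >= 5 counts, `lb = 2·L_eff·slope`).  Standard
errors come from a seeded bootstrap over molecules (default 1000
resamples), respecting within-molecule correlation.

## Virtual AFM renderer

The renderer is the synthetic-data generator standing in for real
(non-deposited) scans.  Height at a pixel is
`h·exp(-d²/(2·sigma²)) + noise`, with `d` the true distance from the pixel
center to the centerline polyline.  Defaults, chosen once as plausible for
tapping-mode imaging of DNA in liquid: ridge height `h = 2.0 nm` (the
hydrated duplex), cross-section `sigma = 2.5 nm` (FWHM ≈ 6 nm, i.e.
tip-broadened well past the 2 nm physical diameter), background noise
0–0.1 nm RMS (images are assumed flattened; the baseline is zero).  Pixel
sizes exercised: 1.95 and 3.9 nm.

An optional *helical undulation* displaces the rendered centerline
perpendicular to the local tangent by `A·sin(2·pi·s/period + phase)`
(period one helical turn, 3.5 nm; `A <= 1 nm`, half the 2 nm envelope).
This models the fact that the height-maximum line of B-DNA wanders inside
the enveloping cylinder, so the helix axis cannot be localized to better
than the duplex width no matter how sharp the tip.

Fixture sets pair every image with its generating chain; self-crossing
chains are redrawn by default.  Same seed, same bytes.

What the renderer does *not* emulate: scan-line artifacts and drift,
tip asymmetry and variable apparent width along the molecule, adsorption
inhomogeneity, neighboring molecules.  Consequences are discussed under
*Limitations*.

## Tracer

Stage 1, prediction–correction: from two seed points at one chain end,
each vertex is predicted one link ahead along the previous link and
corrected three times via the height-weighted integral
`X = ∫ Z(x)·x ds` over a 10 nm segment through the predicted point,
perpendicular to the prediction direction, position vectors from the
previous vertex (composite midpoint rule, step <= pixel/4; segments
partially outside the image are truncated and flagged, flagged stretches
are excluded from statistics).  The final step has exactly the requested
chord `l0`.  Heights are bilinear-interpolated, so the tracer is
sub-pixel.  Termination: corrected height below 25% of the running median
ridge height, image boundary, or a turn larger than 90° in one link — the
last stops the end-of-chain instability in which the iterated correction
swings the direction around and retraces the molecule (a >90° link turn is
a ~14 sigma event for the chains simulated here, so no genuine
configuration is lost).

Stage 2, refinement: sample the trace every half pixel; at each point find
the height maximum on a perpendicular segment (same 10 nm length, search
step pixel/10, then a least-squares parabola over a ±2 nm window — the
windowed fit halves the peak-position noise relative to a three-point
stencil); prune vertices whose interior turning exceeds 90° (perpendicular
searches near strong bends can land ahead of or behind the reference
link), worst vertex per sweep to a fixpoint; re-step the cleaned broken
line with exact chord `l0`; repeat until vertices move < 0.05 px or 10
rounds.  Peak *finding* uses a cached cubic-spline interpolant: a bilinear
surface is piecewise linear along grid-aligned lines, so its maximum snaps
to pixel rows (a 0.37 px systematic bias on an axis-aligned noiseless
ridge; 4e-5 px with the spline).  `interpolate_height` itself remains
bilinear.

Accuracy floor, measured on noiseless renders: lateral error < 0.001 px
(raw) and < 0.01 px (refined) on straight ridges; per-link turning on a
50 nm-radius arc recovered to 2% (raw) / 0.5% (refined).

Bundle diagnostics: repeat traces of one molecule are aligned by
closest-point projection onto the longest trace and their lateral scatter
and maximum pairwise distance are profiled along arc length, restricted to
the arc range all traces share.  Refinement pulls deliberately perturbed
traces (±2 nm wobbles) back to a common crest line, leaving the bundle
under one pixel for >= 90% of the arc.

## Width-noise model

The irreducible localization limit is emulated on *contours*: every
interior vertex is shifted along the bisector of its two links by a signed
distance uniform on `[-A/2, +A/2]` (endpoints: perpendicular to their
single link, and endpoints never enter angle statistics anyway).  The
injected angle variance scales as `1/l0²`, so at amplitude 1.5 nm the
apparent `lb` at the one-turn scale collapses (56 → ~17 nm) while
estimates at `L >= 10.5 nm` (measured at `l0 = L`, matching how longer
scales are digitized) move by < 10%.  Longer separations on a *fixed*
short link length are hit harder (the shared-link geometry adds
`~4·(A²/12)/l0²` of variance regardless of `k`), which is why the
longer-scale checks use longer links.

## Pipeline and reproducibility

Three orchestrated experiments — reference MC, noise experiment, imaging
experiment — communicate only through documented formats (contour CSV,
float-TIFF + JSON sidecar, TSV tables, JSON estimates, YAML configs).
Every config carries a mandatory seed; outputs embed the seed and a config
hash, and reruns are bit-identical.  Desk-scale defaults: 30–300 molecules
per condition, full-length chains (4363 beads) for pure-simulation runs
and 1200-bead chains for rendered runs, sizes chosen so sampling error on
`lb` stays at the few-percent level.

## Limitations

* The renderer's ridge is symmetric and its width constant, so the
  prediction–correction (centroid) tracer is better conditioned here than
  on real scans: it low-pass filters the centerline and on clean renders
  *over*-smooths at short link lengths (apparent `lb` slightly above
  truth) instead of reproducing the noisy, nearly exponential short-scale
  distributions real images give the original algorithm.  The short-scale
  artifact does appear, strongly, when the crest-following refined tracer
  meets the helical undulation (apparent `lb` ≈ 25 nm at `l0 = 3.5` vs
  ≈ 50 nm at `l0 = 10.5` for a 1 nm amplitude) — the mechanism the
  width-noise model then reproduces without imaging.
* Passing tests show the measurement chain is unbiased on this image
  model; they cannot certify behavior under tip artifacts, crossings or
  crowding, which are out of scope.
* The kinkable model's parameters are taken as given; no fitting of kink
  parameters to data is provided.
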