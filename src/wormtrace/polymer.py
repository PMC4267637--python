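"""Planar discrete chain models of DNA bending.

Two bending potentials are implemented for a chain discretized at one bead
per base pair (0.34 nm rise):

* ``harmonic`` — the worm-like chain (WLC): quadratic bending energy
  parameterized by the bending persistence length ``lb``.  In the planar
  convention used throughout this package the bend angle between tangents
  separated by contour length ``L`` is Gaussian with variance ``L / lb``, so
  the tangent correlation decays as ``<cos theta> = exp(-L / (2 lb))``.
* ``lsec`` — a kinkable, linear sub-elastic chain potential: quadratic
  (``q theta^2``) below a small flex angle ``theta0`` and concave beyond it,
  so that bends larger than ``theta0`` concentrate into kinks instead of
  distributing along the chain::

      E(theta) = q theta^2                                     theta < theta0
      E(theta) = q theta0^2
                 - (q/k) theta0 (theta0 - pi)
                   [1 - ((theta - pi)/(theta0 - pi))^(2k)]     theta >= theta0

  The default parameters are ``theta0 = 2 deg``, ``k = 2``,
  ``q = 110 kcal/mol``.

Chains are "phantom": no excluded volume, self-crossings allowed.  All
randomness flows through an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._geometry import perp, unit

#: Thermal energy at 298 K in kcal/mol, used to turn bending energies into
#: Boltzmann weights.
KT_KCAL_MOL = 0.593

#: Rise per base pair of B-DNA, nm.
BP_STEP_NM = 0.34

#: Resolution of the tabulated inverse CDF used for kinkable-potential
#: sampling, radians.
_LSEC_GRID_STEP = 1e-4


@dataclass(frozen=True)
class EnergyModel:
    """Bending potential of a single chain link.

    Parameters
    ----------
    kind
        ``"harmonic"`` (WLC) or ``"lsec"`` (kinkable).
    lb
        Bending persistence length in nm; required for the harmonic model.
    theta0, k, q
        Kinkable-potential parameters: flex angle (radians), exponent and
        stiffness (kcal/mol).
    kT
        Thermal energy in kcal/mol.
    """

    kind: str = "harmonic"
    lb: float | None = 56.0
    theta0: float = np.deg2rad(2.0)
    k: int = 2
    q: float = 110.0
    kT: float = KT_KCAL_MOL

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic", "lsec"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "harmonic":
            if self.lb is None or self.lb <= 0:
                raise ValueError("harmonic model requires lb > 0")
        else:
            if not 0.0 < self.theta0 < np.pi:
                raise ValueError("theta0 must lie in (0, pi)")
            if int(self.k) != self.k or self.k < 1:
                raise ValueError("k must be a positive integer")
            if self.q <= 0:
                raise ValueError("q must be positive")
        if self.kT <= 0:
            raise ValueError("kT must be positive")


@dataclass
class BeadChain:
    """Planar chain with equal link lengths (one bead per base pair)."""

    positions: np.ndarray  # (n, 2) nm
    step: float  # nm
    model: EnergyModel

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.positions) < 2:
            raise ValueError("a chain needs at least 2 beads")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def contour_length(self) -> float:
        return (self.n_beads - 1) * self.step

    def translated(self, offset: np.ndarray) -> "BeadChain":
        return replace(self, positions=self.positions + np.asarray(offset, float))


@dataclass
class Contour:
    """Discretized molecule outline with nominal link length ``l0``.

    ``source`` records provenance: ``mc_resampled`` (stride resampling of a
    simulated chain; the stored ``l0`` is then the exact contour stride,
    i.e. stride x bead step), ``traced`` (measured from an image) or
    ``noisy`` (after the bisector-shift noise model).
    """

    vertices: np.ndarray  # (n, 2) nm
    l0: float  # nm
    source: str = "mc_resampled"
    stride: int | None = None  # beads per link for mc_resampled contours

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 2:
            raise ValueError("a contour needs at least 2 vertices")
        if self.l0 <= 0:
            raise ValueError("l0 must be positive")

    @property
    def n_links(self) -> int:
        return len(self.vertices) - 1


def bend_energy(theta, model: EnergyModel, step: float = BP_STEP_NM):
    """Bending energy (kcal/mol) of a single link bent by ``theta`` radians.

    The harmonic branch is ``kT * lb * theta^2 / (2 * step)`` (planar
    convention); the kinkable branch evaluates the two-piece potential on
    ``|theta|``.  Scalar or array ``theta`` accepted; ``|theta|`` must not
    exceed pi.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(np.abs(theta) > np.pi + 1e-12):
        raise ValueError("theta outside [-pi, pi]")
    t = np.abs(theta)
    if model.kind == "harmonic":
        if step <= 0:
            raise ValueError("step must be positive")
        out = model.kT * model.lb * t**2 / (2.0 * step)
    else:
        ratio = (t - np.pi) / (model.theta0 - np.pi)
        concave = model.q * model.theta0**2 - (model.q / model.k) * model.theta0 * (
            model.theta0 - np.pi
        ) * (1.0 - ratio ** (2 * model.k))
        out = np.where(t < model.theta0, model.q * t**2, concave)
    return out if out.ndim else float(out)


def _lsec_inverse_cdf(model: EnergyModel):
    """Tabulated quantile function of the kinkable Boltzmann density."""
    grid = np.arange(-np.pi, np.pi + _LSEC_GRID_STEP, _LSEC_GRID_STEP)
    grid[-1] = np.pi
    pdf = np.exp(-bend_energy(grid, model) / model.kT)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(grid))])
    if cdf[-1] <= 0 or not np.isfinite(cdf[-1]):
        raise ValueError("bend-angle density is not normalizable")
    cdf /= cdf[-1]
    return cdf, grid


_LSEC_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def sample_bend_angles(
    model: EnergyModel, step: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. signed bend angles from exp(-E(theta)/kT) on (-pi, pi).

    The harmonic case is a normal distribution with variance ``step / lb``,
    truncated to (-pi, pi) by redrawing out-of-range values (negligible for
    ``lb >> step``).  The kinkable case uses inverse-CDF sampling on a dense
    tabulated grid, deterministic for a given generator state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model.kind == "harmonic":
        sigma = np.sqrt(step / model.lb)
        out = rng.normal(0.0, sigma, n)
        bad = np.abs(out) > np.pi
        while bad.any():
            out[bad] = rng.normal(0.0, sigma, int(bad.sum()))
            bad = np.abs(out) > np.pi
        return out
    key = (model.theta0, model.k, model.q, model.kT)
    if key not in _LSEC_CACHE:
        _LSEC_CACHE[key] = _lsec_inverse_cdf(model)
    cdf, grid = _LSEC_CACHE[key]
    return np.interp(rng.random(n), cdf, grid)


def sample_chain(
    model: EnergyModel,
    n_beads: int,
    step: float = BP_STEP_NM,
    rng: np.random.Generator | None = None,
) -> BeadChain:
    """Grow a phantom planar chain by cumulative turning of a unit tangent.

    The first link points along +x; each subsequent link turns by a bend
    angle drawn from the model's Boltzmann distribution.  All link lengths
    equal ``step`` exactly.
    """
    if n_beads < 2:
        raise ValueError("n_beads must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    turns = sample_bend_angles(model, step, n_beads - 2, rng) if n_beads > 2 else np.empty(0)
    headings = np.concatenate([[0.0], np.cumsum(turns)])
    steps = step * np.column_stack([np.cos(headings), np.sin(headings)])
    positions = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return BeadChain(positions=positions, step=step, model=model)


def resample_with_stride(chain: BeadChain, l0: float) -> Contour:
    """Keep every m-th bead, ``m = round(l0 / step)``; drop the remainder.

    Mirrors how digitized AFM contours subsample the underlying base-pair
    chain.  The returned contour's ``l0`` is the exact contour stride
    ``m * step`` (e.g. 7.14 nm for a nominal 7 nm on a 0.34 nm chain), which
    is the contour length separating consecutive tangents.
    """
    if l0 < chain.step:
        raise ValueError("l0 must be at least the bead step")
    m = int(round(l0 / chain.step))
    vertices = chain.positions[:: m]
    return Contour(vertices=vertices, l0=m * chain.step, source="mc_resampled", stride=m)


def apply_bisector_noise(
    contour: Contour, amplitude: float, rng: np.random.Generator
) -> Contour:
    """Blur vertex positions along interior-angle bisectors.

    Models the irreducible centerline localization error of AFM imaging (the
    2 nm width of the double helix): every interior vertex is shifted along
    the bisector of the angle between its two adjacent links by a signed
    distance uniform on ``[-amplitude/2, +amplitude/2]``.  Endpoints, whose
    bisector is undefined, move along the perpendicular to their single
    link.  ``amplitude = 0`` returns an identical contour.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    v = contour.vertices
    if amplitude == 0:
        return Contour(vertices=v.copy(), l0=contour.l0, source="noisy", stride=contour.stride)
    n = len(v)
    dirs = np.zeros_like(v)
    # interior vertices: bisector of the two adjacent links
    u_prev = v[:-2] - v[1:-1]
    u_next = v[2:] - v[1:-1]
    u_prev = u_prev / np.hypot(u_prev[:, 0], u_prev[:, 1])[:, None]
    u_next = u_next / np.hypot(u_next[:, 0], u_next[:, 1])[:, None]
    b = u_prev + u_next
    norm = np.hypot(b[:, 0], b[:, 1])
    straight = norm < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        b = b / norm[:, None]
    if straight.any():
        # locally straight: bisector degenerates to the link perpendicular
        pp = np.column_stack([-u_next[:, 1], u_next[:, 0]])
        b[straight] = pp[straight]
    dirs[1:-1] = b
    dirs[0] = perp(unit(v[1] - v[0]))
    dirs[-1] = perp(unit(v[-1] - v[-2]))
    shifts = rng.uniform(-amplitude / 2.0, amplitude / 2.0, n)
    return Contour(
        vertices=v + shifts[:, None] * dirs,
        l0=contour.l0,
        source="noisy",
        stride=contour.stride,
    )
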