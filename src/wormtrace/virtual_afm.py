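"""Virtual AFM: render simulated chains into height images.

The renderer is the package's synthetic-data generator.  It emulates the
features of flattened tapping-mode scans of surface-adsorbed DNA that matter
for contour tracing:

* a tip-broadened ridge — Gaussian cross-section of width ``ridge_sigma``
  around the molecule centerline, peak height ``ridge_height``;
* an optional helical centerline undulation — the height-maximum line of
  real B-DNA wanders inside the 2 nm enveloping cylinder of the double
  helix, so the rendered centerline can be offset perpendicular to the local
  tangent by ``amplitude * sin(2 pi s / period + phase)`` (period defaults to
  one helical turn, 3.5 nm);
* additive zero-mean Gaussian background noise (images are assumed already
  flattened, so the baseline is zero).

Heights are computed from the true distance to the centerline polyline, not
from per-vertex splats, so bead spacing leaves no artifacts.  Ground truth
is carried alongside every rendered image for oracle-based scoring of the
tracer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import polymer
from ._geometry import arc_lengths
from .polymer import BeadChain, Contour, EnergyModel


@dataclass
class HeightImage:
    """Flattened AFM height map: heights in nm on a square-pixel grid.

    Pixel ``[row, col]`` is centred at physical ``(x, y) =
    (col * pixel_size, row * pixel_size)``.
    """

    heights: np.ndarray  # (rows, cols), nm
    pixel_size: float  # nm per pixel

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (x, y) position of the last pixel center, nm."""
        rows, cols = self.heights.shape
        return ((cols - 1) * self.pixel_size, (rows - 1) * self.pixel_size)


@dataclass(frozen=True)
class RenderParams:
    """Appearance of the rendered molecule.

    ``ridge_height`` ~ apparent height of hydrated DNA in liquid scans;
    ``ridge_sigma`` sets the tip-broadened apparent width (FWHM =
    2.355 sigma, so the 2.5 nm default gives ~6 nm, well above the 2 nm
    physical diameter); ``undulation_amplitude`` is capped at 1 nm, half the
    enveloping cylinder.
    """

    ridge_height: float = 2.0
    ridge_sigma: float = 2.5
    undulation_amplitude: float = 0.0
    undulation_period: float = 3.5
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.ridge_sigma <= 0:
            raise ValueError("ridge_sigma must be positive")
        if not 0.0 <= self.undulation_amplitude <= 1.0:
            raise ValueError("undulation_amplitude must lie in [0, 1]")
        if self.undulation_period <= 0:
            raise ValueError("undulation_period must be positive")
        if self.ridge_height < 0 or self.noise_sigma < 0:
            raise ValueError("ridge_height and noise_sigma must be >= 0")


def undulate_centerline(
    contour: Contour, amplitude: float, period: float = 3.5, phase: float = 0.0
) -> Contour:
    """Offset each vertex perpendicular to the local tangent by a sine wave.

    The offset at arc length ``s`` from the chain start is
    ``amplitude * sin(2 pi s / period + phase)``; all displaced points stay
    within ``amplitude`` of the original polyline.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if not 0.0 <= amplitude <= 1.0:
        raise ValueError("amplitude must lie in [0, 1] nm")
    v = contour.vertices
    if amplitude == 0.0:
        return Contour(vertices=v.copy(), l0=contour.l0, source=contour.source, stride=contour.stride)
    s = arc_lengths(v)
    # vertex tangent = normalized mean of adjacent link directions
    d = np.diff(v, axis=0)
    d = d / np.hypot(d[:, 0], d[:, 1])[:, None]
    t = np.empty_like(v)
    t[0], t[-1] = d[0], d[-1]
    mid = d[:-1] + d[1:]
    nrm = np.hypot(mid[:, 0], mid[:, 1])
    nrm = np.where(nrm < 1e-12, 1.0, nrm)
    t[1:-1] = mid / nrm[:, None]
    normal = np.column_stack([-t[:, 1], t[:, 0]])
    offset = amplitude * np.sin(2.0 * np.pi * s / period + phase)
    return Contour(
        vertices=v + offset[:, None] * normal,
        l0=contour.l0,
        source=contour.source,
        stride=contour.stride,
    )


def _min_dist_sq_grid(
    shape: tuple[int, int], pixel_size: float, poly: np.ndarray, cutoff: float
) -> np.ndarray:
    """Squared distance from each pixel center to the polyline, computed on
    per-segment local windows (inf beyond ``cutoff``)."""
    rows, cols = shape
    d2 = np.full(shape, np.inf)
    a_all = poly[:-1]
    b_all = poly[1:]
    for a, b in zip(a_all, b_all):
        x_lo = min(a[0], b[0]) - cutoff
        x_hi = max(a[0], b[0]) + cutoff
        y_lo = min(a[1], b[1]) - cutoff
        y_hi = max(a[1], b[1]) + cutoff
        c0 = max(int(np.floor(x_lo / pixel_size)), 0)
        c1 = min(int(np.ceil(x_hi / pixel_size)), cols - 1)
        r0 = max(int(np.floor(y_lo / pixel_size)), 0)
        r1 = min(int(np.ceil(y_hi / pixel_size)), rows - 1)
        if c1 < c0 or r1 < r0:
            continue
        xs = np.arange(c0, c1 + 1) * pixel_size
        ys = np.arange(r0, r1 + 1) * pixel_size
        gx, gy = np.meshgrid(xs, ys)
        dx, dy = b[0] - a[0], b[1] - a[1]
        len2 = dx * dx + dy * dy
        if len2 == 0.0:
            px, py = gx - a[0], gy - a[1]
        else:
            t = np.clip(((gx - a[0]) * dx + (gy - a[1]) * dy) / len2, 0.0, 1.0)
            px = gx - (a[0] + t * dx)
            py = gy - (a[1] + t * dy)
        window = d2[r0 : r1 + 1, c0 : c1 + 1]
        np.minimum(window, px * px + py * py, out=window)
    return d2


def render_image(
    contour: Contour | np.ndarray,
    params: RenderParams,
    pixel_size: float,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
) -> HeightImage:
    """Render a centerline polyline into a height image.

    Height at a pixel is ``ridge_height * exp(-d^2 / (2 ridge_sigma^2))``
    with ``d`` the distance from the pixel center to the polyline, plus
    optional Gaussian background noise.  The polyline (in physical nm
    coordinates, which are also image coordinates) must fit inside the
    canvas with a margin of at least ``3 * ridge_sigma``; if ``shape`` is
    omitted a canvas just large enough is chosen.
    """
    pts = contour.vertices if isinstance(contour, Contour) else np.asarray(contour, float)
    margin = 3.0 * params.ridge_sigma
    if shape is None:
        hi = pts.max(axis=0) + margin
        shape = (
            int(np.ceil(hi[1] / pixel_size)) + 1,
            int(np.ceil(hi[0] / pixel_size)) + 1,
        )
    rows, cols = shape
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    if (
        lo[0] < margin - 1e-9
        or lo[1] < margin - 1e-9
        or hi[0] > (cols - 1) * pixel_size - margin + 1e-9
        or hi[1] > (rows - 1) * pixel_size - margin + 1e-9
    ):
        raise ValueError("contour does not fit in the canvas with a 3-sigma margin")
    cutoff = 4.0 * params.ridge_sigma + pixel_size
    d2 = _min_dist_sq_grid(shape, pixel_size, pts, cutoff)
    heights = np.where(
        np.isfinite(d2),
        params.ridge_height * np.exp(-d2 / (2.0 * params.ridge_sigma**2)),
        0.0,
    )
    if params.noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        heights = heights + rng.normal(0.0, params.noise_sigma, shape)
    return HeightImage(heights=heights, pixel_size=pixel_size)


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for a reproducible set of virtual scans."""

    n_molecules: int = 20
    n_beads: int = 4363
    step: float = polymer.BP_STEP_NM
    lb: float = 56.0
    pixel_size: float = 1.95
    render: RenderParams = field(default_factory=RenderParams)
    undulation_phase_random: bool = True
    allow_crossings: bool = False
    max_retries: int = 50


@dataclass
class Fixture:
    """One rendered molecule with its ground truth."""

    image: HeightImage
    chain: BeadChain  # true per-bp chain, in image coordinates
    centerline: np.ndarray  # rendered centerline (undulated if requested)
    index: int


def _is_simple(points: np.ndarray) -> bool:
    from shapely.geometry import LineString

    return LineString(points).is_simple


def make_fixture_set(
    config: FixtureConfig, rng: np.random.Generator
) -> list[Fixture]:
    """Generate seeded (image, ground-truth chain) pairs.

    Chains are drawn from the harmonic planar model at ``config.lb``,
    optionally given a helical undulation, translated into the canvas with
    the required margin and rendered one molecule per image.  Self-crossing
    chains are redrawn by default (phantom chains may cross; crossing images
    confuse single-molecule tracing), up to ``max_retries`` per molecule.
    """
    model = EnergyModel(kind="harmonic", lb=config.lb)
    out: list[Fixture] = []
    margin = 3.0 * config.render.ridge_sigma + config.pixel_size
    for i in range(config.n_molecules):
        for _ in range(config.max_retries):
            chain = polymer.sample_chain(model, config.n_beads, config.step, rng)
            if config.allow_crossings or _is_simple(chain.positions):
                break
        else:
            raise RuntimeError(
                "could not draw a non-self-crossing chain; "
                "raise max_retries or set allow_crossings"
            )
        offset = margin - chain.positions.min(axis=0)
        chain = chain.translated(offset)
        centerline = chain.positions
        if config.render.undulation_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi) if config.undulation_phase_random else 0.0
            c = Contour(vertices=centerline, l0=config.step, source="mc_resampled")
            centerline = undulate_centerline(
                c,
                config.render.undulation_amplitude,
                config.render.undulation_period,
                phase,
            ).vertices
        image = render_image(centerline, config.render, config.pixel_size, rng)
        out.append(Fixture(image=image, chain=chain, centerline=centerline, index=i))
    return out
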