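"""Sub-pixel contour tracing of filament height images.

The measurement chain has two stages:

1. **Prediction–correction tracing.**  Starting from two seed points at one
   end of the molecule, each new vertex is predicted by stepping forward
   along the previous link, then corrected by recomputing the direction from
   the height-weighted integral

       X = integral_0^10nm  ds  Z(x(s)) x(s)

   taken over a 10 nm segment through the predicted point, perpendicular to
   the current prediction direction, with position vectors measured from the
   previous accepted vertex.  The correction is applied three times, after
   which a step of exactly the requested link length ``l0`` is taken along
   the corrected direction.  Heights ``Z`` are evaluated anywhere by
   bilinear interpolation from the pixel grid, so the whole procedure runs
   at sub-pixel resolution.

2. **Centerline refinement.**  The correction integral is a centroid
   measure and inherits the seed placement, so repeated manual traces of one
   molecule form a bundle whose spread grows sharply at short link lengths.
   Refinement re-anchors the trace to the ridge crest: points are sampled
   every half pixel along the trace, the height maximum is located on a
   perpendicular segment through each (sub-pixel, parabolic peak
   interpolation), vertices whose interior turning exceeds 90 degrees are
   pruned iteratively (perpendicular searches near strong bends can land
   ahead of or behind the reference link), and the cleaned broken line is
   re-stepped with exact chord ``l0``.  The cycle repeats until vertex
   displacements fall below 0.05 px or a round limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._geometry import (
    arc_lengths,
    chord_step_polyline,
    closest_points_on_polyline,
    dedupe_consecutive,
    min_distance_to_polyline,
    perp,
    point_at_arc,
    tangents_at_arc,
    unit,
)
from .polymer import Contour
from .virtual_afm import HeightImage

log = logging.getLogger(__name__)

#: Length of the perpendicular correction segment, nm.
CORRECTION_SEGMENT_NM = 10.0


@dataclass
class Trace:
    """Traced molecule contour; every chord equals ``l0`` by construction."""

    vertices: np.ndarray  # (n, 2) nm
    l0: float
    image_ref: str = ""
    truncated: np.ndarray | None = None  # per-vertex flag: correction segment clipped

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.truncated is None:
            self.truncated = np.zeros(len(self.vertices), dtype=bool)

    @property
    def n_links(self) -> int:
        return len(self.vertices) - 1

    def as_contour(self) -> Contour:
        """Drop flagged boundary vertices and package as a Contour."""
        v, flags = self.vertices, self.truncated
        ok = ~flags
        if ok.sum() < 2:
            raise ValueError("trace has fewer than 2 clean vertices")
        # keep the longest run of unflagged vertices (flags cluster at ends)
        best, cur, start, best_start = 0, 0, 0, 0
        for i, good in enumerate(ok):
            if good:
                if cur == 0:
                    start = i
                cur += 1
                if cur > best:
                    best, best_start = cur, start
            else:
                cur = 0
        v = v[best_start : best_start + best]
        return Contour(vertices=v, l0=self.l0, source="traced")


@dataclass
class Bundle:
    """Traces of one molecule from different seeds/directions."""

    traces: list

    def __post_init__(self) -> None:
        if len(self.traces) < 2:
            raise ValueError("a bundle needs at least 2 traces")
        refs = {t.image_ref for t in self.traces}
        if len(refs) > 1:
            raise ValueError("bundle traces must share one image")


def interpolate_height(image: HeightImage, points: np.ndarray) -> np.ndarray:
    """Bilinear height at arbitrary (x, y) nm positions.

    Exact at pixel centers; raises if any point leaves the grid spanned by
    the outermost pixel centers.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    z, inside = _interp_masked(image, pts)
    if not inside.all():
        raise ValueError("point outside the image grid")
    return z if np.asarray(points).ndim == 2 else float(z[0])


def _interp_masked(image: HeightImage, pts: np.ndarray):
    """Bilinear interpolation with an inside-grid mask (outside -> 0)."""
    rows, cols = image.heights.shape
    c = pts[:, 0] / image.pixel_size
    r = pts[:, 1] / image.pixel_size
    inside = (c >= 0) & (c <= cols - 1) & (r >= 0) & (r <= rows - 1)
    z = ndimage.map_coordinates(
        image.heights, [np.clip(r, 0, rows - 1), np.clip(c, 0, cols - 1)], order=1
    )
    z[~inside] = 0.0
    return z, inside


def _interp_smooth_masked(image: HeightImage, pts: np.ndarray):
    """Cubic-spline interpolation for sub-pixel peak localization.

    A bilinear surface is piecewise linear along grid-aligned lines, so the
    height maximum on a perpendicular segment would snap to pixel rows or
    columns (up to half a pixel of bias on a noiseless ridge).  Peak
    finding therefore uses a smooth C2 interpolant; the spline coefficients
    are prefiltered once per image and cached on it.
    """
    coeffs = getattr(image, "_spline_coeffs", None)
    if coeffs is None:
        coeffs = ndimage.spline_filter(image.heights, order=3)
        image._spline_coeffs = coeffs
    rows, cols = image.heights.shape
    c = pts[:, 0] / image.pixel_size
    r = pts[:, 1] / image.pixel_size
    inside = (c >= 0) & (c <= cols - 1) & (r >= 0) & (r <= rows - 1)
    z = ndimage.map_coordinates(
        coeffs,
        [np.clip(r, 0, rows - 1), np.clip(c, 0, cols - 1)],
        order=3,
        prefilter=False,
    )
    z[~inside] = 0.0
    return z, inside


def correction_direction(
    image: HeightImage,
    origin: np.ndarray,
    predicted: np.ndarray,
    segment_length: float = CORRECTION_SEGMENT_NM,
    quad_step: float | None = None,
):
    """Height-weighted direction integral X over the perpendicular segment.

    The segment is centred on ``predicted``, perpendicular to
    ``predicted - origin``, and discretized by the composite midpoint rule at
    a step of at most ``pixel_size / 4``.  Position vectors are taken from
    ``origin`` (the previous accepted vertex).  Parts of the segment outside
    the image are dropped and the result flagged.

    Returns ``(X, truncated)``.
    """
    origin = np.asarray(origin, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    u = unit(predicted - origin)
    n_hat = perp(u)
    h = image.pixel_size / 4.0 if quad_step is None else quad_step
    m = max(int(np.ceil(segment_length / h)), 2)
    hs = segment_length / m
    s = -segment_length / 2.0 + (np.arange(m) + 0.5) * hs
    pts = predicted[None, :] + s[:, None] * n_hat[None, :]
    z, inside = _interp_masked(image, pts)
    x = (z[:, None] * (pts - origin[None, :])).sum(axis=0) * hs
    return x, bool((~inside).any())


def trace_molecule(
    image: HeightImage,
    seed_points: np.ndarray,
    l0: float,
    direction: int = 1,
    n_corrections: int = 3,
    segment_length: float = CORRECTION_SEGMENT_NM,
    termination_fraction: float = 0.25,
    max_turn: float = np.pi / 2.0,
    max_steps: int = 100_000,
    image_ref: str = "",
) -> Trace:
    """Trace one molecule by iterative prediction and correction.

    ``seed_points`` are two points near one chain end roughly ``l0`` apart;
    ``direction = -1`` swaps them, tracing the molecule the other way.  The
    trace stops when the interpolated height at the corrected prediction
    falls below ``termination_fraction`` of the running median ridge height,
    when the corrected direction turns back by more than ``max_turn``
    (at a chain end the iterated correction otherwise swings around and
    retraces the molecule), or when the prediction leaves the image.
    """
    seed_points = np.asarray(seed_points, dtype=float)
    if seed_points.shape != (2, 2):
        raise ValueError("seed_points must be two planar points")
    p0, p1 = (seed_points if direction >= 0 else seed_points[::-1])
    vertices = [p0.copy()]
    flags = [False]
    d = unit(p1 - p0)
    heights = []
    z0, ins = _interp_masked(image, p0[None, :])
    if ins[0]:
        heights.append(float(z0[0]))
    for _ in range(max_steps):
        prev = vertices[-1]
        pred = prev + l0 * d
        truncated = False
        ok = True
        for _ in range(n_corrections):
            x_vec, trunc = correction_direction(image, prev, pred, segment_length)
            truncated = truncated or trunc
            nx = np.hypot(x_vec[0], x_vec[1])
            if nx == 0.0:
                ok = False
                break
            pred = prev + l0 * (x_vec / nx)
        if not ok:
            break
        new_dir = unit(pred - prev)
        if np.arccos(np.clip(float(d @ new_dir), -1.0, 1.0)) > max_turn:
            break
        z, ins = _interp_masked(image, pred[None, :])
        if not ins[0]:
            break
        ridge_ref = float(np.median(heights)) if len(heights) >= 5 else np.inf
        if len(heights) >= 5 and z[0] < termination_fraction * ridge_ref:
            break
        vertices.append(pred)
        flags.append(truncated)
        heights.append(float(z[0]))
        d = unit(pred - prev)
    return Trace(
        vertices=np.asarray(vertices),
        l0=l0,
        image_ref=image_ref,
        truncated=np.asarray(flags, dtype=bool),
    )


def _perpendicular_maxima(
    image: HeightImage,
    points: np.ndarray,
    normals: np.ndarray,
    segment_length: float,
    search_step: float,
    peak_half_width: float = 2.0,
) -> np.ndarray:
    """Sub-pixel height maximum along a perpendicular segment at each point.

    The grid maximum is refined by a least-squares parabola fitted over the
    samples within ``peak_half_width`` of it (the ridge cross-section is
    locally parabolic there); fitting a window rather than a three-point
    stencil keeps the peak-position variance under background noise low.
    """
    m = int(np.floor(segment_length / 2.0 / search_step))
    offsets = np.arange(-m, m + 1) * search_step
    cand = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    flat = cand.reshape(-1, 2)
    z, inside = _interp_smooth_masked(image, flat)
    z = np.where(inside, z, -np.inf).reshape(len(points), len(offsets))
    idx = z.argmax(axis=1)
    best = offsets[idx].astype(float)
    w = max(int(round(peak_half_width / search_step)), 1)
    # clamp the window inside the segment; identical relative offsets per row
    ctr = np.clip(idx, w, len(offsets) - 1 - w)
    rel_idx = np.arange(-w, w + 1)
    rel = rel_idx * search_step
    zwin = z[np.arange(len(points))[:, None], ctr[:, None] + rel_idx[None, :]]
    finite = np.isfinite(zwin).all(axis=1)
    # closed-form quadratic LS on the common symmetric abscissa
    s2 = (rel**2).sum()
    s4 = (rel**4).sum()
    n_pts = len(rel)
    zf = np.where(np.isfinite(zwin), zwin, 0.0)
    b1 = (zf * rel[None, :]).sum(axis=1) / s2  # linear coefficient
    a_den = s4 - s2 * s2 / n_pts
    a2 = ((zf * (rel**2)[None, :]).sum(axis=1) - zf.sum(axis=1) * s2 / n_pts) / a_den
    good = finite & (a2 < 0)
    shift = np.zeros(len(points))
    shift[good] = -b1[good] / (2.0 * a2[good])
    shift = np.clip(shift, -peak_half_width, peak_half_width)
    best = np.where(good, offsets[ctr] + shift, best)
    return points + best[:, None] * normals


def _prune_acute(points: np.ndarray, max_turn: float = np.pi / 2.0) -> np.ndarray:
    """Iteratively delete the worst vertex whose turning exceeds ``max_turn``."""
    pts = points
    while len(pts) > 2:
        d = np.diff(pts, axis=0)
        lens = np.hypot(d[:, 0], d[:, 1])
        lens = np.where(lens == 0.0, 1.0, lens)
        u = d / lens[:, None]
        cosang = np.clip((u[:-1] * u[1:]).sum(axis=1), -1.0, 1.0)
        turn = np.arccos(cosang)
        worst = int(turn.argmax())
        if turn[worst] <= max_turn:
            break
        pts = np.delete(pts, worst + 1, axis=0)
    return pts


def refine_trace(
    image: HeightImage,
    trace: Trace,
    l0: float | None = None,
    segment_length: float = CORRECTION_SEGMENT_NM,
    max_rounds: int = 10,
    tol_px: float = 0.05,
) -> Trace:
    """Refine a trace onto the ridge crest (see module docstring).

    One round: half-pixel sampling along the polyline -> perpendicular
    height maxima -> acute-angle pruning -> exact-chord re-stepping.  Rounds
    repeat until the maximum displacement of the new vertices from the
    previous polyline is below ``tol_px`` pixels or ``max_rounds`` is hit.
    """
    if trace.n_links < 2:
        raise ValueError("refinement needs a trace with at least 2 links")
    l0 = trace.l0 if l0 is None else l0
    ps = image.pixel_size
    pts = trace.vertices
    for _ in range(max_rounds):
        total = arc_lengths(pts)[-1]
        s = np.arange(0.0, total + ps / 4.0, ps / 2.0)
        s[-1] = min(s[-1], total)
        base = point_at_arc(pts, s)
        tang = tangents_at_arc(pts, s)
        normals = np.column_stack([-tang[:, 1], tang[:, 0]])
        crest = _perpendicular_maxima(image, base, normals, segment_length, ps / 10.0)
        crest = dedupe_consecutive(crest, tol=1e-6)
        if len(crest) < 3:
            break
        crest = _prune_acute(crest)
        new_pts = chord_step_polyline(crest, l0)
        if len(new_pts) < 3:
            break
        disp = min_distance_to_polyline(new_pts, pts).max()
        pts = new_pts
        if disp < tol_px * ps:
            break
    return Trace(vertices=pts, l0=l0, image_ref=trace.image_ref)


def _oriented(trace_pts: np.ndarray, ref_pts: np.ndarray) -> np.ndarray:
    """Flip a trace if its end is closer to the reference start than its start."""
    if np.linalg.norm(trace_pts[0] - ref_pts[0]) > np.linalg.norm(trace_pts[-1] - ref_pts[0]):
        return trace_pts[::-1]
    return trace_pts


def bundle_spread(bundle: Bundle, station_step: float | None = None):
    """Cross-trace spread profile along the molecule.

    The longest trace serves as the arc-length reference; stations are
    placed every ``station_step`` (default: half the reference link length)
    along it, and every other trace contributes its closest polyline point
    at each station.  Returns a :class:`pandas.DataFrame` with columns
    ``arc_nm`` (station arc position), ``lateral_std_nm`` (RMS scatter of
    the bundle around its mean point) and ``max_pairwise_nm``.
    """
    import pandas as pd

    traces = sorted(bundle.traces, key=lambda t: -len(t.vertices))
    ref = traces[0].vertices
    if station_step is None:
        station_step = traces[0].l0 / 2.0
    total = arc_lengths(ref)[-1]
    s = np.arange(0.0, total + 1e-9, station_step)
    stations = point_at_arc(ref, s)
    pts_per_trace = [stations]
    supported = np.ones(len(stations), dtype=bool)
    for t in traces[1:]:
        v = _oriented(t.vertices, ref)
        proj = closest_points_on_polyline(stations, v)
        # stations projecting onto a trace endpoint lie outside that trace's
        # arc range; the spread is defined on the common overlap only
        at_end = (np.linalg.norm(proj - v[0], axis=1) < 1e-9) | (
            np.linalg.norm(proj - v[-1], axis=1) < 1e-9
        )
        supported &= ~at_end
        pts_per_trace.append(proj)
    stack = np.stack(pts_per_trace)  # (n_traces, n_stations, 2)
    stack = stack[:, supported]
    s = s[supported]
    mean = stack.mean(axis=0)
    dev = stack - mean[None]
    lateral_std = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    # max pairwise distance at each station
    diff = stack[:, None, :, :] - stack[None, :, :, :]
    pair = np.sqrt((diff**2).sum(axis=3)).max(axis=(0, 1))
    return pd.DataFrame(
        {"arc_nm": s, "lateral_std_nm": lateral_std, "max_pairwise_nm": pair}
    )
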