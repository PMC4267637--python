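"""Planar polyline helpers shared by the tracing and rendering stages.

All coordinates are (x, y) pairs in nanometres, stored as float64 arrays of
shape (n, 2).
"""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a single 2-vector; zero vectors are rejected."""
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def perp(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees."""
    return np.array([-v[1], v[0]], dtype=float)


def signed_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Signed planar angle (radians, in (-pi, pi]) turning u onto v."""
    return float(np.arctan2(u[0] * v[1] - u[1] * v[0], u[0] * v[0] + u[1] * v[1]))


def signed_angles(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized :func:`signed_angle` over rows of (n, 2) arrays."""
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = u[:, 0] * v[:, 0] + u[:, 1] * v[:, 1]
    return np.arctan2(cross, dot)


def segment_lengths(pts: np.ndarray) -> np.ndarray:
    return np.hypot(*np.diff(pts, axis=0).T)


def arc_lengths(pts: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    out = np.zeros(len(pts))
    out[1:] = np.cumsum(segment_lengths(pts))
    return out


def point_at_arc(pts: np.ndarray, s: np.ndarray | float) -> np.ndarray:
    """Position(s) at arc length(s) ``s`` along the polyline (linear interp)."""
    cum = arc_lengths(pts)
    s = np.atleast_1d(np.asarray(s, dtype=float))
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    out = np.column_stack([x, y])
    return out[0] if out.shape[0] == 1 and np.isscalar(s) else out


def tangents_at_arc(pts: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Unit direction of the polyline segment containing each arc position."""
    cum = arc_lengths(pts)
    d = np.diff(pts, axis=0)
    lens = np.hypot(d[:, 0], d[:, 1])
    dirs = d / lens[:, None]
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(dirs) - 1)
    return dirs[idx]


def chord_step_polyline(pts: np.ndarray, l0: float) -> np.ndarray:
    """Walk a polyline with a compass of opening ``l0``.

    Starting from the first point, each next vertex is the first forward
    intersection of the polyline with the circle of radius ``l0`` centred on
    the current vertex, so every chord of the result equals ``l0`` exactly.
    The trailing remainder shorter than ``l0`` is dropped.
    """
    if l0 <= 0:
        raise ValueError("l0 must be positive")
    pts = np.asarray(pts, dtype=float)
    verts = [pts[0]]
    c = pts[0]
    j, t0 = 0, 0.0
    n = len(pts)
    while True:
        found = False
        jj, tt = j, t0
        while jj < n - 1:
            a_pt = pts[jj]
            d = pts[jj + 1] - a_pt
            a = float(d @ d)
            if a > 0.0:
                f = a_pt - c
                b = 2.0 * float(f @ d)
                cc = float(f @ f) - l0 * l0
                disc = b * b - 4.0 * a * cc
                if disc >= 0.0:
                    r = np.sqrt(disc)
                    for t in ((-b - r) / (2 * a), (-b + r) / (2 * a)):
                        if tt + 1e-12 < t <= 1.0 + 1e-12:
                            t = min(t, 1.0)
                            c = a_pt + t * d
                            verts.append(c)
                            j, t0 = jj, t
                            found = True
                            break
            if found:
                break
            jj += 1
            tt = 0.0
        if not found:
            break
    return np.asarray(verts)


def min_distance_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each query point to the nearest point of a polyline."""
    points = np.atleast_2d(points)
    a = poly[:-1]
    d = poly[1:] - a
    len2 = np.einsum("ij,ij->i", d, d)
    len2 = np.where(len2 == 0.0, 1.0, len2)
    # (npts, nseg) projection parameter, clipped to the segment
    w = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("psk,sk->ps", w, d) / len2[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * d[None, :, :]
    dist = np.hypot(*(points[:, None, :] - closest).transpose(2, 0, 1))
    return dist.min(axis=1)


def closest_points_on_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Nearest point of ``poly`` for each query point."""
    points = np.atleast_2d(points)
    a = poly[:-1]
    d = poly[1:] - a
    len2 = np.einsum("ij,ij->i", d, d)
    len2 = np.where(len2 == 0.0, 1.0, len2)
    w = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("psk,sk->ps", w, d) / len2[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * d[None, :, :]
    dist2 = np.einsum("psk,psk->ps", points[:, None, :] - closest, points[:, None, :] - closest)
    idx = dist2.argmin(axis=1)
    return closest[np.arange(len(points)), idx]


def dedupe_consecutive(pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Drop consecutive duplicate vertices (within ``tol``)."""
    if len(pts) < 2:
        return pts
    keep = np.ones(len(pts), dtype=bool)
    d = segment_lengths(pts)
    keep[1:] = d > tol
    return pts[keep]
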