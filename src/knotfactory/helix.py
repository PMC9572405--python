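"""Implicit helical channel geometry.

The channel is a tube of radius R_ch around the helical mid-curve

    r0(t) = (k t, R_H cos(omega t), R_H sin(omega t)),

with the cylinder as the R_H = 0 special case.  The nearest mid-curve point of
a bead is found from the stationarity condition (p - r0(t)) . r0'(t) = 0,
which (the R_H^2 cross terms cancel) reduces to the scalar root problem

    g(t) = k (x - k t) - R_H omega (y sin(omega t) - z cos(omega t)) = 0,

solved by a safeguarded Newton iteration started from the axial projection
t0 = x/k — the same initial-estimate trick used for Kepler's equation in
celestial mechanics.  Under 2 pi k > R_ch the interior nearest-point problem
has a unique solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .config import HelixChannel

__all__ = [
    "midcurve_point",
    "stationarity_residual",
    "nearest_helix_point",
    "nearest_helix_points",
    "wall_force",
    "NearestPoint",
    "SolverError",
]


class SolverError(RuntimeError):
    pass


@dataclass
class NearestPoint:
    t: float
    point: np.ndarray
    distance: float
    normal: np.ndarray
    inside: bool


def midcurve_point(t, channel: HelixChannel) -> np.ndarray:
    """Point(s) on the channel mid-curve at parameter t (t may be an array)."""
    t = np.asarray(t, float)
    wt = channel.omega * t
    return np.stack(
        [channel.pitch_k * t, channel.R_H * np.cos(wt), channel.R_H * np.sin(wt)],
        axis=-1,
    )


def stationarity_residual(t, p, channel: HelixChannel):
    """g(t) for point p; g(t*) = 0 at the nearest mid-curve parameter."""
    t = np.asarray(t, float)
    x, y, z = np.asarray(p, float)
    k, RH, w = channel.pitch_k, channel.R_H, channel.omega
    wt = w * t
    return k * (x - k * t) - RH * w * (y * np.sin(wt) - z * np.cos(wt))


def nearest_helix_point(p, channel: HelixChannel, t0: float | None = None) -> NearestPoint:
    """Nearest mid-curve point, distance and unit outward normal for one bead.

    Points outside the tube (d > R_ch) are solved as well but flagged with
    ``inside=False``; at d = 0 the normal is the zero vector.
    """
    x, y, z = (float(v) for v in np.asarray(p, float))
    if t0 is None:
        t0 = x / channel.pitch_k
    t, d, nx, ny, nz, ok = _kernel.helix_distance_normal(
        x, y, z, channel.pitch_k, channel.R_H, float(channel.omega), t0
    )
    if not ok:
        raise SolverError(
            f"helix nearest-point iteration did not converge for p = {p!r}, "
            f"channel R_ch={channel.R_ch}, k={channel.pitch_k}, R_H={channel.R_H}"
        )
    point = midcurve_point(t, channel)
    return NearestPoint(
        t=float(t),
        point=point,
        distance=float(d),
        normal=np.array([nx, ny, nz]),
        inside=bool(d <= channel.R_ch),
    )


def nearest_helix_points(points: np.ndarray, channel: HelixChannel) -> tuple[np.ndarray, np.ndarray]:
    """Batch (t*, d) for an (n, 3) array of points; no per-call allocation."""
    pts = np.asarray(points, float)
    n = len(pts)
    ts = np.empty(n)
    ds = np.empty(n)
    kp, RH, w = channel.pitch_k, channel.R_H, float(channel.omega)
    for i in range(n):
        x, y, z = pts[i]
        t, d, _, _, _, ok = _kernel.helix_distance_normal(x, y, z, kp, RH, w, x / kp)
        if not ok:
            raise SolverError(f"nearest-point solve failed for point index {i}")
        ts[i] = t
        ds[i] = d
    return ts, ds


def wall_force(p, channel: HelixChannel) -> np.ndarray:
    """Repulsive wall force on a bead: WCA on the surface gap R_ch - d.

    The interaction length scale is the bead radius (``channel.wall_sigma``,
    default sigma/2), so contact occurs when the bead surface touches the
    channel surface; the force points along -normal, toward the mid-curve,
    and vanishes for gaps beyond 2^(1/6) wall_sigma.
    """
    np_ = nearest_helix_point(p, channel)
    if not np_.inside:
        raise RuntimeError(
            f"bead outside the channel wall: d = {np_.distance:.6g} > R_ch = {channel.R_ch}"
        )
    gap = channel.R_ch - np_.distance
    cut = 2.0 ** (1.0 / 6.0) * channel.wall_sigma
    if gap >= cut or np_.distance == 0.0:
        return np.zeros(3)
    fr = _kernel.wca_force_over_r(gap * gap, channel.wall_sigma) * gap  # -U'(gap)
    return -fr * np_.normal
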