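"""Deterministic synthetic curves and micro-trajectories for testing.

Parametric knots (torus knots, figure-eight), circles, rods and seeded random
walks provide exact, known topological invariants without running a
simulation; micro-trajectories exercise the full engine end-to-end at tiny
sizes.  Fixture randomness is isolated from simulation seeds: a fixture seed
never touches a production RNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np

from .config import SimulationConfig, HelixChannel, Protocol
from .dynamics import Trajectory, run_simulation

__all__ = ["CurveSpec", "make_curve", "make_micro_trajectory"]

_FAMILIES = ("circle", "torus_knot", "figure_eight", "random_walk", "rod")


@dataclass
class CurveSpec:
    family: str = "circle"
    n_vertices: int = 100
    p: int = 2                  # torus-knot winding (around the axis)
    q: int = 3                  # torus-knot winding (around the tube)
    handedness: int = 1         # -1 gives the exact z-mirror image
    persistence: float = 5.0    # random-walk bond correlation length (bonds)
    seed: int = 0
    closed: bool = True

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown curve family {self.family!r}")
        if self.family == "torus_knot":
            if gcd(self.p, self.q) != 1:
                raise ValueError(f"torus knot requires gcd(p, q) = 1, got ({self.p}, {self.q})")
            if self.n_vertices < 3 * self.p * self.q:
                raise ValueError(
                    "torus knot needs n_vertices >= 3 p q for a faithful discretization"
                )
        if self.handedness not in (1, -1):
            raise ValueError("handedness must be +1 or -1")
        if self.n_vertices < 3:
            raise ValueError("need at least 3 vertices")


def make_curve(spec: CurveSpec) -> np.ndarray:
    """Vertices (n, 3) of the requested curve; deterministic in the spec.

    ``handedness = -1`` returns the exact mirror image (z negated) of the
    ``handedness = +1`` curve, so chirality identities can be tested bitwise.
    """
    n = spec.n_vertices
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    if spec.family == "circle":
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros(n)])
    elif spec.family == "torus_knot":
        # (p,q) torus knot on a torus of radii (2, 1); (2,3) is the trefoil.
        # The -sin(q t) axial component makes handedness +1 the right-handed
        # (positive-writhe) representative.
        pts = np.column_stack([
            (2.0 + np.cos(spec.q * t)) * np.cos(spec.p * t),
            (2.0 + np.cos(spec.q * t)) * np.sin(spec.p * t),
            -np.sin(spec.q * t),
        ])
    elif spec.family == "figure_eight":
        pts = np.column_stack([
            (2.0 + np.cos(2.0 * t)) * np.cos(3.0 * t),
            (2.0 + np.cos(2.0 * t)) * np.sin(3.0 * t),
            np.sin(4.0 * t),
        ])
    elif spec.family == "rod":
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n, dtype=float)
    else:  # random_walk: correlated unit steps, optionally bridged closed
        rng = np.random.default_rng(spec.seed)
        steps = rng.standard_normal((n, 3))
        steps /= np.linalg.norm(steps, axis=1)[:, None]
        alpha = np.exp(-1.0 / max(spec.persistence, 1e-6))
        for i in range(1, n):
            v = alpha * steps[i - 1] + (1.0 - alpha) * steps[i]
            steps[i] = v / np.linalg.norm(v)
        pts = np.concatenate([[np.zeros(3)], np.cumsum(steps[:-1], axis=0)])
        if spec.closed:
            # harmonic bridge: remove the linear drift so the walk closes
            drift = (pts[-1] + steps[-1]) / n
            pts = pts - np.outer(np.arange(n), drift)
    if spec.handedness == -1:
        pts = pts.copy()
        pts[:, 2] = -pts[:, 2]
    return pts


def make_micro_trajectory(
    n_beads: int = 10,
    n_steps: int = 1000,
    seed: int = 0,
    helical: bool = True,
    omega: int = 1,
    piston_force: float = 0.0,
    mirror_noise: bool = False,
    D_over_P: float = 1.0,
    sample_interval: int = 100,
    gamma: float = 1.0,
    piston_gamma: float | None = None,
) -> Trajectory:
    """Seeded end-to-end mini simulation for integration tests.

    Bitwise reproducible for identical arguments; the mirrored setup
    (omega -> -omega, mirror_noise=True) yields the exactly z-mirrored
    trajectory.
    """
    config = SimulationConfig(n_beads=n_beads, gamma=gamma)
    channel = HelixChannel.from_confinement(
        D_over_P, helical=helical, omega=omega, bottom_wall=piston_force > 0
    )
    protocol = Protocol(
        pre_steps=0,
        prod_steps=n_steps,
        sample_interval=sample_interval,
        seed=seed,
        piston_force=piston_force,
        piston_gamma=piston_gamma,
        mirror_noise=mirror_noise,
    )
    return run_simulation(config, channel, protocol)
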