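"""Coarse-grained DNA force field: bonds, bending, excluded volume.

Potentials (reduced units, eps0 = k_B T = 1, sigma = 1):

* stretching  U_s(r)     = k_s (r - r0)^2
* bending     U_b(theta) = c (theta - theta0)^2 with theta0 = pi and
  c = k_bend/2 (default "half" convention, calibrated so k_bend = 20 gives a
  persistence length of 20 sigma) or c = k_bend ("full")
* excluded volume: Weeks-Chandler-Andersen (truncated + shifted LJ),
  U_ex(r) = 4 [(1/r)^12 - (1/r)^6 + 1/4] for r < 2^(1/6), else 0.

Scalar operations below are reference implementations used directly by tests;
`total_force` evaluates the complete per-bead force through the same compiled
kernel the integrator uses.
"""

from __future__ import annotations

import numpy as np

from . import _kernel
from .config import SimulationConfig, HelixChannel

__all__ = [
    "InvalidGeometryError",
    "bond_energy_force",
    "bend_energy_force",
    "wca_pair_energy_force",
    "total_force",
    "total_energy",
    "WCA_CUTOFF",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class InvalidGeometryError(ValueError):
    pass


def bond_energy_force(r: float, k_s: float = 80.0, r0: float = 1.0) -> tuple[float, float]:
    """Harmonic bond energy and scalar force magnitude -dU/dr at distance r."""
    if r <= 0:
        raise InvalidGeometryError(f"non-positive bond length r = {r}")
    dr = r - r0
    return k_s * dr * dr, -2.0 * k_s * dr


def bend_energy_force(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    k_bend: float = 20.0,
    theta0: float = np.pi,
    convention: str = "half",
) -> tuple[float, np.ndarray]:
    """Bending energy at the interior bead p2 and forces on the triplet.

    Returns (energy, forces) with forces of shape (3, 3); the three force
    vectors sum to zero (no net translation) and exert no net torque.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float)
    a = p1 - p2
    b = p3 - p2
    la = np.linalg.norm(a)
    lb = np.linalg.norm(b)
    if la == 0.0 or lb == 0.0:
        raise InvalidGeometryError("degenerate bead triplet (coincident beads)")
    pref = 0.5 * k_bend if convention == "half" else k_bend
    ah, bh = a / la, b / lb
    ct = float(np.clip(ah @ bh, -1.0, 1.0))
    theta = np.arccos(ct)
    dth = theta - theta0
    energy = pref * dth * dth
    st = np.sqrt(1.0 - ct * ct)
    coef = 2.0 * pref * dth / st if st > 1e-8 else -2.0 * pref
    f1 = -coef * (ct * ah - bh) / la
    f3 = -coef * (ct * bh - ah) / lb
    forces = np.stack([f1, -(f1 + f3), f3])
    return energy, forces


def wca_pair_energy_force(r: float) -> tuple[float, float]:
    """WCA pair energy and scalar force -dU/dr at distance r (sigma = 1)."""
    if r <= 0:
        raise InvalidGeometryError(f"WCA singularity: r = {r}")
    if r >= WCA_CUTOFF:
        return 0.0, 0.0
    inv6 = r ** -6
    energy = 4.0 * (inv6 * inv6 - inv6 + 0.25)
    force = 24.0 * (2.0 * inv6 * inv6 - inv6) / r
    return energy, force


class BlowUpError(RuntimeError):
    """Overlapping beads produced a diverging force; carries the frame."""

    def __init__(self, message: str, positions: np.ndarray | None = None):
        super().__init__(message)
        self.positions = positions


def _kernel_call(positions, config, channel, piston_x, piston_force_active):
    pos = np.ascontiguousarray(positions, dtype=float)
    n = pos.shape[0]
    pairs = np.empty((max(n * 64, 64), 2), dtype=np.int64)
    npairs = _kernel.build_pairs(pos, (WCA_CUTOFF + config.skin) ** 2, pairs)
    if npairs < 0:
        raise BlowUpError("neighbor-pair buffer overflow (extreme bead overlap)", pos)
    forces = np.empty_like(pos)
    if channel is not None:
        has_channel = True
        R_ch, RH, kp, omega = channel.R_ch, channel.R_H, channel.pitch_k, float(channel.omega)
        wall_sig = channel.wall_sigma
        bottom = channel.bottom_wall
    else:
        has_channel = False
        R_ch, RH, kp, omega, wall_sig, bottom = 1.0, 0.0, 1.0, 1.0, 0.5, False
    t_warm = pos[:, 0] / kp if kp != 0 else np.zeros(n)
    t_warm = np.ascontiguousarray(t_warm, dtype=float)
    epot, piston_rx, status = _kernel.compute_forces(
        pos, forces, pairs, npairs, t_warm,
        config.k_s, config.r0, config.bend_prefactor, config.k_tether,
        has_channel, R_ch, RH, kp, omega, wall_sig, bottom,
        piston_force_active, piston_x, 99.5,
    )
    return forces, epot, piston_rx, status


def total_force(
    positions: np.ndarray,
    config: SimulationConfig | None = None,
    channel: HelixChannel | None = None,
    piston_x: float | None = None,
) -> np.ndarray:
    """Per-bead total force for a conformation (free chain if channel is None)."""
    config = config or SimulationConfig(n_beads=max(3, len(positions)))
    forces, _, _, status = _kernel_call(
        positions, config, channel,
        piston_x if piston_x is not None else 0.0,
        piston_x is not None,
    )
    if status == 1:
        raise BlowUpError("bead outside the channel wall (d > R_ch)", np.asarray(positions))
    if not np.all(np.isfinite(forces)):
        raise BlowUpError("non-finite force (overlapping beads?)", np.asarray(positions))
    return forces


def total_energy(
    positions: np.ndarray,
    config: SimulationConfig | None = None,
    channel: HelixChannel | None = None,
    piston_x: float | None = None,
) -> float:
    """Total potential energy of a conformation (same terms as total_force)."""
    config = config or SimulationConfig(n_beads=max(3, len(positions)))
    _, epot, _, _ = _kernel_call(
        positions, config, channel,
        piston_x if piston_x is not None else 0.0,
        piston_x is not None,
    )
    return float(epot)
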