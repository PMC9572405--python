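"""Simulation parameters in reduced units.

The model works throughout in reduced units: the bead diameter ``sigma`` is the
length unit (one bead covers 8.5 bp of double-stranded DNA, 2.5 nm), the thermal
energy ``eps0 = k_B T`` is the energy unit and ``tau`` the intrinsic time unit
(74 ns of physical time).  Physical conversions are metadata only; nothing in
the engine depends on them.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

__all__ = ["SimulationConfig", "HelixChannel", "Protocol", "ConfigError"]

#: physical mapping constants (reporting only)
SIGMA_NM = 2.5
BP_PER_BEAD = 8.5
TAU_NS = 74.0


class ConfigError(ValueError):
    """A configuration invariant was violated; the message names the invariant."""


@dataclass
class SimulationConfig:
    """Force-field and integrator parameters of the coarse-grained DNA chain.

    Defaults correspond to a discretized worm-like chain of N = 300 beads with
    harmonic bonds U_s = k_s (r - r0)^2, harmonic bending and a purely repulsive
    WCA excluded volume.  The bending prefactor convention is switchable: with
    ``bend_convention = "half"`` the energy is (k_bend/2)(theta - pi)^2, which
    for k_bend = 20 reproduces the target persistence length P = 20 sigma
    (50 nm); ``"full"`` uses the bare quadratic k_bend (theta - pi)^2.
    """

    n_beads: int = 300
    k_s: float = 80.0          # bond stiffness, eps0/sigma^2 (no 1/2 prefactor)
    r0: float = 1.0            # equilibrium bond length, sigma
    k_bend: float = 20.0       # bending constant, eps0/rad^2
    bend_convention: str = "half"
    theta0: float = math.pi
    persistence_length: float = 20.0   # target P, sigma (metadata / analysis)
    gamma: float = 1.0         # Langevin friction, 1/tau
    mass: float = 1.0          # bead mass, reduced
    dt: float = 0.01           # integration time step, tau
    k_tether: float = 0.0      # optional harmonic tether of bead 0 to the origin
    skin: float = 0.8          # Verlet-list skin, sigma

    def __post_init__(self) -> None:
        if self.n_beads < 3:
            raise ConfigError("invariant N >= 3 violated: n_beads = %d" % self.n_beads)
        for name in ("k_s", "k_bend", "dt", "mass"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"invariant {name} > 0 violated: {getattr(self, name)}")
        if self.gamma < 0:
            raise ConfigError(f"invariant gamma >= 0 violated: {self.gamma}")
        if self.r0 <= 0:
            raise ConfigError("invariant r0 > 0 violated")
        if abs(self.theta0 - math.pi) > 1e-12:
            raise ConfigError("invariant theta0 = pi violated")
        if self.bend_convention not in ("half", "full"):
            raise ConfigError("bend_convention must be 'half' or 'full'")
        if self.k_tether < 0:
            raise ConfigError("invariant k_tether >= 0 violated")

    @property
    def bend_prefactor(self) -> float:
        """Effective prefactor c in U_b = c (theta - theta0)^2."""
        return 0.5 * self.k_bend if self.bend_convention == "half" else self.k_bend

    @property
    def contour_length(self) -> float:
        """Contour length L = N sigma (in sigma)."""
        return float(self.n_beads)

    @property
    def length_bp(self) -> float:
        """Represented DNA length in base pairs (N x 8.5 bp)."""
        return self.n_beads * BP_PER_BEAD

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class HelixChannel:
    """Implicit confining channel along the x axis.

    The mid-curve is r0(t) = (k t, R_H cos(omega t), R_H sin(omega t)); a bead
    is confined to mid-curve distance d <= R_ch (tube radius, D = 2 R_ch).
    ``R_H = 0`` is the cylinder.  The pitch parameter ``k`` sets the loop
    spacing d_H = 2 pi k; the default k = D/(2 pi) makes d_H = D.  ``omega``
    (+1/-1) is the handedness.  The bottom wall is the plane x = 0.
    """

    R_ch: float = 5.0
    R_H: float | None = None          # default R_ch / 3
    pitch_k: float | None = None      # default D / (2 pi) = R_ch / pi
    omega: int = 1
    length: float = 400.0             # L_ch, sigma
    bottom_wall: bool = False
    wall_sigma: float = 0.5           # wall WCA length scale (bead radius)

    def __post_init__(self) -> None:
        if self.R_ch <= 0:
            raise ConfigError("invariant R_ch > 0 violated")
        if self.R_H is None:
            self.R_H = self.R_ch / 3.0
        if self.pitch_k is None:
            self.pitch_k = self.R_ch / math.pi
        if self.omega not in (1, -1):
            raise ConfigError("invariant omega in {+1, -1} violated: omega = %r" % (self.omega,))
        if not 0.0 <= self.R_H < self.R_ch:
            raise ConfigError(
                "invariant 0 <= R_H < R_ch violated: R_H = %g, R_ch = %g" % (self.R_H, self.R_ch)
            )
        if 2.0 * math.pi * self.pitch_k <= self.R_ch:
            raise ConfigError(
                "invariant 2*pi*k > R_ch (nearest-point uniqueness) violated: "
                "2*pi*k = %g, R_ch = %g" % (2 * math.pi * self.pitch_k, self.R_ch)
            )
        if self.length <= 0:
            raise ConfigError("invariant L_ch > 0 violated")

    @property
    def diameter(self) -> float:
        return 2.0 * self.R_ch

    @property
    def loop_spacing(self) -> float:
        """Axial distance between helical loops, d_H = 2 pi k (sigma)."""
        return 2.0 * math.pi * self.pitch_k

    @property
    def is_cylinder(self) -> bool:
        return self.R_H == 0.0

    def mirrored(self) -> "HelixChannel":
        """The mirror-image channel (z -> -z, i.e. opposite handedness)."""
        return HelixChannel(
            R_ch=self.R_ch, R_H=self.R_H, pitch_k=self.pitch_k,
            omega=-self.omega, length=self.length,
            bottom_wall=self.bottom_wall, wall_sigma=self.wall_sigma,
        )

    @classmethod
    def from_confinement(
        cls,
        D_over_P: float,
        P: float = 20.0,
        helical: bool = True,
        omega: int = 1,
        length: float | None = None,
        bottom_wall: bool = False,
    ) -> "HelixChannel":
        """Channel for a confinement strength D/P (paper values 0.5, 1, 2)."""
        D = D_over_P * P
        R_ch = D / 2.0
        if length is None:
            length = 420.0
        return cls(
            R_ch=R_ch,
            R_H=(R_ch / 3.0 if helical else 0.0),
            pitch_k=D / (2.0 * math.pi),
            omega=omega,
            length=length,
            bottom_wall=bottom_wall,
        )


@dataclass
class Protocol:
    """Run protocol: equilibration, production sampling and optional piston."""

    pre_steps: int = 200_000
    prod_steps: int = 200_000
    sample_interval: int = 1_000
    seed: int = 0
    piston_force: float = 0.0          # F, eps0/sigma, >= 0, toward the bottom wall
    piston: bool = False
    piston_radius: float = 100.0       # sigma, fixed by the compression setup
    piston_gamma: float | None = None  # default 200 x bead friction (radius ratio)
    piston_thermostat: bool = True     # False = quasi-static (no piston noise)
    mirror_noise: bool = False         # negate z-noise (mirror-equivariance runs)

    def __post_init__(self) -> None:
        if self.pre_steps < 0 or self.prod_steps < 0:
            raise ConfigError("invariant step counts >= 0 violated")
        if self.sample_interval < 1:
            raise ConfigError("invariant sample_interval >= 1 violated")
        if self.piston_force < 0:
            raise ConfigError("invariant F >= 0 violated")
        if self.piston_force > 0:
            self.piston = True
        if self.piston_radius != 100.0:
            raise ConfigError("invariant piston radius fixed at 100 sigma violated")

    def resolved_piston_gamma(self, config: SimulationConfig) -> float:
        if self.piston_gamma is not None:
            return self.piston_gamma
        # radius ratio 100 sigma / 0.5 sigma = 200x the bead friction
        return 200.0 * config.gamma * config.mass
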