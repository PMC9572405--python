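"""Langevin dynamics of the confined chain with piston compression.

The equations of motion m r'' = -gamma m r' - grad U + R(t) sqrt(2 eps0 m
gamma) are integrated with a BAOAB velocity-Verlet/Ornstein-Uhlenbeck
splitting at dt = 0.01 tau.  The piston is a sphere of radius 100 sigma whose
center is constrained to the channel axis and moves as a single overdamped
Langevin coordinate under the applied compressive force plus the polymer
reaction; it interacts with the chain only (never with the walls).

A run consists of a pre-equilibration segment (discarded) followed by a
production segment sampled at a fixed interval.  Runs are deterministic for a
given seed; mirrored runs (mirrored channel, initial condition and noise
stream) produce bitwise-mirrored trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .config import HelixChannel, Protocol, SimulationConfig

__all__ = [
    "Conformation",
    "PistonState",
    "Trajectory",
    "InstabilityError",
    "initial_conformation",
    "langevin_step",
    "piston_update",
    "run_simulation",
    "run_repeats",
]

_STATUS_MESSAGES = {
    1: "wall violation: bead mid-curve distance exceeded R_ch",
    2: "instability: per-step displacement exceeded 0.5 sigma",
    3: "helix nearest-point solver failed to converge",
    4: "neighbor-pair buffer overflow",
}


class InstabilityError(RuntimeError):
    """Integration failed; carries the last-good frame for diagnosis."""

    def __init__(self, message: str, positions: np.ndarray, step: int):
        super().__init__(f"{message} (step {step})")
        self.positions = positions
        self.step = step


@dataclass
class Conformation:
    positions: np.ndarray
    velocities: np.ndarray
    frame_time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, float)
        self.velocities = np.ascontiguousarray(self.velocities, float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have matching shapes")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in conformation")


@dataclass
class PistonState:
    x: float
    radius: float = 100.0
    force: float = 0.0


@dataclass
class Trajectory:
    """Sampled production frames of one run."""

    positions: np.ndarray        # (n_frames, N, 3)
    velocities: np.ndarray
    times: np.ndarray            # (n_frames,), tau
    piston_x: np.ndarray         # (n_frames,), channel-axis piston center
    epot: np.ndarray             # (n_frames,), potential energy
    config: SimulationConfig
    channel: HelixChannel | None
    protocol: Protocol
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def frame(self, i: int) -> Conformation:
        return Conformation(self.positions[i], self.velocities[i], float(self.times[i]))


def initial_conformation(
    config: SimulationConfig,
    channel: HelixChannel | None = None,
    x_start: float = 1.0,
    mode: str = "axis",
    seed: int = 0,
) -> Conformation:
    """Extended starting conformation at bead spacing r0.

    ``mode="axis"`` (default) lays the chain straight along the channel x
    axis: the axis sits exactly R_H from the helical mid-curve, so the start
    is wall-violation-free whenever R_ch - R_H clears the wall cutoff, and it
    is the same near-equilibrium "I" conformation for every channel geometry.
    ``mode="midcurve"`` lays the beads on the mid-curve at arc-length spacing
    r0 instead (always wall-free, but tortuosity-shortened in a helix).
    ``mode="wlc"`` (free chains only) draws a worm-like random walk whose
    tangent correlations decay as exp(-s/P) by construction, so large-scale
    orientational statistics start at equilibrium; overlapping draws are
    rejected.  Velocities start at zero; the thermostat equilibrates them
    within ~1/gamma.
    """
    n = config.n_beads
    if mode == "wlc":
        if channel is not None:
            raise ValueError("wlc start is for free chains (no channel)")
        return _wlc_conformation(config, seed=seed)
    pos = np.zeros((n, 3))
    if channel is not None and not channel.is_cylinder:
        clearance = channel.R_ch - channel.R_H
        if mode == "axis" and clearance < 2.0 ** (1.0 / 6.0) * channel.wall_sigma:
            mode = "midcurve"
    if channel is None or channel.is_cylinder or mode == "axis":
        pos[:, 0] = x_start + config.r0 * np.arange(n)
    else:
        kp, RH = channel.pitch_k, channel.R_H
        dt_arc = config.r0 / np.hypot(kp, RH)       # |r0'(t)| = sqrt(k^2 + R_H^2)
        t = x_start / kp + dt_arc * np.arange(n)
        wt = channel.omega * t
        pos[:, 0] = kp * t
        pos[:, 1] = RH * np.cos(wt)
        pos[:, 2] = RH * np.sin(wt)
    return Conformation(pos, np.zeros((n, 3)))


def _wlc_conformation(config: SimulationConfig, seed: int = 0) -> Conformation:
    """Equilibrium-statistics worm-like random walk (self-avoiding draw).

    Successive bond directions turn by a polar angle drawn from the model's
    own Boltzmann bending density, sin(t') exp(-c t'^2) with c the bending
    prefactor (inverse-CDF sampling), with uniform azimuth — so the drawn
    ensemble has exactly the chain's equilibrium tangent statistics.  Draws
    with non-bonded bead pairs closer than 0.9 sigma are rejected.
    """
    n = config.n_beads
    rng = np.random.Generator(np.random.PCG64(seed))
    grid = np.linspace(0.0, np.pi, 4001)
    pdf = np.sin(grid) * np.exp(-config.bend_prefactor * grid ** 2)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    for _ in range(200):
        t = rng.standard_normal(3)
        t /= np.linalg.norm(t)
        pos = np.zeros((n, 3))
        thetas = np.interp(rng.uniform(size=n - 2), cdf, grid)
        for i in range(1, n):
            if i > 1:
                perp = rng.standard_normal(3)
                perp -= (perp @ t) * t
                perp /= np.linalg.norm(perp)
                th = thetas[i - 2]
                t = np.cos(th) * t + np.sin(th) * perp
            pos[i] = pos[i - 1] + config.r0 * t
        d2 = ((pos[None, :, :] - pos[:, None, :]) ** 2).sum(axis=2)
        iu = np.triu_indices(n, k=2)
        if d2[iu].min() > 0.81:          # non-bonded pairs clear of overlap
            return Conformation(pos, np.zeros((n, 3)))
    raise RuntimeError("could not draw a non-overlapping worm-like start")


def _channel_params(channel: HelixChannel | None):
    if channel is None:
        return False, 1.0, 0.0, 1.0, 1.0, 0.5, False
    return (
        True,
        channel.R_ch,
        channel.R_H,
        channel.pitch_k,
        float(channel.omega),
        channel.wall_sigma,
        channel.bottom_wall,
    )


def _run_kernel(conf, config, channel, protocol, n_steps, n_pre, piston_x0):
    """Drive the compiled stepper in chunks of the sampling interval.

    Gaussian noise is drawn in bulk from a PCG64 generator seeded by the
    protocol seed; chunk boundaries recompute forces from identical positions
    and therefore do not perturb the dynamics.  The noise stream is a function
    of the seed and the protocol only.
    """
    has_channel, R_ch, RH, kp, omega, wall_sig, bottom = _channel_params(channel)
    n = config.n_beads
    pos = conf.positions.copy()
    vel = conf.velocities.copy()
    t_warm = np.ascontiguousarray(pos[:, 0] / kp if kp != 0 else np.zeros(n))
    rng = np.random.Generator(np.random.PCG64(int(protocol.seed)))
    chunk = protocol.sample_interval
    piston_gamma = protocol.resolved_piston_gamma(config)

    sp, sv, spi, st, se = [], [], [], [], []
    piston_x = piston_x0
    done = 0
    while done < n_steps:
        # chunks align to the sampling grid: land exactly on the end of
        # pre-equilibration, then advance one sampling interval at a time
        if done < n_pre:
            m = min(chunk, n_pre - done)
        else:
            m = min(chunk, n_steps - done)
        if config.gamma > 0.0:
            noise = rng.standard_normal((m, n, 3))
            if protocol.mirror_noise:
                noise[:, :, 2] *= -1.0
        else:
            noise = np.zeros((m, n, 3))
        pnoise = rng.standard_normal(m) if protocol.piston else np.zeros(m)
        status, fail_step, piston_x, epot = _kernel.step_chunk(
            pos, vel, t_warm, noise, pnoise,
            config.dt, config.gamma, config.mass,
            config.k_s, config.r0, config.bend_prefactor, config.k_tether,
            config.skin,
            has_channel, R_ch, RH, kp, omega, wall_sig, bottom,
            protocol.piston, piston_x, 99.5, protocol.piston_force,
            piston_gamma, protocol.piston_thermostat,
        )
        if status != 0:
            raise InstabilityError(_STATUS_MESSAGES[status], pos, done + fail_step)
        done += m
        if done > n_pre and (done - n_pre) % protocol.sample_interval == 0:
            sp.append(pos.copy())
            sv.append(vel.copy())
            spi.append(piston_x)
            st.append(done * config.dt)
            se.append(epot)
    empty = np.zeros((0, n, 3))
    return (
        np.array(sp) if sp else empty,
        np.array(sv) if sv else empty,
        np.array(spi), np.array(st), np.array(se),
        pos, vel, piston_x,
    )


def langevin_step(
    conformation: Conformation,
    config: SimulationConfig,
    channel: HelixChannel | None = None,
    seed: int = 0,
    n_steps: int = 1,
    piston: PistonState | None = None,
    piston_force: float = 0.0,
    mirror_noise: bool = False,
) -> Conformation:
    """Advance a conformation by n_steps Langevin steps (deterministic per seed)."""
    protocol = Protocol(
        pre_steps=0, prod_steps=n_steps, sample_interval=max(n_steps, 1),
        seed=seed, piston_force=piston_force, piston=piston is not None,
        mirror_noise=mirror_noise,
    )
    piston_x0 = piston.x if piston is not None else 0.0
    *_, pos, vel, _ = _run_kernel(conformation, config, channel, protocol, n_steps, 0, piston_x0)
    return Conformation(pos, vel, conformation.frame_time + n_steps * config.dt)


def piston_update(
    piston: PistonState,
    chain_force_x: float,
    F: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    piston_gamma: float | None = None,
    thermostat: bool = True,
    dt: float | None = None,
) -> PistonState:
    """One overdamped Langevin step of the axial piston coordinate.

    dx = dt (chain_force_x - F)/gamma_p + sqrt(2 kT dt / gamma_p) xi.  The
    piston surface is clamped at the bottom-wall plane (x >= radius).
    """
    dt = dt if dt is not None else config.dt
    gp = piston_gamma if piston_gamma is not None else 200.0 * config.gamma * config.mass
    dx = dt * (chain_force_x - F) / gp
    if thermostat:
        dx += np.sqrt(2.0 * dt / gp) * rng.standard_normal()
    x = max(piston.x + dx, piston.radius)
    return PistonState(x=x, radius=piston.radius, force=F)


def run_simulation(
    config: SimulationConfig,
    channel: HelixChannel | None,
    protocol: Protocol,
    initial: Conformation | None = None,
) -> Trajectory:
    """Full run: equilibration then sampled production, per the protocol.

    The chain starts extended along the channel axis near the bottom wall and
    the piston (when present) is placed just beyond the far chain end.
    """
    conf = initial if initial is not None else initial_conformation(config, channel)
    if protocol.piston:
        piston_x0 = float(conf.positions[:, 0].max()) + 99.5 + 2.0 ** (1.0 / 6.0)
    else:
        piston_x0 = 0.0
    n_steps = protocol.pre_steps + protocol.prod_steps
    if n_steps == 0:
        return Trajectory(
            positions=conf.positions[None].copy(),
            velocities=conf.velocities[None].copy(),
            times=np.array([conf.frame_time]),
            piston_x=np.array([piston_x0]),
            epot=np.array([np.nan]),
            config=config, channel=channel, protocol=protocol,
            seed=protocol.seed, metadata={"zero_step": True},
        )
    sp, sv, spi, st, se, *_ = _run_kernel(
        conf, config, channel, protocol, n_steps, protocol.pre_steps, piston_x0
    )
    return Trajectory(
        positions=sp, velocities=sv, times=st, piston_x=spi, epot=se,
        config=config, channel=channel, protocol=protocol, seed=protocol.seed,
        metadata={"config_hash": config.config_hash()},
    )


def run_repeats(
    config: SimulationConfig,
    channel: HelixChannel | None,
    protocol: Protocol,
    seeds: list[int],
) -> list[Trajectory]:
    """Independent repeat runs differing only by seed (paper protocol: 5 repeats)."""
    out = []
    for s in seeds:
        p = Protocol(**{**protocol.__dict__, "seed": int(s)})
        out.append(run_simulation(config, channel, p))
    return out
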