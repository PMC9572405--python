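"""Integrator contracts: determinism, NVE limit, thermostat statistics, piston."""

import numpy as np
import pytest
from scipy import stats

import knotfactory as kf
from knotfactory.config import SimulationConfig, HelixChannel, Protocol
from knotfactory.dynamics import (
    InstabilityError,
    initial_conformation,
    piston_update,
    run_simulation,
)
from knotfactory.forcefield import total_energy


def test_identical_seeds_bitwise_identical():
    a = kf.make_micro_trajectory(n_beads=10, n_steps=1000, seed=3)
    b = kf.make_micro_trajectory(n_beads=10, n_steps=1000, seed=3)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.velocities, b.velocities)


def test_different_seeds_differ():
    a = kf.make_micro_trajectory(n_beads=10, n_steps=1000, seed=3)
    b = kf.make_micro_trajectory(n_beads=10, n_steps=1000, seed=4)
    assert not np.array_equal(a.positions, b.positions)
    assert a.config.config_hash() == b.config.config_hash()


def test_zero_step_protocol_returns_initial():
    config = SimulationConfig(n_beads=12)
    proto = Protocol(pre_steps=0, prod_steps=0, sample_interval=1, seed=0)
    conf = initial_conformation(config)
    traj = run_simulation(config, None, proto, initial=conf)
    assert traj.n_frames == 1
    assert np.array_equal(traj.positions[0], conf.positions)


def test_nve_limit_energy_conservation():
    """gamma = 0 and no noise reduces BAOAB to velocity Verlet: no drift."""
    # thermalize with the thermostat first, then switch it off (gamma = 0)
    warm = kf.make_micro_trajectory(n_beads=20, n_steps=2000, seed=5, helical=False,
                                    D_over_P=2.0, sample_interval=2000)
    conf = warm.frame(-1)
    # dt = 0.002 keeps the bounded Verlet energy oscillation small enough
    # that the secular-drift estimate resolves the 1e-4 eps0 bound
    nve = SimulationConfig(n_beads=20, gamma=0.0, dt=0.002)
    proto = Protocol(pre_steps=0, prod_steps=100_000, sample_interval=100, seed=0)
    traj = run_simulation(nve, None, proto, initial=conf)
    etot = np.array([
        total_energy(traj.positions[i], nve) + 0.5 * (traj.velocities[i] ** 2).sum()
        for i in range(traj.n_frames)
    ])
    # secular drift (least-squares slope); Verlet energy error is a bounded
    # oscillation, the slope must vanish
    steps = np.arange(traj.n_frames) * 100.0
    slope = np.polyfit(steps, etot, 1)[0]
    assert abs(slope) * 1e4 < 1e-4       # < 1e-4 eps0 per 1e4 steps


def test_equipartition_dimer():
    """Thermostatted bonded dimer: <KE> = (3/2) * 2 * kT within 2%."""
    config = SimulationConfig(n_beads=3, gamma=1.0)
    proto = Protocol(pre_steps=20_000, prod_steps=400_000, sample_interval=200, seed=9)
    traj = run_simulation(config, None, proto)
    ke = 0.5 * (traj.velocities ** 2).sum(axis=(1, 2))
    assert ke.mean() == pytest.approx(1.5 * config.n_beads, rel=0.02)


def test_boltzmann_bond_length_distribution():
    """Thermostatted bond lengths sample P(r) ~ r^2 exp(-k_s (r - r0)^2).

    In internal coordinates of the trimer the bond-length marginal
    factorizes exactly; a KS test compares the sampled lengths with the
    numerically integrated Boltzmann CDF.
    """
    k_s = 80.0
    config = SimulationConfig(n_beads=3, gamma=1.0, k_s=k_s)
    proto = Protocol(pre_steps=20_000, prod_steps=600_000, sample_interval=300, seed=17)
    traj = run_simulation(config, None, proto)
    r = np.linalg.norm(traj.positions[:, 1] - traj.positions[:, 0], axis=1)

    grid = np.linspace(0.5, 1.5, 4001)
    pdf = grid ** 2 * np.exp(-k_s * (grid - 1.0) ** 2)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]

    def boltzmann_cdf(x):
        return np.interp(x, grid, cdf)

    stat, p = stats.kstest(r, boltzmann_cdf)
    assert p > 0.01, f"KS p = {p}"


def test_confinement_containment():
    """No bead mid-curve distance exceeds R_ch during a stable run."""
    traj = kf.make_micro_trajectory(n_beads=30, n_steps=20_000, seed=23, D_over_P=0.5,
                                    sample_interval=500)
    ch = traj.channel
    for pos in traj.positions:
        _, d = kf.nearest_helix_points(pos, ch)
        assert np.all(d <= ch.R_ch)


def test_mirror_equivariance_bitwise():
    """Mirrored channel + mirrored noise stream = exactly mirrored trajectory."""
    kw = dict(n_beads=16, n_steps=3000, seed=7, piston_force=0.5, piston_gamma=10.0,
              sample_interval=300)
    a = kf.make_micro_trajectory(omega=1, **kw)
    b = kf.make_micro_trajectory(omega=-1, mirror_noise=True, **kw)
    mirrored = a.positions.copy()
    mirrored[:, :, 2] *= -1.0
    assert np.array_equal(mirrored, b.positions)
    vm = a.velocities.copy()
    vm[:, :, 2] *= -1.0
    assert np.array_equal(vm, b.velocities)
    assert np.array_equal(a.piston_x, b.piston_x)


def test_piston_drifts_toward_wall_without_contact():
    """No polymer contact, F > 0: monotone drift toward the bottom."""
    piston = kf.PistonState(x=500.0, force=2.0)
    config = SimulationConfig(n_beads=3)
    rng = np.random.default_rng(0)
    xs = [piston.x]
    for _ in range(2000):
        piston = piston_update(piston, 0.0, 2.0, config, rng, piston_gamma=10.0,
                               thermostat=False)
        xs.append(piston.x)
    assert all(b < a for a, b in zip(xs, xs[1:]))


def test_piston_free_diffusion():
    """F = 0, no contact: <dx^2> grows linearly with 2 kT t / gamma_p."""
    config = SimulationConfig(n_beads=3)
    gp = 25.0
    n_steps, n_rep = 400, 600
    rng = np.random.default_rng(3)
    disp = []
    for _ in range(n_rep):
        piston = kf.PistonState(x=1000.0)
        for _ in range(n_steps):
            piston = piston_update(piston, 0.0, 0.0, config, rng, piston_gamma=gp)
        disp.append(piston.x - 1000.0)
    var = np.var(disp)
    expected = 2.0 * n_steps * config.dt / gp
    assert var == pytest.approx(expected, rel=0.2)


def test_piston_force_balance():
    """Steady state: time-averaged polymer push on the piston balances F."""
    F = 2.0
    traj = kf.make_micro_trajectory(n_beads=20, n_steps=60_000, seed=31,
                                    piston_force=F, piston_gamma=10.0,
                                    D_over_P=0.5, sample_interval=200)
    # recover the mean reaction from the piston displacement statistics:
    # overdamped piston, <dx/dt> ~ 0 at steady state => <reaction> ~ F.
    xs = traj.piston_x
    late = xs[len(xs) // 2:]
    drift_per_tau = np.polyfit(np.arange(late.size) * 2.0, late, 1)[0]
    # <reaction> = F + gamma_p * <dx/dt>
    reaction = F + 10.0 * drift_per_tau
    assert reaction == pytest.approx(F, rel=0.25)


def test_instability_reported():
    """A hugely overlapping start must abort with a diagnosable error."""
    config = SimulationConfig(n_beads=8, dt=0.01)
    pos = np.zeros((8, 3))
    pos[:, 0] = np.arange(8) * 1e-4      # extreme overlap
    conf = kf.Conformation(pos, np.zeros((8, 3)))
    proto = Protocol(pre_steps=0, prod_steps=100, sample_interval=10, seed=0)
    with pytest.raises(InstabilityError):
        run_simulation(config, None, proto, initial=conf)
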