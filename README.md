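# knotfactory

Langevin molecular dynamics of coarse-grained DNA confined in **implicit
cylindrical or helical nano-channels** under piston compression, with the
full polymer-metric and knot-theoretic analysis suite. The scientific
question it addresses: can a "knot factory" — a nano-channel that compresses
a DNA molecule — *bias the chirality* of the knots it produces when the
channel itself is helical, and how do helical grooves change confinement
observables relative to a plain cylinder?

Intended users: polymer/biophysics researchers studying DNA in nanofluidic
confinement and the topology (knotting, writhe, chirality) of confined
chains.

## Model

DNA is a discretized worm-like chain of N beads (default 300; one bead =
8.5 bp, diameter sigma = 2.5 nm, so L = 2.55 kbp), with

* harmonic bonds `U_s = k_s (r - r0)^2`, `k_s = 80 eps0/sigma^2`, `r0 = sigma`,
* harmonic bending `U_b = (k_b/2)(theta - pi)^2`, `k_b = 20 eps0/rad^2`,
  calibrated so the persistence length is P = 20 sigma = 50 nm,
* WCA excluded volume `4 eps0[(sigma/r)^12 - (sigma/r)^6 + 1/4]`, r < 2^(1/6) sigma,

integrated by Langevin dynamics `m r'' = -gamma m r' - grad U +
R(t)(2 eps0 m gamma)^(1/2)` (BAOAB splitting, dt = 0.01 tau).

The channel is implicit: a tube of radius `R_ch` around the helical
mid-curve `r0(t) = (k t, R_H cos wt, R_H sin wt)` (cylinder: R_H = 0;
defaults R_H = R_ch/3, pitch k = D/2pi, handedness omega = +-1). Each bead's
nearest mid-curve point is found by Newton iteration on
`k(x - kt) - R_H w (y sin wt - z cos wt) = 0` from the axial-projection
initial estimate, and the wall repels along the outward normal (WCA on the
surface gap). A piston bead of radius 100 sigma compresses the chain toward
the bottom wall with force F.

Topology pipeline per frame: minimally-interfering radial closure → KMT
triangle-elimination simplification → Alexander determinant `|Delta(-1)|`
(1 = unknot, 3 = trefoil, 5 = figure-eight, ...) → knot class; chirality via
the Gauss-integral writhe Wr and the signed crossing counts (n+, n-) of the
minimal reduced diagram; entanglement via the average crossing number (ACN,
2000 random projections).

## Worked example

```python
import numpy as np
from knotfactory import (SimulationConfig, HelixChannel, Protocol,
                         run_simulation, analyze_chain)

config = SimulationConfig(n_beads=100)
channel = HelixChannel.from_confinement(0.5, helical=True)   # D = 10 sigma
protocol = Protocol(pre_steps=100_000, prod_steps=150_000,
                    sample_interval=2_000, seed=1)
traj = run_simulation(config, channel, protocol)
spans = traj.positions[:, :, 0].max(1) - traj.positions[:, :, 0].min(1)
print(f"mean S(x) = {spans.mean():.1f} sigma")
rep = analyze_chain(traj.positions[-1], rng=0)
print(rep.knot_class, rep.determinant, round(rep.chain_writhe, 2))
```

prints (exact numbers vary with seed/protocol)

```
mean S(x) = 87.3 sigma
0_1 1 -0.02
```

— the 100-bead chain in strong confinement stays extended near the Odijk
prediction `L[1 - 0.1701 (D/P)^(2/3)] = 89.3 sigma` and is unknotted
(determinant 1, writhe ~ 0). The `examples/` directory has one short script
per capability (channel geometry, confinement spans, knot census on
parametric curves, compression with mirror-image channels); each prints the
numbers it computes and what they mean. A thin CLI (`knotfactory simulate /
analyze / fixtures / report`) wraps the same API for shell use.

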