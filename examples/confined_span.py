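"""Chain extension in cylindrical vs helical confinement (scaled down).

Runs a short 100-bead chain at strong confinement (D/P = 0.5) in both
geometries and prints the mean axial span S(x).  At paper scale (N = 300,
1e9 steps, 5 repeats) the same comparison gives 266.7 sigma (cylinder) vs
271.2 sigma (helix): helical grooves act as a slightly *stronger* effective
confinement, pre-stretching the chain more.
"""

import numpy as np

from knotfactory import HelixChannel, Protocol, SimulationConfig, run_simulation
from knotfactory.observables import odijk_span

config = SimulationConfig(n_beads=100)
protocol = Protocol(pre_steps=100_000, prod_steps=150_000, sample_interval=2_000, seed=1)

for label, helical in (("cylinder", False), ("helix   ", True)):
    channel = HelixChannel.from_confinement(0.5, helical=helical)
    traj = run_simulation(config, channel, protocol)
    spans = traj.positions[:, :, 0].max(axis=1) - traj.positions[:, :, 0].min(axis=1)
    print(f"{label}: mean S(x) = {spans.mean():6.1f} sigma "
          f"(SE {spans.std(ddof=1) / np.sqrt(len(spans) / 10):.1f})")

print(f"Odijk prediction L[1 - 0.1701 (D/P)^(2/3)] = "
      f"{odijk_span(100.0, 0.5):.1f} sigma")
# The spans cluster near the Odijk value; the helical span is slightly larger.
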