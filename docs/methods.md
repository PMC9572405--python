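# Methods

## The model

`knotfactory` simulates double-stranded DNA as a discretized semi-flexible
worm-like chain of `N` beads (default 300). One bead represents 8.5 bp of
hydrated DNA; its diameter `sigma` = 2.5 nm is the length unit, the thermal
energy `eps0 = k_B T` the energy unit, and `tau` (74 ns) the time unit. The
default chain is therefore 2550 bp (2.55 kbp), the size of a small plasmid.
The chain is nicked/torsionally relaxed: there is no twist energy.

Interactions:

* **Bonds** — harmonic, `U_s(r) = k_s (r - r0)^2` with `k_s = 80 eps0/sigma^2`
  and `r0 = 1 sigma`. The stiff bond prevents strand passage under strong
  compression.
* **Bending** — harmonic in the angle at each interior bead,
  `U_b = c (theta - pi)^2`. The bending constant is quoted in the field in
  two conventions; with the engine-style convention `c = k_bend/2` and
  `k_bend = 20 eps0/rad^2` the chain reproduces a persistence length of
  P = 20 sigma = 50 nm, which is the calibration target. The bare-quadratic
  convention (`c = k_bend`, giving P near 40 sigma) is available as
  `bend_convention="full"`; the package default is `"half"` because only it
  is consistent with P = 50 nm, and the persistence-length recovery test pins
  this choice.
* **Excluded volume** — Weeks–Chandler–Andersen (purely repulsive truncated
  and shifted Lennard-Jones), `U_ex = 4 eps0 [(sigma/r)^12 - (sigma/r)^6 +
  1/4]` for `r < 2^(1/6) sigma`. Directly bonded neighbors are excluded
  (standard bead-spring practice; the bond already penalizes overlap).

Langevin dynamics `m r'' = -gamma m r' - grad U + R(t) sqrt(2 eps0 m gamma)`
is integrated with a BAOAB velocity-Verlet/Ornstein–Uhlenbeck splitting at
`dt = 0.01 tau`. Bead mass `m = 1` and friction `gamma = 1/tau` are
conventions, not measurements: they set kinetics but no equilibrium average.
With `gamma = 0` the integrator reduces exactly to velocity Verlet (tested by
energy conservation).

## Implicit channels

The confining channel is a tube of radius `R_ch` (`D = 2 R_ch`) around the
helical mid-curve `r0(t) = (k t, R_H cos wt, R_H sin wt)` along the x axis;
`R_H = 0` is the cylinder. Defaults follow the geometry family studied here:
`R_H = R_ch/3` and pitch `k = D/(2 pi)`, so the loop spacing `d_H = 2 pi k`
equals `D` (10, 20, 40 sigma at D/P = 0.5, 1, 2) and the channel is
self-similar under scaling. `omega = +-1` is the handedness; the mirror image
of a channel is `z -> -z` with `omega -> -omega`.

The wall is implicit: each step, the nearest mid-curve point of every bead is
found by solving the stationarity condition
`g(t) = k(x - kt) - R_H w (y sin wt - z cos wt) = 0` with a safeguarded
Newton iteration started from the axial projection `t0 = x/k` (the same
initial-estimate trick that stabilizes Newton solutions of Kepler's
equation), warm-started from the previous step inside the integrator.
Tolerance is `|g| < 1e-10` within 50 iterations with a bisection fallback on
a bracket of +-1 pitch (widened if needed). Under the tube condition
`2 pi k > R_ch` the interior nearest-point problem is unique; this is
validated against a dense grid-search oracle in the tests. The wall force is
WCA-form on the surface gap `g_w = R_ch - d` with length scale `sigma/2` (the
bead radius), so bead centers are softly confined to `d <= R_ch` with contact
at the standard soft-wall convention. The bottom wall (plane x = 0) uses the
same form on the gap `x`.

## Piston compression

Compression is applied by a sphere of radius 100 sigma whose center is
constrained to the channel axis; it interacts with the polymer only (WCA on
`r - 99.5 sigma`, so contact occurs at the piston surface) and never with the
walls. The piston coordinate follows overdamped Langevin dynamics under the
applied force `F` (toward the bottom wall) plus the polymer reaction. Its
friction defaults to 200x the bead friction (the bead-to-piston radius
ratio); because equilibrium averages are independent of friction, desk-scale
protocols override `piston_gamma` to a smaller value (typically 10) so the
piston reaches the chain within the shortened runs. The piston surface is
clamped at the bottom-wall plane. The force grid of interest is
`F sigma/eps0` in {0, 0.1, 0.35, 0.5, 1, 2, 5, 10, 15, 20}.

## Protocols and problem sizes

The reference study protocol is 1e9 equilibration + 1e9 production steps with
5000 samples and 5 repeats per condition. This package's default desk-scale
protocols, chosen by monitoring the running average of the span (and of the
writhe for compressed runs) until the last-quartile mean agrees with the full
mean within one standard error, are:

* uncompressed span comparisons (D/P = 0.5): 2-3e5 equilibration + 3-6e5
  production steps, 3-5 seeds, starting from the extended axis-aligned
  conformation (which is the near-equilibrium "I" conformation in strong
  confinement);
* free-chain persistence recovery: 24 independent chains, 3e4 + 3e4 steps
  each (ensemble averaging; see below);
* compressed runs: N = 150 at 5e5-1e6 steps with `piston_gamma = 10`.

The initial conformation lies straight along the channel axis (inside every
channel with `R_ch - R_H` above the wall cutoff; beads fall back to the
mid-curve when not). Starting on the mid-curve is available but begins a
helix run ~30% below the equilibrium span because of the mid-curve tortuosity
`sqrt(k^2 + R_H^2)/k`, which wastes equilibration time.

Randomness: each run draws its noise from a PCG64 stream seeded by the
protocol seed; trajectories are bitwise reproducible. A mirrored run
(mirrored channel, initial condition and noise stream, i.e. the z component
of every Gaussian negated) produces the exactly mirrored trajectory, because
the stationarity residual and all force terms are bitwise symmetric under
`z -> -z, omega -> -omega`. This is the mechanistic statement behind the
handedness results: the model has no intrinsic chirality, only the channel
does.

## Observables

* Span `S(x)` = axial extent (the primary extension measure; the euclidean
  `S(r)` is also provided but is biased for collapsed chains lying flat at
  the channel bottom). Histograms use half-open 1-sigma bins anchored at 0.
* Elastic free energy `A(R) = -kT ln P(R)` (reported with min 0), restoring
  force by central differences on non-empty bin centers, no smoothing.
* Gyration radius and its transverse component `R_perp` (y, z only).
* Radial monomer distributions in 0.5-sigma shells, measured both from the
  helical mid-curve (using the same nearest-point solver as the dynamics)
  and from the channel axis; reported as per-shell monomer probability
  (sums to 1), with the shell volumes `2 pi L_ch (0.5 sigma)^2 [(n+1)^2 -
  n^2]` attached for density normalization. The per-shell reading of the
  normalization is one of two possible conventions; it is the stated one and
  the uniform-fill oracle test pins the implementation.
* Confinement free energy `A_C`: the per-frame mean number of monomers whose
  mid-curve distance lies within `delta = sigma/5` of the wall — the
  integral of the monomer number density over the surface layer. This is an
  occupancy measure, monotone in wall contacts and intensive in frames.
* Orientational correlations `<cos theta(s)>` over all bond pairs; the free
  chain decays as `exp(-s/P)` and the fit over `s <= 50 sigma` recovers
  P = 20 sigma within 10% (the calibration check). Because the large-s
  correlations of a *single* chain decorrelate far too slowly for time
  averaging at desk scale, the persistence estimate is an ensemble average:
  many independent chains are drawn from the model's own Boltzmann
  worm-like-walk ensemble (polar turning angles inverse-CDF-sampled from
  `sin(t') exp(-c t'^2)`, uniform azimuths, overlap-rejected), briefly
  thermalized — Langevin dynamics preserves equilibrium, so any run length
  is unbiased — and pooled; the exponential fit is inverse-variance
  weighted by the frame-scatter standard errors so the noisy tail does not
  dominate.
* Scaling fits: Odijk prefactor A in `R = L[1 - A (D/P)^(2/3)]` by least
  squares over D/P in [0.5, 1]; power-law exponents by linear fits in
  log-log (span vs D/P in [1, 2]; span vs force). Deflection length
  `lambda = D^(2/3) P^(1/3)`.
* 2-D projection heatmaps (cross-section and side view), normalized to
  probability.

## Knot analysis

Knots exist only on closed curves, so open conformations are closed first.
The default *radial-outward* closure extends both endpoints away from the
chain centroid to a sphere at 3x the maximal extent and joins them by a
great-circle arc — far outside the chain, minimizing spurious entanglement
(in the spirit of minimally interfering closure; the direct-segment and
centroid-ray variants are provided and fixture tests confirm all preserve
the knot type on well-separated ends).

The closed polygon is simplified by KMT triangle elimination: vertex j is
removed when triangle (j-1, j, j+1) is pierced by no other segment, with
exact segment-triangle intersection tests (coplanar cases resolved by 2-D
clipping; ties conservatively block removal; segments sharing a triangle
corner are tested with the shared end clipped), iterated to a fixed point.

From a regular projection of the simplified curve (random rotations are
retried up to 100 times when a tangency, graze or height tie is detected)
the crossing diagram gives:

* the **Alexander determinant** `|Delta(-1)|` via the standard crossing
  matrix over arcs between successive underpasses, evaluated exactly with
  integer (Bareiss) elimination. At t = -1 the matrix entries are crossing-
  sign independent; the determinant is projection independent (asserted over
  many directions), odd for every knot, 1 for the unknot, 3 for trefoils,
  5 for the figure-eight.
* **signed crossing counts** (n+, n-) by the right-hand rule, after R1/R2
  Gauss-code eliminations, minimized over sampled projection directions;
  their difference is the *core writhe*, whose sign assigns chirality
  (3_1 vs 3_1m). Knot-class labels come from (determinant, minimal observed
  crossing count); the Alexander determinant cannot separate all knots, so
  ambiguous determinants fall back to a candidate label, and diagrams with
  more than 11 crossings are reported as "complex, k > 11".

Geometry-side entanglement measures need no closure conventions:

* **writhe** by the exact discretized Gauss double integral (pairwise
  segment solid angles); equals the projection average of signed crossing
  numbers (validated within 0.02 at 5000 projections against the
  Monte-Carlo estimator);
* **ACN**, the unsigned crossing count averaged over 2000 uniformly random
  projections (seeded; also available in closed form as the absolute-value
  Gauss integral, used as the oracle).

The **knotted core** is localized by bidirectional shrinking: each end
advances (coarse stride, then single beads) while the closed subchain keeps
the full chain's determinant.

## What the synthetic fixtures do and do not show

Parametric fixtures (torus knots, figure-eight, circles, seeded correlated
random walks) have exactly known invariants and exact mirror images, so the
topological pipeline is tested without simulation. They do not emulate
excluded volume, wall interactions or equilibrium ensembles — passing
fixture tests validates the analyzers, not the physics; the physics is
validated by the equilibrium checks (equipartition, Boltzmann sampling,
persistence-length recovery, Odijk-level span values).

## Numerical choices and limitations

* Verlet pair list with 0.8-sigma skin, rebuilt when any displacement
  exceeds skin/2; asserted identical to all-pairs forces.
* Newton tolerance 1e-10 on the helix residual; bisection fallback.
* Histogram edges anchored at 0; half-open bins.
* Degenerate projections: deterministic seeded retries, max 100.
* Alexander-based typing cannot resolve chirality (done via writhe instead)
  nor all knots of equal determinant; this mirrors the information available
  to determinant-based pipelines.
* Desk-scale runs are 1e3-1e4 x shorter than the reference protocol: slow
  observables (knotting probabilities at weak force, the full force-extension
  law at cluster scale) carry correspondingly larger uncertainty, and the
  directional/sign properties are the robust statements at this scale.
* Compression/decompression cycling, flow-driven compression, twist
  elasticity, Jones-polynomial invariants and knotoids are out of scope.
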