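"""Chain metrics, distributions, free-energy estimates and scaling fits.

Everything operates on position arrays in reduced units (sigma): a single
conformation is (N, 3), a trajectory sample is (n_frames, N, 3).  The channel
axis is x throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .config import HelixChannel
from .helix import nearest_helix_points

__all__ = [
    "gyration_radii",
    "span",
    "SpanHistogram",
    "span_histogram",
    "elastic_free_energy",
    "RadialProfile",
    "radial_profiles",
    "confinement_free_energy",
    "orientational_correlation",
    "fit_persistence_length",
    "odijk_span",
    "fit_odijk_prefactor",
    "fit_power_law",
    "deflection_length",
    "projection_heatmap",
    "running_average",
]


# ---------------------------------------------------------------------------
# chain metrics
# ---------------------------------------------------------------------------

def gyration_radii(positions: np.ndarray) -> tuple[float, float]:
    """(R_g, R_perp): gyration radius and its transverse (y, z) component.

    R_g^2 = <|r - r_cm|^2>; R_perp uses only the coordinates transverse to
    the channel axis, so R_g^2 = R_parallel^2 + R_perp^2.
    """
    pos = np.asarray(positions, float)
    if len(pos) < 2:
        raise ValueError("gyration radius needs at least 2 beads")
    d = pos - pos.mean(axis=0)
    rg2 = (d ** 2).sum(axis=1).mean()
    rperp2 = (d[:, 1:] ** 2).sum(axis=1).mean()
    return float(np.sqrt(rg2)), float(np.sqrt(rperp2))


def span(positions: np.ndarray, mode: str = "axial") -> float:
    """Chain span R: axial S(x) (default) or maximal pairwise distance S(r).

    S(x) = max_i x_i - min_i x_i is the primary extension measure for
    channel-confined chains (S(r) is biased for collapsed chains lying flat
    at the channel bottom).
    """
    pos = np.asarray(positions, float)
    if mode in ("axial", "S(x)"):
        return float(pos[:, 0].max() - pos[:, 0].min())
    if mode in ("euclidean", "S(r)"):
        # max pairwise distance via hull-free blocking (N is small)
        d2max = 0.0
        for i in range(len(pos) - 1):
            d2 = ((pos[i + 1:] - pos[i]) ** 2).sum(axis=1).max()
            d2max = max(d2max, float(d2))
        return float(np.sqrt(d2max))
    raise ValueError(f"unknown span mode {mode!r}")


# ---------------------------------------------------------------------------
# span histograms and the elastic free energy
# ---------------------------------------------------------------------------

@dataclass
class SpanHistogram:
    edges: np.ndarray           # bin edges, width 1 sigma, anchored at 0
    probability: np.ndarray     # P(R) per bin, sums to 1 with the bin width
    counts: np.ndarray
    n_frames: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def span_histogram(spans: np.ndarray, bin_width: float = 1.0) -> SpanHistogram:
    """Probability distribution of the span, bin width 1 sigma, edges at 0."""
    spans = np.asarray(spans, float)
    hi = np.ceil(spans.max() / bin_width) + 1
    edges = np.arange(0.0, (hi + 1) * bin_width, bin_width)
    counts, _ = np.histogram(spans, bins=edges)
    prob = counts / (counts.sum() * bin_width)
    return SpanHistogram(edges=edges, probability=prob, counts=counts, n_frames=len(spans))


def elastic_free_energy(hist: SpanHistogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Elastic free energy A(R) = -kT ln P(R) and restoring force F = -dA/dR.

    Returns (centers, A, F) on the non-empty bins; A is shifted so its
    minimum is 0, the force uses central differences (one-sided at the ends)
    on the surviving bin centers; empty bins are masked, never interpolated.
    """
    mask = hist.probability > 0
    if mask.sum() < 2:
        raise ValueError("elastic free energy undefined: fewer than 2 non-empty bins")
    centers = hist.centers[mask]
    A = -np.log(hist.probability[mask])
    A -= A.min()
    F = -np.gradient(A, centers)
    return centers, A, F


# ---------------------------------------------------------------------------
# radial distributions and the confinement free energy
# ---------------------------------------------------------------------------

@dataclass
class RadialProfile:
    r_over_Rch: np.ndarray      # shell centers in r/R_ch
    probability: np.ndarray     # probability of a monomer in the shell (sums to 1)
    reference: str              # "mid-curve" or "axis"
    bin_width: float
    shell_volumes: np.ndarray   # 2 pi L_ch (0.5 s)^2 [(n+1)^2 - n^2] per shell


def _radial_histogram(dists, channel, bin_width, reference):
    n_shells = int(np.ceil(channel.R_ch / bin_width)) + 1
    edges = np.arange(n_shells + 1) * bin_width
    counts, _ = np.histogram(dists, bins=edges)
    prob = counts / max(counts.sum(), 1)
    n = np.arange(n_shells)
    volumes = 2.0 * np.pi * channel.length * bin_width ** 2 * ((n + 1) ** 2 - n ** 2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(
        r_over_Rch=centers / channel.R_ch,
        probability=prob,
        reference=reference,
        bin_width=bin_width,
        shell_volumes=volumes,
    )


def radial_profiles(
    frames: np.ndarray,
    channel: HelixChannel,
    bin_width: float = 0.5,
) -> tuple[RadialProfile, RadialProfile]:
    """Monomer radial distributions from the mid-curve and from the x axis.

    Monomers are counted in concentric shells of width 0.5 sigma; the
    mid-curve distance uses the same helix nearest-point solver as the
    dynamics.  For a cylinder the two profiles coincide exactly.
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.size == 0:
        raise ValueError("empty trajectory")
    pts = frames.reshape(-1, 3)
    if channel.is_cylinder:
        d_mid = np.hypot(pts[:, 1], pts[:, 2])
    else:
        _, d_mid = nearest_helix_points(pts, channel)
    d_axis = np.hypot(pts[:, 1], pts[:, 2])
    return (
        _radial_histogram(d_mid, channel, bin_width, "mid-curve"),
        _radial_histogram(d_axis, channel, bin_width, "axis"),
    )


def confinement_free_energy(
    frames: np.ndarray,
    channel: HelixChannel,
    delta: float = 0.2,
) -> float:
    """Surface-layer occupancy A_C: mean monomers within delta of the wall.

    The confinement free energy is estimated as the integral of the monomer
    number density over the surface layer of thickness delta = sigma/5, i.e.
    the per-frame average count of monomers whose mid-curve distance lies in
    [R_ch - delta, R_ch].  Monotone in the number of wall contacts and
    intensive in the number of frames.
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    pts = frames.reshape(-1, 3)
    if channel.is_cylinder:
        d = np.hypot(pts[:, 1], pts[:, 2])
    else:
        _, d = nearest_helix_points(pts, channel)
    in_layer = (d >= channel.R_ch - delta).sum()
    return float(in_layer) / len(frames)


# ---------------------------------------------------------------------------
# orientational correlations and persistence length
# ---------------------------------------------------------------------------

def orientational_correlation(
    frames: np.ndarray,
    s_max: int | None = None,
    with_std: bool = False,
):
    """<cos theta(s)>: mean dot product of unit bond vectors s bonds apart.

    Averaged over all frames and all bond pairs at each contour separation;
    for a free worm-like chain this decays as exp(-s/P).  With
    ``with_std=True`` also returns the standard error of each point
    estimated from the frame-to-frame scatter of the per-frame means.
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    bonds = np.diff(frames, axis=1)
    bonds /= np.linalg.norm(bonds, axis=2, keepdims=True)
    n_frames, n_bonds = bonds.shape[:2]
    if s_max is None:
        s_max = n_bonds - 1
    s_max = min(s_max, n_bonds - 1)
    s_vals = np.arange(s_max + 1)
    corr = np.empty(s_max + 1)
    std = np.zeros(s_max + 1)
    for s in s_vals:
        if s == 0:
            corr[0] = 1.0
        else:
            per_frame = np.mean(np.sum(bonds[:, :-s] * bonds[:, s:], axis=2), axis=1)
            corr[s] = float(per_frame.mean())
            if n_frames > 1:
                std[s] = float(per_frame.std(ddof=1) / np.sqrt(n_frames))
    if with_std:
        return s_vals.astype(float), corr, std
    return s_vals.astype(float), corr


def fit_persistence_length(
    s: np.ndarray,
    corr: np.ndarray,
    s_fit_max: float = 50.0,
    sigma: np.ndarray | None = None,
) -> float:
    """Persistence length from an exponential fit of <cos theta(s)>.

    Fits exp(-s/P) over 0 <= s <= s_fit_max (positive correlations only),
    optionally weighted by per-point uncertainties ``sigma`` so the noisy
    large-separation tail does not dominate the fit.
    """
    s = np.asarray(s, float)
    corr = np.asarray(corr, float)
    m = (s <= s_fit_max) & (corr > 0)
    if sigma is not None:
        sigma = np.asarray(sigma, float)
        m &= sigma > 0
    if m.sum() < 3:
        raise ValueError("not enough points for a persistence-length fit")
    popt, _ = curve_fit(
        lambda x, P: np.exp(-x / P), s[m], corr[m], p0=[20.0],
        sigma=sigma[m] if sigma is not None else None,
    )
    return float(popt[0])


# ---------------------------------------------------------------------------
# scaling laws
# ---------------------------------------------------------------------------

def deflection_length(D: float, P: float) -> float:
    """Odijk deflection length lambda = D^(2/3) P^(1/3)."""
    if D <= 0 or P <= 0:
        raise ValueError("D and P must be positive")
    return D ** (2.0 / 3.0) * P ** (1.0 / 3.0)


def odijk_span(L: float, D_over_P: float, A: float = 0.1701) -> float:
    """Odijk-regime mean span R = L [1 - A (D/P)^(2/3)]."""
    return L * (1.0 - A * D_over_P ** (2.0 / 3.0))


def fit_odijk_prefactor(D_over_P: np.ndarray, R: np.ndarray, L: float) -> float:
    """Least-squares A in R = L[1 - A (D/P)^(2/3)] over the strong regime."""
    x = np.asarray(D_over_P, float) ** (2.0 / 3.0)
    y = 1.0 - np.asarray(R, float) / L
    return float((x @ y) / (x @ x))


def fit_power_law(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(exponent, prefactor) of y = c x^a by linear least squares in log-log."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values")
    a, logc = np.polyfit(np.log(x), np.log(y), 1)
    return float(a), float(np.exp(logc))


# ---------------------------------------------------------------------------
# heat maps and convergence
# ---------------------------------------------------------------------------

def projection_heatmap(
    frames: np.ndarray,
    plane: str = "cross-section",
    bins: int = 40,
    extent: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D monomer density projection: (y, z) cross-section or (x, y) side view.

    Returns (H, xedges, yedges) with H normalized to a probability (sums to 1).
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    pts = frames.reshape(-1, 3)
    if plane in ("cross-section", "yz"):
        u, v = pts[:, 1], pts[:, 2]
    elif plane in ("side", "xy"):
        u, v = pts[:, 0], pts[:, 1]
    else:
        raise ValueError(f"unknown plane {plane!r}")
    rng = None
    if extent is not None:
        rng = [[-extent, extent], [-extent, extent]]
    H, xe, ye = np.histogram2d(u, v, bins=bins, range=rng)
    total = H.sum()
    if total > 0:
        H = H / total
    return H, xe, ye


def running_average(values: np.ndarray) -> np.ndarray:
    """Cumulative running average, for convergence monitoring."""
    values = np.asarray(values, float)
    return np.cumsum(values) / np.arange(1, len(values) + 1)
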