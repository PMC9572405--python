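"""Knot analysis: determinants, KMT safety, writhe oracle, parity, core."""

import numpy as np
import pytest

from knotfactory import topology as tp
from knotfactory.fixtures import CurveSpec, make_curve


def _mirror(v):
    m = np.array(v, float)
    m[:, 2] *= -1.0
    return m


# ---------------------------------------------------------------------------
# Alexander determinant
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "family, kw, expected",
    [
        ("circle", {}, 1),                      # Delta_unknot = 1
        ("torus_knot", dict(p=2, q=3), 3),      # |t^2 - t + 1| at t = -1
        ("figure_eight", {}, 5),                # |t^2 - 3t + 1| at t = -1
        ("torus_knot", dict(p=2, q=5), 5),
        ("torus_knot", dict(p=2, q=7), 7),
    ],
)
def test_alexander_determinants(family, kw, expected):
    v = make_curve(CurveSpec(family=family, n_vertices=200, **kw))
    assert tp.alexander_determinant(tp.ClosedCurve(v), rng=0) == expected


def test_determinant_projection_independent(trefoil, figure_eight):
    """The determinant must not depend on the projection direction."""
    for v in (trefoil, figure_eight):
        dets = {tp.alexander_determinant(tp.ClosedCurve(v), rng=s) for s in range(12)}
        assert len(dets) == 1


# ---------------------------------------------------------------------------
# closure
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["radial-outward", "direct-segment", "centroid-ray"])
def test_closure_preserves_unknot(method):
    rod = make_curve(CurveSpec(family="rod", n_vertices=20))
    closed = tp.close_curve(rod, method)
    assert tp.alexander_determinant(closed, rng=1) == 1


def test_reclosed_circle_stays_unknot(circle):
    # cut a closed circle at a vertex and re-close it
    closed = tp.close_curve(circle, "radial-outward")
    assert tp.alexander_determinant(closed, rng=2) == 1


@pytest.mark.parametrize("method", ["radial-outward", "direct-segment"])
def test_open_trefoil_closure(method, trefoil):
    """Trefoil with 5% of vertices removed keeps determinant 3 when closed."""
    open_chain = trefoil[: int(0.95 * len(trefoil))]
    closed = tp.close_curve(open_chain, method)
    assert tp.alexander_determinant(closed, rng=3) == 3


def test_closure_too_short():
    with pytest.raises(ValueError):
        tp.close_curve(np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# KMT simplification
# ---------------------------------------------------------------------------

def test_kmt_reduces_convex_planar_polygon():
    poly = make_curve(CurveSpec(family="circle", n_vertices=120))
    out = tp.kmt_simplify(tp.ClosedCurve(poly))
    assert out.n == 3


def test_kmt_preserves_knot_type(trefoil, figure_eight):
    for v, det in ((trefoil, 3), (figure_eight, 5)):
        simple = tp.kmt_simplify(tp.ClosedCurve(v))
        assert simple.n < len(v) / 4
        assert tp.alexander_determinant(simple, rng=4, simplify=False) == det


def test_kmt_idempotent(trefoil):
    once = tp.kmt_simplify(tp.ClosedCurve(trefoil))
    twice = tp.kmt_simplify(once)
    assert np.array_equal(once.vertices, twice.vertices)


def test_kmt_300_vertex_trefoil():
    v = make_curve(CurveSpec(family="torus_knot", n_vertices=300, p=2, q=3))
    out = tp.kmt_simplify(tp.ClosedCurve(v))
    assert tp.alexander_determinant(out, rng=5, simplify=False) == 3


# ---------------------------------------------------------------------------
# writhe and ACN
# ---------------------------------------------------------------------------

def test_writhe_planar_polygon_zero(circle):
    assert tp.writhe_gauss(circle) == pytest.approx(0.0, abs=1e-10)


def test_writhe_mirror_antisymmetry(trefoil, figure_eight):
    for v in (trefoil, figure_eight):
        assert tp.writhe_gauss(_mirror(v)) == -tp.writhe_gauss(v)   # exact


def test_writhe_equals_projection_average():
    """Gauss-integral writhe = mean signed crossings over 5000 projections."""
    rng = np.random.default_rng(77)
    for k in range(20):
        spec = CurveSpec(family="random_walk", n_vertices=20, seed=k, persistence=5.0)
        v = make_curve(spec)
        wr = tp.writhe_gauss(v)
        est = tp.writhe_projection_average(v, n_projections=5000, rng=rng)
        assert est == pytest.approx(wr, abs=0.02)


def test_acn_seeded_reproducible(trefoil):
    a = tp.acn(trefoil, n_projections=2000, rng=42)
    b = tp.acn(trefoil, n_projections=2000, rng=42)
    assert a == b


def test_acn_trefoil_bound_and_analytic(trefoil):
    val = tp.acn(trefoil, n_projections=2000, rng=7)
    assert val >= 3.0                       # crossing-number lower bound
    assert val == pytest.approx(tp.acn_analytic(trefoil), abs=0.15)


def test_acn_planar_convex_zero(circle):
    assert tp.acn(circle, n_projections=200, rng=1) == 0.0


def test_acn_exceeds_abs_writhe(trefoil):
    rng = np.random.default_rng(3)
    for k in range(5):
        v = make_curve(CurveSpec(family="random_walk", n_vertices=40, seed=k))
        assert tp.acn_analytic(v) >= abs(tp.writhe_gauss(v)) - 1e-9


# ---------------------------------------------------------------------------
# signed crossings and classification
# ---------------------------------------------------------------------------

def test_signed_counts_trefoil_and_mirror(trefoil):
    c = tp.ClosedCurve(trefoil)
    assert tp.signed_crossing_counts(c, rng=5) == (3, 0)
    assert tp.signed_crossing_counts(c.mirrored(), rng=5) == (0, 3)


def test_signed_counts_unknot(circle):
    assert tp.signed_crossing_counts(tp.ClosedCurve(circle), rng=6) == (0, 0)


def test_knot_class_labels():
    assert tp.knot_class(1, 0) == "0_1"
    assert tp.knot_class(3, 3, +3) == "3_1"
    assert tp.knot_class(3, 3, -3) == "3_1m"
    assert tp.knot_class(5, 4, 0) == "4_1"
    assert tp.knot_class(5, 5, +5) == "5_1"
    assert tp.knot_class(13, 13) == "complex, k > 11"


def test_complex_torus_knot_labelled_complex():
    v = make_curve(CurveSpec(family="torus_knot", n_vertices=400, p=2, q=13))
    rep = tp.analyze_chain(v[:-4], rng=8)
    assert rep.determinant == 13
    assert rep.knot_class == "complex, k > 11"


def test_analyze_chain_parity(trefoil):
    a = tp.analyze_chain(trefoil[:-6], rng=9)
    b = tp.analyze_chain(_mirror(trefoil[:-6]), rng=9)
    assert a.determinant == b.determinant == 3
    assert (a.n_plus, a.n_minus) == (b.n_minus, b.n_plus)
    assert a.core_writhe == -b.core_writhe
    assert a.chain_writhe == -b.chain_writhe      # exact parity
    assert a.knot_class == "3_1" and b.knot_class == "3_1m"


# ---------------------------------------------------------------------------
# knotted core
# ---------------------------------------------------------------------------

def test_core_of_unknot_is_empty():
    rod = make_curve(CurveSpec(family="rod", n_vertices=30))
    assert tp.locate_knot_core(rod, rng=1) is None


def test_core_localizes_spliced_trefoil(trefoil):
    """Trefoil spliced into a long straight chain: core near the splice."""
    rot_rng = np.random.default_rng(55)
    q, r = np.linalg.qr(rot_rng.standard_normal((3, 3)))
    knot = (trefoil * 0.5) @ q.T          # rotated to avoid exact incidences
    knot = knot - knot[0] + np.array([0.0, 0.2, 0.1])
    lead = np.column_stack([np.linspace(-30, -1.0, 30), np.zeros(30), np.zeros(30)])
    tail_dir = knot[-1] - knot[-2]
    tail_dir /= np.linalg.norm(tail_dir)
    tail = knot[-1] + np.outer(np.linspace(1.0, 30, 30), tail_dir)
    chain = np.vstack([lead, knot, tail])
    core = tp.locate_knot_core(chain, rng=2)
    assert core is not None
    a, b = core
    assert a >= 15 and b <= len(chain) - 10    # localized inside, +- margin
    assert b - a >= 10


def test_core_of_closed_trefoil_is_whole(trefoil):
    rep = tp.analyze_chain(trefoil[:-4], rng=11, locate_core=True)
    assert rep.core_start is not None
    assert rep.core_end - rep.core_start > 0.5 * len(trefoil[:-4])


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def test_knot_spectrum_counting():
    reports = {
        0.5: ["0_1", "0_1", "3_1"],
        2.0: ["0_1"],
    }
    spec = tp.knot_spectrum(reports)
    assert spec[0.5]["0_1"] == pytest.approx(2 / 3)
    assert spec[0.5]["3_1"] == pytest.approx(1 / 3)
    assert sum(spec[0.5].values()) == pytest.approx(1.0, abs=1e-12)
    assert spec[2.0] == {"0_1": 1.0}
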