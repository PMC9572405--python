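"""Compiled geometry kernels for the knot-analysis pipeline.

All routines treat the input (n, 3) vertex array as a closed polygon: segment
i runs from vertex i to vertex (i+1) mod n.
"""

import numpy as np
from numba import njit

FOUR_PI = 4.0 * np.pi
DEG_EPS = 1e-9          # projection regularity margin


# ---------------------------------------------------------------------------
# writhe: exact Gauss double integral over segment pairs
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pair_solid_angle(p1, p2, p3, p4):
    """Signed Gauss-integral contribution Omega/(4 pi) of two segments.

    Exact analytic solid-angle evaluation for a straight segment pair
    (Klenin & Langowski's method); the sign is the (projection-independent)
    crossing sign of the pair.
    """
    r12 = p2 - p1
    r34 = p4 - p3
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2

    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)
    a1 = np.sqrt(n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2)
    a2 = np.sqrt(n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2)
    a3 = np.sqrt(n3[0] ** 2 + n3[1] ** 2 + n3[2] ** 2)
    a4 = np.sqrt(n4[0] ** 2 + n4[1] ** 2 + n4[2] ** 2)
    if a1 < 1e-14 or a2 < 1e-14 or a3 < 1e-14 or a4 < 1e-14:
        return 0.0
    n1 = n1 / a1
    n2 = n2 / a2
    n3 = n3 / a3
    n4 = n4 / a4

    def _asin_dot(u, v):
        d = u[0] * v[0] + u[1] * v[1] + u[2] * v[2]
        if d > 1.0:
            d = 1.0
        elif d < -1.0:
            d = -1.0
        return np.arcsin(d)

    omega = (
        _asin_dot(n1, n2) + _asin_dot(n2, n3) + _asin_dot(n3, n4) + _asin_dot(n4, n1)
    )
    cr = np.cross(r34, r12)
    s = cr[0] * r13[0] + cr[1] * r13[1] + cr[2] * r13[2]
    sign = 1.0 if s > 0.0 else (-1.0 if s < 0.0 else 0.0)
    return omega * sign / FOUR_PI


@njit(cache=True)
def writhe_gauss(verts):
    """Writhe of a closed polygon by the discretized Gauss double integral."""
    n = verts.shape[0]
    wr = 0.0
    for i in range(n):
        i2 = (i + 1) % n
        for j in range(i + 2, n):
            j2 = (j + 1) % n
            if j2 == i:        # adjacent across the seam
                continue
            wr += 2.0 * _pair_solid_angle(verts[i], verts[i2], verts[j], verts[j2])
    return wr


@njit(cache=True)
def acn_exact(verts):
    """Average crossing number: the same double integral with |integrand|."""
    n = verts.shape[0]
    acn = 0.0
    for i in range(n):
        i2 = (i + 1) % n
        for j in range(i + 2, n):
            j2 = (j + 1) % n
            if j2 == i:
                continue
            acn += 2.0 * np.abs(_pair_solid_angle(verts[i], verts[i2], verts[j], verts[j2]))
    return acn


# ---------------------------------------------------------------------------
# planar diagrams from projections
# ---------------------------------------------------------------------------

@njit(cache=True)
def diagram_crossings(verts, rot, pos_over, pos_under, signs):
    """Crossings of the projection of a closed polygon along rot's third row.

    ``rot`` is a 3x3 rotation; the curve is expressed in the rotated frame
    and projected on its xy plane (viewing direction = rotated z axis,
    looking down).  For each transversal crossing the arrays receive the
    curve positions (segment index + fractional parameter, in [0, n)) of the
    over- and under-passage and the right-hand-rule sign.  Returns
    (n_crossings, degenerate): degenerate is 1 when the projection is not
    regular (parallel overlap, endpoint grazing, height tie) and the caller
    should retry with a new rotation.  n_crossings = -1 on buffer overflow.
    """
    n = verts.shape[0]
    cap = pos_over.shape[0]
    u = verts @ rot.T
    m = 0
    for i in range(n):
        i2 = (i + 1) % n
        pix = u[i, 0]
        piy = u[i, 1]
        rx = u[i2, 0] - pix
        ry = u[i2, 1] - piy
        for j in range(i + 2, n):
            j2 = (j + 1) % n
            if j2 == i:
                continue
            qx = u[j, 0]
            qy = u[j, 1]
            sx = u[j2, 0] - qx
            sy = u[j2, 1] - qy
            denom = rx * sy - ry * sx
            dqpx = qx - pix
            dqpy = qy - piy
            scale = (abs(rx) + abs(ry)) * (abs(sx) + abs(sy))
            if abs(denom) < 1e-12 * max(scale, 1e-300):
                # parallel in projection: degenerate only if collinear AND the
                # 1-D parameter intervals on the common line overlap
                if abs(dqpx * ry - dqpy * rx) < DEG_EPS * max(abs(rx) + abs(ry), 1e-300):
                    rr = rx * rx + ry * ry
                    a0 = dqpx * rx + dqpy * ry
                    a1 = a0 + (sx * rx + sy * ry)
                    lo = min(a0, a1)
                    hi = max(a0, a1)
                    if hi > -DEG_EPS * rr and lo < rr * (1.0 + DEG_EPS):
                        return m, 1
                continue
            t = (dqpx * sy - dqpy * sx) / denom
            v = (dqpx * ry - dqpy * rx) / denom
            if -DEG_EPS < t < DEG_EPS or 1.0 - DEG_EPS < t < 1.0 + DEG_EPS:
                if -4.0 * DEG_EPS < v < 1.0 + 4.0 * DEG_EPS:
                    return m, 1
            if -DEG_EPS < v < DEG_EPS or 1.0 - DEG_EPS < v < 1.0 + DEG_EPS:
                if -4.0 * DEG_EPS < t < 4.0 * DEG_EPS + 1.0:
                    return m, 1
            if t <= 0.0 or t >= 1.0 or v <= 0.0 or v >= 1.0:
                continue
            zi = u[i, 2] + t * (u[i2, 2] - u[i, 2])
            zj = u[j, 2] + v * (u[j2, 2] - u[j, 2])
            if abs(zi - zj) < DEG_EPS:
                return m, 1
            if m >= cap:
                return -1, 0
            # right-hand rule: sign((t_over x t_under) . z), viewer at +z
            if zi > zj:
                pos_over[m] = i + t
                pos_under[m] = j + v
                signs[m] = 1.0 if denom > 0.0 else -1.0
            else:
                pos_over[m] = j + v
                pos_under[m] = i + t
                signs[m] = -1.0 if denom > 0.0 else 1.0
            m += 1
    return m, 0


@njit(cache=True)
def count_crossings(verts, rot):
    """Transversal crossing count of one projection (-1 if degenerate)."""
    n = verts.shape[0]
    u = verts @ rot.T
    m = 0
    for i in range(n):
        i2 = (i + 1) % n
        pix = u[i, 0]
        piy = u[i, 1]
        rx = u[i2, 0] - pix
        ry = u[i2, 1] - piy
        for j in range(i + 2, n):
            j2 = (j + 1) % n
            if j2 == i:
                continue
            qx = u[j, 0]
            qy = u[j, 1]
            sx = u[j2, 0] - qx
            sy = u[j2, 1] - qy
            denom = rx * sy - ry * sx
            if denom == 0.0:
                continue
            dqpx = qx - pix
            dqpy = qy - piy
            t = (dqpx * sy - dqpy * sx) / denom
            v = (dqpx * ry - dqpy * rx) / denom
            if 0.0 < t < 1.0 and 0.0 < v < 1.0:
                m += 1
    return m


@njit(cache=True)
def signed_crossing_sum(verts, rot):
    """Sum of crossing signs of one projection (projection-estimate of Wr)."""
    n = verts.shape[0]
    u = verts @ rot.T
    total = 0.0
    for i in range(n):
        i2 = (i + 1) % n
        pix = u[i, 0]
        piy = u[i, 1]
        rx = u[i2, 0] - pix
        ry = u[i2, 1] - piy
        for j in range(i + 2, n):
            j2 = (j + 1) % n
            if j2 == i:
                continue
            qx = u[j, 0]
            qy = u[j, 1]
            sx = u[j2, 0] - qx
            sy = u[j2, 1] - qy
            denom = rx * sy - ry * sx
            if denom == 0.0:
                continue
            dqpx = qx - pix
            dqpy = qy - piy
            t = (dqpx * sy - dqpy * sx) / denom
            v = (dqpx * ry - dqpy * rx) / denom
            if 0.0 < t < 1.0 and 0.0 < v < 1.0:
                zi = u[i, 2] + t * (u[i2, 2] - u[i, 2])
                zj = u[j, 2] + v * (u[j2, 2] - u[j, 2])
                s = 1.0 if denom > 0.0 else -1.0
                total += s if zi > zj else -s
    return total


@njit(cache=True)
def acn_projections(verts, rots):
    """Per-projection crossing counts for a stack of rotations (k, 3, 3)."""
    k = rots.shape[0]
    out = np.empty(k)
    for a in range(k):
        out[a] = count_crossings(verts, rots[a])
    return out


@njit(cache=True)
def writhe_projection_counts(verts, rots):
    """Per-projection signed crossing sums for a stack of rotations."""
    k = rots.shape[0]
    out = np.empty(k)
    for a in range(k):
        out[a] = signed_crossing_sum(verts, rots[a])
    return out


# ---------------------------------------------------------------------------
# KMT triangle-elimination simplification
# ---------------------------------------------------------------------------

@njit(cache=True)
def _segment_hits_triangle(p, q, a, b, c, skip_p, skip_q):
    """Does segment pq cross triangle abc?  Conservative (ties count as hits).

    ``skip_p``/``skip_q`` clip a tiny fraction off the respective segment end
    when that end coincides with a triangle vertex, so contact at a shared
    vertex alone does not count.
    """
    lo = 1e-7 if skip_p else -1e-12
    hi = 1.0 - 1e-7 if skip_q else 1.0 + 1e-12
    ab = b - a
    ac = c - a
    nrm = np.cross(ab, ac)
    nn = np.sqrt(nrm[0] ** 2 + nrm[1] ** 2 + nrm[2] ** 2)
    if nn < 1e-14:
        return False          # degenerate triangle handled by the caller
    d1 = nrm[0] * (p[0] - a[0]) + nrm[1] * (p[1] - a[1]) + nrm[2] * (p[2] - a[2])
    d2 = nrm[0] * (q[0] - a[0]) + nrm[1] * (q[1] - a[1]) + nrm[2] * (q[2] - a[2])
    tol = 1e-12 * nn
    if (d1 > tol and d2 > tol) or (d1 < -tol and d2 < -tol):
        return False
    if abs(d1) <= tol and abs(d2) <= tol:
        # coplanar: 2-D overlap test in the triangle plane (clipped segment)
        pp = p + lo * (q - p)
        qq = p + hi * (q - p)
        e0 = ab
        e1 = ac
        # coordinates in the (e0, e1) basis via normal-equation solve
        g00 = e0[0] ** 2 + e0[1] ** 2 + e0[2] ** 2
        g01 = e0[0] * e1[0] + e0[1] * e1[1] + e0[2] * e1[2]
        g11 = e1[0] ** 2 + e1[1] ** 2 + e1[2] ** 2
        det = g00 * g11 - g01 * g01
        if det == 0.0:
            return True
        # barycentric coordinates of the two clipped segment ends
        b0 = e0[0] * (pp[0] - a[0]) + e0[1] * (pp[1] - a[1]) + e0[2] * (pp[2] - a[2])
        b1 = e1[0] * (pp[0] - a[0]) + e1[1] * (pp[1] - a[1]) + e1[2] * (pp[2] - a[2])
        up = (g11 * b0 - g01 * b1) / det
        vp = (g00 * b1 - g01 * b0) / det
        b0 = e0[0] * (qq[0] - a[0]) + e0[1] * (qq[1] - a[1]) + e0[2] * (qq[2] - a[2])
        b1 = e1[0] * (qq[0] - a[0]) + e1[1] * (qq[1] - a[1]) + e1[2] * (qq[2] - a[2])
        uq = (g11 * b0 - g01 * b1) / det
        vq = (g00 * b1 - g01 * b0) / det
        # clip the parameter interval against u >= 0, v >= 0, u + v <= 1
        t0 = 0.0
        t1 = 1.0
        for cons in range(3):
            if cons == 0:
                f0 = up
                df = uq - up
            elif cons == 1:
                f0 = vp
                df = vq - vp
            else:
                f0 = 1.0 - up - vp
                df = (1.0 - uq - vq) - (1.0 - up - vp)
            if abs(df) < 1e-300:
                if f0 < -1e-10:
                    return False
            elif df > 0.0:
                tc = (-1e-10 - f0) / df
                if tc > t0:
                    t0 = tc
            else:
                tc = (-1e-10 - f0) / df
                if tc < t1:
                    t1 = tc
        return t0 <= t1
    t = d1 / (d1 - d2)
    if t < lo or t > hi:
        return False
    x = np.empty(3)
    for k in range(3):
        x[k] = p[k] + t * (q[k] - p[k])
    # barycentric inside-test, boundary counts as inside
    v0 = ac
    v1 = ab
    v2 = x - a
    dot00 = v0[0] ** 2 + v0[1] ** 2 + v0[2] ** 2
    dot01 = v0[0] * v1[0] + v0[1] * v1[1] + v0[2] * v1[2]
    dot02 = v0[0] * v2[0] + v0[1] * v2[1] + v0[2] * v2[2]
    dot11 = v1[0] ** 2 + v1[1] ** 2 + v1[2] ** 2
    dot12 = v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]
    den = dot00 * dot11 - dot01 * dot01
    if den == 0.0:
        return True
    uu = (dot11 * dot02 - dot01 * dot12) / den
    vv = (dot00 * dot12 - dot01 * dot02) / den
    return uu >= -1e-10 and vv >= -1e-10 and uu + vv <= 1.0 + 1e-10


@njit(cache=True)
def kmt_pass(verts, alive):
    """One sweep of triangle eliminations; updates ``alive`` in place.

    Vertex j is removed when the triangle (prev, j, next) is pierced by no
    other surviving segment; near-collinear vertices are removed outright.
    Segments incident to a triangle corner are tested with the shared end
    clipped, so mere vertex contact does not block removal.  Returns the
    number of removals.
    """
    n = verts.shape[0]
    idx = np.empty(n, dtype=np.int64)
    removed = 0
    for j in range(n):
        if not alive[j]:
            continue
        # surviving vertex list (recomputed cheaply each attempt)
        m = 0
        for i in range(n):
            if alive[i]:
                idx[m] = i
                m += 1
        if m <= 3:
            break
        # position of j among survivors
        jj = 0
        for i in range(m):
            if idx[i] == j:
                jj = i
                break
        p = idx[(jj - 1) % m]
        q = idx[(jj + 1) % m]
        a = verts[p]
        b = verts[j]
        c = verts[q]
        nrm = np.cross(b - a, c - a)
        area2 = np.sqrt(nrm[0] ** 2 + nrm[1] ** 2 + nrm[2] ** 2)
        base = np.sqrt(
            (c[0] - a[0]) ** 2 + (c[1] - a[1]) ** 2 + (c[2] - a[2]) ** 2
        )
        if area2 < 1e-12 * max(base, 1.0):
            alive[j] = False
            removed += 1
            continue
        hit = False
        for spos in range(m):
            s = idx[spos]
            s2 = idx[(spos + 1) % m]
            if s == p or s == j:      # the two segments being replaced
                continue
            if _segment_hits_triangle(
                verts[s], verts[s2], a, b, c, s == q, s2 == p
            ):
                hit = True
                break
        if not hit:
            alive[j] = False
            removed += 1
    return removed
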