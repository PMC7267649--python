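"""Internal-coordinate primitives with analytic Cartesian derivatives.

Each helper returns the scalar value and the derivative with respect to the
Cartesian positions of the atoms involved.  Torsions are formulated in
cos(phi) via the two bond-normal vectors, which keeps every expression
polynomial/rational in the coordinates: no arccos, no division by sin(theta),
hence no singularity at planar or linear arrangements (terms that need it are
damped by sin^2 factors computed here as rational expressions too).
"""

from __future__ import annotations

import numpy as np


def distance(xyz, i, j):
    d = xyz[i] - xyz[j]
    r = float(np.linalg.norm(d))
    u = d / r
    return r, u  # dr/dx_i = u, dr/dx_j = -u


def cos_angle(xyz, i, j, k):
    """cos of the angle at j; returns (c, gi, gj, gk)."""
    u = xyz[i] - xyz[j]
    v = xyz[k] - xyz[j]
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    c = float(np.dot(u, v) / (nu * nv))
    gi = v / (nu * nv) - c * u / nu**2
    gk = u / (nu * nv) - c * v / nv**2
    gj = -gi - gk
    return c, gi, gj, gk


def _cross_mats(b1, b2, b3):
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    return n1, n2


def cos_dihedral(xyz, i, j, k, l, eps=1e-12):
    """cos(phi) for the torsion i-j-k-l and its atom gradients.

    Returns (c, (gi, gj, gk, gl), ok); ok is False when either bond normal
    nearly vanishes (collinear arm), in which case gradients are zeroed --
    callers multiply by sin^2 damping that vanishes faster.
    """
    b1 = xyz[j] - xyz[i]
    b2 = xyz[k] - xyz[j]
    b3 = xyz[l] - xyz[k]
    n1, n2 = _cross_mats(b1, b2, b3)
    p2 = float(np.dot(n1, n1))
    q2 = float(np.dot(n2, n2))
    if p2 < eps or q2 < eps:
        z = np.zeros(3)
        return 1.0, (z, z, z, z), False
    p = np.sqrt(p2)
    q = np.sqrt(q2)
    a = float(np.dot(n1, n2))
    c = a / (p * q)

    # derivatives of a, p^2, q^2 with respect to b1, b2, b3
    da_b1 = np.cross(b2, n2)
    da_b2 = np.cross(n2, b1) + np.cross(b3, n1)
    da_b3 = np.cross(n1, b2)
    dp2_b1 = 2.0 * np.cross(b2, n1)
    dp2_b2 = 2.0 * np.cross(n1, b1)
    dq2_b2 = 2.0 * np.cross(b3, n2)
    dq2_b3 = 2.0 * np.cross(n2, b2)

    inv_pq = 1.0 / (p * q)
    dc_b1 = da_b1 * inv_pq - 0.5 * c * dp2_b1 / p2
    dc_b2 = da_b2 * inv_pq - 0.5 * c * (dp2_b2 / p2 + dq2_b2 / q2)
    dc_b3 = da_b3 * inv_pq - 0.5 * c * dq2_b3 / q2

    gi = -dc_b1
    gj = dc_b1 - dc_b2
    gk = dc_b2 - dc_b3
    gl = dc_b3
    return c, (gi, gj, gk, gl), True


def sin2_angle_from_bonds(xyz, i, j, k):
    """sin^2 of the angle at j as |u x v|^2 / (|u|^2 |v|^2), with gradients."""
    u = xyz[i] - xyz[j]
    v = xyz[k] - xyz[j]
    w = np.cross(u, v)
    u2 = float(np.dot(u, u))
    v2 = float(np.dot(v, v))
    w2 = float(np.dot(w, w))
    s = w2 / (u2 * v2)
    # d w2 / du = 2 v x w ... since w = u x v: dw2 = 2 w . (du x v) = 2 (v x w) . du
    dw2_du = 2.0 * np.cross(v, w)
    dw2_dv = 2.0 * np.cross(w, u)
    ds_du = dw2_du / (u2 * v2) - s * 2.0 * u / u2
    ds_dv = dw2_dv / (u2 * v2) - s * 2.0 * v / v2
    gi = ds_du
    gk = ds_dv
    gj = -ds_du - ds_dv
    return s, gi, gj, gk
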