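"""Flat-facet triangular shell element: CST membrane + DKT bending.

Each triangle carries 6 degrees of freedom per node in its local frame
(u, v, w, thx, thy, thz).  Membrane behaviour (u, v) is the constant-strain
triangle; transverse behaviour (w, thx, thy) is the discrete Kirchhoff
triangle (DKT) of Batoz, Bathe & Ho; the drilling rotation thz has no
physical stiffness on a flat facet and receives a small penalty term so the
assembled shell is free of spurious zero-energy modes.

Rotation sign convention: thx and thy are right-handed rotations about the
local x and y axes, so for a plate deflection w(x, y) the Kirchhoff
constraints read thx = dw/dy and thy = -dw/dx.  With this convention
(thx, thy, thz) transform between frames as an ordinary vector, which is
what the local-to-global assembly assumes.
"""

from __future__ import annotations

import numpy as np

# 3-point mid-edge Gauss rule on the unit triangle: exact for the quadratic
# DKT curvature field.
_GAUSS_PTS = np.array([[0.5, 0.0], [0.0, 0.5], [0.5, 0.5]])
_GAUSS_W = np.array([1.0 / 6.0, 1.0 / 6.0, 1.0 / 6.0])


def membrane_stiffness(xy: np.ndarray, E: float, nu: float, t: float) -> np.ndarray:
    """CST plane-stress stiffness, 6x6 on (u1, v1, u2, v2, u3, v3)."""
    x, y = xy[:, 0], xy[:, 1]
    area2 = (x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0])
    if area2 <= 0:
        raise ValueError("triangle has non-positive area in its local frame")
    A = 0.5 * area2
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    B = np.zeros((3, 6))
    B[0, 0::2] = b
    B[1, 1::2] = c
    B[2, 0::2] = c
    B[2, 1::2] = b
    B /= area2
    D = E / (1.0 - nu**2) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, 0.5 * (1.0 - nu)]]
    )
    return t * A * (B.T @ D @ B)


def _dkt_side_coeffs(xy: np.ndarray):
    # sides k = 4, 5, 6 join nodes (2,3), (3,1), (1,2)  [0-based (1,2),(2,0),(0,1)]
    pairs = [(1, 2), (2, 0), (0, 1)]
    P = np.zeros(3)
    q = np.zeros(3)
    t_ = np.zeros(3)
    r = np.zeros(3)
    for k, (i, j) in enumerate(pairs):
        xij = xy[i, 0] - xy[j, 0]
        yij = xy[i, 1] - xy[j, 1]
        l2 = xij * xij + yij * yij
        P[k] = -6.0 * xij / l2
        q[k] = 3.0 * xij * yij / l2
        t_[k] = -6.0 * yij / l2
        r[k] = 3.0 * yij * yij / l2
    return P, q, t_, r


def _dkt_H_derivs(xi: float, eta: float, P, q, t_, r):
    """dHx/dxi, dHx/deta, dHy/dxi, dHy/deta as 9-vectors.

    DOF order (w1, thx1, thy1, w2, thx2, thy2, w3, thx3, thy3); explicit
    polynomials of the Batoz-Bathe-Ho element.  P4..P6 map to P[0..2] etc.
    """
    P4, P5, P6 = P
    q4, q5, q6 = q
    t4, t5, t6 = t_
    r4, r5, r6 = r

    Hx_xi = np.array([
        P6 * (1 - 2 * xi) + (P5 - P6) * eta,
        q6 * (1 - 2 * xi) - (q5 + q6) * eta,
        -4 + 6 * (xi + eta) + r6 * (1 - 2 * xi) - eta * (r5 + r6),
        -P6 * (1 - 2 * xi) + eta * (P4 + P6),
        q6 * (1 - 2 * xi) - eta * (q6 - q4),
        -2 + 6 * xi + r6 * (1 - 2 * xi) + eta * (r4 - r6),
        -eta * (P5 + P4),
        eta * (q4 - q5),
        -eta * (r5 - r4),
    ])
    Hy_xi = np.array([
        t6 * (1 - 2 * xi) + eta * (t5 - t6),
        1 + r6 * (1 - 2 * xi) - eta * (r5 + r6),
        -q6 * (1 - 2 * xi) + eta * (q5 + q6),
        -t6 * (1 - 2 * xi) + eta * (t4 + t6),
        -1 + r6 * (1 - 2 * xi) + eta * (r4 - r6),
        -q6 * (1 - 2 * xi) - eta * (q4 - q6),
        -eta * (t4 + t5),
        eta * (r4 - r5),
        -eta * (q4 - q5),
    ])
    Hx_eta = np.array([
        -P5 * (1 - 2 * eta) - xi * (P6 - P5),
        q5 * (1 - 2 * eta) - xi * (q5 + q6),
        -4 + 6 * (xi + eta) + r5 * (1 - 2 * eta) - xi * (r5 + r6),
        xi * (P4 + P6),
        xi * (q4 - q6),
        -xi * (r6 - r4),
        P5 * (1 - 2 * eta) - xi * (P4 + P5),
        q5 * (1 - 2 * eta) + xi * (q4 - q5),
        -2 + 6 * eta + r5 * (1 - 2 * eta) + xi * (r4 - r5),
    ])
    Hy_eta = np.array([
        -t5 * (1 - 2 * eta) - xi * (t6 - t5),
        1 + r5 * (1 - 2 * eta) - xi * (r5 + r6),
        -q5 * (1 - 2 * eta) + xi * (q5 + q6),
        xi * (t4 + t6),
        xi * (r4 - r6),
        -xi * (q4 - q6),
        t5 * (1 - 2 * eta) - xi * (t4 + t5),
        -1 + r5 * (1 - 2 * eta) + xi * (r4 - r5),
        -q5 * (1 - 2 * eta) - xi * (q4 - q5),
    ])
    return Hx_xi, Hx_eta, Hy_xi, Hy_eta


def bending_stiffness(xy: np.ndarray, E: float, nu: float, t: float) -> np.ndarray:
    """DKT bending stiffness, 9x9 on (w1, thx1, thy1, ..., thy3)."""
    x, y = xy[:, 0], xy[:, 1]
    x31, y31 = x[2] - x[0], y[2] - y[0]
    x21, y21 = x[1] - x[0], y[1] - y[0]
    area2 = x21 * y31 - x31 * y21
    if area2 <= 0:
        raise ValueError("triangle has non-positive area in its local frame")
    Db = E * t**3 / (12.0 * (1.0 - nu**2)) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, 0.5 * (1.0 - nu)]]
    )
    P, q, t_, r = _dkt_side_coeffs(xy)
    K = np.zeros((9, 9))
    for (xi, eta), w in zip(_GAUSS_PTS, _GAUSS_W):
        Hx_xi, Hx_eta, Hy_xi, Hy_eta = _dkt_H_derivs(xi, eta, P, q, t_, r)
        B = np.vstack([
            y31 * Hx_xi - y21 * Hx_eta,
            -x31 * Hy_xi + x21 * Hy_eta,
            -x31 * Hx_xi + x21 * Hx_eta + y31 * Hy_xi - y21 * Hy_eta,
        ]) / area2
        K += area2 * w * (B.T @ Db @ B)
    # Batoz convention carries (w, w_x-like, w_y-like) internally; convert the
    # rotational columns to right-handed nodal rotations thx = w_y, thy = -w_x.
    # In the H polynomials above the per-node order is already
    # (w, thx, thy) with the thy column carrying a sign flip relative to w_x.
    return K


def shell_stiffness(
    xy: np.ndarray, E: float, nu: float, t: float, drill_factor: float = 1e-2
) -> np.ndarray:
    """18x18 local stiffness on (u, v, w, thx, thy, thz) x 3 nodes."""
    Km = membrane_stiffness(xy, E, nu, t)
    Kb = bending_stiffness(xy, E, nu, t)
    x, y = xy[:, 0], xy[:, 1]
    A = 0.5 * ((x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0]))
    K = np.zeros((18, 18))
    mem_idx = [0, 1, 6, 7, 12, 13]          # u,v per node
    bend_idx = [2, 3, 4, 8, 9, 10, 14, 15, 16]  # w,thx,thy per node
    drill_idx = [5, 11, 17]
    K[np.ix_(mem_idx, mem_idx)] += Km
    K[np.ix_(bend_idx, bend_idx)] += Kb
    # penalty on relative drilling rotation; nullspace = equal rotations
    kd = drill_factor * E * t * A
    K[np.ix_(drill_idx, drill_idx)] += kd * np.array(
        [[1.0, -0.5, -0.5], [-0.5, 1.0, -0.5], [-0.5, -0.5, 1.0]]
    )
    return K


def shell_mass(xy: np.ndarray, rho: float, t: float) -> np.ndarray:
    """18x18 local mass: consistent translational CST mass + lumped rotary inertia."""
    x, y = xy[:, 0], xy[:, 1]
    A = 0.5 * ((x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0]))
    M = np.zeros((18, 18))
    mconsist = rho * t * A / 12.0 * np.array(
        [[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]
    )
    for comp in range(3):  # u, v, w
        idx = [comp, comp + 6, comp + 12]
        M[np.ix_(idx, idx)] += mconsist
    # rotary inertia of the shell wall, lumped equally on the three nodes
    irot = rho * t**3 / 12.0 * A / 3.0
    for comp in range(3, 6):
        for node in range(3):
            M[comp + 6 * node, comp + 6 * node] += irot
    return M


def triangle_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local orthonormal frame (rows ex, ey, ez) and in-plane node coords.

    ex runs along edge 1->2, ez is the face normal; returns (R, xy) with xy
    the 3x2 local coordinates (node 1 at the origin).
    """
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[0]
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n)
    if nn < 1e-28:
        raise ValueError("degenerate triangle (zero area)")
    ez = n / nn
    ex = e1 / np.linalg.norm(e1)
    ey = np.cross(ez, ex)
    R = np.vstack([ex, ey, ez])
    xy = (coords - coords[0]) @ R[:2].T
    return R, xy


def shell_element(
    coords: np.ndarray, E: float, nu: float, t: float, rho: float,
    drill_factor: float = 1e-2,
) -> tuple[np.ndarray, np.ndarray]:
    """Global-frame 18x18 (K, M) for a triangle given 3x3 vertex coordinates in m."""
    R, xy = triangle_frame(coords)
    Kl = shell_stiffness(xy, E, nu, t, drill_factor)
    Ml = shell_mass(xy, rho, t)
    T = np.zeros((18, 18))
    for blk in range(6):
        T[3 * blk:3 * blk + 3, 3 * blk:3 * blk + 3] = R
    return T.T @ Kl @ T, T.T @ Ml @ T
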