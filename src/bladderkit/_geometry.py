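"""Dependency-light mesh geometry kernels.

Brute-force but fully vectorised point-to-surface distance, point-in-mesh
parity tests, and similarity (scale + rotation + translation) surface
registration.  Written for the mesh sizes this package works with (10^3 to
10^4 faces), where an O(points x faces) sweep is fast and has no spatial-
index dependency.
"""

from __future__ import annotations

import numpy as np
import trimesh


def closest_point(mesh: trimesh.Trimesh, points: np.ndarray):
    """Closest surface point and distance for each query point.

    Returns (closest (n,3), distance (n,), face_index (n,)).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles                                  # (f, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    best_d2 = np.full(len(points), np.inf)
    best_pt = np.zeros((len(points), 3))
    best_face = np.zeros(len(points), dtype=int)
    # chunk over query points to bound memory
    for i0 in range(0, len(points), 64):
        p = points[i0:i0 + 64]                            # (q, 3)
        cp = _closest_on_triangles(p, a, b, c, ab, ac)    # (q, f, 3)
        d2 = ((p[:, None, :] - cp) ** 2).sum(axis=2)      # (q, f)
        idx = d2.argmin(axis=1)
        rows = np.arange(len(p))
        best_d2[i0:i0 + 64] = d2[rows, idx]
        best_pt[i0:i0 + 64] = cp[rows, idx]
        best_face[i0:i0 + 64] = idx
    return best_pt, np.sqrt(best_d2), best_face


def _closest_on_triangles(p, a, b, c, ab, ac):
    """Ericson's point-triangle closest point, broadcast (q points, f tris)."""
    q, f = len(p), len(a)
    ap = p[:, None, :] - a[None, :, :]                    # (q, f, 3)
    d1 = (ab[None] * ap).sum(-1)
    d2 = (ac[None] * ap).sum(-1)
    bp = p[:, None, :] - b[None, :, :]
    d3 = (ab[None] * bp).sum(-1)
    d4 = (ac[None] * bp).sum(-1)
    cp_ = p[:, None, :] - c[None, :, :]
    d5 = (ab[None] * cp_).sum(-1)
    d6 = (ac[None] * cp_).sum(-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom != 0, vb / denom, 0.0)
        w_face = np.where(denom != 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)

    out = a[None] + v_face[..., None] * ab[None] + w_face[..., None] * ac[None]
    # edge BC region
    reg_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(reg_bc[..., None],
                   b[None] + np.clip(w_bc, 0, 1)[..., None] * (c - b)[None], out)
    # edge AC region
    reg_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(reg_ac[..., None],
                   a[None] + np.clip(w_ac, 0, 1)[..., None] * ac[None], out)
    # edge AB region
    reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(reg_ab[..., None],
                   a[None] + np.clip(v_ab, 0, 1)[..., None] * ab[None], out)
    # vertex regions
    reg_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(reg_a[..., None], np.broadcast_to(a[None], out.shape), out)
    reg_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(reg_b[..., None], np.broadcast_to(b[None], out.shape), out)
    reg_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(reg_c[..., None], np.broadcast_to(c[None], out.shape), out)
    return out


def contains(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Ray-parity inside test for watertight meshes.

    The ray direction is irrational so it cannot pass exactly through mesh
    vertices or edges of axis-aligned or symmetric meshes.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = b - a, c - a
    d = np.array([np.sqrt(2.0), np.sqrt(3.0), np.sqrt(5.0)])
    d /= np.linalg.norm(d)
    h = np.cross(np.broadcast_to(d, e2.shape), e2)
    det = (e1 * h).sum(-1)                                 # (f,)
    ok = np.abs(det) > 1e-14
    inside = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        s = p - a
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (s * h).sum(-1) / det
            qv = np.cross(s, e1)
            v = (qv @ d) / det
            t = (e2 * qv).sum(-1) / det
            hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
        inside[i] = (hit.sum() % 2) == 1
    return inside


def _umeyama(src: np.ndarray, dst: np.ndarray, scale: bool = True) -> np.ndarray:
    """Least-squares similarity transform (4x4) mapping src -> dst."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if scale:
        var_s = (xs**2).sum() / len(src)
        s = (D * np.diag(S)).sum() / var_s
    else:
        s = 1.0
    T = np.eye(4)
    T[:3, :3] = s * R
    T[:3, 3] = mu_d - s * R @ mu_s
    return T


def similarity_register(
    source_mesh: trimesh.Trimesh, target_mesh: trimesh.Trimesh,
    samples: int = 400, iterations: int = 30, tol: float = 1e-9, seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Similarity ICP aligning source onto target.

    Initialised from centroids, RMS size and principal axes; refined by
    iterating closest-surface-point correspondence with a Umeyama fit.
    Returns (4x4 matrix, final RMS distance).
    """
    src_pts, _ = trimesh.sample.sample_surface_even(source_mesh, samples,
                                                    seed=seed)[:2]
    src_pts = np.asarray(src_pts, dtype=float)

    def axes(mesh):
        v = mesh.vertices - mesh.vertices.mean(0)
        w, E = np.linalg.eigh(v.T @ v / len(v))
        E = E[:, np.argsort(w)[::-1]]
        for k in range(3):
            j = int(np.argmax(np.abs(E[:, k])))
            if E[j, k] < 0:
                E[:, k] = -E[:, k]
        if np.linalg.det(E) < 0:
            E[:, 2] = -E[:, 2]
        return E

    Es, Et = axes(source_mesh), axes(target_mesh)
    R0 = Et @ Es.T
    rms = lambda mesh: np.sqrt(((mesh.vertices - mesh.vertices.mean(0))**2)
                               .sum(1).mean())
    s0 = rms(target_mesh) / rms(source_mesh)
    T = np.eye(4)
    T[:3, :3] = s0 * R0
    T[:3, 3] = target_mesh.vertices.mean(0) - s0 * R0 @ source_mesh.vertices.mean(0)

    prev = np.inf
    cost = np.inf
    for _ in range(iterations):
        cur = (T[:3, :3] @ src_pts.T).T + T[:3, 3]
        closest, dist, _ = closest_point(target_mesh, cur)
        cost = float(np.sqrt((dist**2).mean()))
        if abs(prev - cost) < tol * max(1.0, cost):
            break
        prev = cost
        T = _umeyama(src_pts, closest, scale=True)
    if not np.isfinite(cost):
        raise RuntimeError("similarity registration failed to converge")
    return T, cost
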