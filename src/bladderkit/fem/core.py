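"""Model assembly, boundary conditions and modal analysis for shell meshes.

The swim bladder wall is modelled as a thin linear-elastic shell discretised
by the flat-facet triangles of :mod:`bladderkit.fem.elements`.  Default
material constants are wall properties measured in the oyster toadfish, a
close relative of the midshipman: Young's modulus 1 MPa, wall thickness
824.5 um, density 1000 kg/m^3 (close to water), and a uniform underdamped
modal damping ratio of 0.325.  Poisson's ratio is not reported for bladder
wall; the default 0.4 is typical of soft biological tissue and is
configurable.

Meshes are supplied in millimetres (the morphometric unit) and converted to
metres here; every node carries 6 degrees of freedom (3 translations, 3
rotations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh

from .elements import shell_element

MM_TO_M = 1e-3
DOF_PER_NODE = 6


@dataclass
class FemModel:
    """Shell model: mesh (coordinates in metres) + material and damping constants."""

    mesh: trimesh.Trimesh
    youngs_modulus: float = 1.0e6       # Pa
    thickness: float = 824.5e-6         # m
    density: float = 1000.0             # kg m^-3
    damping_ratio: float = 0.325
    poisson_ratio: float = 0.4
    drill_factor: float = 1e-2
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        for name in ("youngs_modulus", "thickness", "density", "poisson_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.damping_ratio < 1:
            raise ValueError("damping_ratio must lie in (0, 1): underdamped shell")
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=int)

    @classmethod
    def from_mesh_mm(cls, mesh_mm: trimesh.Trimesh, caudal_fraction: float = 0.25,
                     **kwargs) -> "FemModel":
        """Build a model from a mesh in mm: convert units, centre at the
        centroid, and fix the dorsal-caudal midline nodes."""
        mesh = mesh_mm.copy()
        mesh.vertices = (mesh.vertices - mesh.centroid) * MM_TO_M
        model = cls(mesh=mesh, **kwargs)
        model.fixed_nodes = select_dorsal_caudal_midline(mesh, caudal_fraction)
        return model

    @property
    def n_dof(self) -> int:
        return len(self.mesh.vertices) * DOF_PER_NODE


def select_dorsal_caudal_midline(
    mesh: trimesh.Trimesh, caudal_fraction: float = 0.25,
    band_width: float | None = None,
) -> np.ndarray:
    """Nodes along the dorsal midline over the caudal part of the bladder.

    These model the ligamentous attachment of the bladder to the dorsal body
    wall: displacement and rotation are suppressed there.  Rostral is +x,
    dorsal +z; the midline band is |y| <= band_width (default 1.5 median
    edge lengths) over the caudal ``caudal_fraction`` of the x-extent.
    """
    v = mesh.vertices
    if band_width is None:
        band_width = 1.5 * float(np.median(mesh.edges_unique_length))
    x0, x1 = v[:, 0].min(), v[:, 0].max()
    x_cut = x0 + caudal_fraction * (x1 - x0)
    cand = (v[:, 0] <= x_cut) & (np.abs(v[:, 1]) <= band_width) & (v[:, 2] > 0)
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        raise ValueError(
            "no dorsal-caudal midline nodes found; widen band_width or "
            "check mesh orientation (rostral +x, dorsal +z)"
        )
    return idx


def assemble(model: FemModel) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Global stiffness and consistent mass matrices (SI units)."""
    mesh = model.mesh
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    areas = mesh.area_faces
    bad = np.flatnonzero(areas < 1e-14)
    if bad.size:
        raise ValueError(f"degenerate triangle(s) with area < 1e-14 m^2: {bad[:5].tolist()}")

    nf = len(faces)
    rows = np.empty(nf * 18 * 18, dtype=np.int64)
    cols = np.empty_like(rows)
    kval = np.empty(nf * 18 * 18, dtype=float)
    mval = np.empty_like(kval)
    for e, tri in enumerate(faces):
        Ke, Me = shell_element(
            verts[tri], model.youngs_modulus, model.poisson_ratio,
            model.thickness, model.density, model.drill_factor,
        )
        edof = (tri[:, None] * DOF_PER_NODE + np.arange(DOF_PER_NODE)).ravel()
        rr, cc = np.meshgrid(edof, edof, indexing="ij")
        s = slice(e * 324, (e + 1) * 324)
        rows[s] = rr.ravel()
        cols[s] = cc.ravel()
        kval[s] = Ke.ravel()
        mval[s] = Me.ravel()

    n = model.n_dof
    K = sp.csr_matrix((kval, (rows, cols)), shape=(n, n))
    M = sp.csr_matrix((mval, (rows, cols)), shape=(n, n))
    K = 0.5 * (K + K.T)
    M = 0.5 * (M + M.T)
    return K, M


@dataclass
class ConstrainedSystem:
    """Reduced (K, M) after eliminating the fixed degrees of freedom."""

    K: sp.csr_matrix
    M: sp.csr_matrix
    free_dofs: np.ndarray
    n_dof_full: int

    def expand(self, u_free: np.ndarray) -> np.ndarray:
        """Scatter a reduced vector/matrix back to full DOF numbering."""
        shape = (self.n_dof_full,) + u_free.shape[1:]
        u = np.zeros(shape, dtype=u_free.dtype)
        u[self.free_dofs] = u_free
        return u

    def restrict(self, f_full: np.ndarray) -> np.ndarray:
        return f_full[self.free_dofs]


def apply_boundary_conditions(
    model: FemModel, K: sp.spmatrix, M: sp.spmatrix
) -> ConstrainedSystem:
    """Eliminate all 6 DOFs of the fixed nodes (clamped attachment)."""
    if model.fixed_nodes.size == 0:
        raise ValueError("fixed node set is empty: structure would be free-floating")
    n = K.shape[0]
    fixed = (model.fixed_nodes[:, None] * DOF_PER_NODE
             + np.arange(DOF_PER_NODE)).ravel()
    mask = np.ones(n, dtype=bool)
    mask[fixed] = False
    free = np.flatnonzero(mask)
    Kf = K.tocsr()[free][:, free]
    Mf = M.tocsr()[free][:, free]
    return ConstrainedSystem(K=Kf.tocsr(), M=Mf.tocsr(), free_dofs=free, n_dof_full=n)


@dataclass
class ModalResult:
    """Natural frequencies (Hz, ascending) and mass-normalised mode shapes.

    ``shapes`` has one column per mode in full DOF numbering (fixed DOFs
    zero); shapes satisfy shape_i^T M shape_j = delta_ij.
    """

    frequencies_hz: np.ndarray
    shapes: np.ndarray          # (n_dof_full, n_modes)
    system: ConstrainedSystem

    @property
    def omegas(self) -> np.ndarray:
        """Angular natural frequencies, rad/s."""
        return 2.0 * np.pi * self.frequencies_hz

    def node_shape(self, mode: int, n_nodes: int) -> np.ndarray:
        """Translational part of one mode shape, (n_nodes, 3)."""
        return self.shapes[:, mode].reshape(n_nodes, DOF_PER_NODE)[:, :3]


def modal_analysis(
    system: ConstrainedSystem, f_max: float, margin: float = 1.2,
    k0: int = 32, max_modes: int = 2000, tol: float = 0.0,
) -> ModalResult:
    """Solve K q = omega^2 M q for all modes up to ``f_max * margin`` Hz.

    Shift-invert Lanczos about zero; the constrained stiffness is positive
    definite so the factorisation is stable.  The number of requested modes
    is doubled until the band is covered.
    """
    n = system.K.shape[0]
    target = f_max * margin
    # symmetric Jacobi scaling: rotational and translational DOF stiffnesses
    # differ by many orders; scaling keeps the shift-invert solves accurate
    d = 1.0 / np.sqrt(system.K.diagonal())
    D = sp.diags(d)
    Ks = (D @ system.K @ D).tocsc()
    Ms = (D @ system.M @ D).tocsr()
    Ks = 0.5 * (Ks + Ks.T)
    Ms = 0.5 * (Ms + Ms.T)
    k = min(k0, n - 2)
    while True:
        try:
            # fixed start vector keeps the Lanczos iteration bit-reproducible
            v0 = np.ones(n) / np.sqrt(n)
            w2, vec = spla.eigsh(Ks, k=k, M=Ms, sigma=0.0,
                                 which="LM", tol=tol, v0=v0)
        except spla.ArpackNoConvergence as err:  # pragma: no cover
            raise RuntimeError(
                f"eigen-solver failed to converge with shift 0, k={k}: {err}"
            ) from err
        order = np.argsort(w2)
        w2, vec = w2[order], vec[:, order]
        f = np.sqrt(np.clip(w2, 0.0, None)) / (2.0 * np.pi)
        if f[-1] >= target or k >= min(max_modes, n - 2):
            break
        k = min(2 * k, n - 2, max_modes)
    vec = D @ vec                           # back to physical DOFs

    keep = f <= target
    # retain the first mode beyond the band so coverage checks are inclusive
    if (~keep).any():
        keep[np.argmax(~keep)] = True
    if not keep.any():
        keep[0] = True
    f, vec = f[keep], vec[:, keep]
    # enforce exact mass-normalisation
    mnorm = np.sqrt(np.einsum("ij,ij->j", vec, system.M @ vec))
    vec = vec / mnorm
    return ModalResult(frequencies_hz=f, shapes=system.expand(vec), system=system)
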