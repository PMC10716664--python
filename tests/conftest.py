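import numpy as np
import pytest
import trimesh

from bladderkit.synthetic import BladderShapeParams, generate_bladder_mesh


@pytest.fixture(scope="session")
def horned_mesh():
    """Coarse non-reproductive-like bladder (30 mm body + 10 mm horns)."""
    return generate_bladder_mesh(BladderShapeParams(
        body_length=30, body_width=20, body_height=15,
        horn_length=10, mesh_resolution=2.0))


@pytest.fixture(scope="session")
def hornless_mesh():
    """Coarse reproductive-like bladder (wider, no horns)."""
    return generate_bladder_mesh(BladderShapeParams(
        body_length=32, body_width=26, body_height=17,
        horn_length=0, mesh_resolution=2.0))


@pytest.fixture(scope="session")
def sphere_mesh():
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)


def make_plate_mesh(side: float, n: int) -> trimesh.Trimesh:
    """Structured right-triangle mesh of a square plate in the z=0 plane."""
    xs = np.linspace(0.0, side, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    verts = np.c_[X.ravel(), Y.ravel(), np.zeros((n + 1) ** 2)]
    faces = []
    vid = lambda i, j: i * (n + 1) + j
    for i in range(n):
        for j in range(n):
            faces.append([vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)])
            faces.append([vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)])
    return trimesh.Trimesh(verts, np.array(faces), process=False)


def plate_bending_system(mesh: trimesh.Trimesh, side: float, E: float,
                         nu: float, t: float, rho: float):
    """Assemble a plate and keep only bending DOFs, simply supported.

    Boundary: w = 0 on the edge; in-plane and drilling DOFs fixed everywhere
    (pure bending problem).  Returns the constrained system.
    """
    from bladderkit.fem import FemModel, assemble
    from bladderkit.fem.core import ConstrainedSystem

    model = FemModel(mesh=mesh, youngs_modulus=E, thickness=t, density=rho,
                     poisson_ratio=nu, fixed_nodes=np.array([0]))
    K, M = assemble(model)
    v = mesh.vertices
    nn = len(v)
    boundary = (np.isclose(v[:, 0], 0) | np.isclose(v[:, 0], side)
                | np.isclose(v[:, 1], 0) | np.isclose(v[:, 1], side))
    free = np.zeros(nn * 6, dtype=bool)
    for i in range(nn):
        if not boundary[i]:
            free[i * 6 + 2] = True          # w
        free[i * 6 + 3] = True              # thx
        free[i * 6 + 4] = True              # thy
    fd = np.flatnonzero(free)
    return ConstrainedSystem(K=K.tocsr()[fd][:, fd], M=M.tocsr()[fd][:, fd],
                             free_dofs=fd, n_dof_full=nn * 6)


def plate_exact_frequencies(side: float, E: float, nu: float, t: float,
                            rho: float, n: int = 3) -> np.ndarray:
    """Closed-form simply-supported thin-plate frequencies (Hz), ascending."""
    D = E * t**3 / (12 * (1 - nu**2))
    f = [(np.pi / 2) * ((m / side) ** 2 + (k / side) ** 2) * np.sqrt(D / (rho * t))
         for m in range(1, 5) for k in range(1, 5)]
    return np.sort(f)[:n]


@pytest.fixture(scope="session")
def small_pipeline_run(tmp_path_factory):
    """One reduced-size end-to-end pipeline run shared across tests."""
    from bladderkit.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(seed=7, n_per_state=2, mesh_resolution_morph=2.5,
                    mesh_resolution_fem=2.8, n_landmarks=60)
    run_pipeline(cfg, out)
    return cfg, out
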