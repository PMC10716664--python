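"""Sectioning, angled pressure loads, damped harmonic response and power.

Sound pressure is modelled as impinging on the bladder in the horizontal
plane: for a loading angle theta the incoming wave travels from azimuth
theta (measured in the horizontal x-y plane, rostral = 0 deg) towards the
bladder.  Every element whose outward normal faces the incoming wave
receives a force of (pressure x projected area) along the propagation
direction, so that the total force divided by the total loaded projected
area equals the nominal pressure amplitude (1 Pa by default).

The steady-state response is computed by modal superposition with a uniform
damping ratio applied to every mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .core import DOF_PER_NODE, ConstrainedSystem, FemModel, ModalResult

N_SECTIONS = 16
SECTION_DEG = 360.0 / N_SECTIONS


def section_mesh(mesh: trimesh.Trimesh, n_sections: int = N_SECTIONS) -> np.ndarray:
    """Assign each face to one of 16 azimuthal sections.

    Dorso-ventral cutting planes every 22.5 deg about the vertical axis
    split the bladder into 16 wedges in the horizontal plane; a face belongs
    to the wedge containing the azimuth of its centroid (half-open sectors,
    azimuth 0 = rostral).  The mesh is centred on its centroid first.
    """
    centroids = mesh.triangles_center - mesh.centroid
    az = np.degrees(np.arctan2(centroids[:, 1], centroids[:, 0])) % 360.0
    width = 360.0 / n_sections
    return (az // width).astype(int) % n_sections


@dataclass
class HarmonicLoad:
    """Unit-amplitude harmonic pressure load at one horizontal incidence angle."""

    theta_deg: float
    amplitude: float                 # Pa
    loaded_faces: np.ndarray         # face indices
    nodal_forces: np.ndarray         # (n_nodes, 3), N
    projected_area: float            # m^2

    @property
    def total_force(self) -> np.ndarray:
        return self.nodal_forces.sum(axis=0)

    def as_dof_vector(self) -> np.ndarray:
        n = self.nodal_forces.shape[0]
        F = np.zeros(n * DOF_PER_NODE)
        F.reshape(n, DOF_PER_NODE)[:, :3] = self.nodal_forces
        return F


def build_pressure_load(
    model: FemModel, theta_deg: float, amplitude: float = 1.0
) -> HarmonicLoad:
    """Pressure load of ``amplitude`` Pa impinging from horizontal azimuth theta."""
    if not 0 <= theta_deg < 360:
        raise ValueError("theta_deg must lie in [0, 360)")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    th = np.radians(theta_deg)
    # propagation direction: from azimuth theta towards the bladder
    d = np.array([-np.cos(th), -np.sin(th), 0.0])
    normals = model.mesh.face_normals
    facing = normals @ d < 0.0
    loaded = np.flatnonzero(facing)
    if loaded.size == 0:
        raise ValueError(f"no elements face the incoming direction at theta={theta_deg}")
    areas = model.mesh.area_faces[loaded]
    proj = areas * np.abs(normals[loaded] @ d)
    forces = amplitude * proj[:, None] * d[None, :]  # per element, along propagation
    nodal = np.zeros((len(model.mesh.vertices), 3))
    np.add.at(nodal, model.mesh.faces[loaded].ravel(),
              np.repeat(forces / 3.0, 3, axis=0))
    return HarmonicLoad(
        theta_deg=float(theta_deg), amplitude=float(amplitude),
        loaded_faces=loaded, nodal_forces=nodal, projected_area=float(proj.sum()),
    )


def detect_horns(mesh: trimesh.Trimesh, band_fraction: float = 0.08) -> bool:
    """True when the rostral-most band of the surface splits into two
    connected components (the paired horn tips)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    v = mesh.vertices - mesh.centroid
    extent = v[:, 0].max() - v[:, 0].min()
    band = max(band_fraction * extent,
               2.0 * float(np.median(mesh.edges_unique_length)))
    in_band = v[:, 0] > v[:, 0].max() - band
    idx = np.flatnonzero(in_band)
    if idx.size < 2:
        return False
    remap = -np.ones(len(v), dtype=int)
    remap[idx] = np.arange(idx.size)
    e = mesh.edges_unique
    keep = in_band[e[:, 0]] & in_band[e[:, 1]]
    ee = remap[e[keep]]
    adj = coo_matrix((np.ones(len(ee)), (ee[:, 0], ee[:, 1])),
                     shape=(idx.size, idx.size))
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp >= 2


@dataclass
class RepresentativePoints:
    """Node ids for response extraction: dorsal / lateral-midline / ventral
    per section, plus the two rostral horn tips on horned bladders."""

    node_ids: np.ndarray
    labels: list[str]
    coords: np.ndarray


def select_representative_points(
    mesh: trimesh.Trimesh, sections: np.ndarray, horned: bool | None = None
) -> RepresentativePoints:
    """Per section the nodes nearest the dorsal apex, the horizontal midline
    and the ventral apex; horn tips appended when the bladder is horned."""
    v = mesh.vertices - mesh.centroid
    n_sections = int(sections.max()) + 1
    ids: list[int] = []
    labels: list[str] = []
    for s in range(n_sections):
        nodes = np.unique(mesh.faces[sections == s].ravel())
        if nodes.size == 0:
            continue
        z = v[nodes, 2]
        r_xy = np.hypot(v[nodes, 0], v[nodes, 1])
        ids.append(int(nodes[np.argmax(z)]))
        labels.append(f"sec{s:02d}_dorsal")
        # horizontal midline: closest to z = 0, outermost on ties
        mid_score = np.abs(z) - 1e-9 * r_xy
        ids.append(int(nodes[np.argmin(mid_score)]))
        labels.append(f"sec{s:02d}_lateral")
        ids.append(int(nodes[np.argmin(z)]))
        labels.append(f"sec{s:02d}_ventral")

    if horned is None:
        horned = detect_horns(mesh)
    if horned:
        for side, name in ((v[:, 1] > 0, "horn_left"), (v[:, 1] < 0, "horn_right")):
            cand = np.flatnonzero(side)
            tip = cand[np.argmax(v[cand, 0])]
            ids.append(int(tip))
            labels.append(name)
    node_ids = np.array(ids, dtype=int)
    return RepresentativePoints(node_ids=node_ids, labels=labels,
                                coords=np.asarray(mesh.vertices)[node_ids])


@dataclass
class FrequencyResponse:
    """Complex steady-state displacement at representative points.

    ``displacement`` is (n_points, n_freq, 3) in metres per Pa of applied
    pressure; ``frequencies_hz`` is the evaluation grid (the regular sweep
    plus every natural frequency inside the band).
    """

    frequencies_hz: np.ndarray
    displacement: np.ndarray
    points: RepresentativePoints
    theta_deg: float

    @property
    def magnitude(self) -> np.ndarray:
        """|U|(point, freq): Euclidean norm over components."""
        return np.linalg.norm(np.abs(self.displacement), axis=2)


def response_grid(f_max: float = 750.0, step: float = 25.0,
                  natural_hz: np.ndarray | None = None) -> np.ndarray:
    """Regular 0..f_max grid plus natural frequencies <= f_max, sorted, unique."""
    grid = np.arange(0.0, f_max + 0.5 * step, step)
    if natural_hz is not None:
        grid = np.concatenate([grid, natural_hz[natural_hz <= f_max]])
    return np.unique(np.round(grid, 9))


def harmonic_response(
    modal: ModalResult, load: HarmonicLoad, frequencies_hz: np.ndarray,
    zeta: float, points: RepresentativePoints, coverage_margin: float = 1.2,
) -> FrequencyResponse:
    """Damped modal-superposition FRF at the representative points.

    For each mode n with angular frequency w_n and mass-normalised shape
    l_n, the modal coordinate under harmonic forcing F e^{iwt} is

        q_n(w) = (l_n . F) / (w_n^2 - w^2 + 2 i zeta w_n w)

    and U(w) = sum_n l_n q_n(w).  The modal basis must extend beyond the
    highest requested frequency by ``coverage_margin``.
    """
    frequencies_hz = np.asarray(frequencies_hz, dtype=float)
    f_req = frequencies_hz.max()
    if modal.frequencies_hz[-1] < coverage_margin * f_req:
        raise ValueError(
            f"modal basis reaches {modal.frequencies_hz[-1]:.1f} Hz but "
            f"{coverage_margin:.2f} x {f_req:.1f} Hz coverage is required"
        )
    F = load.as_dof_vector()
    gamma = modal.shapes.T @ F                       # modal force, (n_modes,)
    wn = modal.omegas
    w = 2.0 * np.pi * frequencies_hz
    denom = (wn[:, None] ** 2 - w[None, :] ** 2
             + 2j * zeta * wn[:, None] * w[None, :])
    q = gamma[:, None] / denom                       # (n_modes, n_freq)
    n_nodes = modal.shapes.shape[0] // DOF_PER_NODE
    pdofs = (points.node_ids[:, None] * DOF_PER_NODE + np.arange(3)).reshape(-1)
    shapes_pts = modal.shapes[pdofs, :]              # (n_pts*3, n_modes)
    U = (shapes_pts @ q).reshape(len(points.node_ids), 3, -1).transpose(0, 2, 1)
    return FrequencyResponse(frequencies_hz=frequencies_hz, displacement=U,
                             points=points, theta_deg=load.theta_deg)


def compute_power(response: FrequencyResponse) -> np.ndarray:
    """Time-averaged vibrational power proxy P = 1/2 w^2 |U|^2 per point/freq.

    This is the kinetic-energy-rate proxy (velocity amplitude squared over
    two); it peaks at the velocity resonance w = w_n of each mode.  Units
    are relative (m^2 s^-2 per Pa^2).
    """
    w = 2.0 * np.pi * response.frequencies_hz
    return 0.5 * (w[None, :] ** 2) * response.magnitude**2


def total_power(response: FrequencyResponse, f_max: float = 750.0,
                step: float = 25.0) -> float:
    """Power summed over points and integrated over the regular grid only.

    Natural-frequency insertions are excluded so that responses of different
    models are comparable on an identical grid.
    """
    grid = np.arange(0.0, f_max + 0.5 * step, step)
    mask = np.isin(np.round(response.frequencies_hz, 9), np.round(grid, 9))
    P = compute_power(response)[:, mask].sum(axis=0)
    return float(np.trapezoid(P, response.frequencies_hz[mask]))


def compare_states(
    responses_a: dict[float, FrequencyResponse],
    responses_b: dict[float, FrequencyResponse],
    f_max: float = 750.0, step: float = 25.0,
):
    """Per-angle aggregate power for two models and their difference (A - B)."""
    import pandas as pd

    angles = sorted(responses_a)
    if sorted(responses_b) != angles:
        raise ValueError("angle sets differ between the two models")
    rows = []
    for th in angles:
        ra, rb = responses_a[th], responses_b[th]
        ga = ra.frequencies_hz[ra.frequencies_hz <= f_max]
        gb = rb.frequencies_hz[rb.frequencies_hz <= f_max]
        reg = np.arange(0.0, f_max + 0.5 * step, step)
        if not (np.isin(reg, np.round(ga, 9)).all() and np.isin(reg, np.round(gb, 9)).all()):
            raise ValueError("frequency grids do not share the regular sweep")
        pa = total_power(ra, f_max, step)
        pb = total_power(rb, f_max, step)
        rows.append({"theta_deg": th, "power_a": pa, "power_b": pb,
                     "difference": pa - pb})
    return pd.DataFrame(rows)
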