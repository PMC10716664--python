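"""Size-normalised bladder morphometrics and pseudo-landmark shape analysis.

Measurements follow the field conventions for the midshipman swim bladder:
horn length is the difference between bladder length and width (floored at
zero — a bladder as wide as it is long has no horns), the bladder-otolith
distance is the minimal surface distance to each sagittal otolith centroid
averaged over the two sides, and every linear measure is normalised by the
fish's standard length (measure in cm / SL in cm).

Shape analysis uses dense surface pseudo-landmarks: farthest-point sampling
seeded at the rostral-most vertex, mirrored across the sagittal plane so
left and right are represented symmetrically; landmarks are transferred to
other specimens by similarity registration (scale + rotation + translation)
followed by nearest-surface projection, then compared by generalized
Procrustes alignment and PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from . import _geometry

MM_PER_CM = 10.0


# --------------------------------------------------------------------------
# somatic indices and linear measures
# --------------------------------------------------------------------------

def gonadosomatic_index(body_mass: float, gonad_mass: float) -> float:
    """GSI (%) = 100 * gonad / (body - gonad); masses in g."""
    if not 0 <= gonad_mass < body_mass:
        raise ValueError("need 0 <= gonad_mass < body_mass")
    return 100.0 * gonad_mass / (body_mass - gonad_mass)


def sonic_muscle_somatic_index(body_mass: float, muscle_mass: float) -> float:
    """SMSI (%) on the same somatic-index convention as the GSI."""
    if not 0 <= muscle_mass < body_mass:
        raise ValueError("need 0 <= muscle_mass < body_mass")
    return 100.0 * muscle_mass / (body_mass - muscle_mass)


def principal_frame(mesh: trimesh.Trimesh) -> np.ndarray:
    """Rows = rostro-caudal, horizontal-transverse, dorso-ventral axes.

    Axes are the eigenvectors of the vertex covariance (descending
    variance), sign-fixed towards +x/+y/+z so results do not depend on file
    orientation conventions.
    """
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    cov = v.T @ v / len(v)
    w, E = np.linalg.eigh(cov)
    E = E[:, np.argsort(w)[::-1]]
    for k in range(3):
        j = int(np.argmax(np.abs(E[:, k])))
        if E[j, k] < 0:
            E[:, k] = -E[:, k]
    if np.linalg.det(E) < 0:
        E[:, 2] = -E[:, 2]
    return E.T


def measure_bladder(mesh: trimesh.Trimesh) -> tuple[float, float, float]:
    """(length, width, horn_length) in mm.

    Length = extent along the principal (rostro-caudal) axis, width = extent
    along the orthogonal horizontal axis, horn length = length - width,
    floored at 0.
    """
    frame = principal_frame(mesh)
    proj = (mesh.vertices - mesh.vertices.mean(axis=0)) @ frame.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    if extents.min() < 1e-9:
        raise ValueError("degenerate (flat) mesh: principal extents not resolvable")
    length, width = float(extents[0]), float(extents[1])
    return length, width, max(length - width, 0.0)


def bladder_otolith_distance(mesh: trimesh.Trimesh,
                             otolith_centroids: np.ndarray) -> float:
    """Mean over the two sides of the minimal surface distance (mm)."""
    pts = np.asarray(otolith_centroids, dtype=float).reshape(2, 3)
    if _geometry.contains(mesh, pts).any():
        raise ValueError("otolith centroid lies inside the bladder (non-physical)")
    _, dist, _ = _geometry.closest_point(mesh, pts)
    return float(np.mean(dist))


def normalize_by_standard_length(measure_mm: float, standard_length_cm: float) -> float:
    """Dimensionless ratio: (measure converted mm -> cm) / standard length."""
    if standard_length_cm <= 0:
        raise ValueError("standard length must be positive")
    if measure_mm < 0:
        raise ValueError("measure must be non-negative")
    return (measure_mm / MM_PER_CM) / standard_length_cm


@dataclass
class MorphometricRecord:
    """Normalised measures + somatic indices for one specimen."""

    specimen_id: str
    state: str
    width_norm: float
    horn_length_norm: float
    otolith_distance_norm: float
    smsi: float
    gsi: float
    length_mm: float = np.nan
    width_mm: float = np.nan
    horn_length_mm: float = np.nan
    otolith_distance_mm: float = np.nan


def morphometrics_table(records) -> pd.DataFrame:
    """Measure a cohort of SpecimenRecord objects into a tidy table."""
    rows = []
    for r in records:
        length, width, horn = measure_bladder(r.mesh)
        dist = bladder_otolith_distance(r.mesh, r.otolith_centroids)
        rows.append(MorphometricRecord(
            specimen_id=r.specimen_id, state=r.reproductive_state,
            width_norm=normalize_by_standard_length(width, r.standard_length),
            horn_length_norm=normalize_by_standard_length(horn, r.standard_length),
            otolith_distance_norm=normalize_by_standard_length(dist, r.standard_length),
            smsi=sonic_muscle_somatic_index(r.body_mass, r.sonic_muscle_mass),
            gsi=gonadosomatic_index(r.body_mass, r.gonad_mass),
            length_mm=length, width_mm=width, horn_length_mm=horn,
            otolith_distance_mm=dist,
        ).__dict__)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pseudo-landmarks
# --------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Ordered surface points (mm) sharing a correspondence across specimens."""

    points: np.ndarray                      # (n, 3)
    correspondence_id: str = "template"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.points, columns=["x_mm", "y_mm", "z_mm"])
        df.insert(0, "point", np.arange(len(df)))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, correspondence_id="template") -> "LandmarkSet":
        df = pd.read_csv(path)
        return cls(points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                   correspondence_id=correspondence_id)


def _farthest_point_order(candidates: np.ndarray, start: int, n: int) -> np.ndarray:
    """Indices of n farthest-point samples from a candidate cloud."""
    chosen = [start]
    d = np.linalg.norm(candidates - candidates[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(candidates - candidates[nxt], axis=1))
    return np.array(chosen)


def generate_pseudo_landmarks(template: trimesh.Trimesh, n_points: int,
                              correspondence_id: str = "template") -> LandmarkSet:
    """Deterministic symmetric surface sampling.

    Farthest-point sampling over the vertices of the sagittal half
    (y >= 0), seeded at the rostral-most vertex; each sample is paired with
    its mirror image projected back onto the surface, so the output is
    symmetric and its ordering is nested (a run with 2n points starts with
    the same n pairs).  ``n_points`` must be even and >= 4.
    """
    if n_points < 4 or n_points % 2:
        raise ValueError("n_points must be even and >= 4 (mirror-paired sampling)")
    v = np.asarray(template.vertices)
    # strictly off-plane candidates: an on-plane point would mirror onto
    # itself and duplicate a landmark
    tol = 1e-9 * float(np.linalg.norm(v.max(0) - v.min(0)))
    half_idx = np.flatnonzero(v[:, 1] > tol)
    n_half = n_points // 2
    if n_half > half_idx.size:
        raise ValueError(
            f"n_points={n_points} exceeds available vertices after "
            f"symmetrization ({2 * half_idx.size})"
        )
    half = v[half_idx]
    start = int(np.argmax(half[:, 0]))      # rostral-most vertex of the half
    order = _farthest_point_order(half, start, n_half)
    picked = half[order]
    mirrored = picked * np.array([1.0, -1.0, 1.0])
    proj, _, _ = _geometry.closest_point(template, mirrored)
    pts = np.empty((n_points, 3))
    pts[0::2] = picked
    pts[1::2] = proj
    return LandmarkSet(points=pts, correspondence_id=correspondence_id)


def transfer_landmarks(template: LandmarkSet, template_mesh: trimesh.Trimesh,
                       target_mesh: trimesh.Trimesh) -> LandmarkSet:
    """Carry the template landmarks onto a target mesh, order-preserving.

    Similarity registration (uniform scale + rotation + translation, sampled
    ICP with a principal-axis initial guess) maps the template onto the
    target; each mapped landmark is then projected to the nearest point of
    the target surface.  This is a deliberately rigid, deterministic
    correspondence scheme — adequate for smoothly varying synthetic shapes,
    not a substitute for deformable registration on strongly dissimilar
    anatomies.
    """
    matrix, _cost = _geometry.similarity_register(template_mesh, target_mesh)
    pts_h = np.c_[template.points, np.ones(len(template.points))]
    mapped = (matrix @ pts_h.T).T[:, :3]
    proj, _, _ = _geometry.closest_point(target_mesh, mapped)
    return LandmarkSet(points=proj, correspondence_id=template.correspondence_id)


# --------------------------------------------------------------------------
# generalized Procrustes analysis + PCA
# --------------------------------------------------------------------------

@dataclass
class MorphospaceResult:
    """Shape-space PCA: specimen scores, variance fractions, loadings."""

    scores: np.ndarray                      # (n_specimens, n_components)
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray                    # (n_components, n_points, 3)
    mean_shape: np.ndarray                  # (n_points, 3), aligned

    def scores_table(self, labels=None) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i+1}" for i in range(self.scores.shape[1])])
        if labels is not None:
            df.insert(0, "label", list(labels))
        return df


def _kabsch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix aligning a onto b (both centred)."""
    U, _, Vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, 1.0, d])
    return U @ S @ Vt


def generalized_procrustes(configs: np.ndarray, tol: float = 1e-10,
                           max_iter: int = 100) -> np.ndarray:
    """Align (n_spec, n_pts, 3) configurations: translation, scale, rotation."""
    X = np.asarray(configs, dtype=float).copy()
    X -= X.mean(axis=1, keepdims=True)
    size = np.linalg.norm(X, axis=(1, 2), keepdims=True)
    size[size == 0] = 1.0
    X /= size
    mean = X[0]
    for _ in range(max_iter):
        for i in range(len(X)):
            X[i] = X[i] @ _kabsch(X[i], mean)
        new_mean = X.mean(axis=0)
        nrm = np.linalg.norm(new_mean)
        if nrm > 0:
            new_mean /= nrm
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    return X


def procrustes_pca(landmark_sets: list[LandmarkSet]) -> MorphospaceResult:
    """GPA then PCA of aligned coordinates across specimens."""
    if len(landmark_sets) < 3:
        raise ValueError("need >= 3 specimens for a morphospace")
    n_pts = {len(ls) for ls in landmark_sets}
    if len(n_pts) != 1:
        raise ValueError(f"landmark counts differ across specimens: {sorted(n_pts)}")
    configs = np.stack([ls.points for ls in landmark_sets])
    aligned = generalized_procrustes(configs)
    flat = aligned.reshape(len(aligned), -1)
    flat = flat - flat.mean(axis=0)
    U, S, Vt = np.linalg.svd(flat, full_matrices=False)
    # drop null components (rank deficiency from alignment / few specimens)
    # configurations are unit-size after GPA, so an absolute floor separates
    # real shape variance from alignment round-off
    keep = S > max(S[0] * 1e-10, 1e-9)
    if not keep.any():                      # identical shapes: report one null PC
        keep[0] = True
        S = np.zeros_like(S)
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    var = S**2
    total = var.sum()
    frac = var / total if total > 0 else var
    npts = aligned.shape[1]
    return MorphospaceResult(
        scores=U * S,
        explained_variance_fraction=frac,
        loadings=Vt.reshape(-1, npts, 3),
        mean_shape=aligned.mean(axis=0),
    )
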