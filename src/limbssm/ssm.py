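"""Point-distribution shape models of corresponded bone surfaces.

A population of meshes sharing one vertex topology ("corresponded shapes") is
rigidly co-aligned (generalised Procrustes, rigid only — no scaling), and a
PCA of the stacked vertex coordinate vectors yields the statistical shape
model: mean shape, orthonormal modes of variation and per-mode variances.
Mode scores are kept in standard-deviation units, so a score vector ``b`` has
Mahalanobis distance ``Σ b_k²`` and the usual ±3 SD plausibility bounds are
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh
from scipy.interpolate import RBFInterpolator
from scipy.stats import truncnorm

from .errors import InputError
from .geometry import LandmarkSet, new_mesh, rigid_align
from .proximity import SurfaceQuery

__all__ = [
    "CorrespondedShapeSet",
    "StatisticalShapeModel",
    "ShapeParams",
    "correspond",
    "align_shapes",
    "build_ssm",
    "compactness",
    "generality",
    "specificity",
    "save_ssm",
    "load_ssm",
]


@dataclass
class CorrespondedShapeSet:
    """Shapes with identical vertex count and semantics.

    ``shapes`` is (n_shapes, k, 3) in mm; ``faces`` the shared topology;
    ``part_labels`` one label per vertex (e.g. femur / tibia / fibula);
    ``landmark_indices`` maps landmark names to vertex indices.
    """

    shapes: np.ndarray
    faces: np.ndarray
    part_labels: np.ndarray
    landmark_indices: dict[str, int]
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.shapes = np.asarray(self.shapes, dtype=float)
        if self.shapes.ndim != 3 or self.shapes.shape[2] != 3:
            raise InputError("shapes must be (n, k, 3)")
        k = self.shapes.shape[1]
        if len(self.part_labels) != k:
            raise InputError("part_labels must have one entry per vertex")
        if any(i >= k or i < 0 for i in self.landmark_indices.values()):
            raise InputError("landmark vertex index out of range")
        if not self.ids:
            self.ids = list(range(len(self.shapes)))

    @property
    def n_shapes(self) -> int:
        return len(self.shapes)

    @property
    def n_vertices(self) -> int:
        return self.shapes.shape[1]

    def mesh(self, i: int) -> trimesh.Trimesh:
        return new_mesh(self.shapes[i], self.faces)

    def without(self, shape_id) -> "CorrespondedShapeSet":
        keep = [j for j, sid in enumerate(self.ids) if sid != shape_id]
        if len(keep) == len(self.ids):
            raise InputError(f"shape id {shape_id!r} not in set")
        return CorrespondedShapeSet(self.shapes[keep], self.faces, self.part_labels,
                                    self.landmark_indices, [self.ids[j] for j in keep])


@dataclass
class ShapeParams:
    """Mode scores in standard-deviation units."""

    b: np.ndarray

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float).ravel()
        if not np.all(np.isfinite(self.b)):
            raise InputError("shape parameters must be finite")


@dataclass
class StatisticalShapeModel:
    mean_shape: np.ndarray            # (3k,)
    modes: np.ndarray                 # (m, 3k), orthonormal rows
    eigenvalues: np.ndarray           # (m,), mm², descending
    faces: np.ndarray
    part_labels: np.ndarray
    landmark_indices: dict[str, int]
    n_training: int
    total_variance: float = None      # trace of the training covariance

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=float).ravel()
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise InputError("eigenvalues must be sorted descending")
        if self.total_variance is None:
            self.total_variance = float(self.eigenvalues.sum())

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_vertices(self) -> int:
        return self.mean_shape.size // 3

    @property
    def mode_sd(self) -> np.ndarray:
        return np.sqrt(self.eigenvalues)

    # ------------------------------------------------------------------
    def vertices(self, params: ShapeParams | np.ndarray | None = None) -> np.ndarray:
        """Vertex matrix (k, 3) of the model instance for SD-unit scores."""
        x = self.mean_shape.copy()
        if params is not None:
            b = params.b if isinstance(params, ShapeParams) else np.asarray(params, float).ravel()
            if len(b) > self.n_modes:
                raise InputError(f"got {len(b)} scores for a {self.n_modes}-mode model")
            m = len(b)
            x = x + (b * self.mode_sd[:m]) @ self.modes[:m]
        return x.reshape(-1, 3)

    def instance(self, params: ShapeParams | np.ndarray | None = None) -> trimesh.Trimesh:
        return new_mesh(self.vertices(params), self.faces)

    def project(self, vertices: np.ndarray) -> ShapeParams:
        """SD-unit scores of an (aligned) corresponded vertex matrix."""
        x = np.asarray(vertices, dtype=float).ravel()
        raw = self.modes @ (x - self.mean_shape)
        sd = self.mode_sd
        b = np.where(sd > 0, raw / np.where(sd > 0, sd, 1.0), 0.0)
        return ShapeParams(b)

    @staticmethod
    def mahalanobis(params: ShapeParams | np.ndarray) -> float:
        b = params.b if isinstance(params, ShapeParams) else np.asarray(params, float)
        return float(np.sum(b ** 2))


# ---------------------------------------------------------------------------
# correspondence


def _farthest_point_indices(points: np.ndarray, n: int, seeds: Sequence[int]) -> np.ndarray:
    """Deterministic farthest-point subsample, initialised from ``seeds``."""
    P = np.asarray(points, dtype=float)
    chosen = list(dict.fromkeys(int(s) for s in seeds)) or [0]
    d = np.min(np.linalg.norm(P[:, None, :] - P[None, chosen, :], axis=2), axis=1) \
        if len(chosen) > 1 else np.linalg.norm(P - P[chosen[0]], axis=1)
    out = []
    while len(out) < n:
        idx = int(np.argmax(d))
        if d[idx] <= 0:
            break
        out.append(idx)
        d = np.minimum(d, np.linalg.norm(P - P[idx], axis=1))
    return np.array(out, dtype=int)


def correspond(reference: trimesh.Trimesh,
               target: trimesh.Trimesh,
               ref_landmarks: LandmarkSet,
               target_landmarks: LandmarkSet,
               n_pseudo: int = 50) -> np.ndarray:
    """Map the reference topology onto a target surface.

    Two steps: (1) a thin-plate-spline warp driven by the shared named
    landmarks, densified with pseudo-landmark pairs found by farthest-point
    sampling on the reference and closest-point search on the target; (2)
    closest-point projection of every warped reference vertex onto the target
    surface.  Returns one target-surface point per reference vertex.
    """
    shared = [n for n in ref_landmarks.names if n in target_landmarks]
    if len(shared) < 4:
        raise InputError(f"need >= 4 shared landmarks, got {len(shared)}")
    src_lm = ref_landmarks.positions(shared)
    dst_lm = target_landmarks.positions(shared)

    ref_v = np.asarray(reference.vertices, dtype=float)
    query = SurfaceQuery(target)

    warp1 = RBFInterpolator(src_lm, dst_lm, kernel="thin_plate_spline")
    warped = warp1(ref_v)

    if n_pseudo > 0:
        lm_seed_idx = np.argmin(np.linalg.norm(
            ref_v[:, None, :] - src_lm[None, :, :], axis=2), axis=0)
        pseudo_idx = _farthest_point_indices(ref_v, n_pseudo, lm_seed_idx)
        pseudo_dst, _ = query.closest(warped[pseudo_idx])
        centers = np.vstack([src_lm, ref_v[pseudo_idx]])
        values = np.vstack([dst_lm, pseudo_dst])
        # drop near-duplicate centres, which make the TPS system singular
        keep = _unique_rows(centers, tol=1e-6)
        warp2 = RBFInterpolator(centers[keep], values[keep], kernel="thin_plate_spline")
        warped = warp2(ref_v)

    projected, _ = query.closest(warped)
    return projected


def _unique_rows(points: np.ndarray, tol: float) -> np.ndarray:
    keep: list[int] = []
    for i, p in enumerate(points):
        if all(np.linalg.norm(p - points[j]) > tol for j in keep):
            keep.append(i)
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# alignment and model building


def align_shapes(cset: CorrespondedShapeSet,
                 tol: float = 1e-6,
                 max_iterations: int = 100) -> CorrespondedShapeSet:
    """Rigid-only generalised Procrustes alignment to the evolving mean.

    No scaling is applied.  Converged when the mean shape changes by less
    than ``tol`` mm RMS.
    """
    shapes = cset.shapes.copy()
    mean = shapes.mean(axis=0)
    for _ in range(max_iterations):
        for i in range(len(shapes)):
            shapes[i] = rigid_align(shapes[i], mean).apply(shapes[i])
        new_mean = shapes.mean(axis=0)
        change = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if change < tol:
            break
    return CorrespondedShapeSet(shapes, cset.faces, cset.part_labels,
                                cset.landmark_indices, list(cset.ids))


def build_ssm(cset: CorrespondedShapeSet,
              leave_out=None,
              align: bool = True) -> StatisticalShapeModel:
    """PCA point-distribution model from (optionally re-aligned) shapes.

    ``leave_out`` excludes one shape id entirely (leave-one-out protocol).
    Modes with eigenvalue < 1e-12 × the largest are dropped.
    """
    if leave_out is not None:
        cset = cset.without(leave_out)
    if cset.n_shapes < 3:
        raise InputError("need at least 3 shapes to build a model")
    if align:
        cset = align_shapes(cset)
    X = cset.shapes.reshape(cset.n_shapes, -1)
    mean = X.mean(axis=0)
    X0 = X - mean
    U, s, Vt = np.linalg.svd(X0, full_matrices=False)
    eig = s ** 2 / (cset.n_shapes - 1)
    total = float(eig.sum())
    m = min(len(eig), cset.n_shapes - 1)
    eig, Vt = eig[:m], Vt[:m]
    if eig[0] > 0:
        keep = eig >= 1e-12 * eig[0]
        eig, Vt = eig[keep], Vt[keep]
    return StatisticalShapeModel(mean, Vt, eig, cset.faces, cset.part_labels,
                                 dict(cset.landmark_indices), cset.n_shapes,
                                 total_variance=total)


# ---------------------------------------------------------------------------
# model quality metrics


def compactness(ssm: StatisticalShapeModel, n_modes: int) -> float:
    """Cumulative variance fraction captured by the first ``n_modes`` modes."""
    if not 1 <= n_modes <= ssm.n_modes:
        raise InputError("n_modes out of range")
    if ssm.total_variance <= 0:
        return 1.0
    return float(ssm.eigenvalues[:n_modes].sum() / ssm.total_variance)


def _rms_point_error(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def generality(cset: CorrespondedShapeSet, n_modes: int) -> float:
    """Mean leave-one-out reconstruction RMS (mm) with ``n_modes`` modes."""
    errs = []
    for sid in cset.ids:
        model = build_ssm(cset, leave_out=sid, align=True)
        i = cset.ids.index(sid)
        shape = cset.shapes[i]
        T = rigid_align(shape, model.vertices())
        aligned = T.apply(shape)
        b = model.project(aligned).b[:n_modes]
        recon = model.vertices(b)
        errs.append(_rms_point_error(aligned, recon))
    return float(np.mean(errs))


def specificity(ssm: StatisticalShapeModel,
                cset: CorrespondedShapeSet,
                n_modes: int,
                n_samples: int = 1000,
                seed: int = 0) -> float:
    """Mean RMS distance (mm) from random plausible instances to the nearest
    training shape.  Scores are standard normal truncated to ±3 SD."""
    if not 1 <= n_modes <= ssm.n_modes:
        raise InputError("n_modes out of range")
    rng = np.random.default_rng(seed)
    B = truncnorm.rvs(-3, 3, size=(n_samples, n_modes), random_state=rng)
    samples = ssm.mean_shape + (B * ssm.mode_sd[:n_modes]) @ ssm.modes[:n_modes]
    train = cset.shapes.reshape(cset.n_shapes, -1)
    k = cset.n_vertices
    out = np.empty(n_samples)
    chunk = max(1, int(2e7 // train.size))
    for start in range(0, n_samples, chunk):
        S = samples[start:start + chunk]
        d2 = ((S[:, None, :] - train[None, :, :]) ** 2).sum(axis=2)
        out[start:start + chunk] = np.sqrt(d2.min(axis=1) / k)
    return float(out.mean())


# ---------------------------------------------------------------------------
# serialisation (npz archive with a mandatory version field)

_FORMAT_VERSION = 1


def save_ssm(ssm: StatisticalShapeModel, path) -> None:
    names = list(ssm.landmark_indices)
    np.savez(path,
             version=np.array([_FORMAT_VERSION]),
             mean_shape=ssm.mean_shape,
             modes=ssm.modes,
             eigenvalues=ssm.eigenvalues,
             faces=ssm.faces,
             part_labels=np.asarray(ssm.part_labels, dtype="U16"),
             landmark_names=np.asarray(names, dtype="U16"),
             landmark_vertices=np.array([ssm.landmark_indices[n] for n in names]),
             n_training=np.array([ssm.n_training]),
             total_variance=np.array([ssm.total_variance]))


def load_ssm(path) -> StatisticalShapeModel:
    with np.load(path) as z:
        version = int(z["version"][0])
        if version != _FORMAT_VERSION:
            raise InputError(f"unsupported model file version {version}")
        lm = {str(n): int(i) for n, i in zip(z["landmark_names"], z["landmark_vertices"])}
        return StatisticalShapeModel(z["mean_shape"], z["modes"], z["eigenvalues"],
                                     z["faces"], z["part_labels"], lm,
                                     int(z["n_training"][0]),
                                     total_variance=float(z["total_variance"][0]))
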