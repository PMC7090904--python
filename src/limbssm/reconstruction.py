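"""Fit shape models to sparse landmarks; linear-scaling baselines; hip-centre
regression and femoral-head auxiliary points.

Shape-model fitting optimises a rigid pose (rotation vector + translation)
and the SD-unit mode scores *simultaneously* with bound-constrained L-BFGS-B.
Two objectives are available:

* bone landmarks:  D = Σᵢ dᵢ²  (plain squared distances), and
* skin landmarks:  D = Σᵢ [ ½ log σᵢ² + (dᵢ − d̂ᵢ)² / (2σᵢ²) ]  — the Gaussian
  negative log-likelihood of the measured offset dᵢ around the predicted
  soft-tissue offset d̂ᵢ with its regression dispersion σᵢ,

each plus a Mahalanobis penalty w·Σ b² keeping the shape plausible, with the
scores box-constrained to ±3 SD by default.  dᵢ is the Euclidean distance
between the posed model surface point and the measured landmark.  Anterior
tibial crest landmarks (ATP/ATM/ATD) have no fixed correspondence and are
re-resolved by closest-point search in an outer loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import trimesh
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InputError, MissingLandmarkError
from .geometry import Frame, LandmarkSet, RigidTransform, build_segment_frame, \
    fit_sphere, new_mesh, rigid_align
from .proximity import SurfaceQuery
from .ssm import ShapeParams, StatisticalShapeModel

__all__ = [
    "ReconstructionConfig",
    "ReconstructionResult",
    "ScalingResult",
    "reconstruct_bone_landmarks",
    "reconstruct_skin_landmarks",
    "no_correction_offsets",
    "offsets_from_models",
    "uniform_scale",
    "pelvis_width_scale",
    "estimate_fhc",
    "femoral_head_radius",
    "femoral_head_points",
    "MEAN_FEMORAL_HEAD_RADIUS_MM",
]

MEAN_FEMORAL_HEAD_RADIUS_MM = 21.1

_SEGMENT_LENGTH_LANDMARKS = {"femur": ("FHC", ("LE", "ME")),
                             "tibia": ("TT", ("LM", "MM"))}


@dataclass
class ReconstructionConfig:
    """Options for landmark-driven shape-model fitting."""

    n_modes: int | None = None         # None = all model modes
    param_bound: float = 3.0           # |b_k| bound, SD units
    mahalanobis_weight: float = 1.0
    gtol: float = 1e-10
    ftol: float = 1e-14
    max_evaluations: int = 20000
    seed: int = 0
    n_starts: int = 1                  # extra seeded pose-jitter restarts
    max_outer_iterations: int = 10     # sliding-landmark refresh loop
    translation_bound: float = 1000.0  # mm around the initial pose

    def __post_init__(self):
        if self.n_modes is not None and self.n_modes < 1:
            raise InputError("n_modes must be >= 1")
        if self.param_bound <= 0:
            raise InputError("param_bound must be > 0")


@dataclass
class ReconstructionResult:
    pose: RigidTransform
    params: ShapeParams
    mesh: trimesh.Trimesh
    objective_value: float
    residuals: dict[str, float]
    converged: bool
    method: str = ""

    def __post_init__(self):
        if any(r < 0 for r in self.residuals.values()):
            raise InputError("residuals must be >= 0")


@dataclass
class ScalingResult:
    mesh: trimesh.Trimesh
    scale: float                  # longitudinal scale factor
    transverse_scale: float       # == scale for uniform scaling
    transform: RigidTransform     # rigid part applied after scaling


# ---------------------------------------------------------------------------
# landmark-driven SSM fitting


def _resolve_landmarks(ssm: StatisticalShapeModel, targets: LandmarkSet):
    fixed, sliding = [], []
    for lm in targets:
        if lm.kind == "sliding":
            sliding.append(lm)
        else:
            if lm.name not in ssm.landmark_indices:
                raise MissingLandmarkError(lm.name, "not defined on the shape model")
            fixed.append(lm)
    return fixed, sliding


class _LandmarkBasis:
    """Mean and mode sub-matrices restricted to landmark points.

    Supports fixed vertices and barycentric (face, weights) sliding points;
    evaluating the landmark positions for a score vector b is then a small
    dense product independent of the mesh size.
    """

    def __init__(self, ssm: StatisticalShapeModel, vertex_ids, bary_faces, bary_w, m):
        k = ssm.n_vertices
        mean = ssm.mean_shape.reshape(k, 3)
        modes = ssm.modes[:m].reshape(m, k, 3)
        parts_mean = [mean[vertex_ids]] if len(vertex_ids) else []
        parts_modes = [modes[:, vertex_ids, :]] if len(vertex_ids) else []
        if len(bary_faces):
            tri = ssm.faces[bary_faces]                       # (s, 3)
            w = bary_w[:, :, None]                            # (s, 3, 1)
            parts_mean.append((mean[tri] * w).sum(axis=1))
            parts_modes.append((modes[:, tri, :] * w[None]).sum(axis=2))
        self.mean = np.concatenate(parts_mean, axis=0)
        self.modes = np.concatenate(parts_modes, axis=1) if parts_modes else None
        self.scaled_modes = ssm.mode_sd[:m, None, None] * self.modes

    def points(self, b: np.ndarray) -> np.ndarray:
        return self.mean + np.tensordot(b, self.scaled_modes, axes=(0, 0))


def _fit_landmarks(ssm: StatisticalShapeModel,
                   targets: LandmarkSet,
                   loss: Callable[[np.ndarray], float],
                   config: ReconstructionConfig,
                   method: str) -> ReconstructionResult:
    fixed, sliding = _resolve_landmarks(ssm, targets)
    if len(fixed) + len(sliding) < 6:
        raise InputError("need at least 6 landmarks for shape-model fitting")
    m = ssm.n_modes if config.n_modes is None else min(config.n_modes, ssm.n_modes)
    w = config.mahalanobis_weight
    names = [lm.name for lm in fixed] + [lm.name for lm in sliding]
    S = np.array([lm.position for lm in fixed] + [lm.position for lm in sliding])
    fixed_ids = np.array([ssm.landmark_indices[lm.name] for lm in fixed], dtype=int)

    # initial pose from the mean-shape landmarks; sliding landmarks start at
    # their mapped vertex when the model defines one, else at the closest
    # mean-surface point after a fixed-landmark-only alignment
    mean_v = ssm.vertices()
    init_pts = [mean_v[i] for i in fixed_ids]
    slide_init = []
    for lm in sliding:
        if lm.name in ssm.landmark_indices:
            slide_init.append(mean_v[ssm.landmark_indices[lm.name]])
    if len(init_pts) + len(slide_init) >= 3:
        try:
            T0 = rigid_align(np.array(init_pts + slide_init),
                             S[:len(init_pts) + len(slide_init)])
        except DegenerateGeometryError:
            T0 = RigidTransform.identity()
    else:
        T0 = RigidTransform.identity()

    # sliding correspondences as (face, barycentric) on the model surface
    query_mean = SurfaceQuery(ssm.instance()) if sliding else None
    bary_faces = np.zeros(0, dtype=int)
    bary_w = np.zeros((0, 3))
    if sliding:
        local_targets = T0.inverse().apply(S[len(fixed):])
        _, _, bary_faces, bary_w = query_mean.closest_with_faces(local_targets)

    rng = np.random.default_rng(config.seed)
    best = None
    b_cur = np.zeros(m)
    T_cur = T0
    converged = True
    for outer in range(max(1, config.max_outer_iterations)):
        basis = _LandmarkBasis(ssm, fixed_ids, bary_faces, bary_w, m)
        centroid = basis.mean.mean(axis=0)

        def objective(theta, basis=basis, centroid=centroid):
            rot = Rotation.from_rotvec(theta[:3]).as_matrix()
            b = theta[6:]
            p = basis.points(b)
            x = (p - centroid) @ (rot @ T_cur.rotation).T + theta[3:6]
            d = np.linalg.norm(x - S, axis=1)
            return loss(d) + w * float(b @ b)

        t0 = T_cur.apply(centroid)
        starts = [np.concatenate([np.zeros(3), t0, b_cur])]
        for _ in range(max(0, config.n_starts - 1)):
            jitter = np.concatenate([rng.normal(0, 0.1, 3), rng.normal(0, 5.0, 3),
                                     rng.normal(0, 0.5, m)])
            starts.append(starts[0] + jitter)
        bounds = ([(-np.pi, np.pi)] * 3 +
                  [(v - config.translation_bound, v + config.translation_bound) for v in t0] +
                  [(-config.param_bound, config.param_bound)] * m)
        res = None
        for x0 in starts:
            r = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                         options={"maxfun": config.max_evaluations,
                                  "ftol": config.ftol, "gtol": config.gtol})
            if res is None or r.fun < res.fun:
                res = r
        converged = bool(res.success)
        rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
        R_tot = rot @ T_cur.rotation
        # absorb the centroid shift into the translation
        T_new = RigidTransform(R_tot, res.x[3:6] - R_tot @ centroid)
        b_cur = res.x[6:].copy()
        best = (T_new, b_cur, float(res.fun))
        T_cur = T_new
        if not sliding:
            break
        # refresh sliding correspondences on the current posed instance
        inst = ssm.vertices(b_cur)
        query = SurfaceQuery(new_mesh(T_cur.apply(inst), ssm.faces))
        _, _, new_faces, new_w = query.closest_with_faces(S[len(fixed):])
        if (len(bary_faces) and np.array_equal(new_faces, bary_faces)
                and np.max(np.abs(new_w - bary_w)) < 1e-6):
            break
        bary_faces, bary_w = new_faces, new_w

    T_fin, b_fin, fval = best
    basis = _LandmarkBasis(ssm, fixed_ids, bary_faces, bary_w, m)
    d = np.linalg.norm(T_fin.apply(basis.points(b_fin)) - S, axis=1)
    mesh = new_mesh(T_fin.apply(ssm.vertices(b_fin)), ssm.faces)
    return ReconstructionResult(T_fin, ShapeParams(b_fin), mesh, fval,
                                dict(zip(names, d)), converged, method=method)


def reconstruct_bone_landmarks(ssm: StatisticalShapeModel,
                               targets: LandmarkSet,
                               config: ReconstructionConfig | None = None,
                               ) -> ReconstructionResult:
    """Fit the model to landmarks digitised directly on the bone surface by
    minimising Σ dᵢ² (+ Mahalanobis penalty)."""
    config = config or ReconstructionConfig()
    return _fit_landmarks(ssm, targets, lambda d: float(d @ d), config, "ssm-bone")


def reconstruct_skin_landmarks(ssm: StatisticalShapeModel,
                               targets: LandmarkSet,
                               offsets: Mapping[str, tuple[float, float]],
                               config: ReconstructionConfig | None = None,
                               ) -> ReconstructionResult:
    """Fit the model to skin-digitised landmarks with soft-tissue correction.

    ``offsets`` maps each landmark name to (d_est, sigma) in mm: the expected
    skin-to-bone offset and its dispersion.  Pass zeros/1 mm (see
    :func:`no_correction_offsets`) for the uncorrected variant.
    """
    config = config or ReconstructionConfig()
    fixed, sliding = _resolve_landmarks(ssm, targets)
    names = [lm.name for lm in fixed] + [lm.name for lm in sliding]
    d_est = np.empty(len(names))
    sigma = np.empty(len(names))
    for i, n in enumerate(names):
        if n not in offsets:
            raise InputError(f"no offset estimate for landmark {n!r}")
        d_est[i], sigma[i] = offsets[n]
        if sigma[i] <= 0:
            raise InputError(f"sigma must be > 0 (landmark {n!r})")
    const = float(np.sum(0.5 * np.log(sigma ** 2)))

    def loss(d):
        return const + float(np.sum((d - d_est) ** 2 / (2 * sigma ** 2)))

    return _fit_landmarks(ssm, targets, loss, config, "ssm-skin")


def no_correction_offsets(names, sigma: float = 1.0) -> dict[str, tuple[float, float]]:
    """Offsets for the uncorrected skin fit: d_est = 0, nominal sigma."""
    return {n: (0.0, sigma) for n in names}


def offsets_from_models(targets: LandmarkSet, models, covariates,
                        default: tuple[float, float] | None = None,
                        ) -> dict[str, tuple[float, float]]:
    """Evaluate per-landmark offset models for a subject.

    Landmarks without a model get ``default`` (d_est, sigma) if provided.
    """
    from .soft_tissue import predict_offset, resolve_offset_model
    out = {}
    for lm in targets:
        try:
            model = resolve_offset_model(models, lm.name)
        except InputError:
            if default is None:
                raise
            out[lm.name] = default
            continue
        out[lm.name] = predict_offset(model, covariates)
    return out


# ---------------------------------------------------------------------------
# linear scaling baselines


def _segment_length(landmarks: LandmarkSet, segment: str) -> tuple[float, np.ndarray]:
    if segment not in _SEGMENT_LENGTH_LANDMARKS:
        raise InputError(f"unknown segment {segment!r}")
    top, (a, b) = _SEGMENT_LENGTH_LANDMARKS[segment]
    origin = 0.5 * (landmarks.position(a) + landmarks.position(b))
    length = float(np.linalg.norm(landmarks.position(top) - origin))
    return length, origin


def uniform_scale(mean_shape: trimesh.Trimesh,
                  model_landmarks: LandmarkSet,
                  targets: LandmarkSet,
                  segment: str = "femur") -> ScalingResult:
    """Isotropically scale the mean shape by the subject/model segment-length
    ratio, then rigidly align it to the target landmarks.

    Segment length is FHC ↔ mid(LE, ME) for the femur and TT ↔ mid(LM, MM)
    for the tibia; the model FHC must be present in ``model_landmarks``.
    """
    model_len, model_origin = _segment_length(model_landmarks, segment)
    target_len, _ = _segment_length(targets, segment)
    if model_len <= 0:
        raise InputError("model segment length is zero")
    s = target_len / model_len
    scaled_v = model_origin + s * (np.asarray(mean_shape.vertices) - model_origin)
    shared = [n for n in model_landmarks.names if n in targets]
    scaled_lm = model_origin + s * (model_landmarks.positions(shared) - model_origin)
    T = rigid_align(scaled_lm, targets.positions(shared))
    return ScalingResult(new_mesh(T.apply(scaled_v), mean_shape.faces), s, s, T)


def pelvis_width_scale(mean_shape: trimesh.Trimesh,
                       model_landmarks: LandmarkSet,
                       targets: LandmarkSet,
                       pelvis_width: float,
                       model_pelvis_width: float,
                       segment: str = "femur") -> ScalingResult:
    """Scale longitudinally by the segment-length ratio and transversely
    (anteroposterior and mediolateral, in the segment frame) by the
    subject/model pelvis-width ratio, then rigidly align to the targets."""
    if pelvis_width <= 0 or model_pelvis_width <= 0:
        raise InputError("pelvis widths must be > 0")
    model_len, _ = _segment_length(model_landmarks, segment)
    target_len, _ = _segment_length(targets, segment)
    if model_len <= 0:
        raise InputError("model segment length is zero")
    sy = target_len / model_len
    st = pelvis_width / model_pelvis_width
    frame = build_segment_frame(model_landmarks, segment)
    local = frame.to_local(np.asarray(mean_shape.vertices)) * np.array([st, sy, st])
    scaled_v = frame.to_world(local)
    shared = [n for n in model_landmarks.names if n in targets]
    lm_local = frame.to_local(model_landmarks.positions(shared)) * np.array([st, sy, st])
    T = rigid_align(frame.to_world(lm_local), targets.positions(shared))
    return ScalingResult(new_mesh(T.apply(scaled_v), mean_shape.faces), sy, st, T)


# ---------------------------------------------------------------------------
# hip-joint-centre regression and femoral head points


def estimate_fhc(pelvis_landmarks: LandmarkSet,
                 side: str = "right",
                 as_world: bool = False) -> np.ndarray:
    """Femoral head centre from pelvic landmarks via the standard regression

        ( −0.24·PD − 9.9,  −0.30·PW − 10.9,  ±(0.33·PW + 7.3) )  mm

    expressed in the pelvis frame (x anterior, y superior, z towards the
    subject's right); PW is the inter-ASIS distance and PD the distance
    between the ASIS- and PSIS-connecting lines.  The mediolateral component
    is positive (lateral) for the right hip and mirrored for the left.
    """
    if side not in ("right", "left"):
        raise InputError("side must be 'right' or 'left'")
    for n in ("LASIS", "RASIS", "LPSIS", "RPSIS"):
        if n not in pelvis_landmarks:
            raise MissingLandmarkError(n, "pelvis")
    la, ra = pelvis_landmarks.position("LASIS"), pelvis_landmarks.position("RASIS")
    lp, rp = pelvis_landmarks.position("LPSIS"), pelvis_landmarks.position("RPSIS")
    pw = float(np.linalg.norm(ra - la))
    d1 = ra - la
    d2 = rp - lp
    n1 = np.linalg.norm(d1)
    if n1 <= 1e-12:
        raise DegenerateGeometryError("ASIS landmarks coincide")
    cross = np.cross(d1, d2)
    sep = lp - la
    if np.linalg.norm(cross) > 1e-9 * n1 * max(np.linalg.norm(d2), 1e-12):
        pd = abs(float(sep @ cross) / np.linalg.norm(cross))
    else:  # (anti)parallel connecting lines: perpendicular distance
        u = d1 / n1
        perp = sep - (sep @ u) * u
        pd = float(np.linalg.norm(perp))
    local = np.array([-0.24 * pd - 9.9,
                      -0.30 * pw - 10.9,
                      0.33 * pw + 7.3])
    if side == "left":
        local[2] = -local[2]
    if as_world:
        return build_segment_frame(pelvis_landmarks, "pelvis").to_world(local)
    return local


def femoral_head_radius(femur_length: float, mean_length: float,
                        mean_radius: float = MEAN_FEMORAL_HEAD_RADIUS_MM) -> float:
    """Head radius by linear length scaling of the mean-shape radius."""
    if femur_length <= 0 or mean_length <= 0:
        raise InputError("lengths must be positive")
    return mean_radius * femur_length / mean_length


def femoral_head_points(fhc: np.ndarray, radius: float, frame: Frame,
                        side: str = "right") -> dict[str, np.ndarray]:
    """Auxiliary head-surface points superior/medial/anterior/posterior of
    the FHC along the femoral frame axes (mirrored mediolaterally and
    anteroposteriorly for left limbs)."""
    if radius <= 0:
        raise InputError("radius must be positive")
    if side not in ("right", "left"):
        raise InputError("side must be 'right' or 'left'")
    fhc = np.asarray(fhc, dtype=float).reshape(3)
    sgn = 1.0 if side == "right" else -1.0
    return {"FHS": fhc + radius * frame.y_axis,
            "FHM": fhc - sgn * radius * frame.x_axis,
            "FHA": fhc + sgn * radius * frame.z_axis,
            "FHP": fhc - sgn * radius * frame.z_axis}
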