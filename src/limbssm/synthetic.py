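"""Seeded synthetic long-bone populations.

The generator emulates the statistical structure the reconstruction method
relies on, without any imaging data: a parametric femur (tubular shaft,
condylar flare, offset spherical head set by an anteversion angle) and a
parametric tibia+fibula (twisted plateau and malleoli), a population whose
shapes vary through a known low-rank linear latent model plus vertex noise,
anthropometric covariates coupled to bone length, and skin "digitisations"
displaced from the bone landmarks along outward normals by covariate-driven
soft-tissue offsets.

The canonical template frame is: origin at the distal joint line, +y
longitudinal (proximal), +x mediolateral towards the LE/LM side, +z = x × y.
Vertex positions are, by construction, affine in (length, shaft_radius,
condylar_width, head_radius) at fixed angles, so a linear latent model over
those parameters yields an exactly low-rank shape population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import InputError
from .geometry import Landmark, LandmarkSet, new_mesh
from .soft_tissue import Covariates, OffsetModel, OffsetObservation, predict_offset, \
    resolve_offset_model
from .ssm import CorrespondedShapeSet

__all__ = [
    "BoneTemplateParams",
    "SyntheticBone",
    "SyntheticSubject",
    "SyntheticStudy",
    "generate_bone",
    "generate_population",
    "simulate_digitisation",
    "make_study",
    "FEMUR_TEMPLATE",
    "TIBIA_TEMPLATE",
]


@dataclass(frozen=True)
class BoneTemplateParams:
    """Parametric long-bone dimensions (mm, degrees)."""

    segment: str = "femur"            # femur | tibia
    length: float = 426.0
    shaft_radius: float = 14.0
    condylar_width: float = 80.0
    head_radius: float = 21.1
    anteversion_deg: float = 12.0     # femur only
    bow_deg: float = 0.0              # femur only
    torsion_deg: float = 25.0         # tibia only
    resolution: int = 800             # approximate vertex count

    def __post_init__(self):
        if self.segment not in ("femur", "tibia"):
            raise InputError("segment must be femur|tibia")
        for name in ("length", "shaft_radius", "condylar_width", "head_radius"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.resolution < 500:
            raise InputError("resolution must be >= 500 vertices")


FEMUR_TEMPLATE = BoneTemplateParams(segment="femur")
TIBIA_TEMPLATE = BoneTemplateParams(segment="tibia", length=370.0, shaft_radius=12.0,
                                    condylar_width=72.0, torsion_deg=25.0)

# fixed construction fractions (relative to length / shaft radius)
_NECK_FRAC = 0.18          # femoral neck length / femur length
_NECK_ELEV_DEG = 45.0      # neck elevation above the transverse plane
_FIBULA_OFFSET_FRAC = 0.60  # fibula centreline lateral offset / condylar width


@dataclass
class SyntheticBone:
    """One generated bone: mesh, per-vertex part labels, landmark map and
    ground-truth quantities known from the construction."""

    mesh: trimesh.Trimesh
    part_labels: np.ndarray
    landmark_indices: dict[str, int]
    outward_normals: np.ndarray
    params: BoneTemplateParams
    fhc: np.ndarray | None = None             # femur head centre (exact)
    head_vertices: np.ndarray | None = None   # femoral head vertex indices
    truth: dict = field(default_factory=dict)

    def bone_landmarks(self) -> LandmarkSet:
        pts = {n: self.mesh.vertices[i] for n, i in self.landmark_indices.items()}
        return LandmarkSet.from_points(pts, surface="bone")


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return 3 * s ** 2 - 2 * s ** 3


def _closed_tube(centres: np.ndarray, a: np.ndarray, b: np.ndarray,
                 twist: np.ndarray, n_seg: int) -> tuple[np.ndarray, np.ndarray]:
    """Capped elliptical tube.  ``centres`` (nr, 3); per-ring semi-axes ``a``
    (x) and ``b`` (z); ``twist`` rotates each ring about +y.  Returns
    (vertices, faces) with outward winding."""
    nr = len(centres)
    theta = 2 * np.pi * np.arange(n_seg) / n_seg
    ct, st = np.cos(theta), np.sin(theta)
    cph, sph = np.cos(twist), np.sin(twist)
    # ring-local point (a cosθ, 0, b sinθ) rotated about +y by twist
    x_loc = a[:, None] * ct[None, :]
    z_loc = b[:, None] * st[None, :]
    x = x_loc * cph[:, None] + z_loc * sph[:, None]
    z = -x_loc * sph[:, None] + z_loc * cph[:, None]
    verts = np.empty((nr * n_seg + 2, 3))
    verts[:nr * n_seg, 0] = (x + centres[:, 0:1]).ravel()
    verts[:nr * n_seg, 1] = np.repeat(centres[:, 1], n_seg)
    verts[:nr * n_seg, 2] = (z + centres[:, 2:3]).ravel()
    bottom, top = nr * n_seg, nr * n_seg + 1
    verts[bottom] = centres[0]
    verts[top] = centres[-1]

    faces = []
    for j in range(nr - 1):
        for i in range(n_seg):
            i2 = (i + 1) % n_seg
            v00, v01 = j * n_seg + i, j * n_seg + i2
            v10, v11 = (j + 1) * n_seg + i, (j + 1) * n_seg + i2
            faces.append([v00, v11, v01])
            faces.append([v00, v10, v11])
    for i in range(n_seg):
        i2 = (i + 1) % n_seg
        faces.append([bottom, i, i2])                              # -y cap
        faces.append([top, (nr - 1) * n_seg + i2, (nr - 1) * n_seg + i])  # +y cap
    return verts, np.asarray(faces, dtype=np.int64)


def _oriented(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip winding if the closed surface has negative volume."""
    m = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if m.volume < 0:
        return faces[:, ::-1].copy()
    return faces


def _ring_outward(verts: np.ndarray, centres_per_vertex: np.ndarray) -> np.ndarray:
    d = verts - centres_per_vertex
    n = np.linalg.norm(d, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return d / n


def generate_bone(params: BoneTemplateParams) -> SyntheticBone:
    """Deterministic parametric bone; bitwise reproducible from its params."""
    if params.segment == "femur":
        return _generate_femur(params)
    return _generate_tibia_fibula(params)


def _generate_femur(p: BoneTemplateParams) -> SyntheticBone:
    n_seg = 16
    n_head = 162  # icosphere, 2 subdivisions
    nr = max(8, round((p.resolution - n_head - 2) / n_seg))
    L, rs, cw = p.length, p.shaft_radius, p.condylar_width
    beta = math.radians(_NECK_ELEV_DEG)
    alpha = math.radians(p.anteversion_deg)
    neck_len = _NECK_FRAC * L
    Ls = L - neck_len * math.sin(beta)

    f = np.arange(nr) / (nr - 1)
    g_cond = 1.0 - _smoothstep(f / 0.15)
    g_prox = _smoothstep((f - 0.82) / 0.18)
    a = rs + (cw / 2 - rs) * g_cond + 0.8 * rs * g_prox
    b = rs + (0.70 * cw / 2 - rs) * g_cond + 0.35 * rs * g_prox
    centres = np.zeros((nr, 3))
    centres[:, 0] = 0.9 * rs * g_prox                    # lateral shift -> GT
    centres[:, 1] = f * Ls
    centres[:, 2] = 0.25 * L * math.tan(math.radians(p.bow_deg)) * 4 * f * (1 - f)
    shaft_v, shaft_f = _closed_tube(centres, a, b, np.zeros(nr), n_seg)
    shaft_f = _oriented(shaft_v, shaft_f)

    # femoral head: icosphere at the neck tip
    horiz = np.array([-math.cos(alpha), 0.0, math.sin(alpha)])
    neck_dir = math.cos(beta) * horiz + math.sin(beta) * np.array([0.0, 1.0, 0.0])
    fhc = np.array([0.0, Ls, 0.0]) + neck_len * neck_dir
    sphere = trimesh.creation.icosphere(subdivisions=2)
    head_v = fhc + p.head_radius * np.asarray(sphere.vertices)
    head_f = np.asarray(sphere.faces, dtype=np.int64)

    n_shaft = len(shaft_v)
    verts = np.vstack([shaft_v, head_v])
    faces = np.vstack([shaft_f, head_f + n_shaft])
    mesh = new_mesh(verts, faces)
    part_labels = np.full(len(verts), "femur", dtype="U16")

    # outward directions: radial from ring centre (shaft) / head centre (head)
    ring_centres = np.vstack([np.repeat(centres, n_seg, axis=0),
                              centres[[0]], centres[[-1]]])
    outward = np.vstack([_ring_outward(shaft_v, ring_centres),
                         _ring_outward(head_v, np.tile(fhc, (n_head, 1)))])
    # cap apexes point along -y/+y
    outward[n_shaft - 2] = [0, -1, 0]
    outward[n_shaft - 1] = [0, 1, 0]

    lm_targets = {
        "LE": np.array([cw / 2, 0.0, 0.0]),
        "ME": np.array([-cw / 2, 0.0, 0.0]),
        "GT": np.array([0.9 * rs + a[-1], Ls, centres[-1, 2]]),
        "FN": np.array([0.0, 0.12 * Ls, b[np.searchsorted(f, 0.12)]]),
    }
    lm_idx = {n: int(np.argmin(np.linalg.norm(shaft_v - t, axis=1)))
              for n, t in lm_targets.items()}

    femur_len = float(np.linalg.norm(fhc))  # condyle midpoint is the origin
    truth = {
        "anteversion_deg": p.anteversion_deg,
        "anat_mech_angle_deg": math.degrees(math.acos(fhc[1] / femur_len)),
        "femur_length_mm": femur_len,
    }
    return SyntheticBone(mesh, part_labels, lm_idx, outward, p, fhc=fhc,
                         head_vertices=np.arange(n_shaft, n_shaft + n_head),
                         truth=truth)


def _generate_tibia_fibula(p: BoneTemplateParams) -> SyntheticBone:
    n_seg_t, n_seg_f = 14, 10
    L, rs, cw = p.length, p.shaft_radius, p.condylar_width
    tau = math.radians(p.torsion_deg)
    nr_t = max(8, round(p.resolution * 0.7 / n_seg_t))
    nr_f = max(8, round(p.resolution * 0.3 / n_seg_f))

    # tibia: plateau flare proximally, malleolar flare distally, twist
    # vanishing at the plateau and reaching tau at the ankle
    f = np.arange(nr_t) / (nr_t - 1)
    g_plat = _smoothstep((f - 0.85) / 0.15)
    g_dist = 1.0 - _smoothstep(f / 0.08)
    a = rs + (cw / 2 - rs) * g_plat + 0.35 * rs * g_dist
    b = rs + (0.62 * cw / 2 - rs) * g_plat + 0.20 * rs * g_dist
    centres = np.zeros((nr_t, 3))
    centres[:, 1] = f * L
    twist = tau * (1.0 - f)
    tib_v, tib_f = _closed_tube(centres, a, b, twist, n_seg_t)
    tib_f = _oriented(tib_v, tib_f)

    # fibula: thin lateral tube, following the same twist, distal end (LM)
    # reaching below the tibial ankle line
    ff = np.arange(nr_f) / (nr_f - 1)
    yf = -0.05 * L + ff * (0.92 * L + 0.05 * L)
    twist_f = tau * (1.0 - np.clip(yf / L, 0.0, 1.0))
    off = _FIBULA_OFFSET_FRAC * cw
    cf = np.zeros((nr_f, 3))
    cf[:, 0] = off * np.cos(twist_f)
    cf[:, 2] = -off * np.sin(twist_f)
    cf[:, 1] = yf
    rf = 0.35 * rs + 0.25 * rs * (1.0 - _smoothstep(ff / 0.10))
    fib_v, fib_f = _closed_tube(cf, rf, rf, twist_f, n_seg_f)
    fib_f = _oriented(fib_v, fib_f)

    n_tib = len(tib_v)
    verts = np.vstack([tib_v, fib_v])
    faces = np.vstack([tib_f, fib_f + n_tib])
    mesh = new_mesh(verts, faces)
    part_labels = np.concatenate([np.full(n_tib, "tibia", dtype="U16"),
                                  np.full(len(fib_v), "fibula", dtype="U16")])

    ring_c_t = np.vstack([np.repeat(centres, n_seg_t, axis=0), centres[[0]], centres[[-1]]])
    ring_c_f = np.vstack([np.repeat(cf, n_seg_f, axis=0), cf[[0]], cf[[-1]]])
    outward = np.vstack([_ring_outward(tib_v, ring_c_t), _ring_outward(fib_v, ring_c_f)])
    outward[n_tib - 2] = [0, -1, 0]
    outward[n_tib - 1] = [0, 1, 0]
    outward[-2] = [0, -1, 0]
    outward[-1] = [0, 1, 0]

    def rot_y(phi, v):
        c, s = math.cos(phi), math.sin(phi)
        return np.array([v[0] * c + v[2] * s, v[1], -v[0] * s + v[2] * c])

    def anterior(frac):
        j = int(round(frac * (nr_t - 1)))
        return centres[j] + rot_y(twist[j], np.array([0.0, 0.0, b[j]]))

    lm_targets = {
        "TT": anterior(0.80),
        "TN": anterior(0.05),
        "ATP": anterior(0.72),
        "ATM": anterior(0.52),
        "ATD": anterior(0.32),
        "MM": centres[0] + rot_y(twist[0], np.array([-a[0], 0.0, 0.0])),
    }
    lm_idx = {n: int(np.argmin(np.linalg.norm(tib_v - t, axis=1)))
              for n, t in lm_targets.items()}
    lm_idx["LM"] = n_tib + len(fib_v) - 2  # fibula bottom cap apex
    truth = {"torsion_deg": p.torsion_deg}
    return SyntheticBone(mesh, part_labels, lm_idx, outward, p, truth=truth)


# ---------------------------------------------------------------------------
# population


# latent loadings: columns are latent directions, rows (length, shaft_radius,
# condylar_width); z1 is overall size (tied to stature), z2 shaft girth,
# z3 distal/condylar width
_LOADINGS = {
    "femur": np.array([[26.0, 0.0, 0.0],
                       [0.8, 1.2, 0.0],
                       [2.5, 0.0, 6.0]]),
    "tibia": np.array([[22.0, 0.0, 0.0],
                       [0.7, 1.0, 0.0],
                       [2.2, 0.0, 5.0]]),
}
_MEAN_HEIGHT_M, _SD_HEIGHT_M = 1.74, 0.09
_HEIGHT_RANGE_M = (1.55, 1.93)
_MASS_RANGE_KG = (45.0, 108.0)
_BMI_RANGE = (17.0, 34.8)
_AGE_RANGE = (23, 70)
_FEMALE_FRACTION = 13 / 35


def _params_for_latents(template: BoneTemplateParams, z: np.ndarray) -> BoneTemplateParams:
    W = _LOADINGS[template.segment]
    z3 = np.zeros(3)
    z3[:len(z)] = z
    dl, drs, dcw = W @ z3
    return replace(template,
                   length=template.length + dl,
                   shaft_radius=template.shaft_radius + drs,
                   condylar_width=template.condylar_width + dcw)


def latent_directions(template: BoneTemplateParams, latent_dim: int = 3) -> np.ndarray:
    """Exact per-latent shape directions (latent_dim, 3k): the generator is
    affine in the perturbed parameters, so finite differences are exact."""
    base = generate_bone(template).mesh.vertices
    dirs = []
    for d in range(latent_dim):
        z = np.zeros(3)
        z[d] = 1.0
        v = generate_bone(_params_for_latents(template, z)).mesh.vertices
        dirs.append((np.asarray(v) - np.asarray(base)).ravel())
    return np.array(dirs)


def _draw_covariates(rng: np.random.Generator) -> Covariates:
    from scipy.stats import truncnorm
    lo = (_HEIGHT_RANGE_M[0] - _MEAN_HEIGHT_M) / _SD_HEIGHT_M
    hi = (_HEIGHT_RANGE_M[1] - _MEAN_HEIGHT_M) / _SD_HEIGHT_M
    height = float(truncnorm.rvs(lo, hi, loc=_MEAN_HEIGHT_M, scale=_SD_HEIGHT_M,
                                 random_state=rng))
    bmi = float(truncnorm.rvs((_BMI_RANGE[0] - 24.5) / 3.5, (_BMI_RANGE[1] - 24.5) / 3.5,
                              loc=24.5, scale=3.5, random_state=rng))
    mass = float(np.clip(bmi * height ** 2, *_MASS_RANGE_KG))
    age = int(rng.integers(_AGE_RANGE[0], _AGE_RANGE[1] + 1))
    gender = int(rng.random() < _FEMALE_FRACTION)
    return Covariates(height=height, mass=mass, age=age, gender=gender)


@dataclass
class SyntheticPopulation:
    cset: CorrespondedShapeSet
    latents: np.ndarray
    covariates: list[Covariates]
    template: SyntheticBone
    true_directions: np.ndarray       # (latent_dim, 3k)
    subject_params: list[BoneTemplateParams]
    fhc_true: np.ndarray | None = None  # (n, 3) for femora


def generate_population(n: int,
                        latent_dim: int = 3,
                        latent_sd: float = 1.0,
                        noise_sd: float = 0.1,
                        seed: int = 0,
                        template: BoneTemplateParams = FEMUR_TEMPLATE,
                        covariates: list[Covariates] | None = None,
                        ) -> SyntheticPopulation:
    """Population of corresponded bones from a linear latent shape model.

    The first latent is the standardised stature score, coupling bone length
    to subject height; remaining latents are truncated standard normal.
    Per-vertex Gaussian noise of ``noise_sd`` mm is added independently.
    """
    if not 1 <= latent_dim <= 3:
        raise InputError("latent_dim must be in 1..3")
    if n < latent_dim + 2:
        raise InputError("need n >= latent_dim + 2 subjects")
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n)
    tbone = generate_bone(template)
    k3 = np.asarray(tbone.mesh.vertices).size

    covs, latents, shapes, plist, fhcs = [], [], np.empty((n, k3 // 3, 3)), [], []
    for i in range(n):
        rng = np.random.default_rng(subject_seeds[i])
        cov = covariates[i] if covariates is not None else _draw_covariates(rng)
        z = np.zeros(latent_dim)
        z[0] = latent_sd * (cov.height - _MEAN_HEIGHT_M) / _SD_HEIGHT_M
        if latent_dim > 1:
            extra = rng.standard_normal(latent_dim - 1)
            z[1:] = latent_sd * np.clip(extra, -3, 3)
        params = _params_for_latents(template, z)
        bone = generate_bone(params)
        noise = noise_sd * rng.standard_normal((k3 // 3, 3)) if noise_sd > 0 else 0.0
        shapes[i] = np.asarray(bone.mesh.vertices) + noise
        covs.append(cov)
        latents.append(z)
        plist.append(params)
        fhcs.append(bone.fhc)
    cset = CorrespondedShapeSet(shapes, np.asarray(tbone.mesh.faces),
                                tbone.part_labels, dict(tbone.landmark_indices))
    return SyntheticPopulation(cset, np.array(latents), covs, tbone,
                               latent_directions(template, latent_dim), plist,
                               None if fhcs[0] is None else np.array(fhcs))


def rigid_tangent_basis(vertices: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3k) of infinitesimal rigid motions at a shape."""
    from scipy.linalg import orth
    V = np.asarray(vertices, dtype=float)
    c = V.mean(axis=0)
    rows = []
    for ax in np.eye(3):
        rows.append(np.tile(ax, len(V)))
        rows.append(np.cross(np.tile(ax, (len(V), 1)), V - c).ravel())
    return orth(np.array(rows).T).T


def subspace_recovery_angles(modes: np.ndarray, pop: "SyntheticPopulation") -> np.ndarray:
    """Principal angles (degrees) between estimated modes and the generating
    shape subspace.

    Because model building quotients out rigid motion (Procrustes alignment),
    the reference subspace is span(true latent directions ⊕ rigid tangent
    space at the template); an estimated mode is "recovered" when it lies in
    that span.
    """
    from scipy.linalg import orth, subspace_angles
    tangent = rigid_tangent_basis(np.asarray(pop.template.mesh.vertices))
    ref = orth(np.concatenate([pop.true_directions, tangent]).T)
    return np.degrees(subspace_angles(np.atleast_2d(modes).T, ref))


# ---------------------------------------------------------------------------
# digitisation


def simulate_digitisation(mesh: trimesh.Trimesh,
                          landmark_indices: dict[str, int],
                          covariates: Covariates,
                          offset_models: dict[str, OffsetModel],
                          noise_sd_mm: float = 1.0,
                          seed: int | np.random.Generator = 0,
                          outward_normals: np.ndarray | None = None,
                          ) -> tuple[LandmarkSet, list[OffsetObservation]]:
    """Skin landmarks above the bone landmarks.

    skin = bone + (d_est + N(0, σ_landmark)) · outward-normal + N(0, noise²)
    per axis, with the radial offset clipped at 0.  Returns the skin landmark
    set and the exact offset observations (‖skin − bone‖ recomputed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    normals = outward_normals if outward_normals is not None \
        else np.asarray(mesh.vertex_normals)
    skin = LandmarkSet()
    observations = []
    verts = np.asarray(mesh.vertices)
    for name, vidx in landmark_indices.items():
        model = resolve_offset_model(offset_models, name)
        d_est, sigma = predict_offset(model, covariates)
        d = max(0.0, d_est + sigma * rng.standard_normal())
        n = normals[vidx] / np.linalg.norm(normals[vidx])
        pos = verts[vidx] + d * n
        if noise_sd_mm > 0:
            pos = pos + noise_sd_mm * rng.standard_normal(3)
        skin.add(Landmark(name, pos, surface="skin",
                          kind="sliding" if name in ("ATP", "ATM", "ATD") else "fixed"))
        observations.append(OffsetObservation(
            name, covariates, float(np.linalg.norm(pos - verts[vidx]))))
    return skin, observations


# ---------------------------------------------------------------------------
# full study


@dataclass
class SyntheticSubject:
    subject_id: int
    covariates: Covariates
    latents_femur: np.ndarray
    femur_vertices: np.ndarray
    shank_vertices: np.ndarray
    femur_bone_landmarks: LandmarkSet
    shank_bone_landmarks: LandmarkSet
    femur_skin_landmarks: LandmarkSet
    shank_skin_landmarks: LandmarkSet
    fhc_true: np.ndarray
    fhc_estimate: np.ndarray
    pelvis_width: float


@dataclass
class SyntheticStudy:
    """A fully synthetic cohort emulating the digitisation study design."""

    subjects: list[SyntheticSubject]
    femur_set: CorrespondedShapeSet
    shank_set: CorrespondedShapeSet
    femur_template: SyntheticBone
    shank_template: SyntheticBone
    offset_models: dict[str, OffsetModel]
    seed: int


def make_study(n: int,
               seed: int = 0,
               latent_sd: float = 1.0,
               noise_sd: float = 0.1,
               digitisation_noise_mm: float = 1.0,
               fhc_estimate_sd_mm: float = 8.0,
               offset_models: dict[str, OffsetModel] | None = None,
               resolution: int = 800) -> SyntheticStudy:
    """Generate a complete synthetic study cohort (femur + shank).

    Both bones share the stature latent through the subject covariates; the
    skin digitisation uses the supplied offset models (the published
    thigh/shank table by default).
    """
    from .soft_tissue import builtin_offset_models
    models = offset_models or builtin_offset_models()
    ss = np.random.SeedSequence([seed, 7])
    fem_t = replace(FEMUR_TEMPLATE, resolution=resolution)
    tib_t = replace(TIBIA_TEMPLATE, resolution=resolution)
    latent_dim = min(3, n - 2)  # small cohorts carry fewer latent modes
    fem_pop = generate_population(n, latent_dim=latent_dim, latent_sd=latent_sd,
                                  noise_sd=noise_sd, seed=seed, template=fem_t)
    tib_pop = generate_population(n, latent_dim=latent_dim, latent_sd=latent_sd,
                                  noise_sd=noise_sd, seed=seed + 1, template=tib_t,
                                  covariates=fem_pop.covariates)
    subject_seeds = ss.spawn(n)
    subjects = []
    for i in range(n):
        rng = np.random.default_rng(subject_seeds[i])
        cov = fem_pop.covariates[i]
        fem_mesh = fem_pop.cset.mesh(i)
        tib_mesh = tib_pop.cset.mesh(i)
        fem_bone_lm = LandmarkSet.from_points(
            {name: fem_mesh.vertices[idx]
             for name, idx in fem_pop.cset.landmark_indices.items()}, surface="bone")
        tib_bone_lm = LandmarkSet.from_points(
            {name: tib_mesh.vertices[idx]
             for name, idx in tib_pop.cset.landmark_indices.items()}, surface="bone")
        fem_skin, _ = simulate_digitisation(
            fem_mesh, fem_pop.cset.landmark_indices, cov, models,
            noise_sd_mm=digitisation_noise_mm, seed=rng)
        tib_skin, _ = simulate_digitisation(
            tib_mesh, tib_pop.cset.landmark_indices, cov, models,
            noise_sd_mm=digitisation_noise_mm, seed=rng)
        fhc_true = fem_pop.fhc_true[i]
        fhc_est = fhc_true + fhc_estimate_sd_mm * rng.standard_normal(3)
        pw = float(145.0 * cov.height + rng.normal(0.0, 8.0))  # mm, ~inter-ASIS
        subjects.append(SyntheticSubject(i, cov, fem_pop.latents[i],
                                         np.asarray(fem_mesh.vertices),
                                         np.asarray(tib_mesh.vertices),
                                         fem_bone_lm, tib_bone_lm,
                                         fem_skin, tib_skin,
                                         fhc_true, fhc_est, pw))
    return SyntheticStudy(subjects, fem_pop.cset, tib_pop.cset,
                          fem_pop.template, tib_pop.template, models, seed)
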