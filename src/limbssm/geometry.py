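"""Meshes, landmarks, rigid registration and anatomical coordinate frames.

All coordinates are millimetres.  Triangle meshes are handled as
:class:`trimesh.Trimesh` objects constructed with ``process=False`` so that
vertex order (and hence point correspondence) is always preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import trimesh

from .errors import DegenerateGeometryError, InputError, MissingLandmarkError
from .proximity import SurfaceQuery

__all__ = [
    "RigidTransform",
    "Frame",
    "Landmark",
    "LandmarkSet",
    "new_mesh",
    "load_mesh",
    "save_mesh",
    "rigid_align",
    "icp_register",
    "surface_rmse",
    "fit_sphere",
    "build_segment_frame",
    "SEGMENT_LANDMARKS",
]

# landmarks allowed to slide on the model surface during fitting (anterior
# tibial crest points have no fixed bony correspondence)
SLIDING_LANDMARKS = frozenset({"ATP", "ATM", "ATD"})


# ---------------------------------------------------------------------------
# basic containers


def new_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Create a mesh without any vertex reordering or merging."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise InputError("vertices must be (n, 3)")
    if not np.all(np.isfinite(vertices)):
        raise InputError("mesh vertices must be finite")
    if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
        raise InputError("face indices out of range")
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def load_mesh(path) -> trimesh.Trimesh:
    """Load a PLY/STL/OBJ mesh (mm units assumed)."""
    m = trimesh.load_mesh(str(path), process=False)
    if isinstance(m, trimesh.Scene):
        m = trimesh.util.concatenate(list(m.geometry.values()))
    return new_mesh(m.vertices, m.faces)


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(path))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise InputError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise InputError("rotation is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal anatomical coordinate frame."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        A = self.axes
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("frame axes are not orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-9):
            raise DegenerateGeometryError("frame is not right-handed (x × y != z)")

    @property
    def axes(self) -> np.ndarray:
        """Rows are the x, y, z axes."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.axes.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.axes + self.origin

    def transformed(self, T: RigidTransform) -> "Frame":
        return Frame(T.apply(self.origin),
                     T.rotation @ self.x_axis,
                     T.rotation @ self.y_axis,
                     T.rotation @ self.z_axis)


@dataclass(frozen=True)
class Landmark:
    name: str
    position: np.ndarray
    surface: str = "bone"  # skin | bone
    kind: str = "fixed"    # fixed | sliding

    def __post_init__(self):
        p = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise InputError(f"landmark {self.name!r} has non-finite position")
        if self.surface not in ("skin", "bone"):
            raise InputError(f"landmark {self.name!r}: surface must be skin|bone")
        if self.kind not in ("fixed", "sliding"):
            raise InputError(f"landmark {self.name!r}: kind must be fixed|sliding")
        if self.kind == "sliding" and self.name not in SLIDING_LANDMARKS:
            raise InputError(f"landmark {self.name!r} may not be 'sliding' "
                             f"(only {sorted(SLIDING_LANDMARKS)})")
        object.__setattr__(self, "position", p)


class LandmarkSet:
    """Named 3-D landmarks with surface (skin|bone) and kind (fixed|sliding) tags.

    Behaves like a mapping from name to :class:`Landmark`.
    """

    def __init__(self, landmarks: Iterable[Landmark] = ()):
        self._entries: dict[str, Landmark] = {}
        for lm in landmarks:
            self.add(lm)

    # -- mapping-ish interface ------------------------------------------
    def add(self, lm: Landmark) -> None:
        if lm.name in self._entries:
            raise InputError(f"duplicate landmark name {lm.name!r}")
        self._entries[lm.name] = lm

    def __getitem__(self, name: str) -> Landmark:
        try:
            return self._entries[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def position(self, name: str) -> np.ndarray:
        return self[name].position

    def positions(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.position(n) for n in names])

    def subset(self, names: Iterable[str]) -> "LandmarkSet":
        return LandmarkSet(self[n] for n in names)

    def transformed(self, T: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(replace(lm, position=T.apply(lm.position)) for lm in self)

    @classmethod
    def from_points(cls, points: Mapping[str, np.ndarray], surface: str = "bone") -> "LandmarkSet":
        return cls(Landmark(n, p, surface=surface,
                            kind="sliding" if n in SLIDING_LANDMARKS else "fixed")
                   for n, p in points.items())

    # -- I/O: CSV columns name,x,y,z,surface,kind; JSON mirrors the schema
    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        import pandas as pd
        df = pd.read_csv(path)
        required = {"name", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise InputError(f"landmark CSV needs columns {sorted(required)}")
        out = cls()
        for _, row in df.iterrows():
            out.add(Landmark(str(row["name"]),
                             np.array([row["x"], row["y"], row["z"]], dtype=float),
                             surface=str(row.get("surface", "bone")),
                             kind=str(row.get("kind", "fixed"))))
        return out

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = [{"name": lm.name, "x": lm.position[0], "y": lm.position[1],
                 "z": lm.position[2], "surface": lm.surface, "kind": lm.kind}
                for lm in self]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        data = json.loads(Path(path).read_text())
        return cls(Landmark(e["name"], np.asarray(e["position"], dtype=float),
                            surface=e.get("surface", "bone"), kind=e.get("kind", "fixed"))
                   for e in data["landmarks"])

    def to_json(self, path) -> None:
        data = {"landmarks": [{"name": lm.name, "position": lm.position.tolist(),
                               "surface": lm.surface, "kind": lm.kind} for lm in self]}
        Path(path).write_text(json.dumps(data, indent=1))


# ---------------------------------------------------------------------------
# rigid registration


def rigid_align(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform T minimising Σ‖T(sᵢ) − tᵢ‖² (Kabsch/SVD).

    No scaling component is estimated.  Raises
    :class:`DegenerateGeometryError` for < 3 pairs or collinear sources.
    """
    S = np.asarray(source_points, dtype=float)
    T = np.asarray(target_points, dtype=float)
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 3:
        raise InputError("source/target must be matching (n, 3) arrays")
    n = len(S)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    cs, ct = S.mean(axis=0), T.mean(axis=0)
    S0, T0 = S - cs, T - ct
    # collinearity: second singular value of the centred source must be > 0
    sv = np.linalg.svd(S0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("source points are (nearly) collinear")
    H = S0.T @ T0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, ct - R @ cs)


def _canonical_transform(vertices: np.ndarray) -> RigidTransform:
    """Deterministic centroid + principal-axes pose used to seed ICP.

    Axis signs are resolved with third moments so the result is stable under
    rigid motion of the input.
    """
    V = np.asarray(vertices, dtype=float)
    c = V.mean(axis=0)
    V0 = V - c
    C = V0.T @ V0 / len(V0)
    w, E = np.linalg.eigh(C)      # ascending
    E = E[:, ::-1]                # principal axis first
    # fix signs by skewness along each axis; fall back to +1 for symmetric data
    proj = V0 @ E
    skew = (proj ** 3).sum(axis=0)
    signs = np.where(np.abs(skew) > 1e-9, np.sign(skew), 1.0)
    E = E * signs
    if np.linalg.det(E) < 0:
        E[:, 2] = -E[:, 2]
    # local coords = Eᵀ (x − c)
    return RigidTransform(E.T, -E.T @ c)


def icp_register(source: trimesh.Trimesh,
                 target: trimesh.Trimesh,
                 max_iterations: int = 100,
                 tolerance: float = 1e-6,
                 init: RigidTransform | None = None,
                 source_landmarks: LandmarkSet | None = None,
                 target_landmarks: LandmarkSet | None = None,
                 ) -> tuple[RigidTransform, float]:
    """Iterative closest point: rigidly register ``source`` onto ``target``.

    Correspondences are exact closest points on the target triangles
    (point-to-surface), with a point-to-point rigid update per iteration, so
    the RMSE is monotone non-increasing.  Returns the transform and the final
    RMS of source-vertex to target-surface distances (mm).

    Initialisation: explicit ``init`` > shared landmark names > deterministic
    centroid/principal-axes alignment.
    """
    if len(source.vertices) == 0 or len(target.vertices) == 0:
        raise InputError("ICP requires non-empty meshes")
    if init is None and source_landmarks is not None and target_landmarks is not None:
        shared = [n for n in source_landmarks.names if n in target_landmarks]
        if len(shared) >= 3:
            try:
                init = rigid_align(source_landmarks.positions(shared),
                                   target_landmarks.positions(shared))
            except DegenerateGeometryError:
                init = None
    if init is None:
        init = _canonical_transform(target.vertices).inverse().compose(
            _canonical_transform(source.vertices))

    query = SurfaceQuery(target)
    T = init
    P = np.asarray(source.vertices, dtype=float)
    rmse = np.inf
    for _ in range(max_iterations):
        moved = T.apply(P)
        closest, dist = query.closest(moved)
        new_rmse = float(np.sqrt(np.mean(dist ** 2)))
        if rmse - new_rmse < tolerance and np.isfinite(rmse):
            rmse = min(rmse, new_rmse)
            break
        rmse = new_rmse
        T = rigid_align(P, closest)
    else:
        moved = T.apply(P)
        _, dist = query.closest(moved)
        rmse = float(np.sqrt(np.mean(dist ** 2)))
    return T, rmse


def surface_rmse(recon: trimesh.Trimesh, truth: trimesh.Trimesh, **icp_kwargs) -> float:
    """One-way surface error: ICP-align ``recon`` to ``truth`` then return the
    RMS of recon-vertex → truth-surface distances (mm).

    Rigid-invariant: any rigid pre-transform of ``recon`` is undone by the
    ICP alignment.
    """
    _, rmse = icp_register(recon, truth, **icp_kwargs)
    return rmse


# ---------------------------------------------------------------------------
# sphere fit


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit.

    Solves ‖x‖² = 2 c·x + k linearly; exact for noiseless spherical samples
    and interpolating for exactly four non-coplanar points.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or len(P) < 4:
        raise InputError("need >= 4 points of shape (n, 3)")
    A = np.column_stack([2.0 * P, np.ones(len(P))])
    b = (P ** 2).sum(axis=1)
    # coplanarity check: the centred points must span 3-D
    sv = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
    if sv[2] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are (nearly) coplanar")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    radius = float(np.sqrt(sol[3] + centre @ centre))
    return centre, radius


# ---------------------------------------------------------------------------
# anatomical frames

SEGMENT_LANDMARKS = {
    "femur": ("FHC", "LE", "ME"),
    "tibia": ("TT", "LM", "MM"),
    "pelvis": ("LASIS", "RASIS", "LPSIS", "RPSIS"),
}


def _unit(v: np.ndarray, context: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n <= 1e-12:
        raise DegenerateGeometryError(f"zero-length axis while building {context}")
    return v / n


def build_segment_frame(landmarks: LandmarkSet, segment: str) -> Frame:
    """Anatomical frame of a segment from its landmarks.

    femur:  origin = mid(LE, ME); y towards FHC; x = ME→LE orthogonalised to y.
    tibia:  origin = mid(LM, MM); y towards TT;  x = MM→LM orthogonalised to y.
    pelvis: origin = mid-ASIS; z = LASIS→RASIS; x = anterior component of
            midPSIS→midASIS; y = z × x.
    All frames are right-handed with z = x × y.
    """
    if segment not in SEGMENT_LANDMARKS:
        raise InputError(f"unknown segment {segment!r}")
    for name in SEGMENT_LANDMARKS[segment]:
        if name not in landmarks:
            raise MissingLandmarkError(name, f"{segment} frame")

    if segment in ("femur", "tibia"):
        if segment == "femur":
            a, b, top = landmarks.position("ME"), landmarks.position("LE"), landmarks.position("FHC")
        else:
            a, b, top = landmarks.position("MM"), landmarks.position("LM"), landmarks.position("TT")
        origin = 0.5 * (a + b)
        y = _unit(top - origin, f"{segment} y-axis")
        ml = b - a
        x_raw = ml - (ml @ y) * y
        if np.linalg.norm(x_raw) <= 1e-9 * max(np.linalg.norm(ml), 1.0):
            raise DegenerateGeometryError(f"{segment}: epicondyle/malleolus line parallel to y-axis")
        x = _unit(x_raw, f"{segment} x-axis")
        z = np.cross(x, y)
        return Frame(origin, x, y, z)

    lasis, rasis = landmarks.position("LASIS"), landmarks.position("RASIS")
    lpsis, rpsis = landmarks.position("LPSIS"), landmarks.position("RPSIS")
    origin = 0.5 * (lasis + rasis)
    z = _unit(rasis - lasis, "pelvis z-axis")
    ant = origin - 0.5 * (lpsis + rpsis)
    x_raw = ant - (ant @ z) * z
    if np.linalg.norm(x_raw) <= 1e-9 * max(np.linalg.norm(ant), 1.0):
        raise DegenerateGeometryError("pelvis: anterior direction parallel to inter-ASIS axis")
    x = _unit(x_raw, "pelvis x-axis")
    y = np.cross(z, x)
    return Frame(origin, x, y, z)
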