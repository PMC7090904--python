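"""Reconstruction accuracy metrics and method comparison statistics.

Error tables are pandas DataFrames with one row per subject and one column
per method (cells in mm or degrees); methods are compared with a
Kruskal-Wallis omnibus rank test followed, when significant, by pairwise
Wilcoxon signed-rank tests with Holm step-down adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import stats

from .errors import DegenerateGeometryError, InputError, MissingLandmarkError
from .geometry import Frame, LandmarkSet, build_segment_frame

__all__ = [
    "AnatomicalMeasures",
    "CompareResult",
    "hjc_error",
    "anatomical_measures",
    "compare_methods",
    "holm_adjust",
    "summarize",
    "method_table",
]


@dataclass(frozen=True)
class AnatomicalMeasures:
    """Axis-based bone morphometrics (degrees, in (−180, 180])."""

    femoral_anteversion: float | None = None
    anat_mech_angle: float | None = None
    tibial_torsion: float | None = None


def _wrap_angle(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def hjc_error(recon_fhc: np.ndarray, truth_fhc: np.ndarray, truth_frame: Frame) -> float:
    """Distance (mm) between reconstructed and true hip joint centres,
    evaluated in the true femoral frame (rigid-invariant by construction)."""
    if truth_frame is None:
        raise InputError("a truth frame is required")
    a = truth_frame.to_local(np.asarray(recon_fhc, dtype=float).reshape(3))
    b = truth_frame.to_local(np.asarray(truth_fhc, dtype=float).reshape(3))
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# anatomical measures


def _shaft_axis(local_v: np.ndarray, y_lo: float, y_hi: float, n_bins: int = 8):
    """Least-squares line through cross-section centroids of the diaphysis."""
    mask = (local_v[:, 1] >= y_lo) & (local_v[:, 1] <= y_hi)
    pts = local_v[mask]
    if len(pts) < 4 * n_bins:
        raise DegenerateGeometryError("too few vertices in the diaphyseal window")
    edges = np.linspace(y_lo, y_hi, n_bins + 1)
    which = np.clip(np.digitize(pts[:, 1], edges) - 1, 0, n_bins - 1)
    centroids = np.array([pts[which == i].mean(axis=0)
                          for i in range(n_bins) if np.any(which == i)])
    if len(centroids) < 3:
        raise DegenerateGeometryError("degenerate diaphyseal sampling")
    c0 = centroids.mean(axis=0)
    _, _, Vt = np.linalg.svd(centroids - c0)
    axis = Vt[0]
    if axis[1] < 0:
        axis = -axis
    return c0, axis


def anatomical_measures(mesh: trimesh.Trimesh,
                        landmarks: LandmarkSet,
                        segment: str,
                        part_labels: np.ndarray | None = None) -> AnatomicalMeasures:
    """Anteversion and anatomical–mechanical axis angle (femur) or torsion
    (tibia) from a bone surface and its landmarks.

    All constructions are carried out in the landmark-derived segment frame,
    so the measures are invariant to rigid motion of mesh + landmarks.
    Femoral measures require an FHC landmark (e.g. from a head sphere fit).
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    if segment == "femur":
        if "FHC" not in landmarks:
            raise MissingLandmarkError("FHC", "femoral measures")
        frame = build_segment_frame(landmarks, "femur")
        local = frame.to_local(verts)
        fhc = frame.to_local(landmarks.position("FHC"))
        L = fhc[1]
        c0, axis = _shaft_axis(local, 0.30 * L, 0.65 * L)
        mech = fhc / np.linalg.norm(fhc)
        am = np.degrees(np.arccos(np.clip(abs(axis @ mech), -1.0, 1.0)))
        # neck axis: FHC minus the shaft line evaluated at the proximal end
        top = c0 + axis * ((0.65 * L - c0[1]) / axis[1])
        neck = fhc - top
        neck_p = neck - (neck @ axis) * axis
        ml = frame.to_local(landmarks.position("LE")) - frame.to_local(landmarks.position("ME"))
        medial = -(ml - (ml @ axis) * axis)
        if np.linalg.norm(neck_p) < 1e-9 or np.linalg.norm(medial) < 1e-9:
            raise DegenerateGeometryError("degenerate neck/condylar projection")
        sin = float(np.cross(medial, neck_p) @ axis)
        cos = float(medial @ neck_p)
        anteversion = np.degrees(np.arctan2(sin, cos))
        return AnatomicalMeasures(femoral_anteversion=_wrap_angle(anteversion),
                                  anat_mech_angle=_wrap_angle(am))

    if segment == "tibia":
        frame = build_segment_frame(landmarks, "tibia")
        local = frame.to_local(verts)
        if part_labels is not None:
            local_t = local[np.asarray(part_labels) == "tibia"]
        else:
            local_t = local
        y_max = local_t[:, 1].max()
        y_min = local_t[:, 1].min()
        sl = local_t[local_t[:, 1] >= y_min + 0.94 * (y_max - y_min)]
        if len(sl) < 6:
            raise DegenerateGeometryError("too few plateau vertices")
        xz = sl[:, [0, 2]] - sl[:, [0, 2]].mean(axis=0)
        _, _, Vt = np.linalg.svd(xz)
        u = Vt[0]
        if u[0] < 0:
            u = -u
        wvec = frame.to_local(landmarks.position("LM")) - frame.to_local(landmarks.position("MM"))
        wxz = wvec[[0, 2]]
        if np.linalg.norm(wxz) < 1e-9:
            raise DegenerateGeometryError("malleolar axis parallel to tibial long axis")
        # external torsion positive: distal mediolateral axis rotated towards
        # the canonical −z relative to the plateau axis
        torsion = np.degrees(np.arctan2(u[1] * wxz[0] - u[0] * wxz[1],
                                        u[0] * wxz[0] + u[1] * wxz[1]))
        return AnatomicalMeasures(tibial_torsion=_wrap_angle(torsion))

    raise InputError(f"unknown segment {segment!r}")


# ---------------------------------------------------------------------------
# statistics


@dataclass
class CompareResult:
    omnibus_p: float
    pairwise: pd.DataFrame | None    # Holm-adjusted p-values, or None


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    if table.isna().any().any():
        raise InputError("error table has missing cells (unpaired subjects)")
    return table


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def compare_methods(table: pd.DataFrame, alpha: float = 0.05) -> CompareResult:
    """Kruskal-Wallis omnibus across methods; if significant, all pairwise
    paired Wilcoxon signed-rank tests with Holm adjustment.

    Exact signed-rank p-values are used for n ≤ 25 without ties, a normal
    approximation with continuity correction otherwise (scipy's policy).
    """
    table = _check_table(table)
    methods = list(table.columns)
    if len(methods) < 2:
        raise InputError("need >= 2 methods")
    if len(table) < 5:
        raise InputError("need >= 5 subjects")
    cols = [table[m].to_numpy(dtype=float) for m in methods]
    flat = np.concatenate(cols)
    if np.all(flat == flat[0]):
        return CompareResult(1.0, None)
    omnibus_p = float(stats.kruskal(*cols).pvalue)
    if omnibus_p >= alpha:
        return CompareResult(omnibus_p, None)
    pairs = [(i, j) for i in range(len(methods)) for j in range(i + 1, len(methods))]
    raw = []
    for i, j in pairs:
        diff = cols[i] - cols[j]
        if np.all(diff == 0):
            raw.append(1.0)
        else:
            raw.append(float(stats.wilcoxon(cols[i], cols[j], method="auto").pvalue))
    adj = holm_adjust(raw)
    P = pd.DataFrame(np.ones((len(methods), len(methods))),
                     index=methods, columns=methods)
    for (i, j), p in zip(pairs, adj):
        P.iloc[i, j] = P.iloc[j, i] = p
    return CompareResult(omnibus_p, P)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range per method (linear-interpolation
    quantiles, IQR = Q3 − Q1)."""
    table = _check_table(table)
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise InputError("empty error table")
    rows = {}
    for m in table.columns:
        v = table[m].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows[m] = {"median": med, "iqr": q3 - q1, "q1": q1, "q3": q3}
    return pd.DataFrame(rows).T


def method_table(long_df: pd.DataFrame, metric: str | None = None) -> pd.DataFrame:
    """Pivot a long-format (subject, method, metric, value) table into the
    subjects × methods wide layout used by the statistics."""
    df = long_df
    if metric is not None:
        df = df[df["metric"] == metric]
    wide = df.pivot(index="subject", columns="method", values="value")
    return _check_table(wide)
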