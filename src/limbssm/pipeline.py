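"""End-to-end study orchestration on a synthetic cohort.

For every subject a shape model is built from all *other* subjects
(leave-one-out), the bone is reconstructed by each requested method, and the
reconstruction is scored by surface RMSE (and hip-centre error for the
femur).  Per-subject failures are logged and skipped rather than aborting the
study; all randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, LimbSSMError
from .evaluation import CompareResult, compare_methods, hjc_error, summarize
from .geometry import Landmark, LandmarkSet, build_segment_frame, fit_sphere, \
    new_mesh, surface_rmse
from .reconstruction import ReconstructionConfig, femoral_head_points, \
    femoral_head_radius, no_correction_offsets, offsets_from_models, \
    pelvis_width_scale, reconstruct_bone_landmarks, reconstruct_skin_landmarks, \
    uniform_scale
from .ssm import StatisticalShapeModel, build_ssm
from .synthetic import SyntheticStudy, make_study

logger = logging.getLogger("limbssm.pipeline")

ALL_METHODS = ("ssm-bone", "ssm-skin", "ssm-skin-nocorr", "uniform", "pelvis-width")
_HEAD_POINT_SIGMA_MM = 10.0   # dispersion assigned to derived head points


@dataclass
class StudyConfig:
    """Configuration of a synthetic reconstruction study."""

    n_subjects: int = 8
    seed: int = 0
    segments: tuple = ("femur",)
    methods: tuple = ALL_METHODS
    n_modes: tuple = (3,)
    offset_source: str = "builtin"     # builtin | fitted
    latent_sd: float = 1.0
    noise_sd: float = 0.1
    digitisation_noise_mm: float = 1.0
    fhc_estimate_sd_mm: float = 8.0
    resolution: int = 800
    mahalanobis_weight: float = 1.0
    alpha: float = 0.05
    output_dir: str | None = None

    def __post_init__(self):
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise InputError(f"unknown methods: {sorted(bad)}")
        if not set(self.n_modes) <= set(range(1, 6)):
            raise InputError("n_modes must be within 1..5")
        if not set(self.segments) <= {"femur", "tibia"}:
            raise InputError("segments must be femur and/or tibia")
        if self.n_subjects < 4:
            raise InputError("need at least 4 subjects")
        if self.offset_source not in ("builtin", "fitted"):
            raise InputError("offset_source must be builtin|fitted")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("segments", "methods", "n_modes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class StudyReport:
    config: StudyConfig
    errors: pd.DataFrame                 # long: subject, segment, method, n_modes, metric, value
    summaries: dict                      # (segment, metric, n_modes) -> summary DataFrame
    statistics: dict                     # (segment, metric, n_modes) -> CompareResult
    failures: list = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failures

    def table(self, segment: str, metric: str = "surface_rmse_mm",
              n_modes: int | None = None) -> pd.DataFrame:
        df = self.errors
        df = df[(df["segment"] == segment) & (df["metric"] == metric)]
        if n_modes is not None:
            df = df[df["n_modes"].isin([n_modes, -1])]
        return df.pivot(index="subject", columns="method", values="value")


def _head_point_indices(ssm: StatisticalShapeModel, head_vertices: np.ndarray,
                        landmarks: LandmarkSet) -> dict[str, int]:
    """Template vertex indices of the S/M/A/P femoral-head surface points."""
    verts = ssm.vertices()
    fhc, _ = fit_sphere(verts[head_vertices])
    lm = LandmarkSet(list(landmarks) + [Landmark("FHC", fhc)])
    frame = build_segment_frame(lm, "femur")
    rel = verts[head_vertices] - fhc
    axes = {"FHS": frame.y_axis, "FHM": -frame.x_axis,
            "FHA": frame.z_axis, "FHP": -frame.z_axis}
    return {name: int(head_vertices[np.argmax(rel @ ax)]) for name, ax in axes.items()}


def _femur_targets_with_head(landmarks: LandmarkSet, fhc: np.ndarray,
                             mean_length: float, surface: str) -> LandmarkSet:
    """Augment GT/LE/ME/FN landmarks with derived head-surface points."""
    lm = LandmarkSet(list(landmarks) + [Landmark("FHC", fhc, surface=surface)])
    frame = build_segment_frame(lm, "femur")
    length = float(np.linalg.norm(fhc - frame.origin))
    r = femoral_head_radius(length, mean_length)
    pts = femoral_head_points(fhc, r, frame)
    out = LandmarkSet(list(landmarks))
    for name, p in pts.items():
        out.add(Landmark(name, p, surface=surface))
    return out


def run_study(config: StudyConfig, study: SyntheticStudy | None = None) -> StudyReport:
    """Execute the leave-one-out reconstruction study defined by ``config``."""
    n = config.n_subjects
    study = study or make_study(n, seed=config.seed, latent_sd=config.latent_sd,
                                noise_sd=config.noise_sd,
                                digitisation_noise_mm=config.digitisation_noise_mm,
                                fhc_estimate_sd_mm=config.fhc_estimate_sd_mm,
                                resolution=config.resolution)
    offset_models = study.offset_models
    if config.offset_source == "fitted":
        from .soft_tissue import fit_offset_models
        from .synthetic import simulate_digitisation
        obs = []
        for s in study.subjects:
            for lm_set, cset in ((s.femur_skin_landmarks, study.femur_set),
                                 (s.shank_skin_landmarks, study.shank_set)):
                for lm in lm_set:
                    bone_pos = (s.femur_vertices if cset is study.femur_set
                                else s.shank_vertices)[cset.landmark_indices[lm.name]]
                    from .soft_tissue import OffsetObservation
                    obs.append(OffsetObservation(
                        lm.name, s.covariates,
                        float(np.linalg.norm(lm.position - bone_pos))))
        offset_models = fit_offset_models(obs)

    rows, failures = [], []
    rec_cfg_base = ReconstructionConfig(mahalanobis_weight=config.mahalanobis_weight,
                                        seed=config.seed)
    model_pw = float(np.mean([s.pelvis_width for s in study.subjects]))

    for segment in config.segments:
        cset = study.femur_set if segment == "femur" else study.shank_set
        mean_femur_len = None
        for s in study.subjects:
            sid = s.subject_id
            try:
                ssm = build_ssm(cset, leave_out=sid)
                assert ssm.n_training == cset.n_shapes - 1, "leave-one-out violated"
                truth_mesh = new_mesh(
                    s.femur_vertices if segment == "femur" else s.shank_vertices,
                    cset.faces)
                bone_lm = (s.femur_bone_landmarks if segment == "femur"
                           else s.shank_bone_landmarks)
                skin_lm = (s.femur_skin_landmarks if segment == "femur"
                           else s.shank_skin_landmarks)

                if segment == "femur":
                    head_idx = _head_point_indices(ssm, study.femur_template.head_vertices,
                                                   ssm_mean_landmarks(ssm))
                    ssm.landmark_indices.update(head_idx)
                    model_lm = ssm_mean_landmarks(ssm)
                    mean_fhc, _ = fit_sphere(
                        ssm.vertices()[study.femur_template.head_vertices])
                    model_lm.add(Landmark("FHC", mean_fhc))
                    mean_femur_len = float(np.linalg.norm(
                        mean_fhc - 0.5 * (model_lm.position("LE") + model_lm.position("ME"))))
                    bone_targets = _femur_targets_with_head(
                        bone_lm, s.fhc_true, mean_femur_len, "bone")
                    skin_targets = _femur_targets_with_head(
                        skin_lm, s.fhc_estimate, mean_femur_len, "skin")
                    scale_bone = LandmarkSet(list(bone_lm) + [Landmark("FHC", s.fhc_true)])
                    scale_skin = LandmarkSet(
                        list(skin_lm) + [Landmark("FHC", s.fhc_estimate, surface="skin")])
                else:
                    model_lm = ssm_mean_landmarks(ssm)
                    bone_targets, skin_targets = bone_lm, skin_lm
                    scale_bone, scale_skin = bone_lm, skin_lm

                for method in config.methods:
                    for m in config.n_modes:
                        cfg = ReconstructionConfig(
                            n_modes=m, mahalanobis_weight=config.mahalanobis_weight,
                            seed=config.seed)
                        if method == "ssm-bone":
                            result = reconstruct_bone_landmarks(ssm, bone_targets, cfg)
                            recon = result.mesh
                        elif method in ("ssm-skin", "ssm-skin-nocorr"):
                            if method == "ssm-skin":
                                offs = offsets_from_models(
                                    skin_targets, offset_models, s.covariates,
                                    default=(0.0, _HEAD_POINT_SIGMA_MM))
                            else:
                                offs = no_correction_offsets(skin_targets.names)
                            result = reconstruct_skin_landmarks(ssm, skin_targets, offs, cfg)
                            recon = result.mesh
                        elif method == "uniform":
                            recon = uniform_scale(ssm.instance(), model_lm,
                                                  scale_skin, segment).mesh
                        else:  # pelvis-width
                            recon = pelvis_width_scale(ssm.instance(), model_lm,
                                                       scale_skin, s.pelvis_width,
                                                       model_pw, segment).mesh
                        rmse = surface_rmse(recon, truth_mesh)
                        scalar_m = m if method.startswith("ssm") else -1
                        rows.append({"subject": sid, "segment": segment,
                                     "method": method, "n_modes": scalar_m,
                                     "metric": "surface_rmse_mm", "value": rmse})
                        if segment == "femur":
                            rec_fhc, _ = fit_sphere(
                                np.asarray(recon.vertices)[study.femur_template.head_vertices])
                            truth_frame = build_segment_frame(
                                LandmarkSet(list(bone_lm) + [Landmark("FHC", s.fhc_true)]),
                                "femur")
                            rows.append({"subject": sid, "segment": segment,
                                         "method": method, "n_modes": scalar_m,
                                         "metric": "hjc_error_mm",
                                         "value": hjc_error(rec_fhc, s.fhc_true,
                                                            truth_frame)})
                        if method in ("uniform", "pelvis-width"):
                            break  # scaling methods do not depend on n_modes
            except LimbSSMError as exc:
                logger.warning("subject %s (%s) failed: %s", sid, segment, exc)
                failures.append({"subject": sid, "segment": segment, "error": str(exc)})

    errors = pd.DataFrame(rows)
    summaries, statistics = {}, {}
    if len(errors):
        for segment in config.segments:
            for metric in errors.loc[errors["segment"] == segment, "metric"].unique():
                for m in config.n_modes:
                    df = errors[(errors["segment"] == segment)
                                & (errors["metric"] == metric)
                                & (errors["n_modes"].isin([m, -1]))]
                    wide = df.pivot(index="subject", columns="method", values="value")
                    if wide.isna().any().any():
                        continue
                    summaries[(segment, metric, m)] = summarize(wide)
                    if wide.shape[1] >= 2 and wide.shape[0] >= 5:
                        statistics[(segment, metric, m)] = compare_methods(
                            wide, alpha=config.alpha)
    report = StudyReport(config, errors, summaries, statistics, failures)
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


def ssm_mean_landmarks(ssm: StatisticalShapeModel) -> LandmarkSet:
    """Named landmarks of the model mean shape (from the vertex map)."""
    verts = ssm.vertices()
    return LandmarkSet.from_points(
        {n: verts[i] for n, i in ssm.landmark_indices.items()}, surface="bone")


def _write_report(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.errors.to_csv(out_dir / "errors.csv", index=False)
    payload = {"config": asdict(report.config), "failures": report.failures,
               "summaries": {}, "statistics": {}}
    for key, summ in report.summaries.items():
        payload["summaries"]["/".join(map(str, key))] = json.loads(summ.to_json())
    for key, res in report.statistics.items():
        payload["statistics"]["/".join(map(str, key))] = {
            "omnibus_p": res.omnibus_p,
            "pairwise": None if res.pairwise is None else json.loads(res.pairwise.to_json()),
        }
    (out_dir / "report.json").write_text(json.dumps(payload, indent=1))
    logger.info("study report written to %s", out_dir)
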