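"""Skin-to-bone digitisation offset models.

A landmark palpated on the skin sits some millimetres above the bony point
beneath it.  This module characterises that offset per landmark as a linear
function of simple anthropometrics (height, mass, age, gender, BMI) and, when
the linear model explains too little variance, as a plain population mean.
The fitted (or published) models feed the soft-tissue-corrected likelihood
used for shape-model fitting from skin landmarks.

Model selection per landmark: fit the full five-covariate linear model; if its
adjusted R² is ≤ 0.5 fall back to the sample mean/SD; otherwise greedily
remove single terms while the AIC decreases, then drop all terms whose
marginal F-test p-value is ≥ 0.05 and refit once.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, InputError

__all__ = [
    "COVARIATE_TERMS",
    "Covariates",
    "OffsetObservation",
    "OffsetModel",
    "fit_offset_models",
    "predict_offset",
    "builtin_offset_models",
    "CREST_ALIASES",
    "save_offset_models",
    "load_offset_models",
]

COVARIATE_TERMS = ("height", "mass", "age", "gender", "bmi")


@dataclass
class Covariates:
    """Subject anthropometrics.  height in m, mass in kg, age in years,
    gender coded 0 = male / 1 = female, BMI in kg/m² (derived when absent)."""

    height: float
    mass: float
    age: float
    gender: int
    bmi: float | None = None

    def __post_init__(self):
        if not 1.0 < self.height < 2.5:
            raise InputError(f"implausible height {self.height} m")
        if not 20 < self.mass < 250:
            raise InputError(f"implausible mass {self.mass} kg")
        if self.gender not in (0, 1):
            raise InputError("gender must be 0 (male) or 1 (female)")
        derived = self.mass / self.height ** 2
        if self.bmi is None:
            self.bmi = derived
        elif abs(self.bmi - derived) > 0.1:
            raise InputError(f"BMI {self.bmi:.2f} inconsistent with mass/height² "
                             f"= {derived:.2f}")

    def term(self, name: str) -> float:
        if name not in COVARIATE_TERMS:
            raise InputError(f"unknown covariate {name!r}")
        return float(getattr(self, name))

    def as_dict(self) -> dict[str, float]:
        return {t: self.term(t) for t in COVARIATE_TERMS}


@dataclass(frozen=True)
class OffsetObservation:
    landmark: str
    covariates: Covariates
    offset_mm: float

    def __post_init__(self):
        if self.offset_mm < 0:
            raise InputError("offset must be >= 0 mm")


@dataclass
class OffsetModel:
    """Per-landmark offset predictor.

    ``kind`` is ``regression`` (intercept + retained covariate terms) or
    ``mean_fallback`` (intercept only = sample mean).  ``residual_sd`` is the
    dispersion used as sigma in the skin-landmark fitting likelihood.
    """

    landmark: str
    kind: str
    coefficients: dict[str, float]
    residual_sd: float
    adjusted_r2: float | None = None
    sample_mean: float | None = None
    sample_sd: float | None = None

    def __post_init__(self):
        if self.kind not in ("regression", "mean_fallback"):
            raise InputError("kind must be regression|mean_fallback")
        if self.residual_sd <= 0:
            raise InputError("residual_sd must be > 0")
        if "intercept" not in self.coefficients:
            raise InputError("coefficients must include an intercept")
        if self.kind == "mean_fallback" and len(self.coefficients) != 1:
            raise InputError("mean_fallback models carry only an intercept")


def predict_offset(model: OffsetModel,
                   cov: Covariates | Mapping[str, float]) -> tuple[float, float]:
    """Predicted offset distance (mm, clipped at 0) and its sigma (mm)."""
    d = model.coefficients["intercept"]
    for term, coef in model.coefficients.items():
        if term == "intercept":
            continue
        if isinstance(cov, Covariates):
            value = cov.term(term)
        else:
            if term not in cov:
                raise InputError(f"covariate {term!r} required by the "
                                 f"{model.landmark} model is missing")
            value = float(cov[term])
        d += coef * value
    return max(0.0, float(d)), float(model.residual_sd)


# ---------------------------------------------------------------------------
# fitting


def _design(df: pd.DataFrame, terms: Iterable[str]) -> pd.DataFrame:
    X = df[list(terms)].astype(float)
    return sm.add_constant(X, has_constant="add")


def _fit_ols(df: pd.DataFrame, terms: list[str]):
    return sm.OLS(df["offset_mm"].astype(float), _design(df, terms)).fit()


def fit_offset_models(observations: Iterable[OffsetObservation],
                      r2_gate: float = 0.5,
                      alpha: float = 0.05,
                      min_observations: int = 10) -> dict[str, OffsetModel]:
    """Fit an :class:`OffsetModel` for every landmark present in the data."""
    rows = [{"landmark": o.landmark, "offset_mm": o.offset_mm, **o.covariates.as_dict()}
            for o in observations]
    if not rows:
        raise InputError("no observations")
    data = pd.DataFrame(rows)
    out: dict[str, OffsetModel] = {}
    for landmark, df in data.groupby("landmark", sort=True):
        n = len(df)
        if n < min_observations:
            raise InputError(f"landmark {landmark}: need >= {min_observations} "
                             f"observations, got {n}")
        X_full = _design(df, list(COVARIATE_TERMS)).to_numpy()
        if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            raise FitError(f"singular design matrix for landmark {landmark}")
        full = _fit_ols(df, list(COVARIATE_TERMS))
        if not (full.rsquared_adj > r2_gate):
            mean = float(df["offset_mm"].mean())
            sd = float(df["offset_mm"].std(ddof=1))
            out[landmark] = OffsetModel(landmark, "mean_fallback",
                                        {"intercept": mean}, residual_sd=max(sd, 1e-12),
                                        adjusted_r2=float(full.rsquared_adj),
                                        sample_mean=mean, sample_sd=sd)
            continue

        # greedy backward elimination on AIC
        terms = list(COVARIATE_TERMS)
        res = full
        while len(terms) > 1:
            candidates = [(t, _fit_ols(df, [u for u in terms if u != t])) for t in terms]
            t_best, r_best = min(candidates, key=lambda c: c[1].aic)
            if r_best.aic < res.aic:
                terms.remove(t_best)
                res = r_best
            else:
                break

        # marginal (type-III style) F-tests; single-df F == squared t
        weak = [t for t in terms if res.pvalues[t] >= alpha]
        terms = [t for t in terms if t not in weak]
        res = _fit_ols(df, terms) if terms else sm.OLS(
            df["offset_mm"].astype(float),
            np.ones((n, 1))).fit()

        coefs = {"intercept": float(res.params.iloc[0] if not terms else res.params["const"])}
        for t in terms:
            coefs[t] = float(res.params[t])
        resid_sd = float(np.sqrt(res.mse_resid))
        out[landmark] = OffsetModel(landmark, "regression", coefs,
                                    residual_sd=max(resid_sd, 1e-12),
                                    adjusted_r2=float(res.rsquared_adj),
                                    sample_mean=float(df["offset_mm"].mean()),
                                    sample_sd=float(df["offset_mm"].std(ddof=1)))
    return out


# ---------------------------------------------------------------------------
# published thigh/shank models

# TC1-TC3 of the published table are the anterior tibial crest points
CREST_ALIASES = {"TC1": "ATP", "TC2": "ATM", "TC3": "ATD"}

# landmark: (mean mm, SD mm, full-model R², regression coefficients or None)
_PUBLISHED_OFFSETS = {
    "GT": (41.99, 16.72, 0.61, {"intercept": 16.2, "gender": -32.01, "mass": 0.65}),
    "FN": (27.73, 3.95, 0.33, None),
    "LE": (15.76, 4.49, 0.54, {"intercept": 2.7, "gender": -5.83, "bmi": 0.71}),
    "ME": (18.60, 6.96, 0.71, {"intercept": 2.89, "gender": -14.11, "mass": 0.35}),
    "TT": (7.74, 2.99, 0.13, None),
    "ATP": (6.54, 2.14, 0.39, None),
    "ATM": (5.95, 1.74, 0.40, None),
    "ATD": (7.02, 2.49, 0.33, None),
    "TN": (14.35, 2.40, 0.23, None),
    "LM": (4.81, 0.98, 0.26, None),
    "MM": (5.49, 0.90, 0.17, None),
}


def builtin_offset_models() -> dict[str, OffsetModel]:
    """The published thigh/shank offset models.

    GT, LE and ME carry regression equations in gender and body mass / BMI;
    the remaining landmarks use their sample mean and SD.  For the regression
    landmarks only the sample SD and the full-model R² are published, so the
    fitting sigma is the implied residual SD ``sd·sqrt(1 − R²)``.
    """
    out = {}
    for name, (mean, sd, r2, coefs) in _PUBLISHED_OFFSETS.items():
        if coefs is None:
            out[name] = OffsetModel(name, "mean_fallback", {"intercept": mean},
                                    residual_sd=sd, adjusted_r2=None,
                                    sample_mean=mean, sample_sd=sd)
        else:
            out[name] = OffsetModel(name, "regression", dict(coefs),
                                    residual_sd=sd * math.sqrt(1.0 - r2),
                                    adjusted_r2=r2, sample_mean=mean, sample_sd=sd)
    return out


def resolve_offset_model(models: Mapping[str, OffsetModel], landmark: str) -> OffsetModel:
    """Look up a model accepting the TC1/TC2/TC3 aliases for ATP/ATM/ATD."""
    name = CREST_ALIASES.get(landmark, landmark)
    if name not in models:
        raise InputError(f"no offset model for landmark {landmark!r}")
    return models[name]


# ---------------------------------------------------------------------------
# I/O


def observations_from_csv(path) -> list[OffsetObservation]:
    """CSV columns: landmark,height,mass,age,gender,bmi,offset_mm."""
    df = pd.read_csv(path)
    obs = []
    for _, r in df.iterrows():
        bmi = r.get("bmi")
        cov = Covariates(float(r["height"]), float(r["mass"]), float(r["age"]),
                         int(r["gender"]),
                         None if bmi is None or pd.isna(bmi) else float(bmi))
        obs.append(OffsetObservation(str(r["landmark"]), cov, float(r["offset_mm"])))
    return obs


def save_offset_models(models: Mapping[str, OffsetModel], path) -> None:
    payload = {"version": 1, "models": [
        {"landmark": m.landmark, "kind": m.kind, "coefficients": m.coefficients,
         "residual_sd": m.residual_sd, "adjusted_r2": m.adjusted_r2,
         "sample_mean": m.sample_mean, "sample_sd": m.sample_sd}
        for m in models.values()]}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_offset_models(path) -> dict[str, OffsetModel]:
    data = json.loads(Path(path).read_text())
    if data.get("version") != 1:
        raise InputError("unsupported offset model file version")
    return {m["landmark"]: OffsetModel(m["landmark"], m["kind"], m["coefficients"],
                                       m["residual_sd"], m.get("adjusted_r2"),
                                       m.get("sample_mean"), m.get("sample_sd"))
            for m in data["models"]}
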