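# limbssm

Reconstruction of femur and tibia/fibula bone surfaces from a handful of
digitised anatomical landmarks, using statistical shape models (SSMs) with an
explicit correction for the soft tissue between skin and bone.

## Who this is for

Gait labs and musculoskeletal modellers usually cannot MRI every participant.
What they *can* do is palpate and digitise a few bony landmarks (greater
trochanter, epicondyles, malleoli, ...) with a tracked pointer. This package
turns such sparse, skin-biased point sets into full subject-specific bone
surfaces and hip joint centre (HJC) estimates, and quantifies how much better
that is than conventional linear scaling of a template bone.

## The method

A point distribution model is built from corresponded bone surfaces: after
rigid-only generalised Procrustes alignment, PCA of the stacked vertex
coordinates gives a mean shape `p̄`, orthonormal modes `Φ` and variances
`λ_k`. An instance is

    p(b) = p̄ + Φ diag(√λ) b,   with scores b in SD units, |b_k| ≤ 3.

Reconstruction fits pose `(A, r)` and scores `b` simultaneously
(bound-constrained L-BFGS-B) so that model surface points `x_i = A p_i(b) + r`
meet the measured landmarks `s_i`:

* **bone landmarks** minimise `Σ d_i² + w·Σ b_k²` with `d_i = ‖x_i − s_i‖`;
* **skin landmarks** minimise the Gaussian negative log-likelihood
  `Σ [ ½ log σ_i² + (d_i − d̂_i)² / (2σ_i²) ] + w·Σ b_k²`, where `d̂_i` and
  `σ_i` come from per-landmark linear regressions of the skin-to-bone offset
  on height, mass, age, gender and BMI (selected by an adjusted-R² > 0.5 gate,
  backward AIC elimination and an α = 0.05 ANOVA prune).

The built-in offset table includes, e.g., GT: `16.2 − 32.01·gender +
0.65·mass` mm. The HJC is predicted from pelvic landmarks via
`(−0.24·PD − 9.9, −0.30·PW − 10.9, 0.33·PW + 7.3)` mm in the pelvis frame,
and the femoral head radius by scaling 21.1 mm with the femur-length ratio.
Baselines: isotropic segment-length scaling and pelvis-width planar scaling.
Everything is exercised end-to-end on a seeded synthetic long-bone population
with known low-rank shape variation and covariate-driven skin offsets.

## Worked example

```python
from limbssm.pipeline import StudyConfig, run_study

cfg = StudyConfig(n_subjects=8, seed=1, segments=("femur",), n_modes=(3,))
report = run_study(cfg)
print(report.summaries[("femur", "surface_rmse_mm", 3)].round(2))
```

which prints (surface RMSE in mm, 8 synthetic subjects, leave-one-out models):

```
                 median   iqr    q1    q3
pelvis-width       2.40  0.42  2.30  2.71
ssm-bone           0.29  0.20  0.21  0.40
ssm-skin           1.82  0.89  1.39  2.29
ssm-skin-nocorr    3.83  5.21  2.69  7.91
uniform            2.47  0.66  2.28  2.94
```

Reading it: fitting the model to exact bone landmarks nearly recovers the
true surface (0.29 mm); fitting to *skin* landmarks works only when the
predicted soft-tissue offsets are subtracted in the likelihood (1.82 mm
corrected vs 3.83 mm uncorrected — the greater trochanter alone sits ~40 mm
above the bone); both shape-model routes beat plain linear scaling
(2.4–2.5 mm). Median HJC errors follow the same ordering (0.9 / 7.4 / 9.9 /
16.9 / 16.5 mm).

The same machinery is scriptable from the shell:

```bash
limbssm synth --n 8 --seed 42 --out cohort/          # synthetic cohort
limbssm fit-offsets observations.csv --out offsets.json
limbssm reconstruct --model model.ssm.npz --landmarks lm.csv \
    --method ssm-skin --cov subject.yaml --modes 3 --out recon.ply
limbssm rmse recon.ply segmented.ply
```

## Layout

| module | contents |
| --- | --- |
| `limbssm.geometry` | meshes, landmarks, rigid/ICP registration, sphere fit, anatomical frames |
| `limbssm.proximity` | exact closest-point-on-surface queries |
| `limbssm.ssm` | correspondence, Procrustes alignment, PCA models, quality metrics |
| `limbssm.soft_tissue` | offset observations, regression fitting/selection, published table |
| `limbssm.reconstruction` | landmark fitting (both objectives), scaling baselines, HJC regression |
| `limbssm.evaluation` | surface/HJC errors, anatomical measures, Kruskal-Wallis + Wilcoxon-Holm |
| `limbssm.synthetic` | parametric bone generator, latent populations, simulated digitisation |
| `limbssm.pipeline` | leave-one-out study orchestration and reports |
| `limbssm.cli` | `limbssm` command-line interface |

See `docs/methods.md` for modelling assumptions, parameter defaults and known
limitations.
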