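# crossslope

Cross-slope terrain prediction from residual-limb gait signals.

People walking with a transtibial (below-knee) prosthesis routinely meet
surfaces that tilt sideways — cambered sidewalks, trail cross-slopes. A
semi-active prosthetic foot could adapt its coronal-plane stiffness to
such terrain if, by the end of swing, it knew what the foot was about to
land on. This package implements the offline analysis behind that idea:
classify the upcoming cross-slope (everting −15°, flush 0°, inverting
+15°) from short windows of residual-limb kinematics and kinetics taken
in mid-swing, and find out which of the candidate sensor signals the
classifier actually needs.

For biomechanists and rehab-engineering researchers who want a tested,
reproducible version of this pipeline: windowed feature extraction, a
from-scratch LDA classifier, wrapper feature selection, and the full
evaluation harness, driven by a synthetic stride generator so everything
runs without human-subject data.

## Method

One stride's signals (sampled at 120 Hz, low-pass filtered, body-weight-
and swing-normalized) are cut into overlapping 150 ms windows advancing
one sample at a time. Windows anchored to the residual-limb heel strike
at start times in [−250, −75] ms are *mid-swing* and feed the
classifier. Each window contributes, per signal, its mean, sample sd,
max and min (mean and sd only for GRF/COP), giving x ∈ ℝ¹²⁴ for the full
signal inventory or x ∈ ℝ²⁴ for the in-pylon-sensor-only inventory.

Terrain class c is predicted by maximizing the linear discriminant

    δ_c(x) = xᵀ Σ_λ⁻¹ μ_c − ½ μ_cᵀ Σ_λ⁻¹ μ_c + ln π_c

with class means μ_c, pooled within-class covariance Σ (shrunk toward a
spherical target by λ, default 10⁻⁴), and priors π_c. Signals are ranked
by sequential forward selection (SFS: greedily add the
accuracy-maximizing signal) and sequential backward selection (SBS:
greedily drop the least useful one), scored by leave-one-trial-out
cross-validation or on fixed test sets. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

```python
from crossslope import (SignalInventory, build_feature_matrix, loocv,
                        preprocess_trial, Dataset)
from crossslope.selection import sfs
from crossslope.synthetic import preset_discriminative, generate_dataset

cfg = preset_discriminative(seed=1)          # 3 subjects × 3 terrains × 5 trials
ds = generate_dataset(cfg)
ds = Dataset([preprocess_trial(t) for t in ds.trials], role=ds.role)
m = build_feature_matrix(ds, SignalInventory.full_with_ips())
print(len(m), len(m.feature_names))          # 990 124

cm, rep = loocv(m, signals=["ankle_inversion_angvel",
                            "foot_vert_velocity", "foot_ml_angvel"])
print(round(rep.overall, 4), [round(v, 4) for v in rep.per_class_range])
# 0.9677 [0.9182, 1.0]
```

990 mid-swing windows (45 trials × 22 windows) of 124 features each; the
three signals that carry terrain information in this preset recover the
cross-slope in 96.8% of windows under leave-one-trial-out
cross-validation, with per-terrain accuracy between 91.8% and 100%.

The same workflow is packaged as numbered drivers:

```bash
python analysis/01_simulate_cohort.py --seed 1   # write trials + manifests
python analysis/02_rank_ips_signals.py --seed 1  # SFS/SBS on in-pylon channels
python analysis/03_rank_full_inventory.py --seed 1  # SFS/SBS on all 34 signals
python analysis/04_accuracy_report.py --seed 1   # accuracy tables + curves
```

Outputs land under `results/` (rankings, accuracy tables in the
All/Ind. layout, accuracy-vs-signal-count curves for every pick×measure
combination). On the seed-1 cohort, both SFS and SBS over the full
inventory place the three informative signals at ranks 1–3.

There is also a CLI for the individual stages
(`crossslope simulate|features|train|evaluate|select|run|report`).

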