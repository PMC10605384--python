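# parascint

Quantitative analysis of dual-phase ⁹⁹ᵐTc-MIBI parathyroid scintigraphy for
primary hyperparathyroidism (PHPT), built as a reusable, fully tested
pipeline. It is aimed at nuclear-medicine researchers who want to relate
imaging-derived parameters of a single parathyroid adenoma to the hormonal
and biochemical severity of the disease — and at methodologists who need a
synthetic test-bench for those measurements, since patient imaging of this
kind is rarely shareable.

## What it computes

**Planar dual-phase parameters.** From early (~10 min) and delayed (~90 min)
anterior views, with a lesion ROI mirrored across the neck midline onto the
contralateral thyroid and (with a caudal offset) the contralateral background:

- lesion/background ratio `LBR = mean(lesion) / mean(background)` (eLBR, dLBR)
- lesion/thyroid ratio `LTR = mean(lesion) / mean(thyroid)` (eLTR, dLTR)
- retention index `RI = (eLTR − dLTR) / eLTR`

**SPECT volumetrics.** The adenoma volume Svol (cm³) is the connected
component of voxels at or above 40% of a local peak (the hottest voxel in a
search sphere around an operator seed), times the voxel volume; the
`PTH/Svol` composite (ng/L per cm³) divides serum parathormone by Svol as a
proxy for secretory activity per unit of metabolically active volume.

**Cohort statistics.** Severity grouping on serum calcium (mild
[10.5, 11.5) vs marked ≥ 11.5 mg/dL), Shapiro-Wilk-gated descriptives
(mean ± SD vs median (min–max)), Spearman correlations, t / Mann-Whitney U
group comparisons, empirical ROC curves with DeLong 95% CIs, Youden-index
optimal cut-offs (`J = sensitivity + specificity − 1`), and ICC(2,1)
reliability.

**Synthetic test-bench.** A digital neck phantom (adenoma + two thyroid
lobes, mono-exponential per-compartment washout, Gaussian PSF, Poisson
counting noise, planar projection) and a Gaussian-copula cohort simulator
that reproduces published marginal summaries and rank-correlation structure,
with `PTH/Svol` and `RI` always computed per record from their definitions.

## Worked example

```python
import numpy as np
import parascint as ps

spec = ps.default_phantom_spec(seed=11)
noisy_e = ps.apply_noise(ps.build_activity_volume(spec, "early"), seed=11)
noisy_d = ps.apply_noise(ps.build_activity_volume(spec, "delayed"), seed=12)

rows, cols = np.meshgrid(range(33, 38), range(30, 35), indexing="ij")
lesion = ps.Roi(np.column_stack([rows.ravel(), cols.ravel()]))
params = ps.quantify_patient_planar(
    ps.project_planar(noisy_e), ps.project_planar(noisy_d),
    lesion, midline_column=40,
)
print({k: round(v, 3) for k, v in params.as_dict().items()})

res = ps.quantify_patient_spect(noisy_d, seed_point=(32, 45, 35), pth=128.3)
print(f"Svol = {res.svol:.3f} cm^3, PTH/Svol = {res.pth_svol:.1f} ng/L/cm^3")

cohort = ps.simulate_cohort(ps.default_cohort_spec(n=70, seed=11))
bundle = ps.run_study_analysis(cohort)
roc = bundle["roc_table"]["pth_svol"]
print(f"PTH/Svol AUC = {roc.auc:.2f}, cutoff {roc.cutoff_text}, J = {roc.youden_j:.2f}")
```

prints

```
{'eLBR': 1.28, 'dLBR': 1.342, 'eLTR': 1.156, 'dLTR': 1.257, 'RI': -0.087}
Svol = 2.800 cm^3, PTH/Svol = 45.8 ng/L/cm^3
PTH/Svol AUC = 0.84, cutoff >95.06, J = 0.64
```

The negative RI says the lesion retained tracer relative to the thyroid on
the delayed view (the phantom's adenoma washes out more slowly); Svol
overestimates the 1.41 cm³ ground-truth ellipsoid because the 4 mm PSF
spreads counts past the 40% contour (the partial-volume effect — see
`docs/methods.md`); the ROC block reports how well `PTH/Svol` separates the
simulated mild from marked hypercalcemia groups, with the Youden-optimal
cut-off on the marker scale. Segmentation is run on the *delayed* volume:
by then the thyroid has washed out below the 40% level, so the adenoma
isocontour no longer merges with the adjacent lobe.

The same stages are available as a CLI:

```sh
parascint simulate --seed 3 --n 70 --out artifacts/
parascint quantify-planar --early artifacts/planar_early.nii \
    --delayed artifacts/planar_delayed.nii --roi lesion.json --midline 40 \
    --out params.json
parascint segment-spect --volume artifacts/spect_delayed.nii \
    --seed-voxel 32,45,35 --threshold 40 --search-mm 15 --out svol.json
parascint analyze --cohort artifacts/cohort.csv --out analysis.json
parascint run --seed 3 --n 70 --out artifacts/   # all stages
```

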