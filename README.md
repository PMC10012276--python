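# kbdose

Knowledge-based dose-distribution prediction for radiotherapy planning,
combining **distance** and **anatomical** information, with a synthetic
head-and-neck phantom cohort so the whole method runs without patient data.

## The problem

Inverse treatment planning (IMRT/VMAT) needs per-patient dose objectives,
and knowledge-based planning derives them by predicting the achievable 3D
dose distribution from the patient's anatomy. A voxel's dose in normal
tissue is strongly governed by its proximity to the planning target volume
(PTV), so besides the usual anatomical inputs — CT and an integer-labelled
structure map of targets and organs at risk (OARs) — this package computes
a **DPTV map**: for every normal-tissue voxel *i* inside the body,

```
DPTV_i = min { ‖x_i − x_p‖ : p ∈ PTV }          (mm, full 3D, spacing-aware)
```

with PTV voxels and voxels outside the body coded 0. Two slice-wise
fully-convolutional regressors are then compared:

* **ANAT** — 2-channel input (CT, structure map);
* **COM** — 3-channel input (CT, structure map, DPTV map).

Both use the same residual encoder (7×7/64 stem, max-pool, four stages of
1×1→3×3→1×1 bottleneck blocks, default depths 3/4/23/5, dilated to hold a
1/8 output stride) and a fractionally-strided deconvolution decoder that
restores full resolution. Evaluation uses voxel mean error (ME) and mean
absolute error (MAE) as percent of prescription, DVH metrics (mean dose,
D5%), the Dice coefficient of isodose volumes from 1–60 Gy, and two-sided
paired t-tests between models under k-fold cross-validation.

Because clinical cohorts are private, the `phantom` module generates
synthetic cases — body, PTV with an interior boost (60.06 / 69.96 Gy in 33
fractions), 21 OARs — and a parametric ground-truth dose that plateaus in
the targets and decays exponentially with DPTV outside them, with
OAR-specific sparing and near-zero dose out of field. Distance is
*sufficient information* for this dose by construction, which makes the
COM-vs-ANAT contrast a controlled experiment.

## Worked example

```python
from kbdose import (PhantomSpec, DoseEngineParams, generate_phantom,
                    simulate_dose, compute_dptv, DosePredictor)
from kbdose.evaluation import mean_absolute_error

case = generate_phantom(PhantomSpec(seed=3))          # 64x64x16 @ (4,4,3) mm
dptv = compute_dptv(case.rois.masks["PTV"], case.rois.body_mask, case.spacing)
case.dose_gt = simulate_dose(case, DoseEngineParams(noise_sd=0.0), dptv)

est = DosePredictor(mode="COM", loss="mae", epochs=200, lr=5e-3, seed=0)
est.fit([case])                                        # memorize one case
pred = est.predict(case)
mae = mean_absolute_error(pred, case.dose_gt, case.rois.body_mask, 69.96)
print(f"body MAE {mae:.2f}% of prescription")
```

prints (about two minutes on one CPU):

```
body MAE 0.98% of prescription
```

i.e. the distance-aware model reproduces its own training dose to within
~1% of the 69.96 Gy prescription — the sanity floor for the architecture.

The full comparison (40-case cohort, 2-fold cross-validation, both modes)
runs from the shell:

```bash
kbdose run --out results/exp --seed 1
```

and ends with a markdown report of per-ROI ME/MAE, the isodose-DSC table
and the paired tests. On seed 1 the pooled test-set body MAE is 7.2% for
the COM model versus 12.5% for ANAT — the distance channel carries exactly
the information the phantom dose is built from, and the network uses it.

Other CLI entry points: `kbdose phantom` (write a NIfTI cohort),
`kbdose features` (DPTV + structure maps for one case), `kbdose train` /
`kbdose predict` (single-model workflows), `kbdose summarize`.

## Layout

| module | contents |
|---|---|
| `kbdose.phantom` | synthetic cases, cohort generator, parametric dose engine |
| `kbdose.features` | DPTV maps, structure-map encoding, input stacks |
| `kbdose.nn` | NumPy conv-net layers with manual backprop |
| `kbdose.model` | the FCN dose predictor (sklearn-style estimator), k-fold split |
| `kbdose.evaluation` | ME/MAE, isodose DSC, DVH, D5%, paired t-tests |
| `kbdose.pipeline` | config-driven experiment runner and reporting |

See `docs/methods.md` for the modelling choices and their rationale.
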