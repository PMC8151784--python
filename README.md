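# stablerec

Early prediction of three-year breast-cancer recurrence (BCR) for patients
treated with neoadjuvant chemotherapy, from paired DCE-MRI examinations:
one pre-treatment exam (**T1**) and one early-treatment exam (**T2**,
after the first chemotherapy cycle). The package is aimed at imaging
researchers who want a tested, fully reproducible implementation of a
transfer-learning radiomics pipeline with resampling-based feature
stability selection — including a synthetic cohort generator so the whole
method runs and validates with no clinical data download.

## The method

Patients are labeled by the recurrence-free-survival indicator: RFSi (no
recurrence within three years of chemotherapy initiation) vs non-RFSi
(recurrence; the positive class). For each patient:

1. **ROI standardization** — the lesion mask's largest 8-connected
   component is localized, a square window of side equal to the tumor's
   largest diameter (LD) is cropped around its centroid, and the crop is
   resized to 227×227 (Keys bicubic, a = −0.5).
2. **Low-level CNN features** — each ROI passes through an AlexNET-style
   conv → ReLU → local response normalization → max-pool chain, twice;
   the flattened second pooling output (13×13×256) gives 43 264 features
   per ROI, 86 528 per patient (`x = [x_T1 ; x_T2]`).
3. **Dynamic feature selection** — per leave-one-patient-out (LOO) fold,
   iterate: draw 10 class-stratified subsets of 90% of the training
   patients; on each, keep features with two-sided Wilcoxon rank-sum
   p < 0.001, then re-rank survivors by Gini importance of a 100-tree
   forest; union the 10 selections; intersect unions cumulatively across
   iterations until fewer than 10 features are discarded for ≥95% of
   folds (max 20 iterations).
4. **Optimal subset of features (OSF)** — the patient-by-patient
   intersection of all per-fold sets: features stable under every
   resampling, iteration, and fold.
5. **Classification** — a linear-kernel SVM (C = 1) on the z-scored
   selected features, optionally augmented with four clinical covariates
   (age, ER, PgR, HER2+); evaluated by pooled-LOO ROC/AUC, accuracy,
   sensitivity (non-RFSi recall) and specificity (RFSi recall), or on an
   independent test set guarded against selection leakage by provenance
   checks.

The selection construction is deliberately brutal: a feature enters the
OSF only by surviving the union-then-intersect gauntlet of every fold and
iteration (~200+ resampling rounds), which drives the retention of
borderline features to zero while genuinely informative features pass
unscathed. `docs/methods.md` details the model, the embedded-threshold
design, and what the synthetic generator does and does not emulate.

## Worked example

```python
from stablerec import CohortConfig, RunConfig, SelectionConfig, run

config = RunConfig(
    preset="DSF_T1T2",               # per-fold dynamically selected features
    cohort=CohortConfig(n_patients=20, image_size=96,
                        lesion_diameter_range=(20, 48),
                        t1_effect=1.0, t2_response_effect=0.8),
    selection=SelectionConfig(n_subsets=5, filter_alpha=0.01,
                              max_iterations=2),
    out_dir="runs/demo",
    seed=1,
)
summary = run(config)
print(summary["metrics"])
print(sorted(summary["fold_set_sizes"].values()))
```

prints (about a minute on one core)

```
{'tp': 3, 'fp': 0, 'tn': 15, 'fn': 2, 'accuracy': 0.9,
 'sensitivity': 0.6, 'specificity': 1.0, 'auc': 0.9866666666666667}
[52, 52, 54, 55, 56, 57, 57, 59, 59, 61, 62, 63, 64, 65, 67, 68, 70, 71, 78, 83]
```

Reading: on this 20-patient synthetic cohort (5 non-RFSi / 15 RFSi, with
moderate planted edge-sharpness and treatment-response effects), the
dynamic selection kept 52–83 stable features per LOO fold, and the pooled
held-out SVM scores rank the patients almost perfectly (AUC 0.987): at
decision threshold 0 it catches 3 of 5 recurrences with zero false alarms
among the 15 recurrence-free patients (sensitivity 0.6, specificity 1.0).
The run directory holds `summary.json`, the OSF table with (channel, row,
col) positions and timepoints, per-fold sets, selection traces, and
per-patient decision scores. Identical config + seed reproduces all of
them byte-for-byte.

The demo uses the DSF (per-fold) preset because the OSF — the
*intersection* of all fold sets — is intentionally merciless: CNN
descriptors are highly redundant, and at desk-scale cohorts the
near-duplicate strong features tie-break differently per fold, so their
intersection is typically empty. A stable OSF core is the large-cohort,
many-iteration regime (the `OSF_*` presets behave identically, just with
the fixed intersection set); the acceptance suite demonstrates OSF
recovery at the study's own scale on a surrogate feature space.

The same stages are scriptable from the shell:

```bash
stablerec synth --n-patients 20 --out cohort/
stablerec run --preset DSF_T1T2 --manifest cohort/manifest.csv \
              --alpha 0.01 --max-iterations 2 --seed 1 --out runs/demo
```

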