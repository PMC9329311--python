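# trajbench

Benchmarking deep time-series classifiers on simulated longitudinal
clinical measurements.

## The problem

Clinical prediction models increasingly consume measurement trajectories
from electronic health records — BMI, glucose, blood-pressure series
sampled roughly yearly, at most a handful of points per patient.  Choosing
a classifier architecture for such data is hard to do on real records
alone: true class membership is uncertain, and you cannot turn the knobs
that matter (effect size, dispersion, missingness, visit irregularity,
outcome imbalance).  `trajbench` provides the full loop for doing this on
semi-synthetic data, for methodologists and applied modellers who want to
know *which architecture is robust for data like mine*:

1. **Cohort simulation.** Two-class cohorts are derived from a reference
   trajectory.  *Magnitude* cohorts add one per-individual offset drawn
   from Normal(0, σ) for class 0 and Normal(δ, σ) for class 1.  *Shape*
   cohorts fit the reference on a ten-column orthonormal polynomial basis,
   find the most shape-influential coefficient by a permutation/MSE
   screen, and re-draw that coefficient per individual from class-specific
   normals.  Cohorts are then degraded: exact-count missingness (0-50%),
   scaled-beta visit irregularity, and class imbalance down to 1:4.
2. **Nine classifiers** under one training protocol (Adam, binary
   cross-entropy, lr 1e-3 with 0.92 decay on 3 stagnant epochs, early
   stopping on validation AUC, best-weights restore, successive-halving
   hyperparameter search): MLP, FCNN, TSF-MLP and TSF-CNN on
   time-series-forest interval features (mean/sd/slope of random
   intervals), GAF-CNN on Gramian angular-field images, ResNet, RNN-FCN,
   C-RNN, and a 4-layer Transformer encoder.  The networks run on a small
   numpy autodiff engine bundled with the package.
3. **Evaluation.** AUC with threshold metrics, Friedman rank test with
   Nemenyi critical-difference diagrams across conditions, DeLong's paired
   AUC test with Benjamini-Hochberg FDR correction, and overfitting
   (train − test AUC) summaries.
4. **An observation-window pipeline** for pediatric growth records
   (synthetic generator included): QC by plausibility bounds and modified
   z-scores, local-polynomial smoothing, yearly BMI harmonization, one
   dataset per age window [a, b] ⊆ [2, 12], and DeLong comparison of
   window AUCs against the best window.

See `docs/methods.md` for the model details and the reasoning behind the
design choices.

## Worked example

Simulate one magnitude cohort, train two classifiers, and compare:

```python
import numpy as np
from trajbench import cohort_simulator as cs, model_zoo as mz, reference_profiles as rp

ref = rp.generate_synthetic_references("bmi", n_refs=1, seed=7)[0].prepared()
spec = cs.CohortSpec(variation="magnitude", effect_size=1.75, dispersion=0.6,
                     n_per_class=500, seed=7)
cohort = cs.simulate(ref, spec)
print(f"overlap = {cohort.overlap:.3f}")

policy = mz.TrainPolicy(max_epochs=40, early_stop_patience=8, seed=7)
for arch in ("MLP", "TSF-CNN"):
    rows = mz.evaluate_arch_on_cohort(arch, cohort, policy, fold_count=1,
                                      seed=spec.seed)
    print(arch, f"test AUC = {rows[0]['test_auc']:.3f}")
```

prints

```
overlap = 0.346
MLP test AUC = 0.993
TSF-CNN test AUC = 0.993
```

The overlap — the fraction of trajectories lying inside the opposite
class's per-time-point [min, max] envelope — says about a third of the
curves are not separable by range alone at this cohort size; the planted
δ/σ ratio of 2.9 supports near-perfect ranking, and both classifiers land
at the signal's theoretical ceiling (Φ(δ/(σ√2)) ≈ 0.98 in expectation,
here 0.993 on the 300-sample test split).

The same machinery is scriptable from the shell:

```bash
trajbench simulate --variation shape --effect 1.25 --dispersion 0.6 \
    --missing 0.25 --irregularity moderate --imbalance 0.5 --kind bmi \
    --n 2000 --seed 7 --out cohort.csv
trajbench bench --archs MLP,TSF-CNN --n 300 --epochs 30 --out results.csv
trajbench ehr --n-patients 2000 --arch TSF-CNN --out windows.csv
```

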