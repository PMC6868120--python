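# gcdmap

Voxel-wise **Granger causality density (GCD)** mapping and SVM-based
substate classification for 4D functional images.

Resting-state fMRI cohorts are often compared through undirected functional
connectivity; GCD instead asks *who drives whom*. For every ordered voxel
pair (x → y) two nested autoregressions are fit,

```
y_t = a0 + a1 y_{t-1} + … + am y_{t-m} + e1                    (restricted)
y_t = a0 + … + am y_{t-m} + b1 x_{t-1} + … + bm x_{t-m} + e2   (full)
```

and the directed influence is F_{x→y} = ln(|e1|/|e2|), read as the log
ratio of residual standard deviations, with significance from the nested
F-test. Significant influences (p < 0.05) are summed per voxel into four
density maps — **inflow**, **outflow**, **total-flow** (in + out) and
**int-flow** (in − out) — that localise net causal sources (negative
int-flow) and targets (positive int-flow). Per-voxel linear-SVM accuracy
maps (leave-one-out CV, 70% threshold, ≥5 contiguous voxels) and a
multi-metric combination classifier (SVM-RFE, C = 1, nested 5-fold CV × 5
repeats, 100-label-permutation test, ROC/AUC) then ask whether those maps
discriminate two cohort substates — e.g. epilepsy patients with vs without
interictal epileptiform discharges. A synthetic VAR-network cohort
simulator with planted causal hubs makes the whole pipeline testable
without patient data.

It is aimed at neuroimaging methods researchers who want a transparent,
desk-scale, fully seeded implementation of the GCD + SVM analysis chain:
preprocessing (volume discard, FD scrubbing, Friston-24 + global nuisance
regression, detrend, 0.01–0.1 Hz band-pass), density mapping, and both
classification stages.

## Worked example

```python
import numpy as np
from gcdmap import (simulate_cohort, cohort_metric_arrays,
                    build_feature_table, nested_cv_classify)

# 21 + 21 subjects on an ~208-voxel grid, 240 timepoints at TR 2 s;
# group B has coupling +0.5 on 10 planted hub edges
cohort = simulate_cohort(n_per_group=21, group_effect=0.5, seed=1)
arrays, labels = cohort_metric_arrays(cohort)   # preprocess + GCD per subject

ft = build_feature_table(arrays, labels, ("inflow", "outflow", "intflow"))
report = nested_cv_classify(ft, seed=1)
print(f"AUC {report.auc:.3f}  accuracy {report.accuracy_pct:.1f}%  "
      f"sensitivity {report.sensitivity_pct:.1f}%  specificity {report.specificity_pct:.1f}%")
```

```
AUC 0.955  accuracy 86.7%  sensitivity 83.8%  specificity 89.5%
```

The three-metric combination separates the planted substates well above
chance; on a null cohort (`group_effect=0`) the same pipeline returns
~53% accuracy. Ground truth is available as `cohort.ground_truth` —
the planted hubs are the voxels with the largest group difference in
estimated outflow.

The same stages are exposed as CLI subcommands (`gcdmap simulate`,
`preprocess`, `gcd`, `accuracy-map`, `combine-classify`, `cohort-stats`),
each with `--seed`, `--config` and `--out`, reading/writing NIfTI-1 images,
TSV manifests and YAML configs.

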