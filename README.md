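# ddgen

Disease-driven domain generalization for 3D neuroimaging classification.

Deep 3D classifiers for staging cognitive impairment (normal cognition /
MCI / dementia) from structural brain MRI often degrade badly on cohorts
they were not trained on: scanner protocols, intensity calibration, and
population shifts all move the input distribution. `ddgen` implements a
single-source domain-generalization strategy that uses model
interpretability itself as the regularizer: a baseline classifier is
trained first, per-voxel Shapley attributions of its *correct* predictions
are averaged into one saliency prior per class, and a second,
independently initialized model is then trained with its class-wise
attention maps pulled toward those frozen priors — steering the
classifier's evidence toward disease-relevant anatomy so it transfers to
unseen cohorts.

The package is aimed at method developers: every stage is a plain Python
function over numpy arrays, NIfTI volumes, and pandas tables, and a
seeded synthetic phantom generator makes the whole pipeline testable end
to end on a laptop, with no access to clinical cohorts.

## The model

A volume `x` passes through a convolutional encoder `F = f(x)`; two
parallel 3D convolutions map the `C` encoder channels to `K` class
channels: projected features `F'_k` and *signed* attention maps `M_k`.
The classifier is global average pooling over the element-wise product,

    logit_k = mean_v [ F'_k(v) * M_k(v) ],    y_hat = softmax(logits),

so each class keeps a spatial evidence map. Training minimizes

    L = L_WCE + lambda * L_sim,
    L_WCE = - sum_i w_{y_i} log y_hat_i[y_i],          w_k = 1 / n_k,
    L_sim = sum_i sum_k || M_{i,k} - SHAP_k ||_2,

where `SHAP_k` is the class-k prior: the average Shapley attribution
volume over correctly predicted training samples of class k, scaled to
[-1, 1] by its maximum absolute value and resampled to the attention
grid. Attributions use a sampled path-integral (expected-gradients style)
approximation that is exact for linear models and satisfies the Shapley
completeness axiom in the sampling limit; an exhaustive subset
enumeration is available for tiny inputs as an oracle.

Evaluation follows the usual multi-cohort protocol: stratified k-fold
cross-validation with a 3:1:1 train/validation/test split on the source
domain, accuracy, macro F1 and the multiclass Matthews correlation
coefficient per domain plus an unweighted target mean, and a region-level
validation that rank-correlates (Spearman) the disease-class evidence,
aggregated per parcellation region and normalized by region volume,
against ordinal 0–3 pathology grades.

## Worked example

```python
import numpy as np
from ddgen.study import run_study_seed, study_pathology_rho

runs = [run_study_seed(s) for s in (1, 2, 3)]
base = np.mean([r.base_target_acc for r in runs])
guided = np.mean([r.guided_target_acc for r in runs])
rho = np.mean([study_pathology_rho(r) for r in runs])
print(f"baseline target accuracy {base:.3f}")
print(f"guided   target accuracy {guided:.3f}")
print(f"pathology mean Spearman rho {rho:.3f}")
```

Each `run_study_seed` call builds a 16³ three-class phantom cohort (one
clean training domain, two acquisition-shifted target domains), trains
the baseline, derives the class priors, and trains the prior-guided
model. On seeds 1–3 this prints:

```
baseline target accuracy 0.537
guided   target accuracy 0.551
pathology mean Spearman rho 0.817
```

i.e. the guided model transfers slightly better to the shifted cohorts
on average, and its disease-class region evidence ranks subjects almost
exactly as the underlying pathology grades do in the lesioned regions.

The same pipeline is scriptable from the shell:

```bash
ddgen simulate --config cohort.yaml --out data/ --seed 1
ddgen train-baseline --data data/ --out run/ --train-domain src --seed 1
ddgen compute-priors --model run/baseline.npz --data data/ --out run/priors --seed 1
ddgen train-guided --priors run/priors --data data/ --out run/ --train-domain src --seed 1
ddgen evaluate --model run/guided.npz --data data/ --out run/metrics.csv
ddgen validate-pathology --model run/guided.npz --data data/ \
    --atlas data/atlas.nii.gz --grades data/grades.csv --out run/corr.csv
```

## Layout

| module | contents |
| --- | --- |
| `ddgen.phantom` | seeded synthetic cohorts: atlas, domain shifts, severity-driven grades |
| `ddgen.netcore` | encoder + class-wise attention + GAP classifier, with exact backprop |
| `ddgen.losses` | weighted cross-entropy, prior-alignment loss, combination |
| `ddgen.priors` | Shapley attribution backends, class-prior construction, resampling |
| `ddgen.trainer` | stratified folds, augmentation, Mixup, Adam, the two training stages |
| `ddgen.evalmetrics` | confusion matrices, accuracy / macro F1 / multiclass MCC, fold aggregation |
| `ddgen.pathcorr` | region-level attention scores, Spearman correlation with grades |
| `ddgen.io`, `ddgen.cli` | NIfTI/CSV/YAML I/O, checkpoints, the `ddgen` command |
| `ddgen.study` | the frozen end-to-end phantom study protocol |
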