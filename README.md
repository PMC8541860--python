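# wavprog

Wavelet-denoised CNN gene weighting and Cox prognostic signatures for
tumor cohorts.

## What problem this solves

Building a small, well-calibrated prognostic gene signature from a bulk
tumor cohort means surviving three stages of noise: picking candidate genes
from tens of thousands (here, differentially expressed genes that also
carry differential methylation), weighting them by something better than
marginal statistics, and fitting a survival model that generalizes. This
package implements a pipeline that treats each sample's key-gene expression
profile as a 1-D signal, removes its high-frequency content with a
**discrete stationary wavelet transform** (56 candidate bases across 8
families), trains a **nine-layer 1-D CNN** on the denoised profiles and
extracts its pooling-layer activations as per-gene weights, scores genes
through an **HR-conditioned step function**, and builds a **Cox
proportional-hazards signature** evaluated by Kaplan–Meier separation and
time-dependent ROC at 3 and 5 years. The wavelet basis itself is selected
by running the whole pipeline per basis and preferring the most
parsimonious model.

The core objects, in the field's notation:

- step matrix: `D_ij = 1{B_ij ≥ 0}` if the gene's univariate `HR > 1`,
  `D_ij = 1{B_ij < 0}` if `HR < 1`, where `B` is the median-centered
  key-gene expression matrix;
- association matrix `E = D Cᵀ`, with `C` the channel-averaged final
  max-pooling output of the CNN;
- gene score `GS_i = mean_j E_ij`, ranking genes for Cox screening;
- prognostic risk score `PRS = Σ_i β_i · Exp_i` from the multivariate Cox
  fit, median-split into high/low risk groups.

Intended users: computational biologists who want a runnable, tested
implementation of this pipeline for their own expression + methylation +
survival cohorts, or a synthetic-data harness to study when wavelet/CNN
feature weighting helps.

## Worked example

```python
from wavprog.synthdata import CohortConfig, generate_cohort
from wavprog.pipeline import RunConfig, run_all, evaluate_holdout
from wavprog.cnn_features import CNNConfig

base = CohortConfig(seed=1)          # 300 tumor / 30 normal, 2000 genes,
train = generate_cohort(base)        # 5 planted prognostic genes
valid = generate_cohort(base, noise_seed=10008)  # same truth, fresh noise

config = RunConfig(
    basis_names=("haar", "bior1.5"),
    cnn=CNNConfig(channels=(8, 16), hidden_units=16, epochs=60, repeats=2),
    seed=1,
)
best, report = run_all(train, config)
print(report.drop(columns="genes"))
held = evaluate_holdout(best, valid, horizon=60.0)
print(best.basis, best.n_predictors, round(held["auc"], 3))
```

Output:

```
     basis    auc_3y    auc_5y  predictors     logrank_p
0     haar  0.866179  0.884764           6  8.867168e-32
1  bior1.5  0.893772  0.906933           7  2.704881e-38
haar 6 0.856
```

Reading this: for each basis the full pipeline ran — key-gene filtering
(233 of 2000 genes), denoising, CNN weighting, scoring, Cox screening and
stepwise selection — and produced a signature with its in-sample 3-/5-year
AUC and log-rank p. The haar model wins with 6 predictors (fewest — the
selection rule is parsimony first, so bior1.5's higher in-sample AUC does
not outweigh its extra predictor), and 4 of its 6 genes are truly planted
prognostic genes. Applied to an independent cohort drawn from the same
population, the signature keeps a 5-year AUC of 0.86 — it generalizes
rather than memorizing the training draw.

A command-line interface mirrors the library:
`wavprog simulate|keygenes|denoise|train-extract|score|prognosis|run-all|bases`
(see `wavprog --help`).

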