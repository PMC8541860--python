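# Methods

`wavprog` builds prognostic gene signatures for tumor cohorts by combining
multi-omics feature filtering, stationary-wavelet denoising, CNN-derived
gene weighting, and Cox survival modeling. This note documents the models,
the numerical choices, and what the synthetic benchmark does and does not
establish.

## Pipeline overview

For a cohort with a gene-by-sample expression matrix, a probe-by-sample
methylation beta matrix, a probe-to-gene annotation and per-sample survival
data, each wavelet basis is processed as:

1. **Key genes.** Differentially expressed genes (|log2 FC| ≥ 1.5,
   BH-adjusted p < 0.05) are intersected with genes carrying at least one
   differentially methylated probe (|Δβ| > 0.2, BH-adjusted p < 0.05).
   Boundary conventions are deliberate: the fold-change cut is inclusive,
   the Δβ cut strict, the p cut strict.
2. **Denoising.** Each sample's log2(x+1) key-gene profile is treated as a
   1-D signal and low-pass filtered with a 2-level discrete stationary
   wavelet transform: decompose, zero all detail channels, resynthesize.
3. **CNN weighting.** A nine-layer 1-D CNN (convolution, max-pooling,
   convolution, max-pooling, batch-normalization, flatten, hidden dense,
   dropout, output) is trained to classify vital status from the denoised
   profiles on a stratified 70/30 split; training is repeated with
   consecutive seeds and the run with the best held-out AUC is kept. The
   channel-averaged activations of the final pooling layer form the
   feature-weight matrix C (features × samples).
4. **Gene scores.** Each key gene's (undenoised) log2 row is
   median-centered into B; the univariate Cox hazard ratio decides which
   side of the median is risk-increasing, giving the binary step matrix D
   (HR > 1: D = 1 where B ≥ 0; HR < 1: D = 1 where B < 0; HR = 1 uses the
   first branch for totality). The association matrix is E = DCᵀ and each
   gene's score GS is its row mean of E; genes are ranked by descending GS
   with lexicographic tie-breaks.
5. **Cox modeling.** The top-200 scored genes are screened by univariate
   Cox Wald p < 0.05; bidirectional stepwise selection minimizes AIC; the
   multivariate fit defines the signature. The model keeps every
   stepwise-selected covariate and reports per-covariate significance
   rather than dropping non-significant rows post hoc.
6. **Evaluation.** The prognostic risk score PRS = Σ βᵢ·Expᵢ is split at
   the training median (ties go to the low-risk group); groups are compared
   by Kaplan–Meier curves with a log-rank test, and discrimination is
   summarized by time-dependent ROC/AUC at 36 and 60 months.

Across bases, the winner has the **fewest predictors**, with ties broken by
5-year AUC, then 3-year AUC, then basis name. Parsimony-first is the
operationalization that reproduces the published choice of bior1.5 (5
predictors, 5-year AUC 0.937) over rbio2.8 (10 predictors, higher 3-year
AUC) on the published comparison rows.

## The wavelet registry

Eight families, 56 bases: db2–db8, sym2–sym8, coif2–coif5, bior and rbio
{1.1, 1.3, 1.5, 2.2, 2.4, 2.6, 2.8, 3.1, 3.3, 3.5, 3.7, 3.9, 4.4, 5.5,
6.8}, haar, dmeyer, fk4–fk22. Filter tables come from PyWavelets, with two
exceptions built in-package:

- **Discrete Meyer.** The standard 62-tap FIR approximation is only
  orthogonal to ~1e-3, which leaks directly into reconstruction error. The
  registry stores its projection onto the orthonormal QMF manifold (nearest
  filter by SLSQP under unit-norm, zero even-lag autocorrelation and DC
  constraints); taps move by at most ~1e-3 and perfect reconstruction is
  restored to machine precision.
- **Fejér–Korovkin.** Constructed from the defining kernel: the squared
  frequency response is the ideal half-band indicator smoothed by the
  Fejér–Korovkin kernel (which preserves the quadrature partition of unity
  exactly and gives the family its sharp frequency localization), plus the
  smallest L1 correction on the odd harmonics that restores one vanishing
  moment subject to nonnegativity (a linear program), followed by spectral
  factorization. The resulting fk4 agrees with the widely used table to
  about 2e-3 per tap; all six lengths satisfy orthonormality and perfect
  reconstruction to 1e-10, which is what the transform relies on.

## Transform conventions

The stationary (à-trous) transform upsamples the filters by 2^(level−1)
instead of downsampling the signal, so all channels keep the input length
and the transform commutes exactly with circular shifts. Boundaries are
circular; convolutions run through FFTs. Signals whose length is not a
multiple of 2^levels are right-padded by edge replication and truncated
after reconstruction (a 3864-gene profile needs no padding at 2 levels).
Decomposition depth defaults to 2. The denoised output is the
reconstruction with zeroed details — a signal in the original gene space,
position-aligned with the input, which is what the CNN consumes; returning
raw approximation coefficients is equivalent in length but not in phase.

One property deliberately *not* claimed: low-pass denoising here is not
idempotent. For the undecimated transform the analysis–synthesis round
trip is a Fourier multiplier with per-frequency gain in [0, 1] (for
orthogonal bases), so repeated denoising contracts monotonically toward the
filter's fixed space but `denoise(denoise(x)) ≠ denoise(x)` in general;
exact idempotence is a property of the decimated transform only. The test
suite checks the contraction property and energy non-increase instead.

## The network

Layer order is fixed; everything else is configuration. Defaults: 32→64
channels, kernel 5, pool 2, hidden 32, dropout 0.5, Adam at 1e-2 with L2
weight decay 0.1 on the weight matrices, 100 epochs, minibatch 32. The
network is small because cohorts are small (hundreds of samples); weight
decay plus dropout are what separate held-out accuracy from pure
memorization at these sizes. Inputs are centered per gene with a single
global scale — per-gene unit-variance scaling would erase exactly the
amplitude differences that make a biomarker visible to the convolution.
Batch normalization uses batch statistics during training and running
statistics at extraction, so activations are defined for single samples
and constant inputs.

The tapped layer is the second (final) max-pooling layer; its positions map
to contiguous gene windows of width w1(w2 + k2 − 1) + k1 − 1 at stride
w1·w2 (16 and 4 at the defaults), and the mapping is carried alongside C.
The supervised target is binary vital status; the training objective is
logistic loss. Determinism holds for a fixed seed under single-threaded
execution; the repeat-and-select protocol uses seeds seed+0 … seed+r−1 and
keeps the highest test AUC (ties: accuracy, then lowest seed).

## Survival machinery

Cox fits use the Efron tie approximation via lifelines, with Newton
tolerances tightened to 1e-12 (the library's default relative-likelihood
stop leaves ~1e-5 slack in β, which is visible against an independent
partial-likelihood maximizer). Wald statistics, hazard ratios and 95%
intervals follow the usual exp(β ± 1.96·se) form. Stepwise selection is
bidirectional AIC minimization starting from the univariate-significant
set, deterministic in the candidate order. The time-dependent ROC treats
samples with an event by the horizon as cases, samples followed beyond it
as controls, and excludes samples censored earlier; with score ties merged,
the trapezoid AUC equals the Mann–Whitney pairwise concordance, which the
tests verify exactly. Expression enters Cox models and the PRS on the
log2(x+1) scale.

The step matrix and the Cox stages use the **undenoised** log2 matrix: the
denoised profiles exist to give the CNN a cleaner signal, but a low-pass
filter along the gene axis spreads each gene's hazard association over its
wavelet support, attenuating per-gene effect estimates and manufacturing
collinearity between neighboring rows (with Haar at 2 levels, genes within
a 4-block become identical). Keeping the per-gene analyses on the original
scale preserves effect sizes; the basis still shapes the outcome through
the weight matrix C and hence the ranking that decides which genes reach
the Cox screen.

## Synthetic cohorts

The generator plants known structure: DEGs as log2-mean shifts (±3 by
default) in log-normal expression; DMPs as ±0.3 beta-mean shifts in
Beta-distributed methylation (concentration 50); a probe map in which 80%
of planted DMPs map into the DEG set, always covering the prognostic genes
first so the key-gene intersection provably contains the signal; and
exponential survival whose log-hazard is linear in the standardized
log-expression of five prognostic genes (β = 0.8, −0.8, 0.7, −0.7, 0.6 per
SD), with independent exponential censoring whose rate is solved
numerically for a 20% censored fraction and a 40-month mean baseline
survival. Defaults are 300 tumor / 30 normal samples, 2000 genes, 250
planted DEGs (mirroring the ~22% key-gene yield of the reference cohort so
the top-200 score cut actually filters), 4000 probes, 300 planted DMPs.

The cohort seed fixes the planted structure; a separate noise seed draws
the per-sample randomness, so two cohorts with the same config and
different noise seeds share ground truth and serve as independent
training/validation draws.

What the generator does **not** emulate: batch effects, tumor purity,
count overdispersion beyond log-normal noise, methylation spatial
autocorrelation, non-proportional hazards, or informative censoring.
Passing the synthetic benchmark therefore shows the pipeline recovers
planted linear-hazard signal through all of its stages under clean
conditions; it does not certify performance on real cohorts.

## Problem sizes in the tests

The acceptance-style end-to-end check runs ten replicate cohorts at the
default scale with a two-basis list (haar, bior1.5), a compact network
(8→16 channels, 60 epochs, 2 repeats) and requires held-out 5-year AUC
above 0.7 with log-rank p below 0.01 in at least eight replicates — a
scaled-down version of the 56-basis, 100-repeat protocol, chosen so the
whole suite runs comfortably on one CPU. The full registry is exercised
structurally (all 56 bases must reconstruct exactly and shift-equivariantly)
rather than through full training runs. `scripts/acceptance.py` performs
one such replicate end-to-end and writes every quantity it computes.

## Known limitations

- The Fejér–Korovkin taps are a faithful kernel-based construction, not a
  digit-for-digit copy of the MATLAB tables (~2e-3 per-tap difference on
  fk4); any analysis depending on exact published taps should supply its
  own filters.
- Stepwise AIC on ~15 screened candidates retains occasional noise genes
  (observed 5–12 predictors per winning model on synthetic cohorts at
  n = 300); this is a property of the selection protocol, not a defect of
  the fits.
- The univariate screen fits one model per gene through lifelines, which
  dominates pipeline runtime for large key-gene sets.
- The CNN weighting's contribution is statistical, not guaranteed: on
  cohorts where the key-gene set is smaller than the top-k cut, the score
  ranking does not filter and all bases yield the same candidate set.
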