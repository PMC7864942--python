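# Methods

This note records the modelling choices, defaults and known limitations of
the package, in the spirit of a model-description appendix.

## Problem setting

Three data modalities describe partially overlapping patient subsets:
clinical records for everyone, SNP genotypes and structural MRI for
subsets. The staging task differs by modality, following the clinical
rationale that genotype does not separate MCI from AD and that early-MCI
brains resemble CN while late-MCI brains resemble AD: the EHR network is
trained three-class (CN/MCI/AD), the SNP network two-class (CN vs MCI-or-
AD), the imaging network two-class (CN vs AD). Fusion tasks containing EHR
are three-class; SNP+imaging without EHR is CN vs MCI-or-AD. This task
table is config-overridable.

Representation learning is deliberately two-stage: each modality's network
is trained on its own task, then frozen intermediate features are fused by
a shallow classifier. End-to-end joint training is out of scope.

## Stacked denoising autoencoder (EHR, SNP)

Each layer encodes `y = σ(Wx + b)` and decodes through the transposed
encoder weights, `x̂ = σ(Wᵀy + b′)`; the decoder matrix is tied to the
encoder at all times (one parameter array, verified by tests). Sigmoid is
used throughout because the reconstruction loss — summed Bernoulli
cross-entropy against the *uncorrupted* input, averaged over the batch —
requires outputs in (0, 1). For the same reason inputs must lie in [0, 1]:
the [1, 2]-coded clinical matrix and the 1/2/3 genotype levels are affinely
rescaled before the autoencoder (`x − 1` and `(x − 1)/2`) and the maps are
trivially invertible. Rescaling is monotone-affine per feature, so it
changes neither ranks nor geometry.

Pretraining is greedy and layer-wise: the layer input is corrupted by
masking entries to zero with probability `corruption_p`, Adam minimizes the
reconstruction cross-entropy plus `l2_pretrain · ‖W‖²`, and the next layer
trains on the previous layer's clean codes. Fine-tuning appends a softmax
head and backpropagates label cross-entropy through the stack with inverted
dropout (rate `corruption_p`) on every hidden activation — the raw input is
left intact during fine-tuning; input masking belongs to the denoising
phase. "Regularization coefficient" is implemented as an L2 weight-decay
term; the learning rate defaults to 1e-3 with standard Adam moments, batch
size 3.

Defaults: hidden widths (200, 100, 50) — a narrower (200, 100, 75) EHR
variant is sometimes quoted for this architecture family; `layer_sizes` is
fully configurable and 50 is the default intermediate width. Corruption
0.6; L2 0.03 for pretraining; 0.03 (EHR) / 0.06 (SNP) for fine-tuning;
max epochs 25 (EHR) / 30 (SNP).

**Scale caveat.** Those regularization defaults were tuned against a
~1680-feature clinical space, where the summed reconstruction term is
roughly twenty times larger than on the synthetic desk-scale cohort (~76
encoded features); carried over unchanged they collapse the softmax head to
the majority class. The pipeline's desk-scale configuration therefore uses
corruption 0.3, `l2_pretrain` 0.003 and `l2_finetune` 0.001 (EHR) / 0.002
(SNP), chosen once from a coarse scan of the internal-validation accuracy —
which is exactly the tuning protocol the method prescribes. The estimator
class itself keeps the headline defaults.

## Multi-region 3D CNN (MRI)

Each region crop passes through one shared convolutional module: valid 3D
convolution (10 kernels of 5×5×5, stride 1) → max-pool 3×3×3
(non-overlapping, floor) → ReLU → volumetric batch normalization. Kernels
and batch-norm parameters are shared across regions (a single parameter
array); the first-level fully connected layers (20 ReLU units, dropout 0.5)
are region-specific. Concatenated first-level outputs (5 × 20 = 100 by
default) feed a 20-unit second-level layer, dropout, and a softmax head
trained with negative log-likelihood (Adam, batch size 5). With the default
22×23×18 crop the conv output is 18×19×14 and pooling yields 6×6×4 per
kernel (1440 flattened per region).

Choices where the design was open: max (not average) pooling, pool stride
equal to pool size, no padding, conv stride 1 — the common choices for this
architecture generation and the only ones consistent with the stated
shapes. The module order above follows the architecture's description;
`layer_order="conventional"` switches to conv → BN → ReLU → pool. Dropout
follows both fully connected levels. Optimizer settings are not dictated by
the architecture: Adam at 1e-3 with early stopping (patience 10 by default;
the pipeline's desk config uses 8 epochs / patience 3) on a stratified
validation split carved from the training data. Batch norm uses running
statistics at inference, making prediction deterministic and
batch-size-independent.

The implementation is pure numpy (im2col convolution, recorded-argmax
pooling, hand-written batch-norm backprop, Adam); it is exact rather than
fast, sized for cohorts of a few hundred patients.

## Preprocessing

*EHR*: features missing in **more than** 70% of training rows are dropped
(strictly greater; computed on training rows only to avoid leakage — an
alternative reading computes it on all patients). Remaining missing cells
are imputed with the training median (quantitative) or mode
(binary/categorical), because the autoencoder input may contain no holes.
Quantitative features map train-min → 1, train-max → 2, with out-of-range
test values clipped to preserve the [1, 2] invariant; binary 0/1 → 1/2;
categoricals one-hot with the active level at 2. Unseen test levels encode
as all-reference and warn. Transform state serializes to JSON.

*SNP*: order matters and is fixed — per-genotype GQ masking first, then
per-site missing rate, MAF and HWE computed on the masked calls, then the
known-gene restriction, then mRMR. Thresholds (GQ 20, missing 0.10, MAF
0.05, HWE α 1e-6) are community conventions, all configurable. The HWE test
is the 1-df chi-square against p², 2pq, q² at the sample allele frequency;
monomorphic sites return p = 1. mRMR uses the mutual-information-difference
(MID) form with base-2 logarithms and plug-in MI estimates; ties break
toward the smaller site index, making selection deterministic. The
gene list ships as an editable BED file of reported AD-associated loci.
Genotype levels: hom-ref 1, het 2, hom-alt 3 (reference-count ordering);
residual missing genotypes take the per-site mode.

*Imaging*: volumes are min–max scaled to [0, 1] per patient before
cropping, making all downstream features invariant to global affine
intensity changes. Crops center on the atlas bounding box, zero-padded
symmetrically or center-cropped to the configured shape, with out-of-region
voxels zeroed. Handcrafted features for shallow baselines: per region,
first-order mean/median/entropy of 8-level quantized intensity, and GLCM
contrast at offsets along the three voxel axes at distances 1–5, summarized
as mean/median/sum over the three directions — feature names follow the
`"Mean GLCM 3 <region>"` / `"Entropy intensity <region>"` convention. The
GLCM offset set, level count and the meaning of the numeric suffix (here:
distance) are package choices; the convention this family of features
originally used is not fully specified anywhere.

## Fusion and evaluation

Fused blocks are ordered [EHR | SNP | imaging]; a missing modality's block
is all zeros, which keeps partially observed patients classifiable and is
idempotent by construction. Decision-level voting is majority with ties
broken by highest mean predicted class-probability, then fixed class order
CN < MCI < AD. Decision-layer defaults: random forest with 31 trees for
deep fusion, 20 for the SNP+imaging shallow combination; kNN k = 5;
unlimited tree depth; SVM uses one-vs-one coding.

The split protocol removes a stratified 10% external test set, then
partitions the rest into ten stratified folds: each fold validates (9% of
the total) while the other nine train (81%). Stratification is a package
addition to stabilize small-class folds and can be switched off. meanF1 is
macro F1 (unweighted per-class mean); classes absent from a validation fold
contribute F1 = 0 with a warning. Fold aggregation is mean ± standard
deviation (std, not standard error).

## Interpretation

Feature importance: mask one feature at a time — the whole evaluation
partition at once, mask value 0 in model space, consistent with the
missing-modality convention; mean-masking is available by config — and rank
by drop in accuracy relative to the unmasked baseline. Drops are measured
on held-out data (the pipeline averages over internal validation folds),
never on training rows, so importance is not understated for overfit
models. Single-feature drops for a set of partially redundant planted
features are small (a few percent); resolving them above the noise floor
needs an evaluation set of roughly 200 patients, which is why the pipeline
averages folds and the acceptance checks evaluate on a held-out half
cohort. Cluster comparison: k-means (10 restarts, fixed seed, k = number of
task classes) on raw versus intermediate representations, scored by mean
silhouette.

## Synthetic cohort generator

The generator emulates the structural facts of a multimodal dementia
cohort: three diagnostic classes; clinical data for everyone with genotypes
and imaging for subsets (inclusion probabilities 0.40 / 0.25 by default, or
explicit counts — e.g. 2004/808/503 with 220 fully observed — when exact
marginals are wanted); missing clinical cells (10% MCAR); planted
class-discriminative structure in each modality. Defaults: 400 patients,
class proportions 0.35/0.40/0.25, 60 mixed-type EHR features, 200 SNP
sites, 5 regions of 22×23×18 voxels, 10 causal features per modality,
effect size 1.0.

Signals: causal EHR features are Gaussian with mean shifted by
`effect_size × stage`; causal SNP sites get stage-dependent alternate-allele
frequencies while null sites draw one frequency per site with binomial
(Hardy-Weinberg) genotypes; causal imaging regions get a stage-dependent
mean-intensity shift plus a bright blob whose radius grows with stage.
`stage` blends the class index with a shared per-patient severity scalar
(weight 0.5), so modalities carry partially complementary information and
fusion can genuinely beat single modalities. GQ scores are sampled so ~5%
fall below the GQ-20 filter; ~15% of sites fall outside the packaged gene
intervals; both exercise the filters.

What the generator does **not** emulate — hence what passing tests do not
show about real data: realistic MRI anatomy or registration artifacts,
linkage disequilibrium between sites, informative (non-MCAR) missingness,
longitudinal visits, and real clinical feature distributions, for which no
public characterization exists. All generator distributions are stand-ins
chosen for plausibility and testability.

## Numerical and reproducibility notes

Sigmoid is computed via tanh for stability; reconstruction probabilities
are clipped to [1e-12, 1 − 1e-12] inside the loss. Batch-norm epsilon is
1e-5. One global seed fans out to per-stage seeds through a fixed
`SeedSequence` derivation, so a config plus one integer reproduces cohorts,
splits, initializations, dropout masks and classifier randomness
bitwise on the same platform. Desk-scale problem sizes used by the test
suite and the acceptance script (n = 400 cohort, 3 internal folds, 8-epoch
CNN budgets) were chosen so a full run completes in minutes on one CPU;
they are stated wherever results are reported.

## Known limitations

* The numpy networks are single-threaded and unbatched across patients
  beyond the configured minibatch; they target hundreds, not tens of
  thousands, of samples.
* mRMR is greedy; it matches exhaustive greedy selection by construction
  but not globally optimal subset selection.
* Perturbation importance attributes no interaction effects; fully
  redundant features can all rank low individually.
* The decision layer sees zero-blocks for missing modalities rather than a
  learned missingness embedding; with very low modality coverage this can
  dilute the fused signal.
* VCF reading assumes biallelic sites after the configured multi-allelic
  handling (drop or split); structural variants are out of scope.
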