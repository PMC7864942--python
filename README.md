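# neurofuse

Multimodal deep learning for staging Alzheimer's disease. The package
classifies patients into cognitively normal (CN), mild cognitive impairment
(MCI) and Alzheimer's disease (AD) by fusing three data modalities —
clinical records (EHR), genome-wide SNP genotypes, and structural MRI — and
ships a synthetic multimodal cohort generator so that every stage of the
pipeline is testable without access to any gated clinical repository.

It is intended for methods researchers working on clinical data
integration: each stage is an independently usable scikit-learn-style
estimator, and the end-to-end pipeline is reproducible from one YAML config
and one seed.

## The method

Per modality, an intermediate representation is learned first:

* **EHR** — mixed-type clinical features are normalized to the range
  [1, 2] (quantitative min–max mapped, categorical one-hot, binary → 1/2;
  features with >70% missing values dropped), then passed through a stacked
  denoising autoencoder. Each layer encodes `y = σ(Wx + b)` and decodes
  through tied weights `x̂ = σ(Wᵀy + b′)`; layers are pretrained greedily by
  minimizing the Bernoulli cross-entropy
  `L = −Σₖ [xₖ log x̂ₖ + (1−xₖ) log(1−x̂ₖ)]`
  of the reconstruction of the uncorrupted input from a masked copy, then the
  stack is fine-tuned with a softmax head (Adam, batch size 3). The
  intermediate code is the top hidden layer (50-wide under the default
  200/100/50 stack).
* **SNP** — variants are GQ-masked, filtered on missing rate, minor-allele
  frequency and Hardy–Weinberg equilibrium, restricted to known
  AD-associated genes, reduced with minimum-redundancy maximum-relevance
  (mRMR) selection, and encoded as levels 1/2/3 (hom-ref/het/hom-alt) before
  the same autoencoder treatment.
* **MRI** — atlas-defined brain regions (hippocampus, amygdala, superior
  temporal by default) are cropped to fixed 22×23×18 voxel boxes (9108
  voxels per region) and fed to a multi-region 3D CNN: ten shared 5×5×5
  kernels, 3×3×3 max-pooling, ReLU, volumetric batch norm, then a
  region-specific fully connected layer (20 nodes each; 5 × 20 = 100-wide
  concatenation) and a second-level 20-node layer with a softmax head. The
  imaging code is the concatenated first-level output.

The per-modality codes are concatenated — with all-zero blocks where a
patient lacks a modality — and classified by a shallow decision layer
(random forest by default; kNN, one-vs-one SVM and decision trees are
available). Feature-level and decision-level (majority-vote) fusion are
included as baselines. Evaluation holds out 10% of patients, then runs
tenfold cross-validation on the rest (81% train / 9% validation per fold),
reporting accuracy, macro precision/recall and meanF1 as mean ± std.
Interpretation masks one feature at a time and ranks features by the
resulting drop in held-out accuracy, and compares k-means cluster
separation (mean silhouette) of raw versus learned representations.

## Worked example

```python
from neurofuse import CohortSpec, generate_cohort
from neurofuse.pipeline import TaskRunner, load_config

cohort = generate_cohort(CohortSpec(seed=2026))   # 400 patients, 3 classes
cfg = load_config({
    "seed": 1,
    "snp": {"k_select": 50},
    "cnn": {"max_epochs": 8, "patience": 3},
    "evaluation": {"n_folds": 3},
})
result = TaskRunner(cohort, ["ehr", "snp", "imaging"], cfg).run()
print(result.report.formatted())
```

prints (three-class CN/MCI/AD task, three internal folds):

```
{'accuracy': '0.66 ± 0.03', 'precision': '0.69 ± 0.05',
 'recall': '0.66 ± 0.03', 'mean_f1': '0.66 ± 0.03'}
```

i.e. the fused model stages about two thirds of validation patients
correctly (chance would be 40%, the majority-class rate). An EHR-only run
of the same config scores 0.66 ± 0.01; with this cohort's modality
coverage (SNP for ~40%, imaging for ~25% of patients) fusion matches the
best single modality here and picks up the extra modalities' signal for
the patients who have them — on other cohort draws it comes out a few
points ahead (see `scripts/acceptance.py`).

The same run from a shell:

```bash
neurofuse run-all --config my_config.yaml --out runs/demo
```

writes the evaluation report, the perturbation feature ranking, the
clustering comparison and a frozen config copy into `runs/demo/`.

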