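"""Variant filtering and SNP feature selection.

The preprocessing chain mirrors standard GWAS-style quality control and is
applied in a fixed order: per-genotype quality masking first, then per-site
filters (missing rate, minor-allele frequency, Hardy-Weinberg equilibrium)
computed on the masked calls, then restriction to known disease-associated
gene intervals, and finally greedy minimum-redundancy maximum-relevance
(mRMR) selection down to ``k_select`` sites. Selected genotypes are encoded
as levels 1/2/3 (hom-ref / het / hom-alt).

Thresholds default to community conventions (GQ 20, missing rate 0.10,
MAF 0.05, HWE alpha 1e-6) and are all configurable. The mRMR variant is
the mutual-information difference (MID) form with base-2 logarithms;
ties are broken toward the smaller site index so selection is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin

from .io import MISSING_GT, GenotypeTable, read_bed


@dataclass
class SNPFilterConfig:
    min_gq: float = 20.0
    max_missing_rate: float = 0.10
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    gene_intervals: list | None = None  # (chrom, start0, end, name); None = no gene filter
    k_select: int = 500

    def __post_init__(self):
        for name in ("max_missing_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.hwe_alpha <= 1.0:
            raise ValueError("hwe_alpha must be in [0, 1]")
        if self.k_select < 1:
            raise ValueError("k_select must be >= 1")

    @classmethod
    def with_gene_bed(cls, bed_path, **kwargs) -> "SNPFilterConfig":
        return cls(gene_intervals=read_bed(bed_path), **kwargs)


@dataclass
class SNPMatrix:
    """Patients x selected-sites matrix with genotype levels in {1, 2, 3}."""

    values: np.ndarray          # (n_patients, k), int
    site_ids: list[str]         # in selection order where selection applied
    sample_ids: list[str]

    def __post_init__(self):
        bad = set(np.unique(self.values)) - {1, 2, 3}
        if bad:
            raise ValueError(f"SNP levels must be 1/2/3, found {sorted(bad)}")

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def hwe_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit p-value.

    Expected genotype counts come from the sample allele frequency
    (p^2, 2pq, q^2); monomorphic sites return p = 1 by convention.
    """
    n = n_homref + n_het + n_homalt
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p_ref = (2 * n_homref + n_het) / (2 * n)
    q_alt = 1.0 - p_ref
    if p_ref in (0.0, 1.0):
        return 1.0
    expected = np.array([n * p_ref**2, 2 * n * p_ref * q_alt, n * q_alt**2])
    observed = np.array([n_homref, n_het, n_homalt], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(chi2.sf(stat, df=1))


@dataclass
class FilterLog:
    n_input: int = 0
    dropped_missing_rate: int = 0
    dropped_maf: int = 0
    dropped_hwe: int = 0
    dropped_gene: int = 0
    n_retained: int = 0
    genotypes_masked_low_gq: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_variants(gt: GenotypeTable, cfg: SNPFilterConfig):
    """Apply GQ masking then per-site filters; returns (table, FilterLog).

    Site statistics (missing rate, MAF, HWE) are always computed on the
    GQ-masked genotypes — masking first changes, and must change, which
    sites survive.
    """
    log = FilterLog(n_input=gt.n_sites)
    geno = gt.genotypes.copy()
    low = (gt.quals < cfg.min_gq) & (geno != MISSING_GT)
    geno[low] = MISSING_GT
    log.genotypes_masked_low_gq = int(low.sum())

    observed = geno != MISSING_GT
    n_obs = observed.sum(axis=1)
    miss_rate = 1.0 - n_obs / gt.n_samples
    keep = miss_rate <= cfg.max_missing_rate
    log.dropped_missing_rate = int((~keep).sum())

    with np.errstate(invalid="ignore"):
        alt_af = np.where(n_obs > 0, np.where(observed, geno, 0).sum(axis=1) / (2 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(alt_af, 1.0 - alt_af)
    drop_maf = keep & (maf < cfg.min_maf)
    log.dropped_maf = int(drop_maf.sum())
    keep &= ~drop_maf

    hwe_p = np.ones(gt.n_sites)
    for i in np.flatnonzero(keep):
        row = geno[i][observed[i]]
        hwe_p[i] = hwe_test(int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum()))
    drop_hwe = keep & (hwe_p < cfg.hwe_alpha)
    log.dropped_hwe = int(drop_hwe.sum())
    keep &= ~drop_hwe

    if cfg.gene_intervals is not None:
        in_gene = np.zeros(gt.n_sites, dtype=bool)
        for chrom, start0, end, _name in cfg.gene_intervals:
            # BED is 0-based half-open; VCF POS is 1-based
            in_gene |= (gt.chrom.astype(str) == str(chrom)) & (gt.pos > start0) & (gt.pos <= end)
        drop_gene = keep & ~in_gene
        log.dropped_gene = int(drop_gene.sum())
        keep &= in_gene

    if not keep.any():
        raise ValueError(
            "no variants survive filtering; relax min_gq/max_missing_rate/"
            "min_maf/hwe_alpha or widen the gene interval list"
        )
    out = gt.take_sites(np.flatnonzero(keep))
    out.genotypes = geno[np.flatnonzero(keep)]
    log.n_retained = out.n_sites
    return out, log


def encode_genotypes(gt: GenotypeTable) -> SNPMatrix:
    """Encode genotypes as levels 1/2/3; residual missing -> per-site mode."""
    geno = gt.genotypes.astype(np.int64)
    levels = np.where(geno == MISSING_GT, 0, geno + 1)  # 0 marks missing
    for i in range(levels.shape[0]):
        row = levels[i]
        missing = row == 0
        if missing.any():
            observed = row[~missing]
            if observed.size:
                vals, counts = np.unique(observed, return_counts=True)
                mode = int(vals[np.argmax(counts)])
            else:
                mode = 1
            row[missing] = mode
    return SNPMatrix(values=levels.T, site_ids=gt.site_ids(), sample_ids=list(gt.samples))


# ---------------------------------------------------------------------------
# Mutual information and mRMR
# ---------------------------------------------------------------------------

def mutual_information(x, y) -> float:
    """Plug-in mutual information (bits) between two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def mrmr_select(X, y, k: int) -> list[int]:
    """Greedy MID-form mRMR on categorical features.

    The first pick maximizes MI(feature; label); each subsequent pick
    maximizes MI(feature; label) minus the mean MI with already-selected
    features. Ties go to the smaller column index.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n, p = X.shape
    if k > p:
        raise ValueError(f"k={k} exceeds the {p} candidate features")
    relevance = np.array([mutual_information(X[:, j], y) for j in range(p)])
    selected: list[int] = []
    redundancy_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for _ in range(k):
        if selected:
            score = relevance - redundancy_sum / len(selected)
        else:
            score = relevance.copy()
        score[~remaining] = -np.inf
        # ties (within float tolerance) go to the smallest site index
        best = int(np.flatnonzero(score >= score.max() - 1e-9)[0])
        selected.append(best)
        remaining[best] = False
        if remaining.any():
            for j in np.flatnonzero(remaining):
                redundancy_sum[j] += mutual_information(X[:, j], X[:, best])
    return selected


class MRMRSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn-style wrapper around :func:`mrmr_select`."""

    def __init__(self, k: int = 500):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X)
        self.selected_idx_ = mrmr_select(X, np.asarray(y), self.k)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.selected_idx_] = True
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.selected_idx_]


def prepare_snp_features(gt: GenotypeTable, labels, cfg: SNPFilterConfig):
    """Full chain: filter -> encode -> mRMR; returns (SNPMatrix, FilterLog).

    ``labels`` must be aligned with ``gt.samples``. Raises when fewer than
    ``k_select`` candidate sites survive filtering.
    """
    filtered, log = filter_variants(gt, cfg)
    encoded = encode_genotypes(filtered)
    if cfg.k_select > filtered.n_sites:
        raise ValueError(
            f"k_select={cfg.k_select} but only {filtered.n_sites} sites survive filtering"
        )
    order = mrmr_select(encoded.values, np.asarray(labels), cfg.k_select)
    return (
        SNPMatrix(
            values=encoded.values[:, order],
            site_ids=[encoded.site_ids[j] for j in order],
            sample_ids=encoded.sample_ids,
        ),
        log,
    )


def to_unit_interval(x) -> np.ndarray:
    """Affine {1,2,3} -> [0,1] map used before the autoencoder."""
    return (np.asarray(x, dtype=float) - 1.0) / 2.0
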