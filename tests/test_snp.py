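import numpy as np
import pytest

from neurofuse import (
    MRMRSelector,
    SNPFilterConfig,
    encode_genotypes,
    filter_variants,
    hwe_test,
    mrmr_select,
    mutual_information,
    prepare_snp_features,
)
from neurofuse.io import MISSING_GT, GenotypeTable
from neurofuse.snp import to_unit_interval

from oracles import entropy_oracle, hwe_oracle, mi_oracle, mrmr_oracle


def make_table(genotypes, quals=None, chrom=None, pos=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = genotypes.shape
    if quals is None:
        quals = np.full(genotypes.shape, 99.0)
    return GenotypeTable(
        chrom=np.array(chrom if chrom is not None else ["1"] * n_sites, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, n_sites + 1) * 100),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        genotypes=genotypes,
        quals=np.asarray(quals, dtype=float),
        samples=[f"S{i}" for i in range(n_samples)],
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def test_hwe_exact_proportions_give_p_one():
    assert hwe_test(25, 50, 25) == pytest.approx(1.0)


def test_hwe_matches_hand_computed_chi_square():
    """(50, 20, 30): allele freq 0.6/0.4 -> expected counts (36, 48, 16)."""
    assert hwe_test(50, 20, 30) == pytest.approx(hwe_oracle(50, 20, 30), rel=1e-12)
    # the hand arithmetic, spelled out: chi2 = 14^2/36 + 28^2/48 + 14^2/16
    stat = 14**2 / 36 + 28**2 / 48 + 14**2 / 16
    from scipy.stats import chi2
    assert hwe_test(50, 20, 30) == pytest.approx(float(chi2.sf(stat, 1)), rel=1e-12)


def test_hwe_heterozygote_deficit_is_extreme():
    assert hwe_test(10, 0, 10) < 1e-4


def test_hwe_monomorphic_and_invalid():
    assert hwe_test(40, 0, 0) == 1.0
    with pytest.raises(ValueError):
        hwe_test(0, 0, 0)


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------

def test_filter_fates_enumerated_fixture():
    """Each site's fate (survive / which filter kills it) enumerated by hand."""
    n = 40
    rng = np.random.default_rng(0)
    hwe_ok = rng.binomial(2, 0.4, size=n)  # ~HWE at p=0.4
    sites = {
        "good": hwe_ok,
        "low_maf": np.array([1] + [0] * (n - 1)),                  # MAF 1/80
        "too_missing": np.where(np.arange(n) < 6, MISSING_GT, hwe_ok),  # 15% missing
        "hwe_violator": np.array([0, 2] * (n // 2)),               # no hets
        "off_gene": hwe_ok,
    }
    geno = np.stack(list(sites.values()))
    quals = np.full(geno.shape, 99.0)
    pos = [100, 200, 300, 400, 9_000_000]
    table = make_table(geno, quals, pos=pos)
    cfg = SNPFilterConfig(
        min_gq=20, max_missing_rate=0.10, min_maf=0.05, hwe_alpha=1e-4,
        gene_intervals=[("1", 0, 1000, "geneA")],
    )
    out, log = filter_variants(table, cfg)
    assert out.pos.tolist() == [100]
    assert log.dropped_missing_rate == 1
    assert log.dropped_maf == 1
    assert log.dropped_hwe == 1
    assert log.dropped_gene == 1
    assert log.n_retained == 1


def test_gq_masking_happens_before_site_statistics():
    """A site whose low-GQ calls hide its common alt allele: with masking
    first, MAF falls below threshold and the site must drop; computing MAF
    on raw calls would keep it."""
    n = 20
    geno = np.array([[1] * 5 + [0] * 15])   # raw MAF 5/40 = 0.125
    quals = np.array([[5.0] * 5 + [99.0] * 15])  # the 5 het calls are low-GQ
    table = make_table(geno, quals)
    cfg = SNPFilterConfig(min_gq=20, max_missing_rate=0.5, min_maf=0.05, hwe_alpha=0.0)
    with pytest.raises(ValueError, match="relax"):
        filter_variants(table, cfg)  # masked MAF is 0 -> dropped -> empty
    assert filter_variants(
        make_table(geno, np.full(geno.shape, 99.0)), cfg
    )[0].n_sites == 1  # without low GQ the same site survives


def test_gene_interval_retains_known_locus():
    """A site at chr10:108777098 inside a covering interval passes the
    known-gene filter."""
    geno = np.array([np.random.default_rng(1).binomial(2, 0.4, 50)])
    table = make_table(geno, chrom=["10"], pos=[108_777_098])
    cfg = SNPFilterConfig(gene_intervals=[("10", 108_740_000, 108_810_000, "SORCS3")],
                          hwe_alpha=1e-6)
    out, _ = filter_variants(table, cfg)
    assert out.pos.tolist() == [108_777_098]


def test_empty_result_advises_relaxation():
    table = make_table(np.zeros((3, 10)))  # all monomorphic -> MAF 0
    with pytest.raises(ValueError, match="relax"):
        filter_variants(table, SNPFilterConfig())


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def test_levels_encoding():
    table = make_table(np.array([[0, 1, 2]]))
    out = encode_genotypes(table)
    assert out.values.tolist() == [[1], [2], [3]]


def test_all_homref_site():
    out = encode_genotypes(make_table(np.zeros((1, 4))))
    assert out.values.tolist() == [[1], [1], [1], [1]]


def test_missing_imputed_by_site_mode():
    out = encode_genotypes(make_table(np.array([[0, MISSING_GT, 0]])))
    assert out.values.tolist() == [[1], [1], [1]]


def test_unit_rescale():
    assert to_unit_interval(np.array([1, 2, 3])).tolist() == [0.0, 0.5, 1.0]


# ---------------------------------------------------------------------------
# Mutual information and mRMR
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    counts=st.tuples(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    .filter(lambda t: sum(t) > 0)
)
def test_hwe_p_value_always_valid(counts):
    """For any genotype counts the HWE p-value is a probability and matches
    the literal chi-square oracle."""
    p = hwe_test(*counts)
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(hwe_oracle(*counts), rel=1e-9, abs=1e-300)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 8), st.integers(10, 40))
def test_mrmr_property_matches_oracle(seed, p, n):
    """mRMR equals exhaustive greedy selection on any small instance."""
    rng = np.random.default_rng(seed)
    X = rng.integers(1, 4, (n, p))
    y = rng.integers(0, 2, n)
    k = int(rng.integers(1, p + 1))
    assert mrmr_select(X, y, k) == mrmr_oracle(X, y, k)


def test_mi_properties_and_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.integers(0, 3, 40)
        y = rng.integers(0, 2, 40)
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x.tolist(), y.tolist()), abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x), abs=1e-12)
        assert mutual_information(x, y) >= -1e-12
        assert mutual_information(x, x) == pytest.approx(entropy_oracle(x.tolist()), abs=1e-12)


def test_mrmr_k1_is_max_relevance():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 3, 60)
    X = rng.integers(1, 4, (60, 5))
    X[:, 3] = y + 1  # perfectly informative
    assert mrmr_select(X, y, 1) == [3]


def test_mrmr_matches_exhaustive_greedy_oracle():
    """Selection order equals the literal exhaustive-greedy oracle on random
    small instances (<= 8 candidates)."""
    rng = np.random.default_rng(3)
    for trial in range(15):
        p = int(rng.integers(2, 9))
        n = int(rng.integers(20, 60))
        X = rng.integers(1, 4, (n, p))
        y = rng.integers(0, 2, n)
        k = int(rng.integers(1, p + 1))
        assert mrmr_select(X, y, k) == mrmr_oracle(X, y, k), f"trial {trial}"


def test_mrmr_k_too_large_errors():
    X = np.ones((10, 3), dtype=int)
    with pytest.raises(ValueError, match="exceeds"):
        mrmr_select(X, np.zeros(10, dtype=int), 4)


def test_mrmr_selector_estimator():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 50)
    X = rng.integers(1, 4, (50, 6))
    sel = MRMRSelector(k=3).fit(X, y)
    assert len(sel.selected_idx_) == 3
    assert sel.transform(X).shape == (50, 3)


def test_prepare_snp_features_exact_k(small_cohort):
    y = np.where(np.array([
        small_cohort.labels[small_cohort.patient_ids.index(s)]
        for s in small_cohort.genotypes.samples
    ]) == "CN", "CN", "MCI/AD")
    cfg = SNPFilterConfig(k_select=10, gene_intervals=None, hwe_alpha=1e-6)
    mat, log = prepare_snp_features(small_cohort.genotypes, y, cfg)
    assert mat.values.shape == (small_cohort.genotypes.n_samples, 10)
    assert set(np.unique(mat.values)) <= {1, 2, 3}
    assert len(mat.site_ids) == 10
    cfg_big = SNPFilterConfig(k_select=10_000, gene_intervals=None)
    with pytest.raises(ValueError, match="k_select"):
        prepare_snp_features(small_cohort.genotypes, y, cfg_big)
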