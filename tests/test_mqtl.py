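"""mQTL association scan against independent closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methtrio.core import Thresholds
from methtrio.matrix import GenotypeMatrix, MethMatrix, site_ids
from methtrio.mqtl import (
    association_test,
    bonferroni_threshold,
    cis_mask,
    scan_and_select_heritable,
    _block_stats,
)


def r_to_t_oracle(y, x):
    """Closed-form correlation route: t = r sqrt((n-2)/(1-r^2))."""
    n = len(x)
    r = np.corrcoef(x, y)[0, 1]
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    slope = r * np.std(y, ddof=1) / np.std(x, ddof=1)
    return slope, t, p


def test_perfect_collinearity_gives_p_zero():
    meth = np.array([0, 0, 0, 0, 50, 50, 50, 50, 100, 100, 100, 100], float)
    dosage = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2], float)
    res = association_test(meth, dosage)
    assert res.testable
    assert res.slope == pytest.approx(50.0)
    assert res.p == 0.0


def test_constant_vectors_untestable():
    dosage = np.array([0, 1, 2] * 4, float)
    assert not association_test(np.full(12, 42.0), dosage).testable
    assert not association_test(np.arange(12, dtype=float), np.ones(12)).testable


def test_too_few_pairs_untestable():
    assert not association_test(np.array([1.0, 2.0]), np.array([0.0, 1.0])).testable


def test_association_matches_r_to_t_oracle():
    rng = np.random.default_rng(42)
    dosage = rng.integers(0, 3, size=12).astype(float)
    meth = np.clip(30 + 20 * dosage + rng.normal(0, 10, 12), 0, 100)
    res = association_test(meth, dosage)
    slope, t, p = r_to_t_oracle(meth, dosage)
    assert res.slope == pytest.approx(slope, rel=1e-12)
    assert res.t == pytest.approx(t, rel=1e-12)
    assert res.p == pytest.approx(p, rel=1e-12)


def test_pairwise_complete_observations():
    rng = np.random.default_rng(2)
    dosage = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2], float)
    meth = rng.uniform(0, 100, 12)
    dosage[3] = np.nan
    meth[7] = np.nan
    res = association_test(meth, dosage)
    ok = ~(np.isnan(dosage) | np.isnan(meth))
    slope, t, p = r_to_t_oracle(meth[ok], dosage[ok])
    assert res.n == 10
    assert res.p == pytest.approx(p, rel=1e-12)


@pytest.mark.parametrize("alpha,n_cpg,n_snp,expected", [
    (0.05, 1, 1, 0.05),
    (0.05, 10, 100, 5e-5),
])
def test_bonferroni_exact(alpha, n_cpg, n_snp, expected):
    assert bonferroni_threshold(alpha, n_cpg, n_snp) == pytest.approx(expected, rel=1e-15)


def test_bonferroni_rejects_zero_counts():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0, 10)


def _toy_scan_data(seed=0, n_cpg=20, n_snp=50, missing=False):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(12)]
    dosage = rng.integers(0, 3, size=(n_snp, 12)).astype(float)
    meth = rng.uniform(0, 100, size=(n_cpg, 12))
    cov = np.full((n_cpg, 12), 30, dtype=int)
    if missing:
        mask = rng.random((n_cpg, 12)) < 0.1
        meth[mask] = np.nan
        cov[mask] = 0
        gmask = rng.random((n_snp, 12)) < 0.05
        dosage[gmask] = np.nan
    sites = pd.DataFrame({"chrom": ["chr1"] * (n_cpg // 2) + ["chr2"] * (n_cpg - n_cpg // 2),
                          "pos": np.arange(n_cpg) * 1000 + 500})
    sites.index = site_ids(sites["chrom"], sites["pos"])
    mm = MethMatrix(sites=sites, meth=meth, cov=cov, samples=samples)
    snps = pd.DataFrame({"id": [f"snp{i}" for i in range(n_snp)],
                         "chrom": rng.choice(["chr1", "chr2"], n_snp),
                         "pos": rng.integers(1, 2_000_000, n_snp)})
    gt = GenotypeMatrix(snps=snps, dosage=dosage, samples=samples)
    return mm, gt


@pytest.mark.parametrize("missing", [False, True])
def test_block_scan_equals_per_pair_ols(missing):
    """The matrix-product fast path must agree with scalar OLS per pair."""
    mm, gt = _toy_scan_data(missing=missing)
    slope, t, p, n = _block_stats(mm.meth, gt.dosage)
    for i in range(mm.n_sites):
        for j in range(gt.n_snps):
            ref = association_test(mm.meth[i], gt.dosage[j])
            if not ref.testable:
                assert np.isnan(p[i, j])
                continue
            assert n[i, j] == ref.n
            assert slope[i, j] == pytest.approx(ref.slope, rel=1e-9)
            assert p[i, j] == pytest.approx(ref.p, rel=1e-9, abs=1e-300)


def test_block_scan_matches_oracle_to_12_digits():
    """20 x 50 grid against the independent r-to-t closed form."""
    mm, gt = _toy_scan_data()
    slope, t, p, n = _block_stats(mm.meth, gt.dosage)
    for i in range(mm.n_sites):
        for j in range(gt.n_snps):
            o_slope, o_t, o_p = r_to_t_oracle(mm.meth[i], gt.dosage[j])
            assert t[i, j] == pytest.approx(o_t, rel=1e-12)
            assert p[i, j] == pytest.approx(o_p, rel=1e-12)


def test_cis_trans_labelling_window():
    cpg_chrom = np.array(["chr1", "chr1"])
    cpg_pos = np.array([1_000_000, 1_000_000])
    snp_chrom = np.array(["chr1", "chr1", "chr2"])
    snp_pos = np.array([1_500_000, 2_000_000, 1_000_100])
    m = cis_mask(cpg_chrom, cpg_pos, snp_chrom, snp_pos, 1_000_000)
    # 500 kb away: cis; exactly 1 Mb: trans (strict); other chromosome: trans
    assert m[0].tolist() == [True, False, False]


def test_scan_verdicts_partition_and_precedence():
    rng = np.random.default_rng(5)
    samples = [f"s{i}" for i in range(12)]
    dosage = np.array([[0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2],
                       [2, 2, 2, 2, 1, 1, 1, 1, 0, 0, 0, 0]], float)
    # CpG 0 perfectly explained by both SNPs; SNP0 is cis, SNP1 trans
    meth = np.vstack([50.0 * dosage[0], rng.uniform(0, 100, 12)])
    cov = np.full((2, 12), 30, dtype=int)
    sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1000, 2000]})
    sites.index = site_ids(sites["chrom"], sites["pos"])
    mm = MethMatrix(sites=sites, meth=meth, cov=cov, samples=samples)
    snps = pd.DataFrame({"id": ["a", "b"], "chrom": ["chr1", "chr2"],
                         "pos": [5000, 5000]})
    gt = GenotypeMatrix(snps=snps, dosage=dosage, samples=samples)
    heritable, scan = scan_and_select_heritable(mm, gt, p_threshold=1e-10)
    assert scan.verdicts.tolist() == ["cis_explained", "heritable"]
    counts = scan.counts()
    assert sum(counts.values()) == mm.n_sites
    assert heritable.n_sites == counts["heritable"]


def test_lower_threshold_never_decreases_heritable_count():
    mm, gt = _toy_scan_data(seed=11)
    prev = -1
    for thr in (1e-2, 1e-4, 1e-8, 1e-15):
        heritable, _ = scan_and_select_heritable(mm, gt, p_threshold=thr)
        assert heritable.n_sites >= prev
        prev = heritable.n_sites


def test_recovery_rates_on_planted_classes(recovery_bundle):
    """Low-noise, high-coverage conditions: planted mQTLs removed,
    planted heritable epialleles retained."""
    ev = recovery_bundle.evaluation
    planted_mqtl = ev.loc[["cis_mqtl", "trans_mqtl"], "n_planted"].sum()
    surviving = ev.loc[["cis_mqtl", "trans_mqtl"], "n_heritable_called"].sum()
    assert 1 - surviving / planted_mqtl >= 0.95
    assert ev.attrs["sensitivity"] >= 0.90
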