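"""The CpG pre-filter cascade and the SNP Mendelian-consistency filter."""

import numpy as np
import pandas as pd
import pytest

from methtrio.core import Thresholds, Trio, TrioSet
from methtrio.filtering import (
    FilterLedger,
    apply_cpg_filters,
    filter_snps_mendelian,
    is_autosome,
)
from methtrio.matrix import GenotypeMatrix, MethMatrix, site_ids

from conftest import make_meth_matrix


def _matrix(chroms, positions, samples, cov):
    n = len(positions)
    meth = np.where(np.asarray(cov) > 0, 50.0, np.nan).astype(float)
    sites = pd.DataFrame({"chrom": chroms, "pos": positions})
    sites.index = site_ids(chroms, positions)
    return MethMatrix(sites=sites, meth=meth, cov=np.asarray(cov), samples=samples)


@pytest.fixture
def trios12(toy_trios):
    return toy_trios


def full_cov(n_sites, n_samples, per_sample=10):
    return np.full((n_sites, n_samples), per_sample, dtype=int)


def test_chrx_removed_first(toy_trios, toy_samples):
    cov = full_cov(2, 12)
    mm = _matrix(["chrX", "chr1"], [100, 100], toy_samples, cov)
    out, ledger = apply_cpg_filters(mm, toy_trios, None, None)
    assert out.n_sites == 1
    assert ledger.stages[0] == ("non_autosome", 1, 1)


def test_coverage_boundary_120_reads(toy_trios, toy_samples):
    # 12 samples: 119 total reads removed, 120 kept
    cov = np.full((2, 12), 10, dtype=int)
    cov[0, 0] = 9   # total 119
    mm = _matrix(["chr1", "chr1"], [100, 200], toy_samples, cov)
    out, ledger = apply_cpg_filters(mm, toy_trios, None, None)
    assert list(out.sites["pos"]) == [200]
    stage = dict((s, (r, rem)) for s, r, rem in ledger.stages)
    assert stage["low_coverage"] == (1, 1)


def test_snp_overlap_hits_both_dinucleotide_bases(toy_trios, toy_samples):
    cov = full_cov(3, 12)
    mm = _matrix(["chr1"] * 3, [100, 200, 300], toy_samples, cov)
    # SNP at the C (100), at the G (201), and nowhere near 300
    snps = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 201]})
    out, ledger = apply_cpg_filters(mm, toy_trios, snps, None)
    assert list(out.sites["pos"]) == [300]
    assert dict((s, r) for s, r, _ in ledger.stages)["snp_overlap"] == 2


def test_missing_data_and_imprinted_stages(toy_trios, toy_samples):
    cov = full_cov(3, 12)
    cov[0, 0:6] = 0  # only families 3 and 4 complete -> below min 3
    mm = _matrix(["chr1"] * 3, [100, 5000, 9000], toy_samples, cov)
    mm.meth[0, 0:6] = np.nan
    imprinted = pd.DataFrame({"chrom": ["chr1"], "start": [4500], "end": [5500]})
    out, ledger = apply_cpg_filters(mm, toy_trios, None, imprinted)
    assert list(out.sites["pos"]) == [9000]
    stages = dict((s, r) for s, r, _ in ledger.stages)
    assert stages["missing_data"] == 1
    assert stages["imprinted"] == 1


def test_toy_cascade_ledger_matches_hand_application(toy_trios, toy_samples):
    """Six CpGs, two violating exactly one rule each, applied by hand."""
    cov = full_cov(6, 12)
    cov[4] = 5  # mean coverage 5 < 10
    chroms = ["chr1", "chrY", "chr1", "chr1", "chr1", "chr1"]
    positions = [100, 200, 300, 400, 500, 600]
    mm = _matrix(chroms, positions, toy_samples, cov)
    out, ledger = apply_cpg_filters(mm, toy_trios, None, None)
    remaining = [r for _, _, r in ledger.stages]
    assert remaining == [5, 5, 5, 5, 4]
    assert out.n_sites == 4
    ledger.validate()


def test_filter_counts_invariant_to_row_order(toy_trios, toy_samples):
    rng = np.random.default_rng(0)
    cov = rng.integers(5, 20, size=(20, 12))
    chroms = ["chr1"] * 10 + ["chrX"] * 5 + ["chr2"] * 5
    positions = list(range(100, 2100, 100))
    mm = _matrix(chroms, positions, toy_samples, cov)
    _, ledger1 = apply_cpg_filters(mm, toy_trios, None, None)
    perm = rng.permutation(20)
    mm2 = mm.subset(perm)
    _, ledger2 = apply_cpg_filters(mm2, toy_trios, None, None)
    assert [(s, r) for s, r, _ in ledger1.stages] == \
           [(s, r) for s, r, _ in ledger2.stages]


def test_unknown_chromosome_raises(toy_trios, toy_samples):
    mm = _matrix(["weird"], [100], toy_samples, full_cov(1, 12))
    with pytest.raises(ValueError, match="weird"):
        apply_cpg_filters(mm, toy_trios, None, None)


@pytest.mark.parametrize("name,expected", [
    ("chr1", True), ("22", True), ("chrX", False), ("Y", False), ("chrMT", False),
])
def test_is_autosome(name, expected):
    assert is_autosome(name) is expected


# ------------------------------------------------------------- SNP filter

def _gt(dosages, samples):
    n = len(dosages)
    snps = pd.DataFrame({"id": [f"s{i}" for i in range(n)],
                         "chrom": ["chr1"] * n,
                         "pos": list(range(100, 100 + n))})
    return GenotypeMatrix(snps=snps, dosage=np.asarray(dosages, dtype=float),
                          samples=samples)


def test_mendelian_error_snp_removed(toy_trios, toy_samples):
    base = [0.0] * 12
    bad = list(base)
    bad[2] = 1.0  # parents (0,0) child 1 in family 1
    forced_het = [0, 2, 1] * 4  # parents (0,2) admit only 1
    gt = _gt([base, bad, forced_het], toy_samples)
    out, ledger = filter_snps_mendelian(gt, toy_trios)
    assert list(out.snps["id"]) == ["s0", "s2"]
    assert dict((s, r) for s, r, _ in ledger.stages)["mendelian_error"] == 1


def test_high_missing_rate_snp_removed(toy_trios, toy_samples):
    good = [1.0] * 12
    holey = [1.0] * 12
    holey[0] = np.nan  # 1/12 = 8.3% > 2%
    gt = _gt([good, holey], toy_samples)
    out, ledger = filter_snps_mendelian(gt, toy_trios)
    assert list(out.snps["id"]) == ["s0"]
    assert dict((s, r) for s, r, _ in ledger.stages)["missing_rate"] == 1


def test_consistent_panel_removes_nothing(toy_trios, toy_samples):
    gt = _gt([[0.0] * 12, [1, 1, 1] * 4, [2, 0, 1] * 4], toy_samples)
    out, ledger = filter_snps_mendelian(gt, toy_trios)
    assert out.n_snps == 3
    assert all(r == 0 for _, r, _ in ledger.stages)


def test_invalid_dosage_rejected(toy_samples):
    snps = pd.DataFrame({"id": ["s0"], "chrom": ["chr1"], "pos": [100]})
    with pytest.raises(ValueError):
        GenotypeMatrix(snps=snps, dosage=np.array([[3.0] + [0.0] * 11]),
                       samples=toy_samples)


def test_ledger_invariants():
    ledger = FilterLedger(input_count=10)
    ledger.add("a", 3)
    ledger.add("b", 0)
    ledger.add("c", 7)
    assert ledger.remaining == 0
    ledger.validate()
    with pytest.raises(ValueError):
        ledger.add("d", 1)
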