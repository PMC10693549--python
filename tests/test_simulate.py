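"""Synthetic trio-methylome generator: determinism, truth bookkeeping
and the statistical structure the downstream stages rely on."""

import numpy as np
import pytest

from methtrio.core import MethState, punnett_offspring_states
from methtrio.mendelian import state_codes
from methtrio.simulate import SimConfig, simulate_dataset

from conftest import SMALL_SIM


def test_seeded_determinism():
    a = simulate_dataset(SMALL_SIM)
    b = simulate_dataset(SMALL_SIM)
    assert np.array_equal(a.meth.meth, b.meth.meth, equal_nan=True)
    assert np.array_equal(a.meth.cov, b.meth.cov)
    assert np.array_equal(a.genotypes.dosage, b.genotypes.dosage)
    assert a.truth.table.equals(b.truth.table)
    assert a.layout.sequence == b.layout.sequence


def test_truth_class_counts_match_config(small_dataset):
    counts = small_dataset.truth.class_counts()
    cfg = SMALL_SIM
    assert counts == {
        "stable": cfg.n_stable, "cis_mqtl": cfg.n_cis_mqtl,
        "trans_mqtl": cfg.n_trans_mqtl, "heritable_epiallele": cfg.n_heritable,
        "non_mendelian": cfg.n_non_mendelian, "imprinted": cfg.n_imprinted,
    }


def test_cpg_positions_strictly_increasing_per_chromosome(small_dataset):
    sites = small_dataset.meth.sites
    for _, grp in sites.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        assert (np.diff(pos) >= 2).all()  # dinucleotides cannot overlap


def test_driver_snp_placement(small_dataset):
    truth = small_dataset.truth.table
    snps = small_dataset.genotypes.snps
    for _, row in truth[truth["cls"].isin(["cis_mqtl", "trans_mqtl"])].iterrows():
        snp = snps.loc[row["driver_snp"]]
        if row["cls"] == "cis_mqtl":
            assert snp["chrom"] == row["chrom"]
            assert abs(snp["pos"] - row["pos"]) < 1_000_000
        else:
            assert snp["chrom"] != row["chrom"]


def test_sequence_has_cpg_dinucleotides_and_gc_structure(small_dataset):
    seq = small_dataset.layout.sequence
    sites = small_dataset.meth.sites
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        assert seq[chrom][pos - 1:pos + 1] == "CG"
    # islands markedly GC-richer than background
    isl = small_dataset.layout.islands.iloc[0]
    s = seq[isl["chrom"]]
    island_seq = s[isl["start"]:isl["end"]]
    gc_island = sum(b in "GC" for b in island_seq) / len(island_seq)
    background = s[200_000:210_000]
    gc_bg = sum(b in "GC" for b in background) / len(background)
    assert gc_island > 0.6
    assert gc_bg < 0.55


def test_heritable_cpgs_follow_punnett_when_noise_free():
    cfg = SimConfig(seed=5, n_stable=40, n_cis_mqtl=0, n_trans_mqtl=0,
                    n_heritable=40, n_non_mendelian=0, n_imprinted=0,
                    n_background_snps=10, noise_sd=0.0, mean_coverage=500.0,
                    missing_rate=0.0, chrom_length=1_000_000)
    ds = simulate_dataset(cfg)
    codes = state_codes(ds.meth.meth)
    heritable = ds.truth.table["cls"] == "heritable_epiallele"
    rows = ds.meth.sites.index.get_indexer(ds.truth.table.index[heritable])
    states = [MethState.U, MethState.I, MethState.M]
    for i in rows:
        for f, m, c in ds.trios.member_indices(ds.meth.samples):
            fa, mo, ch = codes[i, f], codes[i, m], codes[i, c]
            assert states[ch] in punnett_offspring_states(states[fa], states[mo])


def test_vcf_trios_pass_transmission_check_without_genotyping_error(small_dataset):
    ds = small_dataset
    for f, m, c in ds.trios.member_indices(ds.genotypes.samples):
        fa = ds.genotypes.dosage[:, f]
        mo = ds.genotypes.dosage[:, m]
        ch = ds.genotypes.dosage[:, c]
        lo = np.maximum(0, fa - 1) + np.maximum(0, mo - 1)
        hi = np.minimum(1, fa) + np.minimum(1, mo)
        assert ((ch >= lo) & (ch <= hi)).all()


def test_binomial_sampling_is_unbiased():
    """Observed percent should track true methylation within MC error."""
    cfg = SimConfig(seed=9, n_stable=400, n_cis_mqtl=0, n_trans_mqtl=0,
                    n_heritable=0, n_non_mendelian=0, n_imprinted=0,
                    n_background_snps=5, noise_sd=0.0, missing_rate=0.0,
                    chrom_length=1_000_000)
    ds = simulate_dataset(cfg)
    truth = ds.truth.table
    sea = (truth["cls"] == "stable").to_numpy()
    means = ds.meth.mean_meth()
    # true values are 95 (open sea) or 3 (island); grand mean of observed
    # per-class means must match within ~3 standard errors
    high = means[sea & (means > 50)]
    low = means[sea & (means <= 50)]
    se_high = 100 * np.sqrt(0.95 * 0.05 / 12) / np.sqrt(len(high))
    assert abs(high.mean() - 95.0) < 3 * se_high + 0.2
    assert abs(low.mean() - 3.0) < 1.0


def test_heritable_cpgs_uncorrelated_with_snps(recovery_bundle):
    """Planted epialleles are independent of every SNP by construction."""
    ev = recovery_bundle.evaluation
    # none of the planted heritable CpGs reaching the scan may be
    # cis-explained, and chance trans hits must stay rare
    assert ev.loc["heritable_epiallele", "n_cis_explained"] == 0
    assert ev.loc["heritable_epiallele", "n_trans_explained"] <= 0.1 * ev.loc[
        "heritable_epiallele", "n_planted"]


def test_non_mendelian_class_stresses_the_filter(small_dataset):
    """Some planted non-Mendelian CpGs must violate trio compatibility."""
    ds = small_dataset
    codes = state_codes(ds.meth.meth)
    from methtrio.mendelian import trio_compatibility_matrix
    compat = trio_compatibility_matrix(codes, ds.trios, ds.meth.samples)
    nm = ds.truth.table["cls"] == "non_mendelian"
    rows = ds.meth.sites.index.get_indexer(ds.truth.table.index[nm])
    violations = (compat[rows] == 0).any(axis=1)
    assert violations.mean() > 0.5


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_families=0)
    with pytest.raises(ValueError):
        SimConfig(mean_coverage=0)
    with pytest.raises(ValueError):
        SimConfig(n_stable=-1)
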