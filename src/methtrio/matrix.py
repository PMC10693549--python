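"""In-memory containers: CpG methylation matrix and SNP dosage matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def site_ids(chroms, positions) -> pd.Index:
    return pd.Index([f"{c}:{p}" for c, p in zip(chroms, positions)])


@dataclass
class MethMatrix:
    """CpG sites x samples methylation percents with read coverage.

    sites : DataFrame with columns ``chrom`` (str) and ``pos`` (int,
        1-based position of the C of the CpG dinucleotide), one row per
        site, indexed by "chrom:pos" ids.
    meth : float array (n_sites, n_samples), percent in [0, 100],
        NaN where unobserved.
    cov : int array (n_sites, n_samples), read counts; 0 iff meth NaN.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    cov: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=float)
        self.cov = np.asarray(self.cov)
        n = len(self.sites)
        if self.meth.shape != (n, len(self.samples)) or self.cov.shape != self.meth.shape:
            raise ValueError("meth/cov shape does not match sites x samples")
        missing = np.isnan(self.meth)
        if np.any(missing != (self.cov == 0)):
            raise ValueError("meth must be NaN exactly where cov == 0")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.meth, initial=0.0) < 0 or np.nanmax(self.meth, initial=0.0) > 100:
                raise ValueError("methylation percents must lie in [0, 100]")
        if not self.sites.index.equals(site_ids(self.sites["chrom"], self.sites["pos"])):
            self.sites = self.sites.copy()
            self.sites.index = site_ids(self.sites["chrom"], self.sites["pos"])

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "MethMatrix":
        """Row-subset by boolean mask or integer index array."""
        return MethMatrix(
            sites=self.sites.iloc[np.asarray(mask).nonzero()[0]]
            if np.asarray(mask).dtype == bool else self.sites.iloc[mask],
            meth=self.meth[mask],
            cov=self.cov[mask],
            samples=list(self.samples),
        )

    def mean_meth(self) -> np.ndarray:
        """Per-site mean methylation across observed samples."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.meth, axis=1)


@dataclass
class GenotypeMatrix:
    """SNPs x samples additive dosages.

    snps : DataFrame with columns ``id``, ``chrom``, ``pos`` (1-based),
        indexed by SNP id.
    dosage : float array (n_snps, n_samples) with values {0, 1, 2} or
        NaN for a missing genotype.
    """

    snps: pd.DataFrame
    dosage: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.snps), len(self.samples)):
            raise ValueError("dosage shape does not match snps x samples")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])
            raise ValueError(f"dosages must be 0, 1 or 2; found {bad}")
        if "id" in self.snps.columns and not self.snps.index.equals(pd.Index(self.snps["id"])):
            self.snps = self.snps.copy()
            self.snps.index = pd.Index(self.snps["id"])

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask).nonzero()[0] if np.asarray(mask).dtype == bool else np.asarray(mask)
        return GenotypeMatrix(
            snps=self.snps.iloc[idx], dosage=self.dosage[idx], samples=list(self.samples)
        )
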