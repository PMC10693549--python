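"""Exhaustive CpG x SNP association scan (mQTL exclusion).

Each Mendelian CpG is regressed on the additive dosage of every SNP
(simple OLS, no covariates).  A CpG with any association below the
Bonferroni threshold is "explained by genetics" — labelled cis if at
least one significant SNP lies within the cis window on the same
chromosome (cis takes precedence), trans otherwise.  Survivors are the
candidate heritable CpGs.

The scan streams CpGs in blocks and computes all per-pair OLS
statistics with masked matrix products; ``association_test`` is the
scalar reference path and the two are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import Thresholds
from .matrix import GenotypeMatrix, MethMatrix


class AssocResult(NamedTuple):
    slope: float
    t: float
    p: float
    n: int
    testable: bool


def association_test(meth_vector: np.ndarray, dosage_vector: np.ndarray) -> AssocResult:
    """OLS of methylation percent on additive dosage, one pair.

    Pairwise-complete observations; untestable (never significant) if
    fewer than 3 complete pairs or either vector is constant.
    """
    x = np.asarray(dosage_vector, dtype=float)
    y = np.asarray(meth_vector, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return AssocResult(np.nan, np.nan, np.nan, n, False)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return AssocResult(np.nan, np.nan, np.nan, n, False)
    sxy = float(xc @ yc)
    slope = sxy / sxx
    rss = syy - slope * sxy
    df = n - 2
    if rss <= 0.0:  # numerically perfect fit
        t = np.inf if slope > 0 else -np.inf
        return AssocResult(slope, t, 0.0, n, True)
    se = np.sqrt(rss / df / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return AssocResult(slope, float(t), float(p), n, True)


def bonferroni_threshold(alpha: float, n_cpg: int, n_snp: int) -> float:
    """Family-wise p-value threshold alpha / (n_cpg * n_snp)."""
    if alpha <= 0 or n_cpg <= 0 or n_snp <= 0:
        raise ValueError("alpha and test counts must be positive")
    return alpha / (n_cpg * n_snp)


def _block_stats(M: np.ndarray, G: np.ndarray):
    """Vectorised per-pair OLS for a CpG block against all SNPs.

    M : (B, S) methylation block, NaN missing.  G : (K, S) dosages,
    NaN missing.  Returns slope, t, p, n arrays of shape (B, K); NaN
    statistics mark untestable pairs.
    """
    B, S = M.shape
    K = G.shape[0]
    VM = ~np.isnan(M)
    VG = ~np.isnan(G)
    M0 = np.where(VM, M, 0.0)
    G0 = np.where(VG, G, 0.0)
    # pairwise-complete counts and sums via masked matrix products
    Vm = VM.astype(float)
    Vg = VG.astype(float)
    n = Vm @ Vg.T                     # (B, K)
    Sx = Vm @ G0.T                    # sum of dosage over complete pairs
    Sy = M0 @ Vg.T
    Sxx = Vm @ (G0 * G0).T
    Syy = (M0 * M0) @ Vg.T
    Sxy = M0 @ G0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx = Sxx - Sx * Sx / n
        syy = Syy - Sy * Sy / n
        sxy = Sxy - Sx * Sy / n
        # relative tolerances: a centred sum of squares at rounding-error
        # scale relative to the raw sum of squares is a constant vector
        testable = (n >= 3) & (sxx > 1e-10 * (Sxx + 1.0)) & (syy > 1e-10 * (Syy + 1.0))
        slope = np.where(testable, sxy / sxx, np.nan)
        rss = np.where(testable, syy - slope * sxy, np.nan)
        df = n - 2
        perfect = testable & (rss <= 1e-10 * syy)
        se = np.sqrt(rss / df / sxx)
        t = slope / se
        t = np.where(perfect, np.where(slope >= 0, np.inf, -np.inf), t)
        p = np.full(t.shape, np.nan)
        fin = testable & np.isfinite(t)
        p[fin] = 2.0 * stats.t.sf(np.abs(t[fin]), df[fin])
        p[testable & ~np.isfinite(t)] = 0.0
    return slope, t, p, n.astype(int)


@dataclass
class ScanResult:
    """Outcome of the mQTL exclusion scan over a Mendelian CpG set."""

    verdicts: pd.Series  # per CpG: cis_explained / trans_explained / heritable
    significant: pd.DataFrame  # cpg, snp, slope, t, p, label
    p_threshold: float

    def counts(self) -> dict[str, int]:
        c = self.verdicts.value_counts().to_dict()
        return {k: int(c.get(k, 0))
                for k in ("cis_explained", "trans_explained", "heritable")}


def cis_mask(cpg_chrom: np.ndarray, cpg_pos: np.ndarray,
             snp_chrom: np.ndarray, snp_pos: np.ndarray,
             cis_window: int) -> np.ndarray:
    """(n_cpg, n_snp) boolean: same chromosome and distance < window."""
    same = cpg_chrom[:, None] == snp_chrom[None, :]
    dist = np.abs(cpg_pos[:, None].astype(np.int64) - snp_pos[None, :].astype(np.int64))
    return same & (dist < cis_window)


def scan_and_select_heritable(
    meth: MethMatrix,
    gt: GenotypeMatrix,
    thresholds: Thresholds = Thresholds(),
    p_threshold: float | None = None,
    block_size: int = 512,
) -> tuple[MethMatrix, ScanResult]:
    """Test every Mendelian CpG against every SNP and keep survivors.

    ``p_threshold`` defaults to the Bonferroni bound
    alpha / (n_cpg * n_snp) computed from the actual scan dimensions.
    """
    if list(meth.samples) != list(gt.samples):
        raise ValueError("methylation and genotype samples differ or are reordered")
    n_cpg, n_snp = meth.n_sites, gt.n_snps
    if p_threshold is None:
        p_threshold = bonferroni_threshold(thresholds.alpha, n_cpg, n_snp)

    cpg_chrom = meth.sites["chrom"].to_numpy()
    cpg_pos = meth.sites["pos"].to_numpy()
    snp_chrom = gt.snps["chrom"].to_numpy()
    snp_pos = gt.snps["pos"].to_numpy()
    snp_ids = gt.snps.index.to_numpy()

    verdicts = np.full(n_cpg, "heritable", dtype=object)
    sig_rows = []
    for lo in range(0, n_cpg, block_size):
        hi = min(lo + block_size, n_cpg)
        slope, t, p, n = _block_stats(meth.meth[lo:hi], gt.dosage)
        sig = np.zeros(p.shape, dtype=bool)
        fin = ~np.isnan(p)
        sig[fin] = p[fin] < p_threshold
        if not sig.any():
            continue
        cm = cis_mask(cpg_chrom[lo:hi], cpg_pos[lo:hi], snp_chrom, snp_pos,
                      thresholds.cis_window)
        any_cis = (sig & cm).any(axis=1)
        any_sig = sig.any(axis=1)
        verdicts[lo:hi][any_cis] = "cis_explained"
        verdicts[lo:hi][any_sig & ~any_cis] = "trans_explained"
        ci, sj = np.where(sig)
        sig_rows.append(pd.DataFrame({
            "cpg": meth.sites.index.to_numpy()[lo + ci],
            "snp": snp_ids[sj],
            "slope": slope[ci, sj],
            "t": t[ci, sj],
            "p": p[ci, sj],
            "label": np.where(cm[ci, sj], "cis", "trans"),
        }))

    significant = (pd.concat(sig_rows, ignore_index=True) if sig_rows
                   else pd.DataFrame(columns=["cpg", "snp", "slope", "t", "p", "label"]))
    verdict_series = pd.Series(verdicts, index=meth.sites.index, name="verdict")
    heritable = meth.subset((verdict_series == "heritable").to_numpy())
    return heritable, ScanResult(verdict_series, significant, p_threshold)
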