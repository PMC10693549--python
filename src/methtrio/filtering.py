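"""Pre-filter cascade for CpGs and Mendelian-consistency filter for SNPs.

Each removal is attributed to the FIRST failing stage in a fixed
order, so the ledger is deterministic and its counts always sum back
to the input count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Thresholds, TrioSet, dosage_transmission_set
from .matrix import GenotypeMatrix, MethMatrix

_AUTOSOME_RE = re.compile(r"^(chr)?(\d+)$", re.IGNORECASE)
_KNOWN_NON_AUTOSOME = {"X", "Y", "M", "MT", "W", "Z"}


@dataclass
class FilterLedger:
    """Ordered bookkeeping of sites removed and remaining per stage."""

    input_count: int
    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_removed: int) -> None:
        prev = self.stages[-1][2] if self.stages else self.input_count
        remaining = prev - n_removed
        if remaining < 0:
            raise ValueError(f"stage {stage!r} removes more sites than remain")
        self.stages.append((stage, n_removed, remaining))

    @property
    def remaining(self) -> int:
        return self.stages[-1][2] if self.stages else self.input_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "removed", "remaining"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def validate(self) -> None:
        total_removed = sum(r for _, r, _ in self.stages)
        if total_removed + self.remaining != self.input_count:
            raise AssertionError("ledger counts do not sum to the input count")
        prev = self.input_count
        for _, _, rem in self.stages:
            if rem > prev:
                raise AssertionError("remaining count increased across stages")
            prev = rem


def is_autosome(chrom: str) -> bool:
    if _AUTOSOME_RE.match(chrom):
        return True
    stripped = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if stripped.upper() in _KNOWN_NON_AUTOSOME:
        return False
    raise ValueError(f"unknown chromosome name: {chrom!r}")


def _autosome_mask(chroms: np.ndarray) -> np.ndarray:
    unknown = []
    mask = np.zeros(len(chroms), dtype=bool)
    for name in pd.unique(chroms):
        try:
            ok = is_autosome(name)
        except ValueError:
            unknown.append(name)
            continue
        mask[chroms == name] = ok
    if unknown:
        raise ValueError(f"unknown chromosome names: {unknown}")
    return mask


def _in_intervals(chroms: np.ndarray, pos: np.ndarray,
                  intervals: pd.DataFrame) -> np.ndarray:
    """1-based positions falling inside 0-based half-open intervals."""
    hit = np.zeros(len(pos), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return hit
    for chrom, grp in intervals.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        p0 = pos[sel] - 1
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        # merge overlapping intervals so searchsorted logic is valid
        ms, me = [], []
        for s, e in zip(starts, ends):
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        ms_a, me_a = np.asarray(ms), np.asarray(me)
        idx = np.searchsorted(ms_a, p0, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(p0.shape, dtype=bool)
        inside[ok] = p0[ok] < me_a[idx[ok]]
        hit[np.where(sel)[0]] = inside
    return hit


def complete_family_counts(meth: MethMatrix, trios: TrioSet) -> np.ndarray:
    """Per-CpG number of families in which all three members are observed."""
    idx = trios.member_indices(meth.samples)
    observed = ~np.isnan(meth.meth)
    counts = np.zeros(meth.n_sites, dtype=int)
    for f, m, c in idx:
        counts += observed[:, f] & observed[:, m] & observed[:, c]
    return counts


def apply_cpg_filters(
    meth: MethMatrix,
    trios: TrioSet,
    snp_positions: pd.DataFrame | None,
    imprinted_regions: pd.DataFrame | None,
    thresholds: Thresholds = Thresholds(),
) -> tuple[MethMatrix, FilterLedger]:
    """Filter CpGs in the fixed cascade order.

    1. drop non-autosomal CpGs;
    2. drop CpGs whose C or G base coincides with a known SNP position
       (snp_positions: DataFrame with 1-based ``chrom``/``pos``);
    3. drop CpGs observed in fewer than ``min_complete_families``
       complete families;
    4. drop CpGs inside imprinted regions (BED-style DataFrame);
    5. drop CpGs with total reads < min_mean_cov * n_samples.
    """
    chroms = meth.sites["chrom"].to_numpy()
    pos = meth.sites["pos"].to_numpy()
    ledger = FilterLedger(input_count=meth.n_sites)
    alive = np.ones(meth.n_sites, dtype=bool)

    keep = _autosome_mask(chroms)
    removed = alive & ~keep
    ledger.add("non_autosome", int(removed.sum()))
    alive &= keep

    if snp_positions is not None and len(snp_positions):
        snp_hit = np.zeros(meth.n_sites, dtype=bool)
        for chrom, grp in snp_positions.groupby("chrom"):
            sel = chroms == chrom
            if not sel.any():
                continue
            spos = np.unique(grp["pos"].to_numpy())
            # either base of the CpG dinucleotide may be the SNP
            hit = np.isin(pos[sel], spos) | np.isin(pos[sel] + 1, spos)
            snp_hit[np.where(sel)[0]] = hit
    else:
        snp_hit = np.zeros(meth.n_sites, dtype=bool)
    removed = alive & snp_hit
    ledger.add("snp_overlap", int(removed.sum()))
    alive &= ~snp_hit

    counts = complete_family_counts(meth, trios)
    enough = counts >= thresholds.min_complete_families
    removed = alive & ~enough
    ledger.add("missing_data", int(removed.sum()))
    alive &= enough

    imprinted_hit = _in_intervals(chroms, pos, imprinted_regions)
    removed = alive & imprinted_hit
    ledger.add("imprinted", int(removed.sum()))
    alive &= ~imprinted_hit

    total_cov = meth.cov.sum(axis=1)
    enough_cov = total_cov >= thresholds.min_mean_cov * meth.n_samples
    removed = alive & ~enough_cov
    ledger.add("low_coverage", int(removed.sum()))
    alive &= enough_cov

    ledger.validate()
    return meth.subset(alive), ledger


def filter_snps_mendelian(
    gt: GenotypeMatrix,
    trios: TrioSet,
    max_missing_rate: float = 0.02,
) -> tuple[GenotypeMatrix, FilterLedger]:
    """Drop SNPs with too many missing calls or a Mendelian error.

    A Mendelian error is a trio with complete data where the child
    dosage is outside the transmission set of the parental dosages.
    """
    ledger = FilterLedger(input_count=gt.n_snps)
    alive = np.ones(gt.n_snps, dtype=bool)

    missing_rate = np.isnan(gt.dosage).mean(axis=1)
    ok = missing_rate <= max_missing_rate
    ledger.add("missing_rate", int((alive & ~ok).sum()))
    alive &= ok

    consistent = np.ones(gt.n_snps, dtype=bool)
    trans_ok = np.zeros((3, 3, 3), dtype=bool)
    for a in range(3):
        for b in range(3):
            for c in dosage_transmission_set(a, b):
                trans_ok[a, b, c] = True
    for f, m, c in trios.member_indices(gt.samples):
        fa, mo, ch = gt.dosage[:, f], gt.dosage[:, m], gt.dosage[:, c]
        complete = ~(np.isnan(fa) | np.isnan(mo) | np.isnan(ch))
        idx = np.where(complete)[0]
        bad = ~trans_ok[fa[idx].astype(int), mo[idx].astype(int), ch[idx].astype(int)]
        consistent[idx[bad]] = False
    ledger.add("mendelian_error", int((alive & ~consistent).sum()))
    alive &= consistent

    ledger.validate()
    return gt.subset(alive), ledger
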