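"""Flanking-region methylation scenarios and flank GC content.

Each index CpG is classified by the cross-sample mean methylation of
the CpGs in its 1 kb upstream and downstream windows:

A   both flanks methylated regions, index methylated (MMM)
B   both flanks unmethylated regions, index unmethylated (UUU)
C   both flanks methylated, index unmethylated (MUM)
D   both flanks unmethylated, index methylated (UMU)
E   one flank methylated, the other unmethylated, any index state
    (a methylation-domain transition)

A flank is a methylated (unmethylated) region when strictly more than
``flank_purity`` of its observed CpGs are methylated (unmethylated).
Everything else, including flanks with too few CpGs, is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Thresholds
from .matrix import MethMatrix

SCENARIOS = ("A", "B", "C", "D", "E", "unclassified")


@dataclass(frozen=True)
class FlankProfile:
    """Counts of methylated/unmethylated/total flanking CpGs per side."""

    up_methylated: int
    up_unmethylated: int
    up_total: int
    down_methylated: int
    down_unmethylated: int
    down_total: int
    index_mean: float

    def __post_init__(self) -> None:
        if self.up_methylated + self.up_unmethylated > self.up_total:
            raise ValueError("upstream state counts exceed total")
        if self.down_methylated + self.down_unmethylated > self.down_total:
            raise ValueError("downstream state counts exceed total")


def _side_counts(means: np.ndarray, thresholds: Thresholds):
    obs = means[~np.isnan(means)]
    meth = int((obs >= thresholds.state_high).sum())
    unmeth = int((obs <= thresholds.state_low).sum())
    return meth, unmeth, obs.size


def flank_profile(index: int, meth: MethMatrix,
                  flank_width: int = 1000,
                  thresholds: Thresholds = Thresholds(),
                  mean_meth: np.ndarray | None = None) -> FlankProfile:
    """Profile the 1 kb flanks of one index CpG (row ``index``).

    Flanking CpGs are classified by their cross-sample mean: methylated
    in [state_high, 100], unmethylated in [0, state_low]; intermediates
    count only toward the totals.  The index CpG itself is excluded.
    """
    if mean_meth is None:
        mean_meth = meth.mean_meth()
    chroms = meth.sites["chrom"].to_numpy()
    pos = meth.sites["pos"].to_numpy()
    c, p = chroms[index], pos[index]
    same = chroms == c
    up = same & (pos >= p - flank_width) & (pos < p)
    down = same & (pos > p) & (pos <= p + flank_width)
    um, uu, ut = _side_counts(mean_meth[up], thresholds)
    dm, du, dt = _side_counts(mean_meth[down], thresholds)
    return FlankProfile(um, uu, ut, dm, du, dt, float(mean_meth[index]))


def _side_region(meth_count: int, unmeth_count: int, total: int,
                 purity: float, min_cpgs: int) -> str:
    if total < min_cpgs:
        return "insufficient"
    if meth_count > purity * total:
        return "methylated"
    if unmeth_count > purity * total:
        return "unmethylated"
    return "mixed"


def classify_scenario(profile: FlankProfile,
                      thresholds: Thresholds = Thresholds()) -> str:
    """Assign a flanking scenario A-E or unclassified."""
    up = _side_region(profile.up_methylated, profile.up_unmethylated,
                      profile.up_total, thresholds.flank_purity,
                      thresholds.min_flank_cpgs)
    down = _side_region(profile.down_methylated, profile.down_unmethylated,
                        profile.down_total, thresholds.flank_purity,
                        thresholds.min_flank_cpgs)
    if "insufficient" in (up, down):
        return "unclassified"
    idx = profile.index_mean
    index_meth = not np.isnan(idx) and idx >= thresholds.state_high
    index_unmeth = not np.isnan(idx) and idx <= thresholds.state_low
    if up == "methylated" and down == "methylated":
        if index_meth:
            return "A"
        if index_unmeth:
            return "C"
        return "unclassified"
    if up == "unmethylated" and down == "unmethylated":
        if index_unmeth:
            return "B"
        if index_meth:
            return "D"
        return "unclassified"
    if {up, down} == {"methylated", "unmethylated"}:
        return "E"
    return "unclassified"


def classify_cpgs(meth: MethMatrix, indices: np.ndarray | None = None,
                  thresholds: Thresholds = Thresholds()) -> pd.Series:
    """Scenario per CpG (rows ``indices``, default all) of a matrix."""
    mean_meth = meth.mean_meth()
    if indices is None:
        indices = np.arange(meth.n_sites)
    out = []
    for i in indices:
        prof = flank_profile(int(i), meth, thresholds.flank_width,
                             thresholds, mean_meth)
        out.append(classify_scenario(prof, thresholds))
    return pd.Series(out, index=meth.sites.index[indices], name="scenario")


def scenario_table(groups: dict[str, pd.Series]) -> pd.DataFrame:
    """Scenario x group count table (rows A-E + unclassified)."""
    table = pd.DataFrame(index=list(SCENARIOS))
    for name, series in groups.items():
        counts = series.value_counts()
        table[name] = [int(counts.get(s, 0)) for s in SCENARIOS]
    return table


def flank_gc_content(chrom: str, pos: int, sequence: dict[str, str],
                     flank_width: int = 1000) -> float:
    """G+C fraction of the two flanks combined, index base excluded.

    The window is [pos - flank_width, pos - 1] and
    [pos + 1, pos + flank_width] (1-based), truncated at chromosome
    ends with the denominator renormalised to the surviving length.
    """
    seq = sequence[chrom]
    L = len(seq)
    if pos < 1 or pos > L:
        raise ValueError(f"position {pos} outside {chrom!r} (length {L})")
    lo = max(pos - flank_width, 1)
    hi = min(pos + flank_width, L)
    window = seq[lo - 1:pos - 1] + seq[pos:hi]
    if not window:
        raise ValueError("flanking window is empty")
    gc = sum(1 for b in window.upper() if b in "GC")
    return gc / len(window)
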