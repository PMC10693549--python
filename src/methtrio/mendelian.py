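"""Selection of Mendelian CpGs.

A Mendelian CpG is parent-variable (mother-father methylation differs
by more than ``parental_delta`` percentage points in at least one
family) and its U/I/M trio pattern is compatible with one-epiallele-
per-parent transmission in every family with complete data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Thresholds, TrioSet, compatibility_lookup
from .filtering import FilterLedger, complete_family_counts
from .matrix import MethMatrix


def state_codes(meth: np.ndarray, thresholds: Thresholds = Thresholds()) -> np.ndarray:
    """Vectorised U/I/M categorisation: 0=U, 1=I, 2=M, -1=missing."""
    bad = (meth < 0) | (meth > 100)
    if np.any(bad):
        raise ValueError("methylation percents out of [0, 100]")
    codes = np.full(meth.shape, -1, dtype=np.int8)
    obs = ~np.isnan(meth)
    codes[obs & (meth <= thresholds.state_low)] = 0
    codes[obs & (meth >= thresholds.state_high)] = 2
    codes[obs & (meth > thresholds.state_low) & (meth < thresholds.state_high)] = 1
    return codes


def parental_variability(meth: MethMatrix, trios: TrioSet,
                         delta: float = 20.0) -> np.ndarray:
    """True where |mother - father| > delta (strict) in >= 1 family."""
    out = np.zeros(meth.n_sites, dtype=bool)
    for f, m, _ in trios.member_indices(meth.samples):
        diff = np.abs(meth.meth[:, m] - meth.meth[:, f])
        out |= np.nan_to_num(diff, nan=0.0) > delta
    return out


def trio_compatibility_matrix(codes: np.ndarray, trios: TrioSet,
                              samples: list[str]) -> np.ndarray:
    """Per (CpG, family): 1 compatible, 0 incompatible, -1 incomplete."""
    lookup = compatibility_lookup()
    n_fam = len(trios)
    out = np.full((codes.shape[0], n_fam), -1, dtype=np.int8)
    for k, (f, m, c) in enumerate(trios.member_indices(samples)):
        fa, mo, ch = codes[:, f], codes[:, m], codes[:, c]
        complete = (fa >= 0) & (mo >= 0) & (ch >= 0)
        idx = np.where(complete)[0]
        ok = lookup[9 * fa[idx].astype(int) + 3 * mo[idx].astype(int) + ch[idx]]
        out[idx, k] = ok.astype(np.int8)
    return out


def select_mendelian(
    meth: MethMatrix,
    trios: TrioSet,
    thresholds: Thresholds = Thresholds(),
) -> tuple[MethMatrix, pd.DataFrame, FilterLedger]:
    """Split filtered CpGs into Mendelian and non-Mendelian.

    Returns the Mendelian subset, a per-CpG info table (variability
    flag, compatibility flag, per-sample state codes) and a ledger with
    the two removal stages (variability first, then compatibility).

    Raises if any CpG has fewer complete families than the upstream
    filter guarantees — that is a contract violation, not data.
    """
    counts = complete_family_counts(meth, trios)
    if np.any(counts < thresholds.min_complete_families):
        bad = meth.sites.index[counts < thresholds.min_complete_families][:5].tolist()
        raise ValueError(
            f"CpGs with < {thresholds.min_complete_families} complete families "
            f"reached Mendelian selection (e.g. {bad}); run apply_cpg_filters first"
        )
    codes = state_codes(meth.meth, thresholds)
    variable = parental_variability(meth, trios, thresholds.parental_delta)
    compat = trio_compatibility_matrix(codes, trios, meth.samples)
    # compatible in every family with complete data
    all_compatible = ~np.any(compat == 0, axis=1)
    keep = variable & all_compatible

    info = pd.DataFrame({
        "variable_parents": variable,
        "all_families_compatible": all_compatible,
        "mendelian": keep,
    }, index=meth.sites.index)
    for j, s in enumerate(meth.samples):
        info[f"state_{s}"] = codes[:, j]

    ledger = FilterLedger(input_count=meth.n_sites)
    ledger.add("not_parent_variable", int((~variable).sum()))
    ledger.add("mendelian_incompatible", int((variable & ~all_compatible).sum()))
    ledger.validate()
    return meth.subset(keep), info, ledger


def export_mendelian_bed(meth: MethMatrix, path) -> None:
    """Single-base BED (0-based half-open) of the selected CpGs."""
    df = pd.DataFrame({
        "chrom": meth.sites["chrom"],
        "start": meth.sites["pos"] - 1,
        "end": meth.sites["pos"],  # the C of the dinucleotide
        "name": meth.sites.index,
    })
    df.to_csv(path, sep="\t", header=False, index=False)
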