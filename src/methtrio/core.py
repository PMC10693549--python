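"""Domain types and the diploid epiallele transmission model.

A CpG's methylation percent in one sample is categorised into three
states: unmethylated (U, <= 20%), intermediate (I, strictly between 20
and 80%) and methylated (M, >= 80%).  Inheritance of the state is
modelled as a diploid epiallele: M carries two methylated epialleles
(mm), I one (mu) and U none (uu).  A child receives one epiallele from
each parent, exactly like a biallelic genotype, so trio compatibility
is plain Punnett-square membership.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field


class MethState(enum.IntEnum):
    """Categorical methylation state of one CpG in one sample.

    The integer values order the states U < I < M, matching the number
    of methylated epialleles carried (0, 1, 2).  MISSING marks an
    unobserved cell (zero coverage).
    """

    U = 0
    I = 1
    M = 2
    MISSING = -1


#: integer codes used in vectorised state matrices
STATE_CODES = {MethState.U: 0, MethState.I: 1, MethState.M: 2, MethState.MISSING: -1}


@dataclass(frozen=True)
class Trio:
    """One family: father, mother and a single offspring."""

    family_id: str
    father: str
    mother: str
    child: str

    def __post_init__(self) -> None:
        members = (self.father, self.mother, self.child)
        if len(set(members)) != 3:
            raise ValueError(
                f"trio {self.family_id!r} must have three distinct samples, got {members}"
            )

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.father, self.mother, self.child)


class TrioSet:
    """A collection of trios; every sample belongs to exactly one trio."""

    def __init__(self, trios: list[Trio]):
        seen: dict[str, str] = {}
        for t in trios:
            for s in t.members:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} appears in trios {seen[s]!r} and {t.family_id!r}"
                    )
                seen[s] = t.family_id
        fam_ids = [t.family_id for t in trios]
        if len(set(fam_ids)) != len(fam_ids):
            raise ValueError("duplicate family ids in trio set")
        self.trios = list(trios)

    def __len__(self) -> int:
        return len(self.trios)

    def __iter__(self):
        return iter(self.trios)

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for t in self.trios:
            out.extend(t.members)
        return out

    def member_indices(self, samples: list[str]) -> list[tuple[int, int, int]]:
        """Column indices of (father, mother, child) per trio in `samples`."""
        pos = {s: i for i, s in enumerate(samples)}
        missing = [s for t in self.trios for s in t.members if s not in pos]
        if missing:
            raise KeyError(f"samples not found in matrix: {missing}")
        return [(pos[t.father], pos[t.mother], pos[t.child]) for t in self.trios]


@dataclass(frozen=True)
class Thresholds:
    """All tunable cut-offs of the pipeline, with their standard defaults.

    state_low / state_high
        Percent boundaries of the U/I/M categorisation; the boundaries
        themselves belong to U and M respectively.
    parental_delta
        Minimum absolute mother-father difference (percentage points,
        strict) required in at least one family for a CpG to count as
        parent-variable.
    min_mean_cov
        Minimum mean read coverage per sample; a CpG needs at least
        min_mean_cov * n_samples total reads.
    min_complete_families
        Minimum number of families in which all three members have a
        methylation call.
    cis_window
        Maximum CpG-SNP distance (bp, same chromosome) for a cis mQTL.
    alpha
        Family-wise error rate for the Bonferroni mQTL threshold.
    flank_width
        Width (bp) of each flanking window around an index CpG.
    flank_purity
        Fraction (strict) of flanking CpGs that must share a state for
        a flank to count as a methylated/unmethylated region.
    min_flank_cpgs
        Minimum observed CpGs per flank for scenario classification.
    max_snp_missing_rate
        Maximum fraction of missing genotypes tolerated per SNP.
    """

    state_low: float = 20.0
    state_high: float = 80.0
    parental_delta: float = 20.0
    min_mean_cov: float = 10.0
    min_complete_families: int = 3
    cis_window: int = 1_000_000
    alpha: float = 0.05
    flank_width: int = 1000
    flank_purity: float = 0.80
    min_flank_cpgs: int = 3
    max_snp_missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.state_low < self.state_high < 100):
            raise ValueError("need 0 < state_low < state_high < 100")
        for name in ("parental_delta", "min_mean_cov", "cis_window", "alpha",
                     "flank_width", "flank_purity", "min_complete_families"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_THRESHOLDS = Thresholds()


def categorize_state(meth_percent: float | None,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS) -> MethState:
    """Categorise a methylation percent into U, I, M or MISSING.

    U if percent <= state_low, M if percent >= state_high, I strictly
    in between; None/NaN input maps to MISSING.
    """
    if meth_percent is None or meth_percent != meth_percent:  # NaN check
        return MethState.MISSING
    if not 0 <= meth_percent <= 100:
        raise ValueError(f"methylation percent out of [0, 100]: {meth_percent}")
    if meth_percent <= thresholds.state_low:
        return MethState.U
    if meth_percent >= thresholds.state_high:
        return MethState.M
    return MethState.I


# epiallele composition of each state: number of methylated epialleles
_EPIALLELES = {
    MethState.U: ("u", "u"),
    MethState.I: ("m", "u"),
    MethState.M: ("m", "m"),
}

_OBSERVABLE = (MethState.U, MethState.I, MethState.M)


def punnett_offspring_states(p1: MethState, p2: MethState) -> frozenset[MethState]:
    """Child states reachable by one-epiallele-per-parent transmission.

    Symmetric in the two parents.  MISSING parents are a caller error:
    missingness must be resolved before asking about transmission.
    """
    for p in (p1, p2):
        if p not in _EPIALLELES:
            raise ValueError(f"parent state must be U, I or M, got {p!r}")
    kids = set()
    for a in _EPIALLELES[p1]:
        for b in _EPIALLELES[p2]:
            n_meth = (a == "m") + (b == "m")
            kids.add(_OBSERVABLE[n_meth])
    return frozenset(kids)


def trio_compatible(father: MethState, mother: MethState, child: MethState) -> bool:
    """True iff the child's state is reachable from the parents' epialleles."""
    if child not in _EPIALLELES:
        raise ValueError(f"child state must be U, I or M, got {child!r}")
    return child in punnett_offspring_states(father, mother)


def compatibility_table() -> dict[tuple[MethState, MethState, MethState], bool]:
    """Compatibility of all 27 ordered (father, mother, child) triples."""
    return {
        (f, m, c): trio_compatible(f, m, c)
        for f, m, c in itertools.product(_OBSERVABLE, repeat=3)
    }


def compatibility_lookup():
    """27-entry boolean array indexed by 9*father + 3*mother + child codes."""
    import numpy as np

    table = np.zeros(27, dtype=bool)
    for (f, m, c), ok in compatibility_table().items():
        table[9 * int(f) + 3 * int(m) + int(c)] = ok
    return table


def dosage_transmission_set(p1: int, p2: int) -> frozenset[int]:
    """Child dosages reachable from parental allele dosages (0/1/2).

    The same one-allele-per-parent rule as the epiallele model: a
    homozygote transmits its only allele, a heterozygote either.
    """
    transmissible = {0: (0,), 1: (0, 1), 2: (1,)}
    for p in (p1, p2):
        if p not in transmissible:
            raise ValueError(f"dosage must be 0, 1 or 2, got {p!r}")
    return frozenset(a + b for a in transmissible[p1] for b in transmissible[p2])
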