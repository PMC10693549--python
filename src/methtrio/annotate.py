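"""Genomic context for CpG sets.

Distance-to-nearest against interval tracks (containment = 0,
otherwise bp to the closest covered base on the same chromosome),
CpG island context bands (island / shore / shelf / open sea), gene
context with promoter > exon > intron precedence, and aggregation of
15-state chromatin segmentation labels into 7 buckets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")
GENE_CONTEXTS = ("promoter", "exon", "intron", "intergenic")

# ChromHMM-style 15-state labels -> 7 aggregate states.  Keys are
# normalised (leading "<n>_" stripped).
CHROMATIN_AGGREGATION = {
    "Active_Promoter": "Promoter",
    "Weak_Promoter": "Promoter",
    "Poised_Promoter": "Poised Promoter",
    "Strong_Enhancer": "Enhancer",
    "Weak_Enhancer": "Enhancer",
    "Weak/Poised_Enhancer": "Enhancer",
    "Insulator": "Insulator",
    "Txn_Transition": "Transcription",
    "Txn_Elongation": "Transcription",
    "Weak_Txn": "Transcription",
    "Repressed": "Polycomb repressed",
    "Polycomb_Repressed": "Polycomb repressed",
    "Heterochrom/lo": "Heterochromatin/low signal/Repetitive/CNV",
    "Repetitive/CNV": "Heterochromatin/low signal/Repetitive/CNV",
}

AGGREGATE_STATES = tuple(dict.fromkeys(CHROMATIN_AGGREGATION.values()))


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    ms, me = [], []
    for s, e in zip(starts, ends):
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


def distance_to_nearest(chroms: np.ndarray, positions: np.ndarray,
                        track: pd.DataFrame) -> np.ndarray:
    """Distance in bp from each 1-based position to the nearest interval.

    ``track`` is BED-style (chrom, start, end; 0-based half-open).
    0 means containment; otherwise the count of bases separating the
    position from the closest covered base.  NaN where the chromosome
    has no intervals.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    out = np.full(len(positions), np.nan)
    if track is None or len(track) == 0:
        return out
    for chrom, grp in track.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts, ends = _merge_intervals(grp["start"].to_numpy(np.int64),
                                        grp["end"].to_numpy(np.int64))
        p0 = positions[sel] - 1  # 0-based point
        idx = np.searchsorted(starts, p0, side="right") - 1
        d = np.full(p0.shape, np.inf)
        has_left = idx >= 0
        inside = np.zeros(p0.shape, dtype=bool)
        inside[has_left] = p0[has_left] < ends[idx[has_left]]
        d[inside] = 0
        left_gap = np.where(has_left & ~inside,
                            p0 - (ends[np.clip(idx, 0, None)] - 1), np.inf)
        right = idx + 1
        has_right = right < len(starts)
        right_gap = np.where(has_right & ~inside,
                             starts[np.clip(right, None, len(starts) - 1)] - p0,
                             np.inf)
        d = np.minimum(d, np.minimum(left_gap, right_gap))
        out[np.where(sel)[0]] = d
    return out


def cpg_island_context(distance_bp) -> np.ndarray:
    """Band a distance-to-island into island/shore/shelf/open_sea.

    island iff 0; shore on (0, 2000); shelf on [2000, 4000]; open sea
    beyond.  NaN distances (chromosome without islands) stay missing.
    """
    d = np.atleast_1d(np.asarray(distance_bp, dtype=float))
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError("distances must be non-negative")
    out = np.full(d.shape, None, dtype=object)
    obs = ~np.isnan(d)
    out[obs & (d == 0)] = "island"
    out[obs & (d > 0) & (d < 2000)] = "shore"
    out[obs & (d >= 2000) & (d <= 4000)] = "shelf"
    out[obs & (d > 4000)] = "open_sea"
    return out if np.ndim(distance_bp) else out[0]


def _parse_exons(row) -> list[tuple[int, int]]:
    starts = [int(x) for x in str(row["exon_starts"]).split(",") if x != ""]
    ends = [int(x) for x in str(row["exon_ends"]).split(",") if x != ""]
    return list(zip(starts, ends))


def gene_context(chroms: np.ndarray, positions: np.ndarray,
                 genes: pd.DataFrame, promoter_bp: int = 2000) -> np.ndarray:
    """promoter / exon / intron / intergenic with fixed precedence.

    Promoter = ``promoter_bp`` upstream of the TSS, strand-aware;
    coordinates in ``genes`` are 1-based inclusive.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    rank = np.full(len(positions), 3, dtype=int)  # 3 = intergenic
    for _, g in genes.iterrows():
        if g["strand"] not in ("+", "-"):
            raise ValueError(f"gene {g.get('gene', '?')!r} lacks a strand")
        sel = chroms == g["chrom"]
        if not sel.any():
            continue
        p = positions[sel]
        if g["strand"] == "+":
            tss = int(g["tx_start"])
            prom = (p >= tss - promoter_bp) & (p <= tss - 1)
        else:
            tss = int(g["tx_end"])
            prom = (p >= tss + 1) & (p <= tss + promoter_bp)
        in_exon = np.zeros(p.shape, dtype=bool)
        for s, e in _parse_exons(g):
            in_exon |= (p >= s) & (p <= e)
        in_body = (p >= int(g["tx_start"])) & (p <= int(g["tx_end"]))
        gene_rank = np.where(prom, 0, np.where(in_exon, 1, np.where(in_body, 2, 3)))
        idx = np.where(sel)[0]
        rank[idx] = np.minimum(rank[idx], gene_rank)
    return np.array(GENE_CONTEXTS, dtype=object)[rank]


def aggregate_chromatin_state(raw_label: str) -> str:
    """Map a 15-state segmentation label onto its aggregate bucket."""
    label = str(raw_label).strip()
    # tolerate UCSC-style numeric prefixes like "2_Weak_Promoter"
    if label[:1].isdigit() and "_" in label:
        head, rest = label.split("_", 1)
        if head.isdigit():
            label = rest
    if label not in CHROMATIN_AGGREGATION:
        raise KeyError(f"unknown chromatin-state label: {raw_label!r}")
    return CHROMATIN_AGGREGATION[label]


def chromatin_state_at(chroms: np.ndarray, positions: np.ndarray,
                       tiles: pd.DataFrame) -> np.ndarray:
    """Aggregate chromatin state of the tile containing each position."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    out = np.full(len(positions), None, dtype=object)
    for chrom, grp in tiles.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        labels = grp["label"].to_numpy()
        p0 = positions[sel] - 1
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = (idx >= 0) & (p0 < ends[np.clip(idx, 0, None)])
        vals = np.full(p0.shape, None, dtype=object)
        for k in np.where(ok)[0]:
            vals[k] = aggregate_chromatin_state(labels[idx[k]])
        out[np.where(sel)[0]] = vals
    return out


def annotate_cpgs(sites: pd.DataFrame, islands: pd.DataFrame,
                  genes: pd.DataFrame, chromatin: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG annotation table: island context, gene context, chromatin."""
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    d_island = distance_to_nearest(chroms, pos, islands)
    out = pd.DataFrame(index=sites.index)
    out["dist_island"] = d_island
    out["island_context"] = cpg_island_context(d_island)
    out["gene_context"] = gene_context(chroms, pos, genes)
    out["chromatin_state"] = chromatin_state_at(chroms, pos, chromatin)
    return out


def context_proportions(annotation: pd.DataFrame, column: str) -> pd.Series:
    """Proportion of CpGs per category of one annotation column."""
    counts = annotation[column].value_counts(dropna=True)
    return counts / counts.sum()
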