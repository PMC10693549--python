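"""Synthetic trio methylome generator.

Emulates the statistical structure a trio WGBS inheritance analysis
assumes: four families of father/mother/child, binomially sampled
methylation calls at Poisson read depth, Mendelian SNP transmission,
and planted CpG classes —

stable
    Same true methylation in every individual (unmethylated inside CpG
    islands, methylated in open sea), arranged in dense local domains
    so flanking-region analyses have context.
cis_mqtl / trans_mqtl
    True methylation is 50 percentage points per dosage unit of a
    driver SNP (cis: same chromosome, < 1 Mb; trans: other chromosome),
    giving the trimodal 0/50/100 pattern genetic epialleles show.
heritable_epiallele
    A diploid methylation epiallele drawn independently of every SNP;
    founders carry two Bernoulli(1/2) epialleles and the child inherits
    one from each parent.
non_mendelian
    Independent per-individual states — environmental noise that should
    fail the trio-compatibility filter in at least one family.
imprinted
    Hemimethylated (~50%) sites inside declared imprinted regions,
    removed up front by the region filter.

Every CpG's class, driver SNP and founder epialleles are recorded in a
truth set so downstream selection can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Trio, TrioSet
from .matrix import GenotypeMatrix, MethMatrix, site_ids

CPG_CLASSES = (
    "stable",
    "cis_mqtl",
    "trans_mqtl",
    "heritable_epiallele",
    "non_mendelian",
    "imprinted",
)

# 15-state chromatin vocabulary (ChromHMM-style labels)
CHROMATIN_LABELS = (
    "Active_Promoter", "Weak_Promoter", "Poised_Promoter",
    "Strong_Enhancer", "Weak_Enhancer", "Insulator",
    "Txn_Transition", "Txn_Elongation", "Weak_Txn",
    "Repressed", "Heterochrom/lo", "Repetitive/CNV",
)


@dataclass
class SimConfig:
    """Study-condition knobs of the generator.

    Defaults mirror a four-trio WGBS design: 12 samples, mean coverage
    12x with unbiased binomial read sampling, a few percent missing
    calls, and enough planted CpGs per class to measure recovery rates.
    """

    n_families: int = 4
    n_stable: int = 1200
    n_cis_mqtl: int = 60
    n_trans_mqtl: int = 60
    n_heritable: int = 60
    n_non_mendelian: int = 60
    n_imprinted: int = 30
    n_background_snps: int = 300
    mean_coverage: float = 12.0
    coverage_dispersion: float = 0.0  # gamma-Poisson overdispersion; 0 = pure Poisson
    noise_sd: float = 5.0  # percent-scale Gaussian jitter on true methylation
    missing_rate: float = 0.01  # extra masking of methylation calls
    geno_error_rate: float = 0.0  # per-child-genotype corruption probability
    seed: int = 0
    chrom_length: int = 3_000_000
    domain_size: int = 20  # stable CpGs per local domain
    domain_spacing_bp: int = 100  # CpG spacing inside a domain

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        for name in ("n_stable", "n_cis_mqtl", "n_trans_mqtl", "n_heritable",
                     "n_non_mendelian", "n_imprinted", "n_background_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")

    def class_counts(self) -> dict[str, int]:
        return {
            "stable": self.n_stable,
            "cis_mqtl": self.n_cis_mqtl,
            "trans_mqtl": self.n_trans_mqtl,
            "heritable_epiallele": self.n_heritable,
            "non_mendelian": self.n_non_mendelian,
            "imprinted": self.n_imprinted,
        }


@dataclass
class GenomeLayout:
    """Synthetic genome: coordinates, tracks and sequence."""

    chrom_lengths: dict[str, int]
    islands: pd.DataFrame  # chrom, start, end (0-based half-open)
    imprinted: pd.DataFrame
    genes: pd.DataFrame  # gene, chrom, strand, tx_start, tx_end (1-based), exon_starts, exon_ends
    chromatin: pd.DataFrame  # chrom, start, end, label
    snps: pd.DataFrame  # id, chrom, pos (1-based), af
    sequence: dict[str, str]

    def validate(self) -> None:
        for df in (self.islands, self.imprinted, self.chromatin):
            for _, row in df.iterrows():
                length = self.chrom_lengths[row["chrom"]]
                if not (0 <= row["start"] < row["end"] <= length):
                    raise ValueError(f"interval out of chromosome bounds: {dict(row)}")


@dataclass
class TruthSet:
    """Planted class label per CpG plus generative bookkeeping.

    table : per-CpG DataFrame (chrom, pos, cls, driver_snp) indexed by
        CpG id; driver_snp is "" except for mQTL classes.
    epialleles : methylated-epiallele count (0/1/2) per sample for
        heritable CpGs, or None when none were planted.
    """

    table: pd.DataFrame
    epialleles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = set(self.table["cls"]) - set(CPG_CLASSES)
        if bad:
            raise ValueError(f"unknown CpG classes: {bad}")

    def class_counts(self) -> dict[str, int]:
        return self.table["cls"].value_counts().to_dict()


@dataclass
class SimulatedDataset:
    layout: GenomeLayout
    meth: MethMatrix
    genotypes: GenotypeMatrix
    trios: TrioSet
    truth: TruthSet
    config: SimConfig


def _make_trios(n_families: int) -> TrioSet:
    trios = [
        Trio(f"F{i}", f"F{i}_father", f"F{i}_mother", f"F{i}_child")
        for i in range(1, n_families + 1)
    ]
    return TrioSet(trios)


def _domain_plan(config: SimConfig) -> pd.DataFrame:
    """Lay out stable-CpG domains over two chromosomes.

    Domain kinds repeat [sea, island, sea, boundary]: boundary domains
    are half island / half open sea, creating methylation transitions.
    """
    size = config.domain_size
    n_domains = -(-config.n_stable // size) if config.n_stable else 0
    kinds = ["sea", "island", "sea", "boundary"]
    rows = []
    chroms = ["chr1", "chr2"]
    per_chrom = -(-n_domains // len(chroms)) if n_domains else 0
    margin = 50_000
    for ci, chrom in enumerate(chroms):
        start_idx = ci * per_chrom
        count = min(per_chrom, n_domains - start_idx)
        if count <= 0:
            continue
        usable = config.chrom_length - 2 * margin
        step = usable // max(count, 1)
        for k in range(count):
            d = start_idx + k
            rows.append({
                "chrom": chrom,
                "start_pos": margin + k * step + 1,  # 1-based first CpG
                "kind": kinds[d % len(kinds)],
            })
    return pd.DataFrame(rows, columns=["chrom", "start_pos", "kind"])


def _free_positions(rng, blocked: list[tuple[int, int]], length: int, n: int,
                    min_gap: int = 50) -> np.ndarray:
    """Sample n 1-based positions outside blocked [start,end] 1-based spans."""
    blocked = sorted(blocked)
    chosen: list[int] = []
    taken = np.zeros(0, dtype=int)
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise RuntimeError("could not place CpGs outside blocked regions")
        p = int(rng.integers(10_000, length - 10_000))
        if any(s <= p <= e for s, e in blocked):
            continue
        if taken.size and np.min(np.abs(taken - p)) < min_gap:
            continue
        chosen.append(p)
        taken = np.asarray(chosen)
    return np.sort(np.asarray(chosen, dtype=int))


def _build_layout(config: SimConfig, rng: np.random.Generator):
    chroms = ["chr1", "chr2"]
    L = config.chrom_length
    chrom_lengths = {c: L for c in chroms}
    domains = _domain_plan(config)

    # stable CpGs and island intervals from the domain plan
    cpg_rows: list[dict] = []
    island_rows: list[dict] = []
    spacing, size = config.domain_spacing_bp, config.domain_size
    n_left = config.n_stable
    for _, dom in domains.iterrows():
        count = min(size, n_left)
        if count <= 0:
            break
        pos = dom["start_pos"] + spacing * np.arange(count)
        for p in pos:
            cpg_rows.append({"chrom": dom["chrom"], "pos": int(p), "cls": "stable", "driver_snp": ""})
        if dom["kind"] == "island":
            island_rows.append({"chrom": dom["chrom"], "start": int(pos[0]) - 51,
                                "end": int(pos[-1]) + 50})
        elif dom["kind"] == "boundary":
            half = pos[: max(count // 2, 1)]
            island_rows.append({"chrom": dom["chrom"], "start": int(half[0]) - 51,
                                "end": int(half[-1]) + 50})
        n_left -= count

    # imprinted regions in the reserved tail of each chromosome
    imprinted_rows = []
    for chrom in chroms:
        imprinted_rows.append({"chrom": chrom, "start": L - 40_000, "end": L - 34_000})
        imprinted_rows.append({"chrom": chrom, "start": L - 28_000, "end": L - 22_000})
    imp_df = pd.DataFrame(imprinted_rows)
    per_region = -(-config.n_imprinted // len(imprinted_rows)) if config.n_imprinted else 0
    n_left = config.n_imprinted
    for _, reg in imp_df.iterrows():
        count = min(per_region, n_left)
        if count <= 0:
            break
        pos = reg["start"] + 500 + 100 * np.arange(count)  # 1-based inside region
        for p in pos:
            cpg_rows.append({"chrom": reg["chrom"], "pos": int(p), "cls": "imprinted", "driver_snp": ""})
        n_left -= count

    # isolated special-class CpGs in the gaps between domains
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _, dom in domains.iterrows():
        span = dom["start_pos"] + spacing * size
        blocked[dom["chrom"]].append((dom["start_pos"] - 2500, span + 2500))
    for _, reg in imp_df.iterrows():
        blocked[reg["chrom"]].append((reg["start"] - 2500, reg["end"] + 2500))
    for chrom in chroms:
        blocked[chrom].append((L - 45_000, L))  # keep tail clear

    special = (
        ["cis_mqtl"] * config.n_cis_mqtl
        + ["trans_mqtl"] * config.n_trans_mqtl
        + ["heritable_epiallele"] * config.n_heritable
        + ["non_mendelian"] * config.n_non_mendelian
    )
    half = -(-len(special) // 2)
    chrom_assign = ["chr1"] * half + ["chr2"] * (len(special) - half)
    for chrom in chroms:
        classes = [c for c, ch in zip(special, chrom_assign) if ch == chrom]
        if not classes:
            continue
        pos = _free_positions(rng, blocked[chrom], L, len(classes))
        order = rng.permutation(len(classes))
        for p, ci in zip(pos, order):
            cpg_rows.append({"chrom": chrom, "pos": int(p), "cls": classes[ci], "driver_snp": ""})

    cpgs = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "cls", "driver_snp"])
    cpgs = cpgs.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if cpgs.duplicated(["chrom", "pos"]).any():
        raise RuntimeError("duplicate CpG positions in layout")

    # genes: fixed slots, alternating strand, three exons each
    gene_rows = []
    for chrom in chroms:
        for k in range(10):
            g0 = 120_000 + k * 260_000
            if g0 + 20_000 > L - 50_000:
                break
            strand = "+" if k % 2 == 0 else "-"
            gene_rows.append({
                "gene": f"{chrom}_g{k}", "chrom": chrom, "strand": strand,
                "tx_start": g0, "tx_end": g0 + 20_000,
                "exon_starts": f"{g0},{g0 + 8000},{g0 + 19000}",
                "exon_ends": f"{g0 + 1000},{g0 + 9000},{g0 + 20000}",
            })
    genes = pd.DataFrame(gene_rows)

    # chromatin tiles
    tile = 25_000
    chrom_rows = []
    for chrom in chroms:
        starts = np.arange(0, L, tile)
        labels = rng.choice(CHROMATIN_LABELS, size=len(starts))
        for s, lab in zip(starts, labels):
            chrom_rows.append({"chrom": chrom, "start": int(s),
                               "end": int(min(s + tile, L)), "label": lab})
    chromatin = pd.DataFrame(chrom_rows)

    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])

    # background SNPs avoiding CpG dinucleotide bases
    cpg_bases: dict[str, set[int]] = {c: set() for c in chroms}
    for _, row in cpgs.iterrows():
        cpg_bases[row["chrom"]].update((row["pos"], row["pos"] + 1))
    snp_rows = []
    for i in range(config.n_background_snps):
        while True:
            chrom = chroms[int(rng.integers(len(chroms)))]
            p = int(rng.integers(10_000, L - 10_000))
            if p not in cpg_bases[chrom] and (p + 1) not in cpg_bases[chrom]:
                break
        snp_rows.append({"id": f"snp{i}", "chrom": chrom, "pos": p,
                         "af": float(rng.uniform(0.1, 0.9))})

    # driver SNPs for the mQTL classes
    other = {"chr1": "chr2", "chr2": "chr1"}
    drv = 0
    for idx, row in cpgs.iterrows():
        if row["cls"] == "cis_mqtl":
            while True:
                delta = int(rng.integers(5_000, 400_000)) * (1 if rng.random() < 0.5 else -1)
                p = row["pos"] + delta
                if 10_000 < p < L - 10_000 and p not in cpg_bases[row["chrom"]] \
                        and (p + 1) not in cpg_bases[row["chrom"]]:
                    break
            snp_chrom = row["chrom"]
        elif row["cls"] == "trans_mqtl":
            snp_chrom = other[row["chrom"]]
            while True:
                p = int(rng.integers(10_000, L - 10_000))
                if p not in cpg_bases[snp_chrom] and (p + 1) not in cpg_bases[snp_chrom]:
                    break
        else:
            continue
        snp_id = f"driver{drv}"
        drv += 1
        snp_rows.append({"id": snp_id, "chrom": snp_chrom, "pos": int(p), "af": 0.5})
        cpgs.loc[idx, "driver_snp"] = snp_id
    snps = pd.DataFrame(snp_rows, columns=["id", "chrom", "pos", "af"])

    # sequence: GC-rich inside islands, AT-leaning elsewhere; a C/G
    # dinucleotide is stamped at every CpG position
    sequence = {}
    bases = np.array(list("ACGT"))
    for chrom in chroms:
        gc = np.full(L, 0.40)
        for _, isl in islands[islands["chrom"] == chrom].iterrows():
            gc[isl["start"]:isl["end"]] = 0.70
        u = rng.random(L)
        is_gc = u < gc
        u2 = rng.random(L)
        idx = np.where(is_gc, np.where(u2 < 0.5, 1, 2), np.where(u2 < 0.5, 0, 3))
        seq = bases[idx]
        mask = cpgs["chrom"] == chrom
        pos0 = cpgs.loc[mask, "pos"].to_numpy(dtype=np.int64) - 1
        seq[pos0] = "C"
        seq[pos0 + 1] = "G"
        sequence[chrom] = seq.astype("S1").tobytes().decode("ascii")

    layout = GenomeLayout(chrom_lengths, islands, imp_df, genes, chromatin, snps, sequence)
    layout.validate()
    return layout, cpgs


def _transmit(rng, father: np.ndarray, mother: np.ndarray) -> np.ndarray:
    """Child dosage: one allele drawn from each parent's dosage."""
    a = rng.random(father.shape) < father / 2.0
    b = rng.random(mother.shape) < mother / 2.0
    return a.astype(float) + b.astype(float)


def _simulate_genotypes(layout: GenomeLayout, trios: TrioSet, config: SimConfig,
                        rng: np.random.Generator) -> GenotypeMatrix:
    samples = trios.samples
    n_snp = len(layout.snps)
    F = len(trios)
    dosage = np.zeros((n_snp, 3 * F))
    af = layout.snps["af"].to_numpy()
    is_driver = layout.snps["id"].str.startswith("driver").to_numpy()
    for fi in range(F):
        fa = rng.binomial(2, af).astype(float)
        mo = rng.binomial(2, af).astype(float)
        ch = _transmit(rng, fa, mo)
        if config.geno_error_rate > 0:
            flip = rng.random(n_snp) < config.geno_error_rate
            ch[flip] = rng.integers(0, 3, size=int(flip.sum())).astype(float)
        cols = slice(3 * fi, 3 * fi + 3)
        dosage[:, cols] = np.stack([fa, mo, ch], axis=1)
    # driver SNPs must be polymorphic in the realized sample or the
    # planted effect is untestable; redraw degenerate ones
    for si in np.where(is_driver)[0]:
        tries = 0
        while np.var(dosage[si]) == 0:
            tries += 1
            if tries > 200:
                raise RuntimeError("failed to draw a polymorphic driver SNP")
            for fi in range(F):
                fa = float(rng.binomial(2, af[si]))
                mo = float(rng.binomial(2, af[si]))
                ch = float(_transmit(rng, np.array([fa]), np.array([mo]))[0])
                dosage[si, 3 * fi:3 * fi + 3] = (fa, mo, ch)
    return GenotypeMatrix(snps=layout.snps.copy(), dosage=dosage, samples=samples)


def _true_methylation(cpgs: pd.DataFrame, layout: GenomeLayout, gt: GenotypeMatrix,
                      trios: TrioSet, config: SimConfig, rng: np.random.Generator):
    samples = gt.samples
    n_cpg, n_s = len(cpgs), len(samples)
    F = len(trios)
    true = np.empty((n_cpg, n_s))

    in_island = np.zeros(n_cpg, dtype=bool)
    for _, isl in layout.islands.iterrows():
        m = (cpgs["chrom"] == isl["chrom"]) & (cpgs["pos"] > isl["start"]) & (cpgs["pos"] <= isl["end"])
        in_island |= m.to_numpy()

    snp_row = {sid: i for i, sid in enumerate(gt.snps["id"])}
    epi_rows: dict[str, np.ndarray] = {}
    for i, row in enumerate(cpgs.itertuples(index=False)):
        cls = row.cls
        if cls == "stable":
            true[i] = 3.0 if in_island[i] else 95.0
        elif cls in ("cis_mqtl", "trans_mqtl"):
            true[i] = 50.0 * gt.dosage[snp_row[row.driver_snp]]
        elif cls == "heritable_epiallele":
            counts = np.zeros(n_s)
            for fi in range(F):
                fa = float(rng.binomial(2, 0.5))
                mo = float(rng.binomial(2, 0.5))
                ch = float(_transmit(rng, np.array([fa]), np.array([mo]))[0])
                counts[3 * fi:3 * fi + 3] = (fa, mo, ch)
            epi_rows[f"{row.chrom}:{row.pos}"] = counts.copy()
            true[i] = 50.0 * counts
        elif cls == "non_mendelian":
            true[i] = rng.choice([3.0, 50.0, 97.0], size=n_s)
        elif cls == "imprinted":
            true[i] = 50.0
        else:  # pragma: no cover
            raise AssertionError(cls)
    if config.noise_sd > 0:
        true = true + rng.normal(0.0, config.noise_sd, size=true.shape)
    true = np.clip(true, 0.0, 100.0)
    epialleles = (
        pd.DataFrame.from_dict(epi_rows, orient="index", columns=samples)
        .rename_axis("cpg")
        if epi_rows else None
    )
    return true, epialleles


def _observe(true: np.ndarray, config: SimConfig, rng: np.random.Generator):
    """Binomial read sampling at Poisson (optionally gamma-Poisson) depth."""
    shape = true.shape
    if config.coverage_dispersion > 0:
        k = 1.0 / config.coverage_dispersion
        lam = rng.gamma(k, config.mean_coverage / k, size=shape)
        cov = rng.poisson(lam)
    else:
        cov = rng.poisson(config.mean_coverage, size=shape)
    if config.missing_rate > 0:
        cov = np.where(rng.random(shape) < config.missing_rate, 0, cov)
    meth = np.full(shape, np.nan)
    obs = cov > 0
    k_meth = rng.binomial(cov[obs], true[obs] / 100.0)
    meth[obs] = 100.0 * k_meth / cov[obs]
    return meth, cov


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a complete, internally consistent trio dataset.

    Deterministic given the config (including its seed): the same
    config yields byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    trios = _make_trios(config.n_families)
    layout, cpgs = _build_layout(config, rng)
    gt = _simulate_genotypes(layout, trios, config, rng)
    true, epialleles = _true_methylation(cpgs, layout, gt, trios, config, rng)
    meth_obs, cov = _observe(true, config, rng)

    sites = cpgs[["chrom", "pos"]].copy()
    sites.index = site_ids(sites["chrom"], sites["pos"])
    meth = MethMatrix(sites=sites, meth=meth_obs, cov=cov, samples=gt.samples)

    truth_table = cpgs[["chrom", "pos", "cls", "driver_snp"]].copy()
    truth_table.index = sites.index.rename("cpg")
    truth = TruthSet(table=truth_table, epialleles=epialleles)
    return SimulatedDataset(layout=layout, meth=meth, genotypes=gt,
                            trios=trios, truth=truth, config=config)
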