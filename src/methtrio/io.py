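"""Readers and writers for the pipeline's on-disk formats.

Conventions: methylation tables are bedGraph-like TSVs with 1-based
CpG positions (chrom, pos, percent, coverage), one file per sample and
only covered sites written; interval tracks are BED (0-based,
half-open); genotypes are VCF with GT calls; pedigrees are PED;
sequence is FASTA.  Coordinate conversion happens here, at the reader
boundary, and nowhere else.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .core import Trio, TrioSet
from .matrix import GenotypeMatrix, MethMatrix, site_ids
from .simulate import GenomeLayout, SimulatedDataset, TruthSet

METH_COLUMNS = ["chrom", "pos", "meth", "cov"]


# ---------------------------------------------------------------- writing

def write_meth_table(meth: MethMatrix, sample: str, path: str | Path) -> None:
    j = meth.samples.index(sample)
    obs = meth.cov[:, j] > 0
    df = pd.DataFrame({
        "chrom": meth.sites["chrom"].to_numpy()[obs],
        "pos": meth.sites["pos"].to_numpy()[obs],
        "meth": meth.meth[obs, j],
        "cov": meth.cov[obs, j],
    })
    # %.17g guarantees the percents survive the text round trip exactly
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.17g")


def read_meth_tables(paths: dict[str, str | Path]) -> MethMatrix:
    """Union of per-sample tables; cells absent from a file are missing."""
    frames = {}
    for sample, path in paths.items():
        df = pd.read_csv(path, sep="\t", header=None, names=METH_COLUMNS,
                         dtype={"chrom": str, "pos": np.int64},
                         float_precision="round_trip")
        df.index = site_ids(df["chrom"], df["pos"])
        frames[sample] = df
    all_sites = pd.concat(
        [f[["chrom", "pos"]] for f in frames.values()]
    ).groupby(level=0, sort=False).first()
    all_sites = all_sites.sort_values(["chrom", "pos"])
    samples = list(paths)
    n = len(all_sites)
    meth = np.full((n, len(samples)), np.nan)
    cov = np.zeros((n, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        df = frames[sample].reindex(all_sites.index)
        got = df["cov"].notna().to_numpy()
        meth[got, j] = df.loc[got, "meth"].to_numpy()
        cov[got, j] = df.loc[got, "cov"].to_numpy().astype(np.int64)
    return MethMatrix(sites=all_sites, meth=meth, cov=cov, samples=samples)


def write_vcf(gt: GenotypeMatrix, chrom_lengths: dict[str, int],
              sequence: dict[str, str] | None, path: str | Path) -> None:
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.samples) + "\n")
        order = np.lexsort((gt.snps["pos"].to_numpy(),
                            gt.snps["chrom"].to_numpy()))
        for i in order:
            row = gt.snps.iloc[i]
            if sequence is not None:
                ref = sequence[row["chrom"]][row["pos"] - 1].upper()
            else:
                ref = "A"
            alt = "G" if ref != "G" else "T"
            calls = [gt_map.get(d, "./.") if not np.isnan(d) else "./."
                     for d in gt.dosage[i]]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{ref}\t{alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    ids, chroms, poss, rows = [], [], [], []
    for rec in vf:
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        row = []
        for s in samples:
            alleles = rec.samples[s]["GT"]
            if alleles is None or any(a is None for a in alleles):
                row.append(np.nan)
            else:
                row.append(float(sum(alleles)))
        rows.append(row)
    snps = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    snps.index = pd.Index(ids)
    return GenotypeMatrix(snps=snps, dosage=np.asarray(rows, dtype=float),
                          samples=samples)


def write_ped(trios: TrioSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trios:
            fh.write(f"{t.family_id}\t{t.father}\t0\t0\t1\t0\n")
            fh.write(f"{t.family_id}\t{t.mother}\t0\t0\t2\t0\n")
            fh.write(f"{t.family_id}\t{t.child}\t{t.father}\t{t.mother}\t1\t0\n")


def read_ped(path: str | Path) -> TrioSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["family", "id", "father", "mother", "sex", "pheno"],
                     dtype=str)
    trios = []
    for fam, grp in df.groupby("family", sort=False):
        kids = grp[(grp["father"] != "0") & (grp["mother"] != "0")]
        if len(kids) != 1:
            raise ValueError(f"family {fam!r} must define exactly one trio child")
        kid = kids.iloc[0]
        trios.append(Trio(fam, kid["father"], kid["mother"], kid["id"]))
    return TrioSet(trios)


def write_bed(intervals: pd.DataFrame, path: str | Path,
              extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    base = ["chrom", "start", "end"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=base + (names or []))
    cols = base + (names or [f"col{i}" for i in range(3, df.shape[1])])
    df.columns = cols[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_fasta(sequence: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequence.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    return df


# ---------------------------------------------------------- dataset bundle

def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a simulated dataset as the pipeline's input formats."""
    out = Path(out_dir)
    (out / "meth").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in dataset.meth.samples:
        p = out / "meth" / f"{sample}.tsv"
        write_meth_table(dataset.meth, sample, p)
        paths[f"meth:{sample}"] = p
    paths["vcf"] = out / "genotypes.vcf"
    write_vcf(dataset.genotypes, dataset.layout.chrom_lengths,
              dataset.layout.sequence, paths["vcf"])
    paths["ped"] = out / "pedigree.ped"
    write_ped(dataset.trios, paths["ped"])
    paths["islands"] = out / "islands.bed"
    write_bed(dataset.layout.islands, paths["islands"])
    paths["imprinted"] = out / "imprinted.bed"
    write_bed(dataset.layout.imprinted, paths["imprinted"])
    paths["chromatin"] = out / "chromatin.bed"
    write_bed(dataset.layout.chromatin, paths["chromatin"], extra_cols=["label"])
    paths["genes"] = out / "genes.tsv"
    write_genes(dataset.layout.genes, paths["genes"])
    paths["fasta"] = out / "genome.fa"
    write_fasta(dataset.layout.sequence, paths["fasta"])
    paths["truth"] = out / "truth.tsv"
    dataset.truth.table.to_csv(paths["truth"], sep="\t", index_label="cpg")
    if dataset.truth.epialleles is not None:
        paths["epialleles"] = out / "epialleles.tsv"
        dataset.truth.epialleles.to_csv(paths["epialleles"], sep="\t",
                                        index_label="cpg")
    return paths


def read_truth(path: str | Path, epiallele_path: str | Path | None = None) -> TruthSet:
    table = pd.read_csv(path, sep="\t", index_col="cpg",
                        dtype={"chrom": str}, keep_default_na=False)
    table["driver_snp"] = table["driver_snp"].fillna("")
    epi = None
    if epiallele_path is not None and Path(epiallele_path).exists():
        epi = pd.read_csv(epiallele_path, sep="\t", index_col="cpg")
    return TruthSet(table=table, epialleles=epi)
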