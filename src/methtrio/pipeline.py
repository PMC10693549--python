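"""End-to-end orchestration: simulate/load -> filter -> Mendelian
selection -> mQTL exclusion -> annotation -> flanking -> clustering.

The run is deterministic given the configuration (including the
simulation seed) and keeps a single CpG ledger across all stages, so
the final heritable count always equals the Mendelian count minus the
cis- and trans-explained counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .annotate import annotate_cpgs, context_proportions
from .clustering import SubjectClustering, cluster_subjects
from .core import Thresholds, TrioSet
from .filtering import FilterLedger, apply_cpg_filters, filter_snps_mendelian
from .flanking import classify_cpgs, scenario_table
from .matrix import GenotypeMatrix, MethMatrix
from .mendelian import export_mendelian_bed, select_mendelian
from .mqtl import ScanResult, scan_and_select_heritable
from .simulate import SimConfig, SimulatedDataset, TruthSet, simulate_dataset


@dataclass
class InputPaths:
    """Locations of a pre-existing dataset on disk."""

    meth_dir: str
    vcf: str
    ped: str
    islands: str
    imprinted: str
    chromatin: str
    genes: str
    fasta: str
    truth: str | None = None
    epialleles: str | None = None


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    sim: SimConfig | None = field(default_factory=SimConfig)
    inputs: InputPaths | None = None
    run_cpg_filters: bool = True
    run_snp_filters: bool = True
    cluster_linkage: str = "complete"
    p_threshold: float | None = None  # override the Bonferroni default

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "thresholds" in raw:
            kwargs["thresholds"] = Thresholds(**raw["thresholds"])
        if raw.get("inputs"):
            kwargs["inputs"] = InputPaths(**raw["inputs"])
            kwargs["sim"] = SimConfig(**raw["sim"]) if raw.get("sim") else None
        elif "sim" in raw:
            kwargs["sim"] = SimConfig(**(raw["sim"] or {}))
        for key in ("run_cpg_filters", "run_snp_filters", "cluster_linkage",
                    "p_threshold"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class ReportBundle:
    """Everything a pipeline run produces, in memory."""

    ledger: FilterLedger
    snp_ledger: FilterLedger
    counts: dict[str, int]
    filtered: MethMatrix
    mendelian: MethMatrix
    heritable: MethMatrix
    scan: ScanResult
    annotations: dict[str, pd.DataFrame]
    proportions: dict[str, pd.DataFrame]
    scenarios: pd.DataFrame
    clustering: SubjectClustering
    evaluation: pd.DataFrame | None
    truth: TruthSet | None


def _load_dataset(paths: InputPaths) -> SimulatedDataset:
    meth_dir = Path(paths.meth_dir)
    files = sorted(meth_dir.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no methylation tables in {meth_dir}")
    meth = mio.read_meth_tables({p.stem: p for p in files})
    gt = mio.read_vcf(paths.vcf)
    trios = mio.read_ped(paths.ped)
    sequence = mio.read_fasta(paths.fasta)
    from .simulate import GenomeLayout

    layout = GenomeLayout(
        chrom_lengths={c: len(s) for c, s in sequence.items()},
        islands=mio.read_bed(paths.islands),
        imprinted=mio.read_bed(paths.imprinted),
        genes=mio.read_genes(paths.genes),
        chromatin=mio.read_bed(paths.chromatin, names=["label"]),
        snps=gt.snps.assign(af=np.nan),
        sequence=sequence,
    )
    truth = (mio.read_truth(paths.truth, paths.epialleles)
             if paths.truth else None)
    # reorder methylation columns to pedigree order
    order = [meth.samples.index(s) for s in trios.samples]
    meth = MethMatrix(sites=meth.sites, meth=meth.meth[:, order],
                      cov=meth.cov[:, order], samples=trios.samples)
    gt_order = [gt.samples.index(s) for s in trios.samples]
    gt = GenotypeMatrix(snps=gt.snps, dosage=gt.dosage[:, gt_order],
                        samples=trios.samples)
    return SimulatedDataset(layout=layout, meth=meth, genotypes=gt,
                            trios=trios, truth=truth, config=None)


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> ReportBundle:
    th = config.thresholds
    if config.inputs is not None:
        dataset = _load_dataset(config.inputs)
    elif config.sim is not None:
        dataset = simulate_dataset(config.sim)
    else:
        raise ValueError("config must request simulation or name input files")

    missing = set(dataset.trios.samples) - set(dataset.meth.samples)
    if missing:
        raise ValueError(f"pedigree samples absent from methylation data: {sorted(missing)}")

    # SNP side
    if config.run_snp_filters:
        gt, snp_ledger = filter_snps_mendelian(
            dataset.genotypes, dataset.trios, th.max_snp_missing_rate)
    else:
        gt = dataset.genotypes
        snp_ledger = FilterLedger(input_count=gt.n_snps)
        snp_ledger.add("disabled", 0)

    # CpG cascade
    ledger = FilterLedger(input_count=dataset.meth.n_sites)
    if config.run_cpg_filters:
        filtered, f_ledger = apply_cpg_filters(
            dataset.meth, dataset.trios,
            gt.snps[["chrom", "pos"]], dataset.layout.imprinted, th)
        for stage, removed, _ in f_ledger.stages:
            ledger.add(stage, removed)
    else:
        filtered = dataset.meth
        ledger.add("filters_disabled", 0)

    mendelian, info, m_ledger = select_mendelian(filtered, dataset.trios, th)
    for stage, removed, _ in m_ledger.stages:
        ledger.add(stage, removed)

    heritable, scan = scan_and_select_heritable(
        mendelian, gt, th, p_threshold=config.p_threshold)
    verdict_counts = scan.counts()
    ledger.add("cis_mqtl", verdict_counts["cis_explained"])
    ledger.add("trans_mqtl", verdict_counts["trans_explained"])
    ledger.validate()

    counts = {
        "input": dataset.meth.n_sites,
        "filtered": filtered.n_sites,
        "mendelian": mendelian.n_sites,
        "cis_explained": verdict_counts["cis_explained"],
        "trans_explained": verdict_counts["trans_explained"],
        "heritable": heritable.n_sites,
        "snps_input": dataset.genotypes.n_snps,
        "snps_kept": gt.n_snps,
    }

    groups = {"filtered": filtered, "mendelian": mendelian, "heritable": heritable}
    annotations, proportions = {}, {}
    for name, mm in groups.items():
        ann = annotate_cpgs(mm.sites, dataset.layout.islands,
                            dataset.layout.genes, dataset.layout.chromatin)
        annotations[name] = ann
        proportions[name] = pd.DataFrame({
            "island_context": context_proportions(ann, "island_context"),
            "gene_context": context_proportions(ann, "gene_context"),
            "chromatin_state": context_proportions(ann, "chromatin_state"),
        })

    # flanking scenarios, with all filtered CpGs as context
    filtered_ids = pd.Index(filtered.sites.index)
    scen_groups = {}
    for name in ("mendelian", "heritable"):
        idx = filtered_ids.get_indexer(groups[name].sites.index)
        scen_groups[name] = classify_cpgs(filtered, idx[idx >= 0], th)
    scenarios = scenario_table(scen_groups)

    clustering = cluster_subjects(mendelian, method=config.cluster_linkage) \
        if mendelian.n_sites else cluster_subjects(filtered, method=config.cluster_linkage)

    evaluation = None
    if dataset.truth is not None:
        evaluation = evaluate_against_truth(
            mendelian_ids=mendelian.sites.index,
            heritable_ids=heritable.sites.index,
            verdicts=scan.verdicts,
            truth=dataset.truth,
        )

    bundle = ReportBundle(ledger=ledger, snp_ledger=snp_ledger, counts=counts,
                          filtered=filtered, mendelian=mendelian,
                          heritable=heritable, scan=scan,
                          annotations=annotations, proportions=proportions,
                          scenarios=scenarios, clustering=clustering,
                          evaluation=evaluation, truth=dataset.truth)
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle


def evaluate_against_truth(mendelian_ids: pd.Index, heritable_ids: pd.Index,
                           verdicts: pd.Series, truth: TruthSet) -> pd.DataFrame:
    """Score pipeline calls against the planted class labels.

    One row per planted class: how many CpGs were planted, how many
    survived to the Mendelian set, how many were called heritable, and
    how many were removed as cis/trans mQTLs.  Appended summary rows
    give heritable-call sensitivity and false-discovery counts.
    """
    table = truth.table
    unknown = heritable_ids.difference(table.index)
    if len(unknown):
        raise ValueError(f"called CpGs absent from the truth set: {list(unknown[:5])}")
    rows = []
    for cls, grp in table.groupby("cls"):
        ids = grp.index
        in_mend = ids.intersection(mendelian_ids)
        rows.append({
            "class": cls,
            "n_planted": len(ids),
            "n_mendelian": len(in_mend),
            "n_heritable_called": len(ids.intersection(heritable_ids)),
            "n_cis_explained": int((verdicts.reindex(in_mend) == "cis_explained").sum()),
            "n_trans_explained": int((verdicts.reindex(in_mend) == "trans_explained").sum()),
        })
    df = pd.DataFrame(rows).set_index("class")
    planted_her = df.loc["heritable_epiallele", "n_planted"] \
        if "heritable_epiallele" in df.index else 0
    called_her = df["n_heritable_called"].sum()
    true_pos = df.loc["heritable_epiallele", "n_heritable_called"] \
        if "heritable_epiallele" in df.index else 0
    df.attrs["sensitivity"] = true_pos / planted_her if planted_her else np.nan
    df.attrs["false_discoveries"] = int(called_her - true_pos)
    df.attrs["precision"] = true_pos / called_her if called_her else np.nan
    return df


def write_report(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["ledger"] = out / "ledger.tsv"
    bundle.ledger.to_tsv(paths["ledger"])
    paths["snp_ledger"] = out / "snp_ledger.tsv"
    bundle.snp_ledger.to_tsv(paths["snp_ledger"])
    paths["heritable_bed"] = out / "heritable.bed"
    export_mendelian_bed(bundle.heritable, paths["heritable_bed"])
    paths["mendelian_bed"] = out / "mendelian.bed"
    export_mendelian_bed(bundle.mendelian, paths["mendelian_bed"])
    for name, ann in bundle.annotations.items():
        paths[f"annotation_{name}"] = out / f"annotation_{name}.tsv"
        ann.to_csv(paths[f"annotation_{name}"], sep="\t")
    paths["scenarios"] = out / "scenarios.tsv"
    bundle.scenarios.to_csv(paths["scenarios"], sep="\t")
    paths["dendrogram"] = out / "subjects.nwk"
    paths["dendrogram"].write_text(bundle.clustering.to_newick() + "\n")
    paths["distances"] = out / "subject_distances.tsv"
    bundle.clustering.distances.to_csv(paths["distances"], sep="\t")
    paths["significant_mqtl"] = out / "significant_mqtl.tsv"
    bundle.scan.significant.to_csv(paths["significant_mqtl"], sep="\t", index=False)
    if bundle.evaluation is not None:
        paths["evaluation"] = out / "evaluation.tsv"
        bundle.evaluation.to_csv(paths["evaluation"], sep="\t")
    counts = pd.Series(bundle.counts, name="count")
    paths["counts"] = out / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t")
    return paths
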