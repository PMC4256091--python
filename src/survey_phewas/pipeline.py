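"""Config-driven end-to-end PheWAS runs.

Stages run in workflow order: harmonize -> per-survey stratified scan ->
cross-survey replication filter -> combined-survey re-test -> catalog
classification (pleiotropy, generalization) -> phenotype correlations ->
SNP-gene-pathway networks.  Every output schema is fixed, stage counts and
flagged degeneracies are logged, and an identical config + seed reproduces
byte-identical TSVs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import classify as _classify
from . import correlate as _correlate
from . import network as _network
from .config import SURVEYS, PopulationConfig
from .harmonize import (
    COMBINED,
    build_combined_measurements,
    build_measurements,
    bin_to_classes,
    harmonize_combined,
    summarize_cohort,
)
from .replicate import (
    CAF_THRESHOLD,
    MIN_SAMPLE_SIZE,
    P_THRESHOLD,
    apply_replication_criteria,
    combined_retest,
    retained_to_frame,
)
from .scan import run_scan, write_results
from .synthetic import SyntheticDataset, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Thresholds default to the replication criteria (p < 0.01, CAF > 0.01,
    n > 200).  All referenced paths must exist at run start.
    """

    genotypes: dict[str, Path] = field(default_factory=dict)  # survey -> TSV
    phenotypes: dict[str, Path] = field(default_factory=dict)
    class_map: Path | None = None
    pheno_meta: Path | None = None
    catalog: Path | None = None
    related_groups: Path | None = None
    gene_table: Path | None = None
    groupings: dict[str, Path] = field(default_factory=dict)  # source -> GMT
    snp_positions: Path | None = None  # TSV: snp, chrom, position[, coded_allele]
    p_threshold: float = P_THRESHOLD
    caf_threshold: float = CAF_THRESHOLD
    min_n: int = MIN_SAMPLE_SIZE
    outdir: Path = Path("phewas_out")
    seed: int = 0

    def validate(self) -> None:
        if self.p_threshold <= 0 or self.caf_threshold <= 0 or self.min_n <= 0:
            raise ValueError("thresholds must be positive")
        paths = [*self.genotypes.values(), *self.phenotypes.values(),
                 *self.groupings.values()]
        paths += [p for p in (self.class_map, self.pheno_meta, self.catalog,
                              self.related_groups, self.gene_table, self.snp_positions) if p]
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


@dataclass
class ResultBundle:
    cohort_summary: dict
    scan: pd.DataFrame
    retained: list
    retained_table: pd.DataFrame
    classified: list
    classified_table: pd.DataFrame
    pleiotropy: pd.DataFrame
    generalization: pd.DataFrame
    summary: dict
    correlations: dict
    networks: dict
    stage_counts: dict


def _stage_logger(outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []

    def log_stage(stage: str, message: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        line = f"{stamp}\t{stage}\t{message}"
        lines.append(line)
        log.info("[%s] %s", stage, message)

    def flush() -> None:
        (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")

    return log_stage, flush


def run_pipeline_from_tables(
    genotypes: Mapping[str, pd.DataFrame],
    phenotypes: Mapping[str, pd.DataFrame],
    pheno_meta: pd.DataFrame,
    class_map: pd.DataFrame,
    catalog: _classify.Catalog,
    outdir: str | Path,
    gene_table: pd.DataFrame | None = None,
    groupings: Mapping[str, set[str]] | None = None,
    snp_positions: pd.DataFrame | None = None,
    coded_alleles: Mapping[str, str] | None = None,
    p_threshold: float = P_THRESHOLD,
    caf_threshold: float = CAF_THRESHOLD,
    min_n: int = MIN_SAMPLE_SIZE,
    carry_transformed: bool = True,
) -> ResultBundle:
    """Run every stage on in-memory tables and write the result bundle."""
    outdir = Path(outdir)
    stage, flush = _stage_logger(outdir)
    counts: dict = {}

    cohort = summarize_cohort(phenotypes)
    stage("cohort", f"pooled n={cohort['pooled_n']}")

    # -- harmonization ----------------------------------------------------
    descriptors = pheno_meta.drop(columns=["class_label"], errors="ignore")
    descriptors, unmapped = bin_to_classes(descriptors, class_map)
    mapped = descriptors[descriptors["class_label"].notna()]
    stage("harmonize", f"{len(mapped)} phenotype descriptors mapped, {len(unmapped)} unmapped")

    measurements = {
        s: build_measurements(phenotypes[s], mapped, s, carry_transformed) for s in sorted(phenotypes)
    }
    combined_vars = harmonize_combined(phenotypes, mapped)
    combined_set = build_combined_measurements(combined_vars, carry_transformed)
    geno_all = dict(genotypes)
    if combined_set is not None:
        measurements[COMBINED] = combined_set
        geno_all[COMBINED] = pd.concat([genotypes[s] for s in sorted(genotypes)])
    stage("harmonize", f"{len(combined_vars)} combined-survey variables")
    counts["combined_variables"] = len(combined_vars)

    # -- scan -------------------------------------------------------------
    scan_results = run_scan(geno_all, measurements, coded_alleles)
    counts["scan_results"] = len(scan_results)
    n_flagged = int((scan_results["flag"] != "ok").sum()) if len(scan_results) else 0
    stage("scan", f"{len(scan_results)} results ({n_flagged} flagged degenerate)")
    write_results(scan_results, outdir / "scan_results.tsv")

    # -- replication filter + combined re-test ----------------------------
    retained = apply_replication_criteria(scan_results, p_threshold, caf_threshold, min_n)
    retained = combined_retest(retained, scan_results)
    retained_table = retained_to_frame(retained)
    counts["retained_groups"] = len(retained)
    stage("replicate", f"{len(retained)} groups pass all seven criteria")
    retained_table.to_csv(outdir / "retained_results.tsv", sep="\t", index=False, float_format="%.6g")

    # -- classification ---------------------------------------------------
    classified = _classify.classify_results(retained, catalog)
    classified_table = _classify.classified_to_frame(classified)
    pleio = _classify.pleiotropy_to_frame(_classify.detect_pleiotropy(classified))
    gen = _classify.assess_generalization(classified)
    summary = _classify.summarize_categories(classified)
    counts.update(summary)
    stage(
        "classify",
        f"replicated={summary['replicated']} related={summary['related']} "
        f"novel={summary['novel']} pleiotropic_snps={summary['pleiotropic_snps']} "
        f"generalized={summary['generalized_groups']}",
    )
    classified_table.to_csv(outdir / "classified_results.tsv", sep="\t", index=False)
    pleio.to_csv(outdir / "pleiotropy.tsv", sep="\t", index=False)
    gen.to_csv(outdir / "generalization.tsv", sep="\t", index=False)

    # -- correlations among significant phenotypes ------------------------
    correlations: dict = {}
    sig_phenos = sorted({rec.best[s]["phenotype"] for rec in retained for s in rec.best})
    for survey in sorted(phenotypes):
        present = [p for p in sig_phenos if p in phenotypes[survey].columns]
        for stratum in sorted(phenotypes[survey]["stratum"].unique()):
            if len(present) < 2:
                continue
            matrix = _correlate.compute_correlations(
                phenotypes[survey], present, survey=survey, stratum=stratum
            )
            tag = f"{survey}_{stratum}"
            correlations[tag] = matrix
            _correlate.write_correlation_outputs(matrix, outdir / "correlations", tag)
    stage("correlate", f"{len(correlations)} survey x stratum matrices")

    # -- networks ---------------------------------------------------------
    networks: dict = {}
    if gene_table is not None and snp_positions is not None and len(classified_table):
        annotations = _network.annotate_nearest_gene(
            snp_positions[snp_positions["snp"].isin(classified_table["snp"])], gene_table
        )
        _network.nearest_gene_frame(annotations).to_csv(
            outdir / "nearest_genes.tsv", sep="\t", index=False
        )
        groupings = groupings or {}
        netdir = outdir / "networks"
        netdir.mkdir(parents=True, exist_ok=True)
        for stratum, sub in classified_table.groupby("stratum"):
            graph = _network.build_graph(sub, annotations, groupings, stratum=str(stratum))
            pruned = _network.prune_components(graph)
            networks[str(stratum)] = pruned
            _network.write_sif(pruned, netdir / f"network_{stratum}.sif")
            _network.write_graphml(pruned, netdir / f"network_{stratum}.graphml")
        stage("network", f"{len(networks)} stratified graphs (pruned)")

    counts["classified"] = len(classified)
    (outdir / "run_summary.json").write_text(json.dumps({**cohort, **counts}, indent=2, default=str))
    flush()
    return ResultBundle(
        cohort_summary=cohort,
        scan=scan_results,
        retained=retained,
        retained_table=retained_table,
        classified=classified,
        classified_table=classified_table,
        pleiotropy=pleio,
        generalization=gen,
        summary=summary,
        correlations=correlations,
        networks=networks,
        stage_counts=counts,
    )


def run_pipeline_from_dataset(
    dataset: SyntheticDataset,
    catalog: _classify.Catalog | None = None,
    outdir: str | Path = "phewas_out",
    **kwargs,
) -> ResultBundle:
    """Convenience entry point: run every stage on a synthetic dataset."""
    catalog = catalog or _classify.Catalog()
    cfg = dataset.config
    snp_positions = pd.DataFrame(
        [{"snp": s.snp_id, "chrom": s.chrom, "position": s.position} for s in cfg.snps]
    )
    coded = {s.snp_id: s.coded_allele for s in cfg.snps}
    return run_pipeline_from_tables(
        genotypes=dataset.genotypes,
        phenotypes=dataset.phenotypes,
        pheno_meta=dataset.pheno_meta,
        class_map=dataset.class_map,
        catalog=catalog,
        outdir=outdir,
        snp_positions=snp_positions,
        coded_alleles=coded,
        **kwargs,
    )


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Load every input named by the config and run the pipeline."""
    config.validate()
    genotypes = {
        s: pd.read_csv(p, sep="\t", index_col="sample_id") for s, p in config.genotypes.items()
    }
    phenotypes = {
        s: pd.read_csv(p, sep="\t", index_col="sample_id") for s, p in config.phenotypes.items()
    }
    pheno_meta = pd.read_csv(config.pheno_meta, sep="\t")
    class_map = pd.read_csv(config.class_map, sep="\t")
    catalog = (
        _classify.Catalog.read(config.catalog, config.related_groups)
        if config.catalog
        else _classify.Catalog()
    )
    gene_table = _network.read_gene_table(config.gene_table) if config.gene_table else None
    groupings: dict[str, set[str]] = {}
    for source, path in config.groupings.items():
        groupings.update(_network.read_gmt(path, source=source))
    snp_positions = (
        pd.read_csv(config.snp_positions, sep="\t", dtype={"snp": str, "chrom": str})
        if config.snp_positions
        else None
    )
    return run_pipeline_from_tables(
        genotypes=genotypes,
        phenotypes=phenotypes,
        pheno_meta=pheno_meta,
        class_map=class_map,
        catalog=catalog,
        outdir=config.outdir,
        gene_table=gene_table,
        groupings=groupings or None,
        snp_positions=snp_positions,
        p_threshold=config.p_threshold,
        caf_threshold=config.caf_threshold,
        min_n=config.min_n,
    )


def export_plot_tables(bundle: ResultBundle, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Plot-ready exports: the replication-matrix table and per-SNP sun-plot
    tables sorted by ascending p so -log10(p) descends clockwise."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = bundle.retained_table
    matrix.to_csv(outdir / "replication_matrix.tsv", sep="\t", index=False, float_format="%.6g")
    rows = []
    for rec in bundle.retained:
        entries = [(s, rec.best[s]) for s in rec.best]
        if rec.combined is not None:
            entries.append((COMBINED, rec.combined))
        for survey, best in entries:
            rows.append(
                {
                    "snp": rec.snp,
                    "survey": survey,
                    "transform": best["transform"],
                    "phenotype": best["phenotype"],
                    "measurement": best["measurement"],
                    "class_label": rec.class_label,
                    "stratum": rec.stratum,
                    "direction": "+" if best["beta"] > 0 else "-",
                    "p": best["p"],
                    "beta": best["beta"],
                    "n": best["n"],
                }
            )
    sun = pd.DataFrame(
        rows,
        columns=[
            "snp", "survey", "transform", "phenotype", "measurement",
            "class_label", "stratum", "direction", "p", "beta", "n",
        ],
    )
    if len(sun):
        sun = sun.sort_values(["snp", "p", "measurement"], kind="mergesort").reset_index(drop=True)
    sun.to_csv(outdir / "sun_plot.tsv", sep="\t", index=False, float_format="%.6g")
    return {"replication_matrix": matrix, "sun_plot": sun}


def simulate_and_run(
    config: PopulationConfig,
    catalog: _classify.Catalog | None = None,
    outdir: str | Path = "phewas_out",
    **kwargs,
) -> tuple[SyntheticDataset, ResultBundle]:
    dataset = generate_dataset(config)
    bundle = run_pipeline_from_dataset(dataset, catalog=catalog, outdir=outdir, **kwargs)
    return dataset, bundle
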