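"""End-to-end orchestration of the integrative analysis.

``run_pipeline`` chains: simulation → per-layer differential analysis
(expression and miRNA, both contrasts) → consensus miRNA-target mapping →
methylation QC / BMIQ / moderated testing / DMP+DMR calling → per-layer
pathway over-representation → cross-layer integration report.  Every stage
logs its input/output sizes; the whole run is a deterministic function of
the configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .containers import OmicsMatrix
from .differential import (
    call_differential,
    filter_low_variance,
    percentile75_normalize,
    row_t_test,
    significant_features,
)
from .enrich import ora, region_enrichment, top_k
from .integrate import IntegrationReport, StageOutputs, build_report
from .methylome import (
    bmiq_normalize,
    call_dmps,
    call_dmrs,
    filter_probes,
    map_probes_to_genes,
    moderated_test,
)
from .mirtarget import consensus_targets
from .simdata import CONTRAST_ECMIX, SimBundle, simulate_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Report plus all intermediate stage outputs (for inspection/tests)."""

    report: IntegrationReport
    bundle: SimBundle
    deg_tnf: pd.DataFrame | None = None
    deg_ecmix: pd.DataFrame | None = None
    demirna_tnf: pd.DataFrame | None = None
    demirna_ecmix: pd.DataFrame | None = None
    target_genes: set = field(default_factory=set)
    dmps: pd.DataFrame | None = None
    dmrs: list = field(default_factory=list)
    dmp_mapping: object = None
    moderated: object = None
    enrichment: dict = field(default_factory=dict)
    region_enrich: dict = field(default_factory=dict)


def _differential_layer(matrix: OmicsMatrix, group_a: str, group_b: str,
                        alpha: float) -> pd.DataFrame:
    results = row_t_test(matrix, group_a, group_b)
    return call_differential(results, alpha)


def execute(config: PipelineConfig) -> PipelineResult:
    """Run the full chain and return the report with all intermediates."""
    config.validate()
    bundle = simulate_all(config.sim)
    logger.info("simulated inputs: %d genes, %d miRNAs, %d probes",
                config.sim.n_genes, config.sim.n_mirna, config.sim.n_probes)

    gene_universe = set(bundle.expression.feature_ids)

    deg_tnf = deg_ecmix = None
    if config.expression:
        expr = filter_low_variance(bundle.expression)
        deg_tnf = _differential_layer(expr, "control", "TNF", config.alpha_genes)
        deg_ecmix = _differential_layer(expr, "TNF", "ECMIX_TNF", config.alpha_genes)
        logger.info("expression: %d TNF-vs-control and %d ECMIX-vs-TNF significant of %d",
                    int(deg_tnf["significant"].sum()),
                    int(deg_ecmix["significant"].sum()), len(expr.feature_ids))

    demirna_tnf = demirna_ecmix = None
    target_genes: set[str] = set()
    if config.mirna:
        mirna = percentile75_normalize(bundle.mirna)
        demirna_tnf = _differential_layer(mirna, "control", "TNF", config.alpha_mirna)
        demirna_ecmix = _differential_layer(mirna, "TNF", "ECMIX_TNF", config.alpha_mirna)
        de_mirnas = significant_features(demirna_ecmix)
        target_genes = consensus_targets(bundle.target_db, de_mirnas,
                                         min_algorithms=config.min_algorithms)
        logger.info("miRNA: %d DE miRNAs -> %d consensus target genes",
                    len(de_mirnas), len(target_genes))

    dmps = None
    dmrs: list = []
    mapping = None
    moderated = None
    region_res: dict = {}
    if config.methylation:
        qc = filter_probes(bundle.methylation, bundle.probe_annotation,
                           max_detection_p=config.max_detection_p)
        logger.info("methylation QC: removed %s", qc.removed)
        normalized = bmiq_normalize(qc.matrix, qc.annotation)
        moderated = moderated_test(normalized, "TNF", "ECMIX_TNF",
                                   use_mvalues=config.use_mvalues)
        dmps = call_dmps(moderated, config.dmp_p_adj_max, config.dmp_min_abs_delta)
        dmrs = call_dmrs(moderated, qc.annotation, config.dmr_max_gap,
                         config.dmr_min_probes, config.dmr_fdr_max,
                         config.dmr_min_peak_delta)
        mapping = map_probes_to_genes(dmps, qc.annotation)
        region_res = {
            cat: region_enrichment(dmps, qc.annotation, cat)
            for cat in ("gene_region", "cgi_class")
        }
        logger.info("methylation: %d DMPs in %d genes, %d DMRs of %d probes",
                    len(dmps), len(mapping.genes), len(dmrs), len(qc.matrix.feature_ids))

    # per-layer pathway over-representation against the measured gene universe
    enrichment: dict[str, pd.DataFrame] = {}
    pathway_top: dict[str, list[str]] = {}
    queries: dict[str, set[str]] = {}
    if deg_ecmix is not None:
        queries["expression"] = significant_features(deg_ecmix)
    if config.mirna:
        queries["mirna_targets"] = target_genes & gene_universe
    if mapping is not None:
        queries["methylation"] = mapping.genes & gene_universe
    for layer, query in queries.items():
        res = ora(query, gene_universe, bundle.pathways)
        enrichment[layer] = res
        pathway_top[layer] = top_k(res, max(config.top_k, len(res))) if len(res) else []
        logger.info("ORA %s: query %d genes, %d sets tested", layer, len(query), len(res))

    provenance = {
        "seed": config.seed,
        "version": __version__,
        "top_k": config.top_k,
        "alpha_genes": config.alpha_genes,
        "alpha_mirna": config.alpha_mirna,
        "min_algorithms": config.min_algorithms,
    }
    outputs = StageOutputs(
        deg_tnf=deg_tnf,
        deg_ecmix=deg_ecmix,
        demirna_tnf=demirna_tnf,
        demirna_ecmix=demirna_ecmix,
        target_genes=target_genes if config.mirna else None,
        dmps=dmps,
        dmp_gene_mapping=mapping,
        dmrs=dmrs if config.methylation else None,
        pathway_top=pathway_top if len(pathway_top) >= 2 else None,
        provenance=provenance,
    )
    report = build_report(outputs, top_k_pathways=config.top_k)
    if region_res:
        report.data["region_enrichment"] = {
            cat: {
                "n_categories": int(len(res)),
                "significant": sorted(res.loc[res["p_adj"] < 0.05, "set_name"].tolist()),
            }
            for cat, res in region_res.items()
        }

    result = PipelineResult(
        report=report, bundle=bundle,
        deg_tnf=deg_tnf, deg_ecmix=deg_ecmix,
        demirna_tnf=demirna_tnf, demirna_ecmix=demirna_ecmix,
        target_genes=target_genes, dmps=dmps, dmrs=dmrs,
        dmp_mapping=mapping, moderated=moderated,
        enrichment=enrichment, region_enrich=region_res,
    )
    if config.outdir:
        _write_outputs(result, config)
    return result


def run_pipeline(config: PipelineConfig) -> IntegrationReport:
    """Full synthetic-data run; returns the integration report."""
    return execute(config).report


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    from . import io as nio

    out = nio.ensure_dir(config.outdir)
    result.report.save(out / "report.json")
    with open(out / "overlaps.tsv", "w", encoding="utf-8") as fh:
        fh.write("comparison\tk\tn\tpercent\n")
        for name, k, n, pct in result.report.flat_rows():
            fh.write(f"{name}\t{k}\t{n}\t{pct!r}\n")
    venn = result.report.data.get("venn", {})
    with open(out / "venn.tsv", "w", encoding="utf-8") as fh:
        fh.write("comparison\tregion\tcount\n")
        for comp in sorted(venn):
            for region, count in sorted(venn[comp]["partitions"].items()):
                fh.write(f"{comp}\t{region}\t{count}\n")
    for name, df in (("deg_tnf", result.deg_tnf), ("deg_ecmix", result.deg_ecmix),
                     ("demirna_tnf", result.demirna_tnf),
                     ("demirna_ecmix", result.demirna_ecmix)):
        if df is not None:
            nio.write_diff_results(df, out / f"{name}.tsv")
    if result.dmps is not None:
        result.dmps.to_csv(out / "dmps.tsv", sep="\t", index=False)
    if result.dmrs:
        from .methylome import dmrs_to_bed

        pd.DataFrame(
            [
                {
                    "chrom": r.chrom, "start": r.start, "end": r.end,
                    "n_probes": r.n_probes, "combined_p": r.combined_p,
                    "fdr": r.fdr, "peak_abs_delta_beta": r.peak_abs_delta_beta,
                }
                for r in result.dmrs
            ]
        ).to_csv(out / "dmrs.tsv", sep="\t", index=False)
        dmrs_to_bed(result.dmrs).to_csv(out / "dmrs.bed", sep="\t", index=False, header=False)
    if result.target_genes:
        nio.write_gene_list(result.target_genes, out / "consensus_targets.txt")
    for layer, res in result.enrichment.items():
        res.to_csv(out / f"enrichment_{layer}.tsv", sep="\t", index=False)
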