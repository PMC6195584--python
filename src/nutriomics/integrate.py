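"""Cross-layer integration of the three omics analyses.

Builds the machine-readable integration report: Venn partitions of
gene-level sets (differentially expressed genes, genes of differentially
methylated positions, consensus miRNA-target genes), pairwise
contrast comparisons, overlap percentages, and the top-K pathway
intersection across layers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

from .containers import InputError
from .differential import ContrastComparison

logger = logging.getLogger(__name__)


def venn_partitions(sets: dict[str, set[str]]) -> dict[str, int]:
    """Disjoint region counts of a 2- or 3-set Venn diagram.

    Keys are ``&``-joined sorted subset names (e.g. ``"A&B"``); each count
    is the number of identifiers in exactly that subset of sets.  The
    region counts sum to the size of the union; the result is invariant to
    the order in which sets are supplied.
    """
    m = len(sets)
    if m not in (2, 3):
        raise InputError(f"venn_partitions needs 2 or 3 sets, got {m}")
    names = sorted(sets)
    out: dict[str, int] = {}
    for r in range(1, m + 1):
        for inside in combinations(names, r):
            members = set.intersection(*(set(sets[n]) for n in inside))
            for other in names:
                if other not in inside:
                    members -= set(sets[other])
            out["&".join(inside)] = len(members)
    return out


class Percentage(NamedTuple):
    """An overlap percentage: full precision plus one-decimal display value."""

    value: float
    display: float
    k: int
    n: int


def percent_overlap(k: int, n: int) -> Percentage:
    """Percentage 100·k/n with one-decimal display rounding.

    The unrounded value is retained alongside the display value; ``n = 0``
    is rejected as undefined.
    """
    if n <= 0:
        raise InputError("percent_overlap undefined for n = 0")
    if not 0 <= k <= n:
        raise InputError(f"need 0 <= k <= n, got k={k}, n={n}")
    value = 100.0 * k / n
    return Percentage(value=value, display=round(value, 1), k=k, n=n)


def pathway_layer_intersection(
    top_lists: dict[str, list[str]], k: int
) -> tuple[set[str], dict[str, int]]:
    """Common pathways among the per-layer top-K lists.

    Each layer's ordered pathway list is truncated to its first ``k``
    entries; the full Venn partition over the truncated sets is returned
    together with the all-layer intersection.  Identity is exact name
    match.
    """
    if not top_lists:
        raise InputError("no pathway layers supplied")
    if len(top_lists) < 2:
        raise InputError("pathway intersection needs >= 2 layers")
    truncated = {layer: set(names[:k]) for layer, names in top_lists.items()}
    common = set.intersection(*truncated.values())
    venn = venn_partitions(truncated) if len(truncated) in (2, 3) else {}
    return common, venn


@dataclass
class StageOutputs:
    """Optional upstream outputs feeding the integration report.

    Per-layer differential tables are the DataFrames produced by
    ``call_differential`` (expression/miRNA) and ``call_dmps``
    (methylation); absent layers stay ``None`` and are marked absent in the
    report rather than silently reported as zero.
    """

    deg_tnf: object = None           # DataFrame: TNF-vs-control gene results
    deg_ecmix: object = None         # DataFrame: ECMIX-vs-TNF gene results
    demirna_tnf: object = None       # DataFrame: TNF-vs-control miRNA results
    demirna_ecmix: object = None     # DataFrame: ECMIX-vs-TNF miRNA results
    target_genes: set | None = None  # consensus targets of ECMIX DE miRNAs
    dmps: object = None              # DataFrame from call_dmps
    dmp_gene_mapping: object = None  # DmpGeneMapping
    dmrs: list | None = None
    pathway_top: dict[str, list[str]] | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class IntegrationReport:
    """Machine-readable summary of all cross-layer comparisons."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "IntegrationReport":
        return cls(data=json.loads(text))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "IntegrationReport":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())

    def flat_rows(self) -> list[tuple[str, int, int, float]]:
        """(comparison, k, n, percent) rows for the flat TSV export."""
        rows = []
        for name, rec in sorted(self.data.get("percentages", {}).items()):
            rows.append((name, rec["k"], rec["n"], rec["percent"]))
        return rows


def _sig_sets(results) -> tuple[set[str], set[str], set[str]]:
    sig = results.loc[results["significant"]]
    up = set(sig.loc[sig["direction"] == "up", "feature_id"])
    down = set(sig.loc[sig["direction"] == "down", "feature_id"])
    return up | down, up, down


def _contrast_block(comparison: ContrastComparison) -> dict:
    return {
        "common": sorted(comparison.common_features),
        "n_common": comparison.n_common,
        "n_same_direction": comparison.n_same_direction,
        "n_opposite_direction": comparison.n_opposite_direction,
    }


def build_report(outputs: StageOutputs, top_k_pathways: int = 40,
                 mirna_gene_prefix: str = "MIR") -> IntegrationReport:
    """Assemble the integration report from whatever stages have run.

    Layers with missing inputs are recorded under ``absent_layers`` —
    downstream consumers can distinguish "not run" from "ran and found
    nothing".  All percentages store k, n, the unrounded value and the
    one-decimal display value; all Venn partitions store the underlying
    sets so the partition sums can be reconciled.
    """
    from .differential import compare_contrasts  # local import avoids cycle at module load

    report: dict = {"layers": {}, "percentages": {}, "venn": {}, "absent_layers": [],
                    "provenance": dict(outputs.provenance)}

    degs: set[str] | None = None
    if outputs.deg_ecmix is not None:
        all_sig, up, down = _sig_sets(outputs.deg_ecmix)
        degs = all_sig
        report["layers"]["expression"] = {
            "contrast": "ECMIX_vs_TNF", "n_significant": len(all_sig),
            "n_up": len(up), "n_down": len(down), "significant": sorted(all_sig),
        }
        if outputs.deg_tnf is not None:
            tnf_sig, tnf_up, tnf_down = _sig_sets(outputs.deg_tnf)
            report["layers"]["expression_tnf"] = {
                "contrast": "TNF_vs_control", "n_significant": len(tnf_sig),
                "n_up": len(tnf_up), "n_down": len(tnf_down),
            }
            comparison = compare_contrasts(outputs.deg_tnf, outputs.deg_ecmix)
            report["expression_contrast_comparison"] = _contrast_block(comparison)
    else:
        report["absent_layers"].append("expression")

    de_mirnas: set[str] | None = None
    if outputs.demirna_ecmix is not None:
        all_sig, up, down = _sig_sets(outputs.demirna_ecmix)
        de_mirnas = all_sig
        report["layers"]["mirna"] = {
            "contrast": "ECMIX_vs_TNF", "n_significant": len(all_sig),
            "n_up": len(up), "n_down": len(down), "significant": sorted(all_sig),
        }
        if outputs.demirna_tnf is not None:
            tnf_sig, tnf_up, tnf_down = _sig_sets(outputs.demirna_tnf)
            report["layers"]["mirna_tnf"] = {
                "contrast": "TNF_vs_control", "n_significant": len(tnf_sig),
                "n_up": len(tnf_up), "n_down": len(tnf_down),
            }
            comparison = compare_contrasts(outputs.demirna_tnf, outputs.demirna_ecmix)
            report["mirna_contrast_comparison"] = _contrast_block(comparison)
    else:
        report["absent_layers"].append("mirna")

    dmp_genes: set[str] | None = None
    if outputs.dmps is not None and outputs.dmp_gene_mapping is not None:
        mapping = outputs.dmp_gene_mapping
        dmp_genes = set(mapping.genes)
        report["layers"]["methylation"] = {
            "contrast": "ECMIX_vs_TNF",
            "n_dmps": int(len(outputs.dmps)),
            "n_hyper": int((outputs.dmps["direction"] == "hyper").sum()),
            "n_hypo": int((outputs.dmps["direction"] == "hypo").sum()),
            "n_genes": len(dmp_genes),
            "n_intergenic_dmps": mapping.intergenic,
            "n_dmrs": len(outputs.dmrs) if outputs.dmrs is not None else None,
            "genes": sorted(dmp_genes),
        }
    else:
        report["absent_layers"].append("methylation")

    if outputs.target_genes is not None and degs is not None:
        from .mirtarget import target_deg_overlap

        overlap, fraction = target_deg_overlap(outputs.target_genes, degs)
        pct = percent_overlap(len(overlap), len(degs)) if degs else None
        report["target_deg_overlap"] = {
            "overlap": sorted(overlap),
            "n_targets": len(outputs.target_genes),
            "fraction_of_degs": fraction,
        }
        if pct is not None:
            report["percentages"]["deg_targeted_by_de_mirna"] = {
                "k": pct.k, "n": pct.n, "percent": pct.value, "display": pct.display,
            }

    if dmp_genes is not None and degs is not None and degs:
        common = sorted(dmp_genes & degs)
        pct = percent_overlap(len(common), len(degs))
        report["deg_methylation_overlap"] = {"overlap": common}
        report["percentages"]["deg_with_methylation_change"] = {
            "k": pct.k, "n": pct.n, "percent": pct.value, "display": pct.display,
        }

    if dmp_genes is not None and de_mirnas is not None:
        mir_symbols = {g for g in dmp_genes if g.startswith(mirna_gene_prefix)}
        de_mirna_symbols = {
            mirna_gene_prefix + m.rsplit("-", 1)[-1].upper().replace("-", "")
            for m in de_mirnas
        }
        common_mirs = sorted(mir_symbols & de_mirna_symbols)
        report["dmp_mirna_gene_overlap"] = {
            "dmp_mirna_genes": sorted(mir_symbols),
            "common_with_de_mirnas": common_mirs,
            "n_common": len(common_mirs),
        }

    gene_sets = {}
    if degs is not None:
        gene_sets["DEG"] = degs
    if dmp_genes is not None:
        gene_sets["DMP_genes"] = dmp_genes
    if outputs.target_genes is not None:
        gene_sets["miRNA_targets"] = set(outputs.target_genes)
    if len(gene_sets) in (2, 3):
        report["venn"]["gene_level"] = {
            "partitions": venn_partitions(gene_sets),
            "sets": {k: sorted(v) for k, v in gene_sets.items()},
        }

    if outputs.pathway_top:
        common, venn = pathway_layer_intersection(outputs.pathway_top, top_k_pathways)
        report["venn"]["pathway_level"] = {
            "partitions": venn,
            "sets": {k: sorted(set(v[:top_k_pathways])) for k, v in outputs.pathway_top.items()},
            "top_k": top_k_pathways,
        }
        report["common_pathways"] = {"names": sorted(common), "n_common": len(common)}

    return IntegrationReport(data=report)
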