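"""Synthetic multi-omics data with planted ground truth.

Generates every input the pipeline consumes — a two-colour expression
matrix, a miRNA expression matrix, a 450K-like beta-value matrix with probe
annotation, a gene-set (pathway) collection and a miRNA-target prediction
table — together with a :class:`SimTruth` record of what was planted, so
that recovery and calibration of every downstream stage can be tested
without any external download.

The default configuration mirrors the reference three-condition endothelial
design: unstimulated cells, TNFα-stimulated cells and cells pre-exposed to
an epicatechin-metabolite mixture before TNFα, with four replicates per
condition.  Differential signal is planted in two contrasts
(``TNF_vs_control`` and ``ECMIX_vs_TNF``); a configurable fraction of the
ECMIX-responsive genes is shared with the TNF-responsive set and a fraction
of those shared genes flips sign between the contrasts, emulating a partial
counteraction of the inflammatory programme.

All generation is a pure function of the configuration (including its
seed); sub-generators derive child seeds from the global seed by fixed
offsets so each layer is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import (
    CONDITIONS,
    ConfigError,
    GeneSetCollection,
    OmicsMatrix,
    ProbeAnnotation,
    TargetPredictionDB,
)

logger = logging.getLogger(__name__)

CONTRAST_TNF = "TNF_vs_control"
CONTRAST_ECMIX = "ECMIX_vs_TNF"

# fixed child-seed offsets per layer
_SEED_EXPR, _SEED_MIRNA, _SEED_METH, _SEED_PATH, _SEED_TARGET = 1, 2, 3, 4, 5


@dataclass
class SimTruth:
    """Ground-truth bookkeeping for one simulated layer (or the full bundle).

    ``de_features`` maps contrast name -> set of planted differential
    feature IDs; ``direction`` maps contrast -> {feature: +1 (up) or -1
    (down)}.  ``dmr_regions`` lists planted (chrom, start, end) regions,
    1-based inclusive, disjoint per chromosome.  ``enriched_sets`` names the
    planted enriched pathway sets and ``true_targets`` maps miRNA ID -> set
    of true target genes.
    """

    de_features: dict[str, set[str]] = field(default_factory=dict)
    direction: dict[str, dict[str, int]] = field(default_factory=dict)
    dmr_regions: list[tuple[str, int, int]] = field(default_factory=list)
    enriched_sets: set[str] = field(default_factory=set)
    true_targets: dict[str, set[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for contrast, dirs in self.direction.items():
            if any(d not in (-1, 1) for d in dirs.values()):
                raise ValueError(f"non ±1 direction in contrast {contrast}")
            extra = set(dirs) - self.de_features.get(contrast, set())
            if extra:
                raise ValueError(f"direction entries for unplanted features: {sorted(extra)[:5]}")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.dmr_regions:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping planted regions on {chrom}")


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Counts, effect sizes and noise levels default to the reference design:
    4 replicates per condition, an 866-feature miRNA layer, planted
    log2-fold-changes of 2 (expression) and methylation shifts of
    Δβ = 0.2 (positions) / 0.3 (regions).  ``frac_shared`` is the fraction
    of ECMIX-responsive genes that are also TNF-responsive and
    ``frac_opposite`` the fraction of those that flip sign between the two
    contrasts (defaults mirror a 66-gene overlap with 44 sign flips out of
    253 ECMIX-responsive genes).
    """

    seed: int = 0
    n_per_group: int = 4

    # expression layer
    n_genes: int = 10_000
    n_de_tnf: int = 1000
    n_de_ecmix: int = 253
    lfc: float = 2.0
    expr_sd: float = 0.25
    frac_shared: float = 66 / 253
    frac_opposite: float = 44 / 66
    expr_baseline_mean: float = 7.0
    expr_baseline_sd: float = 1.5

    # miRNA layer
    n_mirna: int = 866
    n_de_mirna_tnf: int = 19
    n_de_mirna_ecmix: int = 20
    n_mirna_ecmix_down: int = 19
    n_de_mirna_shared: int = 2
    mirna_lfc: float = 1.5
    mirna_sd: float = 0.25
    mirna_scale_sd: float = 0.5

    # methylation layer
    n_probes: int = 20_000
    frac_type1: float = 0.28
    n_chroms: int = 6
    cluster_gap: int = 200
    intercluster_gap: int = 10_000
    cluster_size_min: int = 3
    cluster_size_max: int = 8
    logit_sd: float = 0.15
    probe_logit_sd: float = 0.10
    type2_compression: float = 0.75
    n_dmp: int = 300
    dmp_delta: float = 0.2
    n_dmr: int = 10
    dmr_delta: float = 0.3
    dmr_probes: int = 5
    probe_fail_rate: float = 0.001
    snp_rate: float = 0.02
    gene_cluster_frac: float = 0.85
    mir_gene_frac: float = 0.02
    n_mir_gene_dmps: int = 2

    # pathway collection
    n_sets: int = 200
    set_size_min: int = 20
    set_size_max: int = 100
    n_enriched: int = 20
    enrichment_factor: float = 5.0

    # target prediction DB
    targets_per_mirna_min: int = 100
    targets_per_mirna_max: int = 300
    target_sens: float = 0.9
    target_fpr: float = 0.01

    def validate(self) -> None:
        positive = ("n_per_group", "n_genes", "n_mirna", "n_probes", "n_chroms",
                    "cluster_gap", "intercluster_gap", "cluster_size_min",
                    "cluster_size_max", "n_sets", "set_size_min", "set_size_max",
                    "targets_per_mirna_min", "targets_per_mirna_max")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        nonneg = ("n_de_tnf", "n_de_ecmix", "n_de_mirna_tnf", "n_de_mirna_ecmix",
                  "n_mirna_ecmix_down", "n_de_mirna_shared", "n_dmp", "n_dmr",
                  "n_enriched", "n_mir_gene_dmps")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        fractions = ("frac_shared", "frac_opposite", "probe_fail_rate", "snp_rate",
                     "target_sens", "target_fpr", "frac_type1", "gene_cluster_frac",
                     "mir_gene_frac")
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_per_group < 2:
            raise ConfigError(f"n_per_group must be >= 2, got {self.n_per_group}")
        for name in ("dmp_delta", "dmr_delta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.n_de_tnf > self.n_genes or self.n_de_ecmix > self.n_genes:
            raise ConfigError("planted gene counts exceed n_genes")
        if self.n_de_mirna_tnf > self.n_mirna or self.n_de_mirna_ecmix > self.n_mirna:
            raise ConfigError("planted miRNA counts exceed n_mirna")
        if self.n_mirna_ecmix_down > self.n_de_mirna_ecmix:
            raise ConfigError("n_mirna_ecmix_down exceeds n_de_mirna_ecmix")
        if self.set_size_max > self.n_genes:
            raise ConfigError("set_size_max exceeds the gene universe n_genes")
        if self.set_size_min > self.set_size_max:
            raise ConfigError("set_size_min exceeds set_size_max")
        if self.cluster_size_min > self.cluster_size_max:
            raise ConfigError("cluster_size_min exceeds cluster_size_max")
        if not 1 <= self.dmr_probes:
            raise ConfigError("dmr_probes must be >= 1")
        if self.seed < 0:
            raise ConfigError(f"seed must be non-negative, got {self.seed}")


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    return [f"hsa-miR-{i + 1:04d}" for i in range(n)]


def mirna_gene_symbol(mirna_id: str) -> str:
    """Host-gene symbol for a simulated miRNA ID (``hsa-miR-0007`` -> ``MIR0007``)."""
    return "MIR" + mirna_id.rsplit("-", 1)[-1]


def _sample_ids(n_per_group: int) -> tuple[list[str], pd.Series]:
    samples, cond = [], []
    for c in CONDITIONS:
        for r in range(1, n_per_group + 1):
            samples.append(f"{c}_{r}")
            cond.append(c)
    sheet = pd.Series(cond, index=pd.Index(samples, name="sample_id"), name="condition")
    return samples, sheet


def simulate_expression(cfg: SimConfig) -> tuple[OmicsMatrix, SimTruth]:
    """Simulate the log2 expression matrix for the three-condition design.

    Null genes have zero group-mean difference; planted genes are shifted by
    ``cfg.lfc`` in their designated contrast.  TNF effects persist into the
    ECMIX_TNF arm so that the ECMIX contrast isolates the metabolite effect.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _SEED_EXPR)
    genes = _gene_ids(cfg.n_genes)
    samples, sheet = _sample_ids(cfg.n_per_group)
    n = cfg.n_per_group

    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, cfg.n_genes)

    tnf_idx = rng.choice(cfg.n_genes, size=cfg.n_de_tnf, replace=False)
    n_shared = int(round(cfg.frac_shared * cfg.n_de_ecmix))
    n_shared = min(n_shared, cfg.n_de_tnf)
    shared_idx = rng.choice(tnf_idx, size=n_shared, replace=False)
    pool = np.setdiff1d(np.arange(cfg.n_genes), tnf_idx, assume_unique=False)
    only_idx = rng.choice(pool, size=cfg.n_de_ecmix - n_shared, replace=False)
    ecmix_idx = np.concatenate([shared_idx, only_idx]).astype(int)

    tnf_dir = dict(zip(tnf_idx, rng.choice([-1, 1], size=cfg.n_de_tnf)))
    n_opp = int(round(cfg.frac_opposite * n_shared))
    flip = set(rng.choice(shared_idx, size=n_opp, replace=False)) if n_shared else set()
    ecmix_dir: dict[int, int] = {}
    for i in shared_idx:
        ecmix_dir[int(i)] = -tnf_dir[i] if i in flip else tnf_dir[i]
    for i in only_idx:
        ecmix_dir[int(i)] = int(rng.choice([-1, 1]))

    tnf_eff = np.zeros(cfg.n_genes)
    for i, d in tnf_dir.items():
        tnf_eff[i] = cfg.lfc * d
    ecmix_eff = np.zeros(cfg.n_genes)
    for i, d in ecmix_dir.items():
        ecmix_eff[i] = cfg.lfc * d

    mean = np.tile(baseline[:, None], (1, 3 * n))
    mean[:, n:2 * n] += tnf_eff[:, None]
    mean[:, 2 * n:] += (tnf_eff + ecmix_eff)[:, None]
    values = mean + rng.normal(0.0, cfg.expr_sd, mean.shape)

    df = pd.DataFrame(values, index=pd.Index(genes, name="feature_id"), columns=samples)
    truth = SimTruth(
        de_features={
            CONTRAST_TNF: {genes[i] for i in tnf_idx},
            CONTRAST_ECMIX: {genes[i] for i in ecmix_idx},
        },
        direction={
            CONTRAST_TNF: {genes[i]: int(d) for i, d in tnf_dir.items()},
            CONTRAST_ECMIX: {genes[i]: int(d) for i, d in ecmix_dir.items()},
        },
    )
    truth.validate()
    return OmicsMatrix(df, sheet, kind="expression"), truth


def simulate_mirna(cfg: SimConfig) -> tuple[OmicsMatrix, SimTruth]:
    """Simulate the miRNA log2 matrix (866 features by default).

    Per-sample multiplicative scale offsets (additive on the log2 scale) are
    planted so that 75th-percentile normalization is non-trivial.  The
    planted profile mirrors the reference study: TNF up-regulates its
    responsive miRNAs, while in the ECMIX contrast most planted miRNAs are
    down-regulated and a small shared subset flips sign.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _SEED_MIRNA)
    mirnas = _mirna_ids(cfg.n_mirna)
    samples, sheet = _sample_ids(cfg.n_per_group)
    n = cfg.n_per_group

    baseline = rng.normal(6.0, 1.5, cfg.n_mirna)

    tnf_idx = rng.choice(cfg.n_mirna, size=cfg.n_de_mirna_tnf, replace=False)
    tnf_dir = {int(i): 1 for i in tnf_idx}  # TNF-responsive miRNAs are up-regulated

    n_shared = min(cfg.n_de_mirna_shared, cfg.n_de_mirna_tnf, cfg.n_de_mirna_ecmix)
    shared_idx = rng.choice(tnf_idx, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
    pool = np.setdiff1d(np.arange(cfg.n_mirna), tnf_idx)
    only_idx = rng.choice(pool, size=cfg.n_de_mirna_ecmix - n_shared, replace=False)
    ecmix_idx = np.concatenate([shared_idx, only_idx]).astype(int)

    ecmix_dir: dict[int, int] = {}
    if len(ecmix_idx):
        n_down = min(cfg.n_mirna_ecmix_down, len(ecmix_idx))
        down = set(rng.choice(ecmix_idx, size=n_down, replace=False))
        for i in ecmix_idx:
            ecmix_dir[int(i)] = -1 if i in down else 1

    tnf_eff = np.zeros(cfg.n_mirna)
    for i, d in tnf_dir.items():
        tnf_eff[i] = cfg.mirna_lfc * d
    ecmix_eff = np.zeros(cfg.n_mirna)
    for i, d in ecmix_dir.items():
        ecmix_eff[i] = cfg.mirna_lfc * d

    mean = np.tile(baseline[:, None], (1, 3 * n))
    mean[:, n:2 * n] += tnf_eff[:, None]
    mean[:, 2 * n:] += (tnf_eff + ecmix_eff)[:, None]
    col_offset = rng.normal(0.0, cfg.mirna_scale_sd, 3 * n)
    values = mean + rng.normal(0.0, cfg.mirna_sd, mean.shape) + col_offset[None, :]

    df = pd.DataFrame(values, index=pd.Index(mirnas, name="feature_id"), columns=samples)
    truth = SimTruth(
        de_features={
            CONTRAST_TNF: {mirnas[i] for i in tnf_idx},
            CONTRAST_ECMIX: {mirnas[i] for i in ecmix_idx},
        },
        direction={
            CONTRAST_TNF: {mirnas[i]: int(d) for i, d in tnf_dir.items()},
            CONTRAST_ECMIX: {mirnas[i]: int(d) for i, d in ecmix_dir.items()},
        },
    )
    truth.validate()
    return OmicsMatrix(df, sheet, kind="mirna"), truth


_MODE_CENTERS = np.array([0.10, 0.50, 0.90])  # unmethylated / intermediate / methylated
_MODE_WEIGHTS = np.array([0.45, 0.10, 0.45])


def _layout_probes(cfg: SimConfig, rng: np.random.Generator):
    """Place probes in clusters along synthetic chromosomes.

    Returns (chrom array, pos array, cluster_id array, list of cluster index arrays).
    """
    sizes = []
    total = 0
    while total < cfg.n_probes:
        s = int(rng.integers(cfg.cluster_size_min, cfg.cluster_size_max + 1))
        s = min(s, cfg.n_probes - total)
        sizes.append(s)
        total += s
    n_clusters = len(sizes)
    per_chrom = int(np.ceil(n_clusters / cfg.n_chroms))
    chroms, positions, cluster_ids = [], [], []
    clusters: list[np.ndarray] = []
    probe_i = 0
    for ci, size in enumerate(sizes):
        chrom_i = ci // per_chrom
        if ci % per_chrom == 0:
            pos = 1000  # reset coordinate at each chromosome start
        idx = []
        for k in range(size):
            chroms.append(f"chr{chrom_i + 1}")
            positions.append(pos)
            cluster_ids.append(ci)
            idx.append(probe_i)
            probe_i += 1
            pos += cfg.cluster_gap
        pos += cfg.intercluster_gap
        clusters.append(np.array(idx))
    return np.array(chroms), np.array(positions), np.array(cluster_ids), clusters


def simulate_methylation(
    cfg: SimConfig, de_mirnas: set[str] | None = None
) -> tuple[OmicsMatrix, ProbeAnnotation, SimTruth]:
    """Simulate a 450K-like beta-value matrix with annotation and truth.

    Beta values come from a three-mode mixture (unmethylated, intermediate,
    methylated) with logit-normal jitter; type II probes draw from a
    compressed version of the type I distribution (modes pulled toward 0.5),
    reproducing the between-design distributional shift that BMIQ corrects.
    Probes are laid out in clusters along synthetic chromosomes; planted
    DMPs shift beta by ``dmp_delta`` in the ECMIX contrast and planted DMRs
    are runs of ``dmr_probes`` consecutive probes shifted by ``dmr_delta``.
    Values pushed outside (0, 1) are clipped to [0.01, 0.99] with a logged
    warning.

    If ``de_mirnas`` is given, a few planted DMP clusters are annotated with
    host-gene symbols of those miRNAs (``MIRxxxx``), emulating methylation
    changes at miRNA loci.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _SEED_METH)
    samples, sheet = _sample_ids(cfg.n_per_group)
    n = cfg.n_per_group
    probes = [f"cg{i + 1:08d}" for i in range(cfg.n_probes)]

    chroms, positions, cluster_ids, clusters = _layout_probes(cfg, rng)
    design = np.where(rng.random(cfg.n_probes) < cfg.frac_type1, "I", "II")

    # methylation state is shared within a probe cluster (CpG-island-like
    # coherence), so planted region shifts are directionally coherent
    cluster_state = rng.choice(3, size=len(clusters), p=_MODE_WEIGHTS)
    state = cluster_state[cluster_ids]
    centers_1 = _MODE_CENTERS[state]
    centers_2 = 0.5 + cfg.type2_compression * (centers_1 - 0.5)
    centers = np.where(design == "I", centers_1, centers_2)
    probe_mu = logit(centers) + rng.normal(0.0, cfg.probe_logit_sd, cfg.n_probes)

    noise = rng.normal(0.0, cfg.logit_sd, (cfg.n_probes, 3 * n))
    beta = expit(probe_mu[:, None] + noise)

    # ---- plant DMRs (whole runs of consecutive probes inside clusters) ----
    dmr_regions: list[tuple[str, int, int]] = []
    dmr_probe_idx: list[int] = []
    dmr_dirs: dict[int, int] = {}
    eligible = [c for c in clusters if len(c) >= cfg.dmr_probes]
    eligible = [eligible[i] for i in rng.permutation(len(eligible))]
    delta = np.zeros(cfg.n_probes)
    for c in eligible[: cfg.n_dmr]:
        run = c[: cfg.dmr_probes]
        # shift away from the probe's dominant mode so values stay inside (0,1)
        for i in run:
            d = 1 if centers[i] < 0.5 else -1
            delta[i] = d * cfg.dmr_delta
            dmr_dirs[int(i)] = d
        dmr_probe_idx.extend(int(i) for i in run)
        dmr_regions.append((str(chroms[run[0]]), int(positions[run[0]]), int(positions[run[-1]])))

    # ---- plant isolated DMPs outside planted DMR clusters ----
    dmr_clusters = {int(cluster_ids[i]) for i in dmr_probe_idx}
    free = np.array([i for i in range(cfg.n_probes) if int(cluster_ids[i]) not in dmr_clusters])
    n_dmp = min(cfg.n_dmp, len(free))
    dmp_idx = rng.choice(free, size=n_dmp, replace=False) if n_dmp else np.array([], dtype=int)
    dmp_dirs: dict[int, int] = {}
    for i in dmp_idx:
        d = 1 if centers[i] < 0.5 else -1
        delta[int(i)] = d * cfg.dmp_delta
        dmp_dirs[int(i)] = d

    beta[:, 2 * n:] += delta[:, None]
    n_out = int(((beta < 0.01) | (beta > 0.99)).sum())
    if n_out:
        logger.warning("clipping %d beta values to [0.01, 0.99]", n_out)
    beta = np.clip(beta, 0.01, 0.99)

    # ---- detection p-values and SNP flags ----
    det_p = rng.uniform(0.0, 0.005, (cfg.n_probes, 3 * n))
    fails = rng.random((cfg.n_probes, 3 * n)) < cfg.probe_fail_rate
    det_p[fails] = rng.uniform(0.02, 1.0, int(fails.sum()))
    snp = rng.random(cfg.n_probes) < cfg.snp_rate

    # ---- annotation: one gene (or none) per cluster ----
    n_clusters = len(clusters)
    gene_pool = rng.permutation(_gene_ids(cfg.n_genes))
    mirna_pool = rng.permutation(_mirna_ids(cfg.n_mirna))
    cluster_gene: list[list[str]] = []
    u = rng.random(n_clusters)
    gi = mi = 0
    for ci in range(n_clusters):
        if u[ci] < cfg.mir_gene_frac and mi < len(mirna_pool):
            cluster_gene.append([mirna_gene_symbol(mirna_pool[mi])])
            mi += 1
        elif u[ci] < cfg.mir_gene_frac + cfg.gene_cluster_frac and gi < len(gene_pool):
            cluster_gene.append([gene_pool[gi]])
            gi += 1
        else:
            cluster_gene.append([])
    # optionally re-annotate a few planted-DMP clusters as DE-miRNA host genes
    if de_mirnas and cfg.n_mir_gene_dmps and len(dmp_idx):
        chosen = sorted(de_mirnas)
        picks = rng.choice(len(chosen), size=min(cfg.n_mir_gene_dmps, len(chosen)), replace=False)
        dmp_clusters = sorted({int(cluster_ids[i]) for i in dmp_idx})
        for k, pi in enumerate(picks):
            cluster_gene[dmp_clusters[k % len(dmp_clusters)]] = [mirna_gene_symbol(chosen[pi])]

    gene_symbols = [cluster_gene[int(cluster_ids[i])] for i in range(cfg.n_probes)]
    region_choices = np.array(ProbeAnnotation.GENE_REGIONS[:-1])
    regions = rng.choice(region_choices, size=cfg.n_probes)
    regions = np.where([len(g) == 0 for g in gene_symbols], "intergenic", regions)
    cgi_by_cluster = rng.choice(np.array(ProbeAnnotation.CGI_CLASSES),
                                size=n_clusters, p=[0.35, 0.25, 0.1, 0.3])
    cgi = cgi_by_cluster[cluster_ids]
    strand = rng.choice(np.array(["+", "-"]), size=cfg.n_probes)

    idx = pd.Index(probes, name="probe_id")
    values = pd.DataFrame(beta, index=idx, columns=samples)
    ann_table = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "strand": strand,
            "design_type": design,
            "gene_symbols": gene_symbols,
            "gene_region": regions,
            "cgi_class": cgi,
            "snp_last3": snp,
        },
        index=idx,
    )
    detection = pd.DataFrame(det_p, index=idx, columns=samples)

    all_dirs = {probes[i]: d for i, d in {**dmr_dirs, **dmp_dirs}.items()}
    truth = SimTruth(
        de_features={CONTRAST_ECMIX: set(all_dirs)},
        direction={CONTRAST_ECMIX: all_dirs},
        dmr_regions=dmr_regions,
    )
    truth.validate()
    return (
        OmicsMatrix(values, sheet, kind="methylation-beta"),
        ProbeAnnotation(ann_table, detection),
        truth,
    )


def simulate_pathway_db(
    cfg: SimConfig, layer_genes: dict[str, set[str]] | None = None
) -> tuple[GeneSetCollection, SimTruth]:
    """Simulate a GMT-style pathway collection with planted enriched sets.

    Background sets draw members uniformly from the gene universe.  Each of
    the ``cfg.n_enriched`` planted sets oversamples the supplied
    "interesting" gene groups at ``cfg.enrichment_factor`` times their base
    rate, so a downstream hypergeometric test should flag them.  When
    ``layer_genes`` maps several layers to gene groups, every planted set
    oversamples all of them, creating a shared enriched core across layers.

    With no ``layer_genes``, the planted genes of the expression layer's
    ECMIX contrast (regenerated deterministically from ``cfg``) are used.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _SEED_PATH)
    universe = np.array(_gene_ids(cfg.n_genes))
    if layer_genes is None:
        _, expr_truth = simulate_expression(cfg)
        layer_genes = {"expression": expr_truth.de_features[CONTRAST_ECMIX]}
    groups = [np.array(sorted(g)) for g in layer_genes.values() if g]

    names = [f"PATH{i + 1:04d}" for i in range(cfg.n_sets)]
    if cfg.n_enriched > cfg.n_sets:
        raise ConfigError("n_enriched exceeds n_sets")
    enriched_idx = set(rng.choice(cfg.n_sets, size=cfg.n_enriched, replace=False).tolist())

    # per-group member probability: factor x base rate, capped so that the
    # source probabilities stay a proper distribution
    probs = []
    for g in groups:
        p = cfg.enrichment_factor * len(g) / cfg.n_genes
        probs.append(min(p, 0.9 / max(len(groups), 1)))
    p_bg = 1.0 - sum(probs)

    sets: dict[str, frozenset[str]] = {}
    for si, name in enumerate(names):
        size = int(rng.integers(cfg.set_size_min, cfg.set_size_max + 1))
        if size > cfg.n_genes:
            raise ConfigError(f"set size {size} exceeds gene universe {cfg.n_genes}")
        if si in enriched_idx and groups:
            counts = rng.multinomial(size, probs + [p_bg])
            members: set[str] = set()
            for g, c in zip(groups, counts[:-1]):
                c = min(int(c), len(g))
                members |= set(rng.choice(g, size=c, replace=False))
            need = size - len(members)
            if need > 0:
                members |= set(rng.choice(universe, size=need, replace=False))
        else:
            members = set(rng.choice(universe, size=size, replace=False))
        sets[name] = frozenset(members)

    truth = SimTruth(enriched_sets={names[i] for i in sorted(enriched_idx)})
    return GeneSetCollection(sets), truth


def simulate_target_db(cfg: SimConfig) -> tuple[TargetPredictionDB, SimTruth]:
    """Simulate a 9-algorithm miRNA-target prediction table.

    Each miRNA has a true target set sampled from the gene universe; each of
    the nine algorithms reports a true pair with probability
    ``cfg.target_sens`` and a non-pair with probability ``cfg.target_fpr``.
    The stored table keeps all pairs with support count >= 1.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _SEED_TARGET)
    genes = np.array(_gene_ids(cfg.n_genes))
    mirnas = _mirna_ids(cfg.n_mirna)

    support = rng.binomial(TargetPredictionDB.N_ALGORITHMS, cfg.target_fpr,
                           size=(cfg.n_mirna, cfg.n_genes)).astype(np.int8)
    true_targets: dict[str, set[str]] = {}
    lo, hi = cfg.targets_per_mirna_min, cfg.targets_per_mirna_max
    for mi, m in enumerate(mirnas):
        k = int(rng.integers(lo, hi + 1))
        tgt = rng.choice(cfg.n_genes, size=k, replace=False)
        support[mi, tgt] = rng.binomial(TargetPredictionDB.N_ALGORITHMS, cfg.target_sens, size=k)
        true_targets[m] = {str(g) for g in genes[tgt]}

    mi_idx, gi_idx = np.nonzero(support)
    records = pd.DataFrame(
        {
            "mirna_id": np.array(mirnas, dtype=object)[mi_idx],
            "gene_symbol": genes[gi_idx],
            "support_count": support[mi_idx, gi_idx].astype(int),
        }
    )
    truth = SimTruth(true_targets=true_targets)
    return TargetPredictionDB(records), truth


@dataclass
class SimBundle:
    """All simulated inputs for one full pipeline run."""

    config: SimConfig
    expression: OmicsMatrix
    expression_truth: SimTruth
    mirna: OmicsMatrix
    mirna_truth: SimTruth
    methylation: OmicsMatrix
    probe_annotation: ProbeAnnotation
    methylation_truth: SimTruth
    pathways: GeneSetCollection
    pathway_truth: SimTruth
    target_db: TargetPredictionDB
    target_truth: SimTruth


def simulate_all(cfg: SimConfig) -> SimBundle:
    """Generate every layer with cross-layer structure wired up.

    The pathway collection oversamples the planted gene groups of all three
    layers (planted DEGs, true targets of planted DE miRNAs, genes of
    planted DMPs) so the three per-layer enrichment analyses share a common
    planted core; the methylation annotation marks a couple of planted DMP
    clusters as host genes of planted DE miRNAs.
    """
    cfg.validate()
    expr, expr_truth = simulate_expression(cfg)
    mirna, mirna_truth = simulate_mirna(cfg)
    de_mirnas = mirna_truth.de_features.get(CONTRAST_ECMIX, set())
    meth, ann, meth_truth = simulate_methylation(cfg, de_mirnas=de_mirnas)
    target_db, target_truth = simulate_target_db(cfg)

    target_genes: set[str] = set()
    for m in de_mirnas:
        target_genes |= target_truth.true_targets.get(m, set())
    dmp_probes = meth_truth.de_features.get(CONTRAST_ECMIX, set())
    dmp_genes = {
        g
        for p in dmp_probes
        for g in ann.table.loc[p, "gene_symbols"]
        if not g.startswith("MIR")
    }
    layer_genes = {
        "expression": expr_truth.de_features[CONTRAST_ECMIX],
        "mirna_targets": target_genes,
        "methylation": dmp_genes,
    }
    pathways, pathway_truth = simulate_pathway_db(cfg, layer_genes=layer_genes)
    return SimBundle(
        config=replace(cfg),
        expression=expr,
        expression_truth=expr_truth,
        mirna=mirna,
        mirna_truth=mirna_truth,
        methylation=meth,
        probe_annotation=ann,
        methylation_truth=meth_truth,
        pathways=pathways,
        pathway_truth=pathway_truth,
        target_db=target_db,
        target_truth=target_truth,
    )
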