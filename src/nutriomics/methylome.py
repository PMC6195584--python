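"""450K-style methylation analysis.

Stages, in pipeline order:

1. :func:`filter_probes` — QC removal of probes with failed detection
   p-values, SNPs at the last three bases of the probe sequence, or missing
   beta values.
2. :func:`bmiq_normalize` — beta-mixture quantile dilation: per sample, a
   three-state beta mixture (unmethylated / intermediate / methylated) is
   fitted separately to Infinium type I and type II probes and type II
   values are mapped onto the type I distribution; type I values are left
   untouched.
3. :func:`moderated_test` — empirical-Bayes moderated t-statistics: probe
   variances are shrunk toward a common prior by
   :func:`squeeze_var` (moment matching on log-variances, the classical
   limma-style scheme), buying degrees of freedom at small n.
4. :func:`call_dmps` / :func:`call_dmrs` — differentially methylated
   positions (BH-adjusted p < 0.1 and |Δβ| >= 0.10) and regions (runs of
   >= 3 nearby probes, Stouffer-combined p, region FDR 5%, peak |Δβ| > 0.10).

Coordinates are 1-based inclusive throughout, following the array-manifest
convention; BED export converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .containers import InputError, OmicsMatrix, ProbeAnnotation
from .differential import bh_adjust

logger = logging.getLogger(__name__)

_EPS = 1e-9


# ---------------------------------------------------------------------------
# probe QC
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    """Filtered matrix/annotation plus per-criterion removal counts."""

    matrix: OmicsMatrix
    annotation: ProbeAnnotation
    removed: dict[str, int]
    degenerate: bool = False


def filter_probes(
    beta: OmicsMatrix,
    ann: ProbeAnnotation,
    max_detection_p: float = 0.01,
) -> FilterResult:
    """Remove low-quality probes before normalization and testing.

    A probe is dropped when its detection p-value exceeds
    ``max_detection_p`` in any sample, when it is SNP-flagged (variant
    within the last 3 bases of the probe sequence), or when any beta value
    is missing.  Removal counts are reported per criterion (a probe may
    count toward several).
    """
    unannotated = beta.feature_ids.difference(ann.probe_ids)
    if len(unannotated):
        raise InputError(f"probes without annotation: {list(unannotated[:10])}")
    det = ann.detection_p.loc[beta.feature_ids, beta.sample_ids]
    fail_det = (det > max_detection_p).any(axis=1)
    snp = ann.table.loc[beta.feature_ids, "snp_last3"].astype(bool)
    missing = beta.values.isna().any(axis=1)
    drop = fail_det.to_numpy() | snp.to_numpy() | missing.to_numpy()
    removed = {
        "detection_p": int(fail_det.sum()),
        "snp_last3": int(snp.sum()),
        "missing": int(missing.sum()),
        "total": int(drop.sum()),
    }
    kept = beta.feature_ids[~drop]
    degenerate = len(kept) == 0
    if degenerate:
        logger.warning("probe filtering removed every probe")
    filtered = OmicsMatrix(beta.values.loc[kept].copy(), beta.sample_sheet, kind=beta.kind)
    return FilterResult(filtered, ann.subset(kept), removed, degenerate)


# ---------------------------------------------------------------------------
# three-state beta mixture and BMIQ
# ---------------------------------------------------------------------------

@dataclass
class BetaMixture:
    """A fitted K-component beta mixture, components ordered by mean."""

    weights: np.ndarray
    shapes: list[tuple[float, float]]  # (a, b) per component
    converged: bool
    log_likelihood: float
    n_iter: int

    def component_pdf(self, x: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [stats.beta.pdf(x, a, b) for a, b in self.shapes]
        )

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Responsibility matrix (len(x) x K), rows summing to 1."""
        dens = self.component_pdf(x) * self.weights[None, :]
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total

    def classify(self, x: np.ndarray) -> np.ndarray:
        """Max-posterior state per value (0 = unmethylated, K-1 = methylated)."""
        return np.argmax(self.posterior(x), axis=1)


def _mom_shapes(x: np.ndarray, w: np.ndarray, min_shape: float = 1e-2) -> tuple[float, float]:
    """Weighted method-of-moments beta shapes, bounded below."""
    wsum = w.sum()
    if wsum <= 0:
        return (1.0, 1.0)
    m = float((w * x).sum() / wsum)
    v = float((w * (x - m) ** 2).sum() / wsum)
    m = min(max(m, _EPS), 1 - _EPS)
    v = max(v, 1e-8)
    common = max(m * (1 - m) / v - 1.0, _EPS)
    return (max(m * common, min_shape), max((1 - m) * common, min_shape))


def fit_beta_mixture(
    values: np.ndarray,
    n_states: int = 3,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> BetaMixture:
    """EM fit of an ``n_states``-component beta mixture to values in (0, 1).

    Initialization splits the data at beta = 0.25 and 0.75 into
    unmethylated / intermediate / methylated states (equal-quantile split
    for other K).  The M-step updates shapes by weighted moment matching.
    Convergence is declared when the log-likelihood improves by less than
    ``tol``; non-convergence returns the last iterate with
    ``converged=False`` and a logged warning.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if ((x <= 0) | (x >= 1)).any():
        raise InputError("mixture input values must lie strictly inside (0, 1)")
    if x.size < 100:
        raise InputError(f"need >= 100 values to fit the mixture, got {x.size}")

    # initial hard assignment
    if n_states == 3:
        state = np.digitize(x, [0.25, 0.75])
    else:
        qs = np.quantile(x, np.linspace(0, 1, n_states + 1)[1:-1])
        state = np.digitize(x, qs)
    resp = np.full((x.size, n_states), 1e-6)
    resp[np.arange(x.size), state] = 1.0
    resp /= resp.sum(axis=1, keepdims=True)

    weights = resp.mean(axis=0)
    shapes = [_mom_shapes(x, resp[:, k]) for k in range(n_states)]
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = np.column_stack([stats.beta.pdf(x, a, b) for a, b in shapes])
        dens = np.clip(dens, 1e-300, None) * weights[None, :]
        total = dens.sum(axis=1)
        new_loglik = float(np.log(total).sum())
        resp = dens / total[:, None]
        weights = resp.mean(axis=0)
        weights = weights / weights.sum()
        shapes = [_mom_shapes(x, resp[:, k]) for k in range(n_states)]
        if new_loglik - loglik < tol and it > 1:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    if not converged:
        logger.warning("beta-mixture EM did not converge in %d iterations", max_iter)

    means = np.array([a / (a + b) for a, b in shapes])
    order = np.argsort(means)
    return BetaMixture(
        weights=weights[order],
        shapes=[shapes[k] for k in order],
        converged=converged,
        log_likelihood=loglik,
        n_iter=it,
    )


def _bmiq_sample(x2: np.ndarray, mix1: BetaMixture, mix2: BetaMixture) -> np.ndarray:
    """Map one sample's type II values onto its type I mixture."""
    state = mix2.classify(x2)
    out = x2.copy()
    # quantile-match the outer states onto the corresponding type I component
    for k in (0, 2):
        sel = state == k
        if not sel.any():
            logger.warning("empty state %d among type II probes; identity fallback", k)
            continue
        a2, b2 = mix2.shapes[k]
        a1, b1 = mix1.shapes[k]
        u = stats.beta.cdf(x2[sel], a2, b2)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        out[sel] = stats.beta.ppf(u, a1, b1)
    # dilate the intermediate state linearly between the transformed anchors
    mid = state == 1
    if mid.any():
        left = (state == 0)
        right = (state == 2)
        if left.any() and right.any():
            x_l, x_r = x2[left].max(), x2[right].min()
            eta_l, eta_r = out[left].max(), out[right].min()
            if x_r > x_l and eta_r > eta_l:
                out[mid] = eta_l + (x2[mid] - x_l) * (eta_r - eta_l) / (x_r - x_l)
            else:
                logger.warning("degenerate intermediate anchors; identity fallback")
        else:
            logger.warning("missing outer state; intermediate left unchanged")
    return np.clip(out, 0.0, 1.0)


def bmiq_normalize(beta: OmicsMatrix, ann: ProbeAnnotation) -> OmicsMatrix:
    """Beta-mixture quantile dilation between Infinium designs, per sample.

    For each sample a three-state beta mixture is fitted separately to
    type I and type II probes; type II values are assigned to states by
    maximum posterior, the unmethylated and methylated states are mapped
    onto the corresponding type I component by quantile matching
    (CDF under the type II component followed by the inverse CDF under the
    type I component), and intermediate values are linearly dilated between
    the transformed state boundaries.  Type I values are returned
    bit-identical; all outputs lie in [0, 1].
    """
    design = ann.table.loc[beta.feature_ids, "design_type"]
    is2 = (design == "II").to_numpy()
    if not is2.any():
        return OmicsMatrix(beta.values.copy(), beta.sample_sheet, kind=beta.kind)
    if is2.all():
        raise InputError("BMIQ needs both design types present")
    out = beta.values.copy()
    vals = beta.values.to_numpy(dtype=float)
    clipped = np.clip(vals, 1e-6, 1 - 1e-6)
    for j, sample in enumerate(beta.sample_ids):
        mix1 = fit_beta_mixture(clipped[~is2, j])
        mix2 = fit_beta_mixture(clipped[is2, j])
        out.iloc[is2, j] = _bmiq_sample(clipped[is2, j], mix1, mix2)
    return OmicsMatrix(out, beta.sample_sheet, kind=beta.kind)


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

#: prior df above which the prior is reported as infinite
D0_INFINITE = 1e6


def _trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if -dif / x < tol:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: int, prior_df: float | None = None):
    """Shrink per-probe variances toward a common prior (limma-style).

    The prior degrees of freedom ``d0`` and prior variance ``s0²`` are
    estimated by moment matching on log-variances: with
    e = log(s2) − digamma(df/2) + log(df/2), the excess variance of e over
    trigamma(df/2) determines d0 through a Newton inversion of the trigamma
    function, and s0² follows from the mean of e.  Posterior variances are
    s2_post = (d0·s0² + df·s2)/(d0 + df).

    Parameters
    ----------
    s2
        Per-probe residual sample variances (>= 0).
    df
        Residual degrees of freedom (>= 1), common to all probes.
    prior_df
        Optional forced value of d0 (0 disables shrinkage entirely).

    Returns
    -------
    (d0, s0_sq, s2_post); ``d0`` is ``inf`` when the moment estimate implies
    no excess dispersion (then s2_post = s0² everywhere).
    """
    s2 = np.asarray(s2, dtype=float)
    if (s2 < 0).any():
        raise InputError("variances must be non-negative")
    if df < 1:
        raise InputError(f"df must be >= 1, got {df}")
    z = np.log(np.maximum(s2, 1e-12))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    target = e_var - float(polygamma(1, df / 2.0))

    if prior_df is not None:
        d0 = float(prior_df)
        s0_sq = float(np.exp(e_mean)) if not np.isfinite(d0) or d0 <= 0 else None
        if s0_sq is None:
            s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    elif target > 0:
        d0 = 2.0 * _trigamma_inverse(target)
        if d0 > D0_INFINITE:
            d0 = np.inf
            s0_sq = float(np.exp(e_mean))
        else:
            s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion: with (near-)constant s2 the log-scale bias
        # offset would overcorrect, so fall back to the geometric mean
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(z))) if e_var < 1e-12 else float(np.exp(e_mean))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, s2_post


@dataclass
class ModeratedStats:
    """Per-probe moderated statistics plus the global prior estimates."""

    table: pd.DataFrame  # probe_id, delta_beta, s2, t_mod, p_raw, p_adj
    d0: float
    s0_sq: float
    df_residual: int
    df_total: float = field(init=False)

    def __post_init__(self) -> None:
        self.df_total = self.df_residual + (self.d0 if np.isfinite(self.d0) else np.inf)


def moderated_test(beta: OmicsMatrix, group_a: str, group_b: str,
                   use_mvalues: bool = False) -> ModeratedStats:
    """Moderated two-group comparison of methylation per probe.

    Effects are group-mean beta differences (B − A, with B the treatment
    group).  Residual variances (df = nA + nB − 2) are shrunk by
    :func:`squeeze_var`; the moderated t uses the posterior variance and is
    referred to a t distribution with df_residual + d0 degrees of freedom
    (normal when d0 is infinite).  BH adjustment is applied across probes.

    ``use_mvalues`` switches the *test* to logit2-transformed values while
    keeping the reported effect on the beta scale.
    """
    a = beta.group_values(group_a)
    b = beta.group_values(group_b)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise InputError(f"both groups need >= 2 samples (got {na}, {nb})")
    df = na + nb - 2
    delta_beta = b.mean(axis=1) - a.mean(axis=1)

    if use_mvalues:
        ta = np.log2(np.clip(a, 1e-6, 1 - 1e-6) / (1 - np.clip(a, 1e-6, 1 - 1e-6)))
        tb = np.log2(np.clip(b, 1e-6, 1 - 1e-6) / (1 - np.clip(b, 1e-6, 1 - 1e-6)))
    else:
        ta, tb = a, b
    eff = tb.mean(axis=1) - ta.mean(axis=1)
    ss = ((ta - ta.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((tb - tb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df

    d0, s0_sq, s2_post = squeeze_var(s2, df)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, eff / se, 0.0)
    df_total = df + d0
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    table = pd.DataFrame(
        {
            "probe_id": beta.feature_ids,
            "delta_beta": delta_beta,
            "s2": s2,
            "t_mod": t_mod,
            "p_raw": p,
            "p_adj": bh_adjust(p),
        }
    ).set_index("probe_id", drop=False)
    return ModeratedStats(table=table, d0=d0, s0_sq=s0_sq, df_residual=df)


# ---------------------------------------------------------------------------
# DMP / DMR calling
# ---------------------------------------------------------------------------

def call_dmps(stats_: ModeratedStats, p_adj_max: float = 0.1,
              min_abs_delta: float = 0.10) -> pd.DataFrame:
    """Differentially methylated positions.

    A probe is a DMP iff its BH-adjusted p-value is below ``p_adj_max`` and
    its |Δβ| is at least ``min_abs_delta``; the direction is ``hyper``
    (gain of methylation) or ``hypo`` by the sign of Δβ.
    """
    t = stats_.table
    keep = (t["p_adj"] < p_adj_max) & (t["delta_beta"].abs() >= min_abs_delta)
    out = t.loc[keep, ["probe_id", "delta_beta", "p_adj"]].copy()
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    return out


@dataclass
class DMR:
    """A called differentially methylated region (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    combined_p: float
    fdr: float
    peak_abs_delta_beta: float

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def call_dmrs(
    stats_: ModeratedStats,
    ann: ProbeAnnotation,
    max_gap: int = 1000,
    min_probes: int = 3,
    fdr_max: float = 0.05,
    min_peak_delta: float = 0.10,
) -> list[DMR]:
    """Differentially methylated regions from per-probe moderated statistics.

    Candidate regions are maximal runs of probes on one chromosome with
    inter-probe gaps <= ``max_gap`` (probes sorted by chrom, pos, with
    probe-ID tie-break).  Each candidate's p-value combines its member
    probes by Stouffer's method with equal weights, converting two-sided
    p-values to signed z-scores using the Δβ sign so that coherent
    directional shifts reinforce.  BH adjustment runs across candidates; a
    region is kept when its FDR is below ``fdr_max``, it has at least
    ``min_probes`` probes, and its peak |Δβ| exceeds ``min_peak_delta``.
    """
    t = stats_.table
    ann_t = ann.table.loc[t.index]
    d = pd.DataFrame(
        {
            "probe_id": t["probe_id"].to_numpy(),
            "chrom": ann_t["chrom"].to_numpy(),
            "pos": ann_t["pos"].to_numpy(dtype=int),
            "delta_beta": t["delta_beta"].to_numpy(),
            "p_raw": t["p_raw"].to_numpy(),
        }
    ).sort_values(["chrom", "pos", "probe_id"], kind="mergesort")

    chrom = d["chrom"].to_numpy()
    pos = d["pos"].to_numpy()
    new_run = np.ones(len(d), dtype=bool)
    if len(d) > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) <= max_gap
        new_run[1:] = ~(same_chrom & close)
    run_id = np.cumsum(new_run)
    d = d.assign(run=run_id)

    candidates = []
    for _, grp in d.groupby("run", sort=True):
        p = np.clip(grp["p_raw"].to_numpy(), 1e-300, 1.0)
        z = stats.norm.isf(p / 2.0) * np.sign(grp["delta_beta"].to_numpy())
        z_comb = z.sum() / np.sqrt(len(z))
        p_comb = 2.0 * stats.norm.sf(abs(z_comb))
        candidates.append(
            {
                "chrom": grp["chrom"].iloc[0],
                "start": int(grp["pos"].min()),
                "end": int(grp["pos"].max()),
                "probe_ids": grp["probe_id"].tolist(),
                "combined_p": float(p_comb),
                "peak": float(grp["delta_beta"].abs().max()),
            }
        )
    if not candidates:
        return []
    fdr = bh_adjust([c["combined_p"] for c in candidates])
    out = []
    for c, q in zip(candidates, fdr):
        if q < fdr_max and len(c["probe_ids"]) >= min_probes and c["peak"] > min_peak_delta:
            out.append(DMR(c["chrom"], c["start"], c["end"], c["probe_ids"],
                           c["combined_p"], float(q), c["peak"]))
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


@dataclass
class DmpGeneMapping:
    """Genes hit by DMPs, with an intergenic tally and per-gene region counts."""

    genes: set[str]
    intergenic: int
    region_breakdown: dict[str, dict[str, int]]


def map_probes_to_genes(dmps: pd.DataFrame, ann: ProbeAnnotation) -> DmpGeneMapping:
    """Assign DMPs to genes via the probe annotation.

    A gene is differentially methylated when at least one DMP maps to it
    (set semantics); DMPs with no gene annotation contribute to the
    intergenic tally only.
    """
    genes: set[str] = set()
    intergenic = 0
    breakdown: dict[str, dict[str, int]] = {}
    for probe in dmps["probe_id"]:
        symbols = ann.table.loc[probe, "gene_symbols"]
        region = ann.table.loc[probe, "gene_region"]
        if not symbols:
            intergenic += 1
            continue
        for g in symbols:
            genes.add(g)
            breakdown.setdefault(g, {}).setdefault(str(region), 0)
            breakdown[g][str(region)] += 1
    return DmpGeneMapping(genes=genes, intergenic=intergenic, region_breakdown=breakdown)


def dmrs_to_bed(dmrs: list[DMR]) -> pd.DataFrame:
    """BED-style table (0-based half-open) from 1-based inclusive DMRs."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in dmrs],
            "start": [r.start - 1 for r in dmrs],
            "end": [r.end for r in dmrs],
            "name": [f"DMR_{i + 1}" for i in range(len(dmrs))],
            "score": [r.fdr for r in dmrs],
        }
    )
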