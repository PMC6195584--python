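"""Per-feature two-group differential testing for expression and miRNA layers.

Implements the microarray-style analysis chain: within-array lowess (MA)
normalization for two-colour data, 75th-percentile scaling for the miRNA
layer, a pooled-variance two-sample Student t-test per feature,
Benjamini–Hochberg step-up adjustment, significance/direction calls and a
cross-contrast comparison that splits shared significant features by
direction agreement.

The t-test is the classical equal-variance form with nA + nB − 2 degrees of
freedom; effects are reported as mean(B) − mean(A), with B the treatment
group, in log2 units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import InputError, OmicsMatrix

logger = logging.getLogger(__name__)

#: Columns of a differential-result table.
DIFF_COLUMNS = ("feature_id", "effect", "t_stat", "p_raw", "p_adj", "significant", "direction")


@dataclass
class ContrastComparison:
    """Agreement between two contrasts over their shared significant features."""

    common_features: set[str]
    n_same_direction: int
    n_opposite_direction: int

    @property
    def n_common(self) -> int:
        return len(self.common_features)


def lowess_ma_normalize(
    red: np.ndarray,
    green: np.ndarray,
    span: float = 0.3,
    iterations: int = 2,
) -> np.ndarray:
    """Within-array intensity-dependent normalization of a two-colour array.

    Computes M = log2(red/green) and A = (log2 red + log2 green)/2 per
    feature, fits a locally weighted linear regression of M on A (lowess
    with ``span`` as the smoothing fraction and ``iterations`` robustness
    iterations) and returns the residual M − fit(A).

    Parameters
    ----------
    red, green
        Equal-length positive intensity vectors.
    span
        Lowess smoothing fraction in (0, 1].

    Returns
    -------
    Normalized log-ratio vector whose intensity-dependent trend has been
    removed (mean residual ≈ 0 over the fitting support).
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape or red.ndim != 1:
        raise InputError("red and green must be equal-length 1-D vectors")
    bad = np.nonzero((red <= 0) | (green <= 0))[0]
    if bad.size:
        raise InputError(f"non-positive intensities at features {bad[:10].tolist()}")
    if not 0.0 < span <= 1.0:
        raise InputError(f"span must lie in (0, 1], got {span}")
    m = np.log2(red / green)
    a = 0.5 * np.log2(red * green)
    fit = lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return m - fit


def percentile75_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Scale each sample by subtracting its 75th percentile (log scale).

    Linear interpolation between order statistics is used for the
    percentile, so each output column has a 75th percentile of exactly 0 to
    numeric tolerance.  Columns with fewer than four finite values are
    rejected.
    """
    values = matrix.values
    finite_counts = np.isfinite(values.to_numpy(dtype=float)).sum(axis=0)
    low = [str(c) for c, k in zip(values.columns, finite_counts) if k < 4]
    if low:
        raise InputError(f"columns with fewer than 4 finite values: {low}")
    q75 = values.quantile(0.75, axis=0, interpolation="linear")
    out = values.subtract(q75, axis=1)
    return OmicsMatrix(out, matrix.sample_sheet, kind=matrix.kind)


def row_t_test(matrix: OmicsMatrix, group_a: str, group_b: str) -> pd.DataFrame:
    """Pooled-variance two-sample Student t-test for every feature.

    ``group_b`` is the treatment group: the reported effect is
    mean(B) − mean(A).  Degrees of freedom are nA + nB − 2 and p-values are
    two-sided.  Features with zero pooled variance get t = 0, p = 1 when the
    group means agree, and p = 0 with ``degenerate`` flagged otherwise.

    Returns a DataFrame with columns feature_id, effect, t_stat, p_raw,
    degenerate.
    """
    a = matrix.group_values(group_a)
    b = matrix.group_values(group_b)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise InputError(f"both groups need >= 2 samples (got {na}, {nb})")
    df = na + nb - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((b - mean_b[:, None]) ** 2).sum(axis=1)
    sp2 = (ss_a + ss_b) / df
    effect = mean_b - mean_a
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    zero_var = se == 0
    equal = zero_var & (effect == 0)
    degen = zero_var & (effect != 0)
    t = np.where(equal, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(np.where(zero_var, 0.0, t)), df)
    p = np.where(equal, 1.0, p)
    p = np.where(degen, 0.0, p)
    t = np.where(degen, np.where(effect > 0, np.inf, -np.inf), t)
    if degen.any():
        logger.warning("%d features have zero pooled variance with unequal means", int(degen.sum()))
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "effect": effect,
            "t_stat": t,
            "p_raw": p,
            "degenerate": degen,
        }
    ).set_index("feature_id", drop=False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values in the original order.

    Sort ascending, multiply by n/rank, enforce monotonicity by a cumulative
    minimum from the largest rank downward, and cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def call_differential(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Attach BH-adjusted p-values and significance/direction calls.

    A feature is significant iff p_adj < ``alpha``; its direction is ``up``
    or ``down`` by the sign of the effect, ``none`` otherwise.
    """
    if not 0.0 < alpha <= 1.0:
        raise InputError(f"alpha must lie in (0, 1], got {alpha}")
    out = results.copy()
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    direction = np.where(out["effect"] > 0, "up", np.where(out["effect"] < 0, "down", "none"))
    out["direction"] = np.where(out["significant"], direction, "none")
    # a significant call with a zero effect cannot carry a direction
    out.loc[(out["significant"]) & (out["direction"] == "none"), "significant"] = False
    return out


def significant_features(results: pd.DataFrame) -> set[str]:
    """Feature IDs called significant in a differential-result table."""
    return set(results.loc[results["significant"], "feature_id"])


def filter_low_variance(matrix: OmicsMatrix, min_sd: float = 1e-8) -> OmicsMatrix:
    """Drop features whose across-sample standard deviation is below ``min_sd``.

    A minimal variance-control step applied before testing; features that
    are essentially constant carry no usable signal and destabilise the
    t-statistic denominator.
    """
    sd = matrix.values.std(axis=1, ddof=1)
    keep = sd >= min_sd
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("variance filter removed %d features", n_drop)
    return OmicsMatrix(matrix.values.loc[keep].copy(), matrix.sample_sheet, kind=matrix.kind)


def compare_contrasts(a: pd.DataFrame, b: pd.DataFrame) -> ContrastComparison:
    """Split features significant in both contrasts by direction agreement.

    Both result tables must cover the same feature universe.  Features
    significant in both with a nonzero direction are counted as same- or
    opposite-direction; their union is the ``common_features`` set.
    """
    ua, ub = set(a["feature_id"]), set(b["feature_id"])
    if ua != ub:
        raise InputError("contrast results cover different feature universes")
    sig_a = a.loc[a["significant"]].set_index("feature_id")
    sig_b = b.loc[b["significant"]].set_index("feature_id")
    common = set(sig_a.index) & set(sig_b.index)
    same = opposite = 0
    for f in common:
        da, db = np.sign(sig_a.at[f, "effect"]), np.sign(sig_b.at[f, "effect"])
        if da == 0 or db == 0:
            continue
        if da == db:
            same += 1
        else:
            opposite += 1
    return ContrastComparison(common_features=common, n_same_direction=same,
                              n_opposite_direction=opposite)
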