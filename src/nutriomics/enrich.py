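"""Hypergeometric over-representation analysis (ORA).

One-sided upper-tail tests of a query feature list against named sets
within a measured universe, BH-adjusted across sets.  The same machinery
drives pathway enrichment of gene lists and genomic-category enrichment of
DMPs (gene region or CpG-island class of each probe against the filtered
probe universe).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, InputError, ProbeAnnotation
from .differential import bh_adjust

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("set_name", "k", "K", "n", "N", "p_raw", "p_adj", "fold_enrichment")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts members of a size-``K`` category in a size-``n`` draw without
    replacement from a universe of ``N``.  Computed through the survival
    function of the hypergeometric distribution (stable log-space
    internals); the result lies in (0, 1].
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise InputError(f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def ora(query: set[str], universe: set[str], sets: GeneSetCollection) -> pd.DataFrame:
    """Over-representation of a query list in every set of a collection.

    Query members outside the universe are dropped (logged); sets are
    intersected with the universe and skipped when empty.  Results carry
    raw and BH-adjusted p-values and fold enrichment (k/n)/(K/N), sorted by
    raw p with ties broken by set name.
    """
    universe = set(universe)
    query_in = set(query) & universe
    dropped = len(set(query)) - len(query_in)
    if dropped:
        logger.info("dropped %d query features outside the universe", dropped)
    if not query_in:
        logger.warning("empty query after universe intersection")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    n, N = len(query_in), len(universe)
    rows = []
    for name, members in sets:
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query_in)
        p = hypergeom_upper(k, K, n, N)
        fold = (k / n) / (K / N)
        rows.append((name, k, K, n, N, p, fold))
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_raw", "fold_enrichment"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out = out.sort_values(["p_raw", "set_name"], kind="mergesort").reset_index(drop=True)
    return out[list(RESULT_COLUMNS)]


def region_enrichment(dmps: pd.DataFrame, ann: ProbeAnnotation, category: str) -> pd.DataFrame:
    """Enrichment of DMPs in genomic annotation categories.

    ``category`` selects the annotation column (``gene_region`` or
    ``cgi_class``).  The universe is every annotated probe (callers pass
    the post-QC annotation); each category value is tested
    hypergeometrically for over-representation among DMP probes, with BH
    adjustment across categories.
    """
    if category not in ("gene_region", "cgi_class"):
        raise InputError(f"category must be 'gene_region' or 'cgi_class', got {category!r}")
    labels = ann.table[category].astype(str)
    universe_probes = set(ann.probe_ids)
    dmp_probes = set(dmps["probe_id"]) & universe_probes
    sets = GeneSetCollection(
        {str(value): frozenset(labels.index[labels == value])
         for value in sorted(labels.unique())}
    )
    return ora(dmp_probes, universe_probes, sets)


def top_k(results: pd.DataFrame, k: int) -> list[str]:
    """First ``k`` set names ordered by (raw p, name); fewer if fewer tested."""
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if results.empty:
        return []
    ordered = results.sort_values(["p_raw", "set_name"], kind="mergesort")
    return ordered["set_name"].head(k).tolist()
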