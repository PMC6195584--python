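"""Consensus miRNA-target mapping.

A (miRNA, gene) pair enters the consensus target set when at least
``min_algorithms`` of the nine prediction algorithms report it (default 5,
the specificity-improving rule used with miRWalk-style prediction tables).
The per-condition target list is the union over the queried miRNAs.
"""

from __future__ import annotations

import logging

from .containers import InputError, TargetPredictionDB

logger = logging.getLogger(__name__)


def consensus_targets(
    db: TargetPredictionDB,
    mirnas: set[str],
    min_algorithms: int = 5,
) -> set[str]:
    """Union of genes supported by >= ``min_algorithms`` algorithms for the query.

    miRNAs absent from the database contribute an empty set (with a logged
    warning).  Deterministic and order-independent.
    """
    n_alg = TargetPredictionDB.N_ALGORITHMS
    if not 1 <= min_algorithms <= n_alg:
        raise InputError(f"min_algorithms must lie in [1, {n_alg}], got {min_algorithms}")
    known = db.mirnas()
    missing = set(mirnas) - known
    if missing:
        logger.warning("miRNAs absent from target DB: %s", sorted(missing))
    rec = db.records
    mask = rec["mirna_id"].isin(mirnas) & (rec["support_count"] >= min_algorithms)
    return set(rec.loc[mask, "gene_symbol"])


def target_deg_overlap(targets: set[str], degs: set[str]) -> tuple[set[str], float]:
    """Overlap between a consensus target list and a DEG list.

    Returns (targets ∩ degs, |overlap| / |degs|); the fraction is 0 with a
    logged warning when the DEG list is empty.
    """
    overlap = set(targets) & set(degs)
    if not degs:
        logger.warning("empty DEG list; overlap fraction undefined, reporting 0")
        return overlap, 0.0
    return overlap, len(overlap) / len(degs)
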