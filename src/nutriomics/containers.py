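"""Core in-memory containers shared across the pipeline stages.

All matrices are features-by-samples :class:`pandas.DataFrame` objects with a
sample sheet mapping each sample to its experimental condition.  The three
conditions of the reference design are unstimulated endothelial cells
(``control``), TNFα-stimulated cells (``TNF``) and cells pre-exposed to an
epicatechin-metabolite mixture before TNFα stimulation (``ECMIX_TNF``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Condition labels of the three-arm endothelial-cell design.
CONDITIONS = ("control", "TNF", "ECMIX_TNF")

#: Layer kinds carried by an :class:`OmicsMatrix`.
LAYER_KINDS = ("expression", "mirna", "methylation-beta")


class NutriomicsError(Exception):
    """Base class for all package errors."""


class ConfigError(NutriomicsError):
    """Invalid configuration value; the message names the offending field."""


class InputError(NutriomicsError):
    """Invalid input data (bad values, mismatched identifiers, parse errors)."""


@dataclass
class OmicsMatrix:
    """A feature-by-sample numeric matrix with its sample sheet.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with one column per sample.
        Log2-scale intensities/ratios for expression and miRNA layers,
        beta values in [0, 1] for methylation.
    sample_sheet
        Series mapping sample ID -> condition label.
    kind
        One of ``expression``, ``mirna``, ``methylation-beta``.
    """

    values: pd.DataFrame
    sample_sheet: pd.Series
    kind: str = "expression"

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise InputError(f"unknown layer kind {self.kind!r}; expected one of {LAYER_KINDS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate feature IDs: {dups[:10]}")
        if self.values.columns.has_duplicates:
            raise InputError("duplicate sample IDs in matrix header")
        missing = [s for s in self.values.columns if s not in self.sample_sheet.index]
        if missing:
            raise InputError(f"samples missing from sample sheet: {missing}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_for(self, condition: str) -> list[str]:
        """Sample IDs (matrix column order) belonging to one condition."""
        in_group = set(self.sample_sheet.index[self.sample_sheet == condition])
        return [s for s in self.values.columns if s in in_group]

    def group_values(self, condition: str) -> np.ndarray:
        """Numeric sub-matrix (features x samples) for one condition."""
        cols = self.samples_for(condition)
        if not cols:
            raise InputError(f"no samples with condition {condition!r}")
        return self.values[cols].to_numpy(dtype=float)


@dataclass
class ProbeAnnotation:
    """Per-CpG annotation for a 450K-style methylation array.

    ``table`` is indexed by probe ID with columns: ``chrom``, ``pos``
    (1-based inclusive), ``strand``, ``design_type`` ('I'/'II'),
    ``gene_symbols`` (list of symbols, possibly empty), ``gene_region``,
    ``cgi_class`` and ``snp_last3`` (bool).  ``detection_p`` is a parallel
    probe-by-sample matrix of detection p-values.
    """

    table: pd.DataFrame
    detection_p: pd.DataFrame

    REQUIRED = ("chrom", "pos", "strand", "design_type", "gene_symbols",
                "gene_region", "cgi_class", "snp_last3")

    GENE_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "intergenic")
    CGI_CLASSES = ("island", "shore", "shelf", "opensea")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InputError(f"probe annotation missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise InputError("duplicate probe IDs in annotation")
        if (self.table["pos"] < 1).any():
            raise InputError("probe positions must be 1-based (>= 1)")
        bad = set(self.table["design_type"]) - {"I", "II"}
        if bad:
            raise InputError(f"unknown design types: {sorted(bad)}")
        if not self.detection_p.index.equals(self.table.index):
            self.detection_p = self.detection_p.reindex(self.table.index)
            if self.detection_p.isna().any().any():
                raise InputError("detection p matrix does not cover all annotated probes")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, probe_ids) -> "ProbeAnnotation":
        idx = self.table.index.intersection(pd.Index(probe_ids))
        return ProbeAnnotation(self.table.loc[idx].copy(), self.detection_p.loc[idx].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional per-set descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise InputError(f"empty gene sets not allowed: {empty[:10]}")
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class TargetPredictionDB:
    """miRNA -> gene predictions with per-pair algorithm support out of 9.

    ``records`` has columns ``mirna_id``, ``gene_symbol``, ``support_count``
    (integer in [0, 9]: how many of the nine prediction algorithms report the
    pair).  Pairs are unique.
    """

    N_ALGORITHMS = 9

    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"mirna_id", "gene_symbol", "support_count"}
        missing = need - set(self.records.columns)
        if missing:
            raise InputError(f"target DB missing columns: {sorted(missing)}")
        sc = self.records["support_count"]
        if ((sc < 0) | (sc > self.N_ALGORITHMS)).any():
            raise InputError(f"support_count outside [0, {self.N_ALGORITHMS}]")
        if self.records.duplicated(["mirna_id", "gene_symbol"]).any():
            raise InputError("duplicate (mirna, gene) pairs in target DB")

    def mirnas(self) -> set[str]:
        return set(self.records["mirna_id"].unique())
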