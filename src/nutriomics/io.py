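"""Readers and writers for the pipeline's text formats.

TSV dialect: tab-separated, UTF-8, ``#``-prefixed comment lines ignored,
``.`` for missing values.  Matrices have the feature ID in the first column
and sample IDs in the header.  Gene sets use the GMT standard (name,
description, then members).  Methylation coordinates are written 1-based
inclusive in the annotation and converted to 0-based half-open for BED.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    GeneSetCollection,
    InputError,
    OmicsMatrix,
    ProbeAnnotation,
    TargetPredictionDB,
)
from .simdata import SimTruth

logger = logging.getLogger(__name__)

MISSING = "."


def _data_lines(path):
    """Yield (1-based line number, stripped line) skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line


# ---------------------------------------------------------------------------
# sample sheets and matrices
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.Series:
    """Sample sheet TSV (sample_id, condition) -> Series sample -> condition."""
    ids, conds = [], []
    rows = list(_data_lines(path))
    for lineno, line in rows:
        fields = line.split("\t")
        if fields[0] == "sample_id":
            continue
        if len(fields) != 2:
            raise InputError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        ids.append(fields[0])
        conds.append(fields[1])
    if len(set(ids)) != len(ids):
        raise InputError(f"{path}: duplicate sample IDs")
    return pd.Series(conds, index=pd.Index(ids, name="sample_id"), name="condition")


def write_sample_sheet(sheet: pd.Series, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcondition\n")
        for sid, cond in sheet.items():
            fh.write(f"{sid}\t{cond}\n")


def read_matrix(path, sample_sheet_path, kind: str = "expression") -> OmicsMatrix:
    """Read a feature-by-sample TSV matrix validated against its sample sheet.

    Errors (duplicate feature ID, non-numeric cell, sample missing from the
    sheet) carry the file line number.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    header: list[str] | None = None
    features: list[str] = []
    seen: dict[str, int] = {}
    rows: list[list[float]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields[1:]
            continue
        fid = fields[0]
        if fid in seen:
            raise InputError(
                f"{path}:{lineno}: duplicate feature ID {fid!r} (first seen line {seen[fid]})"
            )
        seen[fid] = lineno
        if len(fields) != len(header) + 1:
            raise InputError(f"{path}:{lineno}: expected {len(header) + 1} fields")
        vals = []
        for tok in fields[1:]:
            if tok == MISSING or tok == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(tok))
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-numeric cell {tok!r}") from None
        features.append(fid)
        rows.append(vals)
    if header is None:
        raise InputError(f"{path}: empty matrix file")
    df = pd.DataFrame(rows, index=pd.Index(features, name="feature_id"), columns=header)
    return OmicsMatrix(df, sheet, kind=kind)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    df = matrix.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, df.columns)) + "\n")
        for fid, row in zip(df.index, df.to_numpy()):
            cells = [MISSING if not np.isfinite(v) else repr(float(v)) for v in row]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """GMT reader: name, description, then tab-separated members."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    n_dups = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise InputError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
        if name in sets:
            raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
        unique = set(members)
        n_dups += len(members) - len(unique)
        sets[name] = frozenset(unique)
        descriptions[name] = desc
    if n_dups:
        logger.info("deduplicated %d repeated members while reading %s", n_dups, path)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("probe_id", "chrom", "pos", "strand", "design_type",
                      "gene_symbols", "gene_region", "cgi_class", "snp_last3")


def write_probe_annotation(ann: ProbeAnnotation, path, detection_path) -> None:
    t = ann.table
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for pid, row in t.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(pid), str(row["chrom"]), str(int(row["pos"])), str(row["strand"]),
                        str(row["design_type"]), ";".join(row["gene_symbols"]),
                        str(row["gene_region"]), str(row["cgi_class"]),
                        "1" if row["snp_last3"] else "0",
                    ]
                )
                + "\n"
            )
    det = ann.detection_p
    with open(detection_path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(map(str, det.columns)) + "\n")
        for pid, row in zip(det.index, det.to_numpy()):
            fh.write(str(pid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_probe_annotation(path, detection_path) -> ProbeAnnotation:
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "probe_id":
            continue
        if len(fields) != len(ANNOTATION_COLUMNS):
            raise InputError(f"{path}:{lineno}: expected {len(ANNOTATION_COLUMNS)} fields")
        rows.append(
            {
                "probe_id": fields[0],
                "chrom": fields[1],
                "pos": int(fields[2]),
                "strand": fields[3],
                "design_type": fields[4],
                "gene_symbols": [g for g in fields[5].split(";") if g],
                "gene_region": fields[6],
                "cgi_class": fields[7],
                "snp_last3": fields[8] == "1",
            }
        )
    table = pd.DataFrame(rows).set_index("probe_id")
    det = pd.read_csv(detection_path, sep="\t", comment="#", index_col="probe_id")
    return ProbeAnnotation(table, det)


# ---------------------------------------------------------------------------
# target DB, truth, results
# ---------------------------------------------------------------------------

def write_target_db(db: TargetPredictionDB, path) -> None:
    db.records.to_csv(path, sep="\t", index=False)


def read_target_db(path) -> TargetPredictionDB:
    rec = pd.read_csv(path, sep="\t", comment="#")
    return TargetPredictionDB(rec)


def write_truth(truth: SimTruth, path) -> None:
    data = {
        "de_features": {c: sorted(s) for c, s in truth.de_features.items()},
        "direction": {c: dict(sorted(d.items())) for c, d in truth.direction.items()},
        "dmr_regions": [[c, s, e] for c, s, e in truth.dmr_regions],
        "enriched_sets": sorted(truth.enriched_sets),
        "true_targets": {m: sorted(g) for m, g in sorted(truth.true_targets.items())},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SimTruth:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return SimTruth(
        de_features={c: set(s) for c, s in data["de_features"].items()},
        direction={c: {f: int(v) for f, v in d.items()} for c, d in data["direction"].items()},
        dmr_regions=[(c, int(s), int(e)) for c, s, e in data["dmr_regions"]],
        enriched_sets=set(data["enriched_sets"]),
        true_targets={m: set(g) for m, g in data["true_targets"].items()},
    )


def write_diff_results(results: pd.DataFrame, path) -> None:
    cols = [c for c in ("feature_id", "effect", "t_stat", "p_raw", "p_adj", "direction")
            if c in results.columns]
    results[cols].to_csv(path, sep="\t", index=False)


def read_diff_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "significant" not in df.columns and "direction" in df.columns:
        df["significant"] = df["direction"].isin(["up", "down"])
    return df.set_index("feature_id", drop=False)


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path) -> set[str]:
    return {line for _, line in _data_lines(path)}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
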