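"""Readers and writers for the pipeline's plain-text formats.

Dialects: plate tables and fit tables are comma-separated CSV with a
mandatory header; call sets are VCF-like TSV with 1-based positions; gene
sets are standard GMT (name, description, genes...); low-mappability masks
are 0-based half-open BED; reports are JSON.  Readers validate the contract
and report the offending line on failure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

PLATE_COLUMNS = ["sample", "drug", "dose_uM", "ir_gy", "replicate", "viability_pct"]
CALLSET_COLUMNS = [
    "chrom", "pos", "ref", "alt", "caller",
    "t_depth", "t_alt", "n_alt", "pop_af", "vaf",
]


class FormatError(ValueError):
    """Malformed input file; message carries the line number."""


def write_plate_csv(plate: pd.DataFrame, path):
    plate.to_csv(path, index=False, columns=PLATE_COLUMNS)


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing plate columns {missing}")
    return df


def write_callset_tsv(calls: pd.DataFrame, path):
    cols = CALLSET_COLUMNS + [
        c for c in ("sample", "gene", "consequence", "context") if c in calls.columns
    ]
    calls.to_csv(path, sep="\t", index=False, columns=cols)


def read_callset_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALLSET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing callset columns {missing}")
    bad = np.nonzero(df["pos"].values < 1)[0]
    if bad.size:
        # +2: header line plus 1-based numbering
        raise FormatError(
            f"{path}: line {bad[0] + 2}: pos must be >= 1 (1-based positions)"
        )
    return df


def write_gmt(genesets: dict[str, list[str]], path, description: str = "na"):
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    "and >= 1 gene"
                )
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def read_bed_mask(path) -> list[tuple[str, int, int]]:
    """BED intervals as (chrom, start, end), 0-based half-open."""
    mask = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer interval"
                ) from exc
            if end <= start:
                raise FormatError(f"{path}: line {lineno}: end must exceed start")
            mask.append((parts[0], start, end))
    return mask


def write_signature_reference(reference: pd.DataFrame, path):
    reference.to_csv(path, sep="\t", index_label="context")


def read_signature_reference(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="context")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json_report(report: dict, path):
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))


def read_json_report(path) -> dict:
    return json.loads(Path(path).read_text())
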