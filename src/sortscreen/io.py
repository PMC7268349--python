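"""Readers and writers for the tab-delimited screen tables.

All tables are UTF-8 TSV with a header row; lines starting with '#' are
comments (output files carry the tool version and run parameters there).
Guide positions are 1-based in tables and converted to 0-based half-open
only when exporting BED.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import __version__
from .bins import BinValidationError, SortingBin, quantile_bins_to_z, validate_bins

__all__ = [
    "read_counts",
    "read_bins",
    "write_table",
    "write_bins",
    "write_bed",
    "file_checksum",
]

_REQUIRED_COUNT_COLS = ("guide_id", "is_negative_control", "unsorted")
_TRUE_STRINGS = {"1", "true", "t", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "no"}
# Consistency tolerance between supplied quantile and Z bin bounds.
_QZ_TOL = 1e-6


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"guide_id": str})


def _parse_bool(series: pd.Series, path, column: str) -> pd.Series:
    def one(v):
        s = str(v).strip().lower()
        if s in _TRUE_STRINGS:
            return True
        if s in _FALSE_STRINGS:
            return False
        raise ValueError(
            f"{path}: column {column!r} has non-boolean value {v!r}"
        )

    return series.map(one)


def read_counts(path, *, bin_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Read and validate a guide count table.

    Requires ``guide_id``, ``is_negative_control`` and ``unsorted`` columns
    plus one non-negative integer column per sorting bin.  When ``bin_ids``
    is given (e.g. from the bin-definition file), those columns must exist
    and count validation is restricted to them; otherwise every numeric
    column apart from annotations is treated as a bin.  Duplicated guide ids
    within one experiment are rejected.
    """
    path = Path(path)
    df = _read_tsv(path)
    for col in _REQUIRED_COUNT_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["is_negative_control"] = _parse_bool(
        df["is_negative_control"], path, "is_negative_control"
    )

    annotation = {"guide_id", "is_negative_control", "experiment_id", "chrom", "pos", "element_label"}
    if bin_ids is None:
        count_cols = [c for c in df.columns if c not in annotation and c != "unsorted"]
    else:
        missing = [b for b in bin_ids if b not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing count columns for bins {missing}")
        count_cols = list(bin_ids)
    for col in [*count_cols, "unsorted"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: column {col!r} row {row + 2} (guide "
                f"{df['guide_id'].iloc[row]!r}) has invalid count "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = vals.astype(np.int64)

    group_keys = ["experiment_id"] if "experiment_id" in df.columns else []
    dup = df.duplicated(subset=[*group_keys, "guide_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"{path}: duplicate guide_id {df['guide_id'].iloc[row]!r} "
            f"at row {row + 2}"
        )
    return df


def read_bins(path) -> dict[str | None, list[SortingBin]]:
    """Read per-experiment bin definitions.

    Requires ``bin_id``, ``binStartQ`` and ``binEndQ`` columns; an
    ``experiment_id`` column splits definitions per experiment (absent: one
    shared set under key ``None``).  ``binStartZ``/``binEndZ`` are recomputed
    from the quantiles when absent and validated for consistency when
    present.
    """
    path = Path(path)
    df = _read_tsv(path)
    for col in ("bin_id", "binStartQ", "binEndQ"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    has_z = "binStartZ" in df.columns and "binEndZ" in df.columns

    def build(sub: pd.DataFrame) -> list[SortingBin]:
        bins = quantile_bins_to_z(
            list(zip(sub["bin_id"], sub["binStartQ"], sub["binEndQ"]))
        )
        if has_z:
            for b, z0, z1 in zip(bins, sub["binStartZ"], sub["binEndZ"]):
                for given, q in ((float(z0), b.start_q), (float(z1), b.end_q)):
                    if abs(norm.cdf(given) - q) > _QZ_TOL:
                        raise BinValidationError(
                            f"{path}: bin {b.bin_id!r} has inconsistent "
                            f"quantile/Z bounds (Phi({given:g}) != {q:g})"
                        )
        validate_bins(bins)
        return bins

    if "experiment_id" in df.columns:
        return {
            exp_id: build(sub) for exp_id, sub in df.groupby("experiment_id", sort=True)
        }
    return {None: build(df)}


def _header_lines(params: Mapping[str, object] | None) -> list[str]:
    lines = [f"# sortscreen {__version__}"]
    for key in sorted(params or {}):
        lines.append(f"# {key}={params[key]}")
    return lines


def write_table(
    df: pd.DataFrame,
    path,
    *,
    params: Mapping[str, object] | None = None,
    sort_by: Sequence[str] | None = None,
) -> None:
    """Write a TSV with a commented provenance header.

    Rows are sorted by ``sort_by`` (when given) for deterministic output;
    identical inputs and parameters produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.sort_values(list(sort_by), ignore_index=True) if sort_by else df
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def write_bins(
    bins: Mapping[str | None, Sequence[SortingBin]] | Sequence[SortingBin],
    path,
    *,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write bin definitions with both quantile and Z bounds."""
    if not isinstance(bins, Mapping):
        bins = {None: bins}
    rows = []
    for exp_id, bin_list in bins.items():
        for b in bin_list:
            row = {
                "bin_id": b.bin_id,
                "binStartQ": b.start_q,
                "binEndQ": b.end_q,
                "binStartZ": b.start_z,
                "binEndZ": b.end_z,
            }
            if exp_id is not None:
                row = {"experiment_id": exp_id, **row}
            rows.append(row)
    write_table(pd.DataFrame(rows), path, params=params)


def write_bed(elements: pd.DataFrame, path, *, score_scale: float = 1.0) -> None:
    """Export called elements as BED6 (0-based half-open).

    The score is ``|significance_z| * score_scale`` clamped to [0, 1000];
    strand is '.'.  Requires ``chrom``/``start``/``end`` columns with 1-based
    inclusive element coordinates.
    """
    for col in ("chrom", "start", "end", "significance_z"):
        if col not in elements.columns:
            raise ValueError(f"BED export needs column {col!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = elements.sort_values(["chrom", "start", "end"], ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for _, row in out.iterrows():
            score = int(min(1000, round(abs(row["significance_z"]) * score_scale)))
            name = row.get("element_id", f"{row['chrom']}:{row['start']}-{row['end']}")
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"{name}\t{score}\t.\n"
            )


def file_checksum(path) -> str:
    """MD5 of a file, recorded in run logs for provenance."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
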