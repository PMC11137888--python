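"""Readers and writers for Ct / FPKM / sample-sheet tables.

Default dialect: tab-separated wide tables, genes in rows, first column
holding the gene id.  A comma delimiter is autodetected by sniffing the
first line.  Group labels can come from an optional second header row
(first cell ``group``) or from a separate two-column sample sheet.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import CtMatrix, FpkmMatrix
from .errors import FormatError, InputValidationError

__all__ = [
    "read_ct_table",
    "read_fpkm_table",
    "read_sample_sheet",
    "write_ct_table",
    "write_report",
]


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file")
    return "," if ("," in first and "\t" not in first) else "\t"


def _read_wide(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path)
    # header parsed by hand: pandas silently renames duplicate column ids,
    # which must instead surface as a validation error
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    columns = [c.strip() for c in header[1:]]
    if not columns:
        raise FormatError(f"{path}: no sample columns found")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         header=None, skiprows=1)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] != len(columns):
        raise FormatError(
            f"{path}: header has {len(columns)} ids but rows have "
            f"{df.shape[1]} values"
        )
    df.columns = columns
    df.index = df.index.astype(str).str.strip()
    return df


def _to_float(df: pd.DataFrame, path: Path, what: str) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for gene in df.index:
            for sample in df.columns:
                cell = df.at[gene, sample]
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise InputValidationError(
                        f"{path}: non-numeric {what} value {cell!r} for "
                        f"gene {gene!r}, sample {sample!r}"
                    ) from None
        raise  # pragma: no cover - unreachable


def read_ct_table(
    path: str | os.PathLike,
    orientation: str = "genes_in_rows",
    sample_sheet: str | os.PathLike | None = None,
    average_replicates: bool = False,
) -> CtMatrix:
    """Read a wide Ct table into a validated :class:`CtMatrix`.

    Parameters
    ----------
    path : path
        Delimited text; first row sample ids, first column gene ids
        (``genes_in_rows``) or transposed (``genes_in_cols``).  An
        optional second header row whose first cell is ``group``
        attaches inline group labels.
    sample_sheet : path, optional
        Two-column table (sample_id, group); overrides inline labels.
    average_replicates : bool
        Technical replicates appear as repeated sample columns; when
        True they are averaged to one Ct per (gene, sample), since every
        stability method consumes one value per sample.  When False a
        repeated sample id is an error.
    """
    if orientation not in ("genes_in_rows", "genes_in_cols"):
        raise InputValidationError(f"unknown orientation {orientation!r}")
    df = _read_wide(path)
    groups: dict[str, str] | None = None
    if orientation == "genes_in_rows" and len(df) and str(df.index[0]).lower() == "group":
        groups = dict(zip(df.columns, df.iloc[0].astype(str)))
        df = df.iloc[1:]
    elif orientation == "genes_in_cols" and str(df.columns[0]).lower() == "group":
        groups = dict(zip(df.index.astype(str), df.iloc[:, 0].astype(str)))
        df = df.iloc[:, 1:]
    if orientation == "genes_in_cols":
        df = df.T
    if df.columns.has_duplicates:
        if average_replicates:
            numeric = _to_float(df, Path(path), "Ct")
            df = numeric.T.groupby(level=0, sort=False).mean().T
        else:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise InputValidationError(
                f"{path}: duplicate sample id(s) {dupes}; pass "
                "average_replicates=True to average technical replicates"
            )
    else:
        df = _to_float(df, Path(path), "Ct")
    if sample_sheet is not None:
        groups = read_sample_sheet(sample_sheet)
    return CtMatrix(df, groups)


def read_fpkm_table(path: str | os.PathLike) -> FpkmMatrix:
    """Read a wide FPKM table (genes in rows) into an :class:`FpkmMatrix`."""
    df = _read_wide(path)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise InputValidationError(f"{path}: duplicate gene or sample ids")
    return FpkmMatrix(_to_float(df, Path(path), "FPKM"))


def read_sample_sheet(path: str | os.PathLike) -> dict[str, str]:
    """Read a sample sheet with columns ``sample_id`` and ``group``."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if "sample_id" in cols and "group" in cols:
        df.columns = cols
        pairs = df[["sample_id", "group"]]
    elif df.shape[1] >= 2:  # headerless two-column sheet
        df = pd.read_csv(path, sep=sep, dtype=str, header=None)
        pairs = df.iloc[:, :2].set_axis(["sample_id", "group"], axis=1)
    else:
        raise FormatError(f"{path}: expected columns sample_id, group")
    sample_ids = pairs["sample_id"].astype(str).str.strip()
    if sample_ids.duplicated().any():
        dupes = sample_ids[sample_ids.duplicated()].tolist()
        raise InputValidationError(f"{path}: duplicate sample id(s) {dupes}")
    return dict(zip(sample_ids, pairs["group"].astype(str).str.strip()))


def write_ct_table(ct: CtMatrix, path: str | os.PathLike, sep: str = "\t") -> None:
    """Write a CtMatrix (with inline group row when labeled).

    Values are written with enough digits (repr round-trip) that reading
    the file back reproduces them bit-identically.
    """
    path = Path(path)
    df = ct.data.map(repr)
    if ct.groups is not None:
        header = pd.DataFrame(
            [[ct.groups[s] for s in ct.sample_ids]], index=["group"],
            columns=ct.sample_ids,
        )
        df = pd.concat([header, df])
    df.to_csv(path, sep=sep, index_label="gene")


def write_report(
    tables: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
    outdir: str | os.PathLike,
    summary: Mapping | None = None,
) -> list[Path]:
    """Write one TSV per labeled table plus a JSON run summary.

    Column order is preserved as given (deterministic output).  Duplicate
    table labels are a naming error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = list(tables.items()) if isinstance(tables, Mapping) else list(tables)
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise InputValidationError(f"duplicate table label(s): {dupes}")
    written: list[Path] = []
    for label, df in items:
        target = outdir / f"{label}.tsv"
        df.to_csv(target, sep="\t", index=False)
        written.append(target)
    summary_doc = dict(summary or {})
    summary_doc["tables"] = [p.name for p in written]
    target = outdir / "summary.json"
    with open(target, "w", encoding="utf-8") as fh:
        json.dump(summary_doc, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(target)
    return written
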