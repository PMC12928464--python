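"""Readers and writers for the $-delimited spontaneous-report dialect.

The on-disk layout mirrors the public FAERS quarterly ASCII extracts:
one UTF-8 text file per entity, ``$``-separated fields, first line a
header.  The four tables are

* DEMO  — ``report_id$case_id$receipt_date$sex$age_group$country$reporter_type$year``
* DRUG  — ``report_id$drug_name$role``
* REAC  — ``report_id$pt_code$pt_name``
* OUTC  — ``report_id$outcome_code``

The reader is deliberately forgiving about *values* (an unparseable
date or year becomes missing, never a dropped row) and strict about
*structure* (a wrong header is a fatal format error naming the file).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    Dataset,
    DRUG_COLUMNS,
    OUTCOME_COLUMNS,
    REACTION_COLUMNS,
    REPORT_COLUMNS,
)

PathLike = Union[str, Path]

DEMO_HEADER = REPORT_COLUMNS
DRUG_HEADER = DRUG_COLUMNS
REAC_HEADER = REACTION_COLUMNS
OUTC_HEADER = ["report_id", "outcome_code"]

SIGNAL_TABLE_COLUMNS = [
    "ranking",
    "drug",
    "cases",
    "ROR",
    "ROR_lo",
    "ROR_hi",
    "PRR",
    "PRR_lo",
    "PRR_hi",
    "chi2",
    "EBGM",
    "EBGM05",
    "IC",
    "IC025",
    "flag_ROR",
    "flag_PRR",
    "flag_EBGM",
    "flag_BCPNN",
    "flag_all_four",
]


class FormatError(ValueError):
    """A report table does not match the declared dialect."""


def _read_table(path: PathLike, expected_header: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"report table not found: {path}")
    df = pd.read_csv(
        path, sep="$", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    if list(df.columns) != list(expected_header):
        raise FormatError(
            f"{path}: bad header {list(df.columns)!r}; "
            f"expected columns {list(expected_header)!r}"
        )
    return df


def read_report_tables(
    demo_path: PathLike,
    drug_path: PathLike,
    reac_path: PathLike,
    outc_path: PathLike,
) -> Dataset:
    """Read the four $-delimited tables into a (not-yet-deduplicated) Dataset.

    Rows are never dropped: a malformed ``receipt_date`` or ``year``
    becomes missing, and the report still counts toward every total.
    When the date parses, ``year`` is taken from the date (the two must
    agree by construction); otherwise the file's year field is used if
    it parses.
    """
    demo = _read_table(demo_path, DEMO_HEADER)
    drug = _read_table(drug_path, DRUG_HEADER)
    reac = _read_table(reac_path, REAC_HEADER)
    outc = _read_table(outc_path, OUTC_HEADER)

    reports = demo.copy()
    dates = pd.to_datetime(
        reports["receipt_date"], format="%Y-%m-%d", errors="coerce"
    )
    file_year = pd.to_numeric(reports["year"], errors="coerce").astype("Int64")
    reports["receipt_date"] = dates
    reports["year"] = file_year.where(dates.isna(), dates.dt.year.astype("Int64"))

    reactions = reac.copy()
    code = pd.to_numeric(reactions["pt_code"], errors="coerce")
    reactions["pt_code"] = [
        None if (isinstance(c, float) and math.isnan(c)) else int(c) for c in code
    ]

    outcomes = outc.rename(columns={"outcome_code": "outcome"})

    ds = Dataset(
        reports=reports,
        drugs=drug.copy(),
        reactions=reactions,
        outcomes=outcomes[OUTCOME_COLUMNS],
        provenance=str(Path(demo_path).parent),
        deduplicated=False,
    )
    ds.validate()
    return ds


def _fmt_date(value) -> str:
    if pd.isna(value):
        return ""
    return pd.Timestamp(value).strftime("%Y-%m-%d")


def write_report_tables(dataset: Dataset, directory: PathLike) -> dict[str, Path]:
    """Write a Dataset as the four-table dialect; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "demo": directory / "DEMO.txt",
        "drug": directory / "DRUG.txt",
        "reac": directory / "REAC.txt",
        "outc": directory / "OUTC.txt",
    }

    demo = dataset.reports.copy()
    demo["receipt_date"] = [_fmt_date(v) for v in demo["receipt_date"]]
    demo["year"] = ["" if pd.isna(v) else str(int(v)) for v in demo["year"]]
    demo[DEMO_HEADER].to_csv(paths["demo"], sep="$", index=False)

    dataset.drugs[DRUG_HEADER].to_csv(paths["drug"], sep="$", index=False)

    reac = dataset.reactions.copy()
    reac["pt_code"] = ["" if pd.isna(v) else str(int(v)) for v in reac["pt_code"]]
    reac[REAC_HEADER].to_csv(paths["reac"], sep="$", index=False)

    outc = dataset.outcomes.rename(columns={"outcome": "outcome_code"})
    outc[OUTC_HEADER].to_csv(paths["outc"], sep="$", index=False)
    return paths


def write_signal_table(results: Iterable, path: PathLike) -> pd.DataFrame:
    """Write SignalResults as a CSV ranked by descending case count.

    Statistics are rounded to 2 decimals in the file (full precision is
    kept on the in-memory objects); undefined values are written as the
    sentinel ``NA``.  Returns the frame that was written.
    """
    results = list(results)
    if not results:
        raise ValueError("write_signal_table: no results to write")
    rows = []
    for r in results:
        rows.append(
            {
                "drug": r.drug,
                "cases": r.a,
                "ROR": r.ror,
                "ROR_lo": r.ror_lo,
                "ROR_hi": r.ror_hi,
                "PRR": r.prr,
                "PRR_lo": r.prr_lo,
                "PRR_hi": r.prr_hi,
                "chi2": r.chi2,
                "EBGM": r.ebgm,
                "EBGM05": r.ebgm05,
                "IC": r.ic,
                "IC025": r.ic025,
                "flag_ROR": r.flag_ror,
                "flag_PRR": r.flag_prr,
                "flag_EBGM": r.flag_ebgm,
                "flag_BCPNN": r.flag_bcpnn,
                "flag_all_four": r.flag_all_four,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["cases", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "ranking", np.arange(1, len(df) + 1))
    out = df.copy()
    stat_cols = [
        "ROR", "ROR_lo", "ROR_hi", "PRR", "PRR_lo", "PRR_hi",
        "chi2", "EBGM", "EBGM05", "IC", "IC025",
    ]
    for c in stat_cols:
        out[c] = [
            "NA" if (v is None or (isinstance(v, float) and math.isnan(v)))
            else f"{v:.2f}"
            for v in out[c]
        ]
    out.to_csv(path, index=False)
    return df


def load_pt_set(path: PathLike) -> set[tuple[int, str]]:
    """Load a PT set from a two-column ``code,name`` CSV (header optional)."""
    pairs: set[tuple[int, str]] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code_s, _, name = line.partition(",")
        code_s, name = code_s.strip(), name.strip()
        if not name:
            raise FormatError(f"{path}: expected 'code,name' lines, got {line!r}")
        try:
            code = int(code_s)
        except ValueError:
            if code_s.lower() in {"code", "pt_code"}:
                continue  # header line
            raise FormatError(f"{path}: non-numeric PT code {code_s!r}")
        pairs.add((code, name))
    if not pairs:
        raise FormatError(f"{path}: no PT entries found")
    return pairs
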