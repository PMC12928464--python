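"""Case deduplication, UGIB event labelling, and descriptive summaries.

Two distinct denominators run through spontaneous-report descriptive
tables and both are kept explicit here:

* *event records* — PT-level reaction rows matching the event set (one
  report can contribute several); used for PT frequency shares.
* *patients* — distinct deduplicated reports carrying at least one
  matching PT; used for demographic shares.  Outcome shares also use
  the patient denominator restricted to reports with at least one known
  outcome code, and one report contributes to every outcome it lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .model import (
    AGE_GROUP_VALUES,
    Dataset,
    REPORTER_TYPE_VALUES,
    SEX_VALUES,
)
from .terms import PTPair, pt_codes, pt_names_lower


@dataclass(frozen=True)
class FrequencyRow:
    """One line of a frequency table: category, count, percent of denominator."""

    label: str
    count: int
    percent: float


@dataclass(frozen=True)
class StudyCounts:
    """Event-level and patient-level UGIB totals (n_patients <= n_event_records)."""

    n_event_records: int
    n_patients: int


def deduplicate(dataset: Dataset) -> Dataset:
    """Keep one report per case: latest receipt_date, ties to largest report_id.

    Drug, reaction and outcome rows belonging to dropped report versions
    are removed with them.  Missing dates sort earliest, so any dated
    version beats an undated one.  Idempotent and order-invariant.
    """
    reports = dataset.reports
    ordered = reports.sort_values(
        ["receipt_date", "report_id"],
        ascending=[True, True],
        na_position="first",
        kind="mergesort",
    )
    survivors = ordered.groupby("case_id", sort=False).tail(1)
    survivors = survivors.sort_values("report_id", kind="mergesort").reset_index(
        drop=True
    )
    keep = set(survivors["report_id"])

    def _filter(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["report_id"].isin(keep)].reset_index(drop=True)

    out = Dataset(
        reports=survivors,
        drugs=_filter(dataset.drugs),
        reactions=_filter(dataset.reactions),
        outcomes=_filter(dataset.outcomes),
        provenance=dataset.provenance,
        deduplicated=True,
    )
    out.validate()
    return out


def match_pt_rows(reactions: pd.DataFrame, pt_set: Iterable[PTPair]) -> pd.Series:
    """Boolean mask of reaction rows in the PT set.

    Matching is by numeric code when the row carries one, else by
    case-insensitive exact name (coded term lists and verbatim files
    both occur in practice).
    """
    pt_set = set(pt_set)
    if not pt_set:
        raise ValueError("empty PT set")
    codes = pt_codes(pt_set)
    names = pt_names_lower(pt_set)
    has_code = reactions["pt_code"].notna()
    by_code = has_code & reactions["pt_code"].isin(codes)
    by_name = ~has_code & reactions["pt_name"].str.lower().isin(names)
    return by_code | by_name


def label_ugib(
    dataset: Dataset, pt_set: Iterable[PTPair]
) -> tuple[pd.DataFrame, set[str]]:
    """Return (matching reaction rows, distinct report ids carrying >=1 match)."""
    if not dataset.deduplicated:
        raise ValueError("label_ugib requires a deduplicated dataset")
    mask = match_pt_rows(dataset.reactions, pt_set)
    rows = dataset.reactions[mask].reset_index(drop=True)
    return rows, set(rows["report_id"])


def study_counts(event_rows: pd.DataFrame, report_ids: set[str]) -> StudyCounts:
    return StudyCounts(n_event_records=len(event_rows), n_patients=len(report_ids))


def _freq_frame(counts: pd.Series, denominator: int) -> pd.DataFrame:
    """counts (index=label) -> DataFrame(label, count, percent), count-descending."""
    df = pd.DataFrame(
        {
            "label": counts.index.astype(str),
            "count": counts.to_numpy(),
        }
    )
    df["percent"] = [round(100.0 * c / denominator, 2) for c in df["count"]]
    return df.reset_index(drop=True)


def pt_frequency_table(event_rows: pd.DataFrame) -> pd.DataFrame:
    """Per-PT share of all matching event records, sorted by descending count.

    The denominator is the event-record total, so a report with two
    distinct UGIB PTs contributes twice.
    """
    if len(event_rows) == 0:
        raise ValueError("pt_frequency_table: no event rows")
    counts = (
        event_rows.groupby("pt_name", sort=False)["report_id"]
        .count()
        .sort_values(ascending=False, kind="mergesort")
    )
    # stable count-then-name ordering
    counts = counts.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )
    return _freq_frame(counts, int(counts.sum()))


def demographic_summary(
    dataset: Dataset, ugib_report_ids: set[str], top_countries: int = 10
) -> dict[str, pd.DataFrame]:
    """Descriptive panels over the UGIB patient population.

    Panels: ``country`` (top N), ``sex``, ``age_group``, ``reporter_type``,
    ``year`` (full series), ``outcomes``.  Percent denominators are the
    UGIB patient count, except ``outcomes`` whose denominator is the
    number of UGIB reports with at least one known outcome code (a
    report with several outcomes contributes to each row).
    """
    if not dataset.deduplicated:
        raise ValueError("demographic_summary requires a deduplicated dataset")
    if not ugib_report_ids:
        raise ValueError("demographic_summary: empty UGIB report set")
    sub = dataset.reports[dataset.reports["report_id"].isin(ugib_report_ids)]
    n = len(sub)
    panels: dict[str, pd.DataFrame] = {}

    def categorical(col: str, order: tuple[str, ...]) -> pd.DataFrame:
        counts = sub[col].value_counts()
        counts = counts.reindex(
            [v for v in order if v in counts.index]
            + [v for v in counts.index if v not in order]
        ).dropna().astype(int)
        return _freq_frame(
            counts.sort_values(ascending=False, kind="mergesort"), n
        )

    country_counts = sub["country"].value_counts().head(top_countries)
    panels["country"] = _freq_frame(country_counts, n)
    panels["sex"] = categorical("sex", SEX_VALUES)
    panels["age_group"] = categorical("age_group", AGE_GROUP_VALUES)
    panels["reporter_type"] = categorical("reporter_type", REPORTER_TYPE_VALUES)

    years = sub["year"].dropna().astype(int).value_counts().sort_index()
    year_df = _freq_frame(years, n)
    panels["year"] = year_df

    outc = dataset.outcomes[
        dataset.outcomes["report_id"].isin(ugib_report_ids)
        & (dataset.outcomes["outcome"] != "unknown")
    ]
    denom = outc["report_id"].nunique()
    if denom:
        oc = outc.groupby("outcome", sort=False)["report_id"].nunique()
        oc = oc.sort_index(kind="mergesort").sort_values(
            ascending=False, kind="mergesort"
        )
        panels["outcomes"] = _freq_frame(oc, denom)
    else:
        panels["outcomes"] = pd.DataFrame(columns=["label", "count", "percent"])
    return panels
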