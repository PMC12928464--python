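"""Core domain types for spontaneous adverse-event report datasets.

A spontaneous-reporting database (FAERS, JADER, VigiBase, ...) is a
collection of *reports*, each describing one suspected adverse-event
episode for one patient.  A single episode (a *case*) may be reported
several times as follow-up versions; versions share a ``case_id`` but
carry distinct ``report_id`` values.  Each report lists one or more
drugs (verbatim names, brand and generic kept distinct) and one or more
adverse events coded as MedDRA Preferred Terms (PTs), plus coarse
demographics and outcome codes.

The in-memory container is a :class:`Dataset`: four pandas DataFrames
(reports / drug mentions / reactions / outcomes) tied together by
``report_id``.  Row-level dataclasses (:class:`Report`,
:class:`DrugMention`, :class:`Reaction`) are provided for constructing
small fixtures by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Optional

import pandas as pd

SEX_VALUES = ("male", "female", "unknown")
AGE_GROUP_VALUES = ("under_18", "18_to_65", "over_65", "unknown")
REPORTER_TYPE_VALUES = (
    "consumer",
    "physician",
    "pharmacist",
    "other_health_professional",
    "lawyer",
    "unknown",
)
OUTCOME_VALUES = (
    "death",
    "life_threatening",
    "hospitalization",
    "disability",
    "congenital_anomaly",
    "other",
    "unknown",
)
DRUG_ROLE_VALUES = ("suspect", "concomitant", "interacting", "unknown")

REPORT_COLUMNS = [
    "report_id",
    "case_id",
    "receipt_date",
    "sex",
    "age_group",
    "country",
    "reporter_type",
    "year",
]
DRUG_COLUMNS = ["report_id", "drug_name", "role"]
REACTION_COLUMNS = ["report_id", "pt_code", "pt_name"]
OUTCOME_COLUMNS = ["report_id", "outcome"]


class DatasetError(ValueError):
    """Raised when a Dataset violates its structural invariants."""


@dataclass(frozen=True)
class Report:
    """One spontaneous adverse-event report (one version of one case)."""

    report_id: str
    case_id: str
    receipt_date: Optional[date] = None
    sex: str = "unknown"
    age_group: str = "unknown"
    country: str = "unknown"
    reporter_type: str = "unknown"
    outcomes: frozenset = frozenset()
    year: Optional[int] = None


@dataclass(frozen=True)
class DrugMention:
    """A drug listed on one report, name kept verbatim as reported."""

    report_id: str
    drug_name: str
    role: str = "unknown"


@dataclass(frozen=True)
class Reaction:
    """One MedDRA Preferred Term coded on a report.

    ``pt_code`` is the 8-digit numeric MedDRA code when available
    (``None`` otherwise); ``pt_name`` is always present.
    """

    report_id: str
    pt_name: str
    pt_code: Optional[int] = None


def _empty(columns: list[str]) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
    if "receipt_date" in columns:
        df["receipt_date"] = pd.Series(dtype="datetime64[ns]")
    if "year" in columns:
        df["year"] = pd.Series(dtype="Int64")
    return df


@dataclass
class Dataset:
    """A spontaneous-report dataset: reports, drug mentions, reactions, outcomes.

    ``deduplicated`` records whether keep-latest case deduplication has
    been applied; several downstream operations require it.
    """

    reports: pd.DataFrame = field(default_factory=lambda: _empty(REPORT_COLUMNS))
    drugs: pd.DataFrame = field(default_factory=lambda: _empty(DRUG_COLUMNS))
    reactions: pd.DataFrame = field(default_factory=lambda: _empty(REACTION_COLUMNS))
    outcomes: pd.DataFrame = field(default_factory=lambda: _empty(OUTCOME_COLUMNS))
    provenance: str = ""
    deduplicated: bool = False

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def copy(self) -> "Dataset":
        return Dataset(
            reports=self.reports.copy(),
            drugs=self.drugs.copy(),
            reactions=self.reactions.copy(),
            outcomes=self.outcomes.copy(),
            provenance=self.provenance,
            deduplicated=self.deduplicated,
        )

    def validate(self) -> None:
        """Check referential integrity and id uniqueness; raise DatasetError."""
        ids = self.reports["report_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DatasetError(f"duplicate report_id {dup!r}")
        id_set = set(ids)
        for name, frame in (
            ("drugs", self.drugs),
            ("reactions", self.reactions),
            ("outcomes", self.outcomes),
        ):
            missing = set(frame["report_id"]) - id_set
            if missing:
                raise DatasetError(
                    f"{name} references unknown report_id(s): {sorted(missing)[:5]}"
                )
        if self.deduplicated and self.reports["case_id"].duplicated().any():
            raise DatasetError("deduplicated dataset has repeated case_id values")

    def equals(self, other: "Dataset") -> bool:
        """Record-for-record equality, ignoring row order within each table."""

        def norm(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            out = df.copy()
            out = out.sort_values(keys, kind="mergesort").reset_index(drop=True)
            return out.astype(object).where(out.notna(), None)

        pairs = [
            (self.reports, other.reports, ["report_id"]),
            (self.drugs, other.drugs, DRUG_COLUMNS),
            (self.reactions, other.reactions, ["report_id", "pt_name"]),
            (self.outcomes, other.outcomes, OUTCOME_COLUMNS),
        ]
        for a, b, keys in pairs:
            if len(a) != len(b):
                return False
            if not norm(a, keys).equals(norm(b, keys)):
                return False
        return True


def dataset_from_records(
    reports: Iterable[Report],
    drugs: Iterable[DrugMention] = (),
    reactions: Iterable[Reaction] = (),
    provenance: str = "records",
    deduplicated: bool = False,
) -> Dataset:
    """Build a Dataset from row dataclasses (convenient for small fixtures)."""
    reports = list(reports)
    rep = pd.DataFrame(
        {
            "report_id": [r.report_id for r in reports],
            "case_id": [r.case_id for r in reports],
            "receipt_date": pd.to_datetime(
                [r.receipt_date for r in reports], errors="coerce"
            ),
            "sex": [r.sex for r in reports],
            "age_group": [r.age_group for r in reports],
            "country": [r.country for r in reports],
            "reporter_type": [r.reporter_type for r in reports],
            "year": pd.array(
                [
                    r.year
                    if r.year is not None
                    else (r.receipt_date.year if r.receipt_date else None)
                    for r in reports
                ],
                dtype="Int64",
            ),
        }
    )
    drugs = list(drugs)
    drg = pd.DataFrame(
        {
            "report_id": [d.report_id for d in drugs],
            "drug_name": [d.drug_name for d in drugs],
            "role": [d.role for d in drugs],
        },
        columns=DRUG_COLUMNS,
    )
    reactions = list(reactions)
    rea = pd.DataFrame(
        {
            "report_id": [x.report_id for x in reactions],
            "pt_code": [x.pt_code for x in reactions],
            "pt_name": [x.pt_name for x in reactions],
        },
        columns=REACTION_COLUMNS,
    )
    out_rows = [
        (r.report_id, o) for r in reports for o in sorted(r.outcomes)
    ]
    outc = pd.DataFrame(out_rows, columns=OUTCOME_COLUMNS)
    ds = Dataset(
        reports=rep,
        drugs=drg,
        reactions=rea,
        outcomes=outc,
        provenance=provenance,
        deduplicated=deduplicated,
    )
    ds.validate()
    return ds
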