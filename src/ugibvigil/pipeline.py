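"""End-to-end study orchestration: dedup -> label -> summaries -> signals.

:func:`run_study` replays the whole analysis on any dataset: keep-latest
case deduplication (optional, for sources that ship pre-deduplicated or
deliberately undeduplicated data), UGIB PT labelling, descriptive
summaries, top-K drug selection by UGIB report frequency, per-drug 2x2
tables, MGPS prior fitting across all drug-event pairs, all four
disproportionality statistics with threshold flags, method-consensus
Venn counts, and the death/non-death outcome split per drug.  Given the
same inputs and configuration the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as io_mod
from .case_processing import (
    StudyCounts,
    deduplicate,
    demographic_summary,
    label_ugib,
    pt_frequency_table,
    study_counts,
)
from .disproportionality import (
    MGPSPrior,
    SignalResult,
    SignalThresholds,
    build_contingency,
    compute_signal,
    consensus_venn,
    evaluate_signal,
    mgps_fit,
)
from .model import Dataset
from .terms import builtin_ugib_pt_set

logger = logging.getLogger(__name__)


class StudyError(RuntimeError):
    """The study cannot proceed (e.g. no UGIB events after filtering)."""


@dataclass
class PipelineConfig:
    """Study configuration.

    ``pt_source`` is ``"builtin"`` for the 17 UGIB terms or a path to a
    ``code,name`` CSV.  ``dedup_enabled`` should be False for sources
    whose cases are not versioned (JADER-style input).  ``ic_mode`` is
    ``standard`` or ``paper_compat`` (see disproportionality docs).
    """

    pt_source: str = "builtin"
    counting_mode: str = "patient"
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    ic_mode: str = "standard"
    top_k: int = 50
    dedup_enabled: bool = True
    output_dir: Optional[str] = None
    min_pairs_for_mgps: int = 50

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    def pt_set(self):
        if self.pt_source == "builtin":
            return builtin_ugib_pt_set()
        return io_mod.load_pt_set(self.pt_source)


@dataclass
class StudyReport:
    """Everything the study produces, in memory."""

    study_counts: StudyCounts
    pt_frequency: pd.DataFrame
    panels: dict
    signal_results: list
    signal_table: pd.DataFrame
    venn: dict
    outcome_table: pd.DataFrame
    prior: MGPSPrior
    config: PipelineConfig


def _drug_event_pairs(dataset: Dataset, ugib_ids: set[str]) -> pd.DataFrame:
    """Per-drug patient-mode 2x2 margins for every drug in the dataset."""
    drugs = dataset.drugs
    n_total = dataset.n_reports
    n_event = len(ugib_ids)
    per_drug = drugs.groupby("drug_name")["report_id"].agg(set)
    rows = []
    for name, ids in per_drug.items():
        a = len(ids & ugib_ids)
        n_drug = len(ids)
        rows.append((name, a, n_drug))
    df = pd.DataFrame(rows, columns=["drug", "a", "n_drug"])
    df["E"] = df["n_drug"] * n_event / n_total
    return df.sort_values("drug", kind="mergesort").reset_index(drop=True)


def outcome_death_analysis(
    dataset: Dataset, ugib_report_ids: set[str], drugs: list[str]
) -> pd.DataFrame:
    """Death vs non-death outcome split per drug among its UGIB reports.

    The denominator is the drug's UGIB reports carrying at least one
    known outcome code; a drug with none gets NA proportions.
    """
    outc = dataset.outcomes[
        dataset.outcomes["report_id"].isin(ugib_report_ids)
        & (dataset.outcomes["outcome"] != "unknown")
    ]
    death_ids = set(outc.loc[outc["outcome"] == "death", "report_id"])
    known_ids = set(outc["report_id"])
    mentions = dataset.drugs[dataset.drugs["drug_name"].isin(drugs)]
    per_drug = mentions.groupby("drug_name")["report_id"].agg(set)
    rows = []
    for drug in drugs:
        ids = per_drug.get(drug, set()) & ugib_report_ids
        with_outcome = ids & known_ids
        n = len(with_outcome)
        deaths = len(ids & death_ids)
        if n:
            death_pct = round(100.0 * deaths / n, 2)
            rows.append((drug, len(ids), n, deaths, death_pct, round(100 - death_pct, 2)))
        else:
            rows.append((drug, len(ids), 0, 0, float("nan"), float("nan")))
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "ugib_reports",
            "with_known_outcome",
            "deaths",
            "death_pct",
            "non_death_pct",
        ],
    )


def run_study(dataset: Dataset, config: PipelineConfig = None) -> StudyReport:
    """Execute the full study on ``dataset`` and (optionally) write outputs."""
    if config is None:
        config = PipelineConfig()
    pt_set = config.pt_set()

    if config.dedup_enabled and not dataset.deduplicated:
        dataset = deduplicate(dataset)
    elif not dataset.deduplicated:
        # pass-through mode: treat reports as already one-per-case
        dataset = dataclasses.replace(dataset.copy(), deduplicated=True)
        dataset.validate()

    event_rows, ugib_ids = label_ugib(dataset, pt_set)
    if len(event_rows) == 0:
        raise StudyError("no reports match the event PT set; nothing to analyse")

    counts = study_counts(event_rows, ugib_ids)
    pt_freq = pt_frequency_table(event_rows)
    panels = demographic_summary(dataset, ugib_ids)

    pairs = _drug_event_pairs(dataset, ugib_ids)
    prior = mgps_fit(
        pairs["a"].to_numpy(),
        pairs["E"].to_numpy(),
        min_pairs=config.min_pairs_for_mgps,
    )

    ranked = pairs.sort_values(
        ["a", "drug"], ascending=[False, True], kind="mergesort"
    )
    with_cases = ranked[ranked["a"] >= 1]
    if len(with_cases) < config.top_k:
        logger.warning(
            "only %d drugs carry UGIB reports (top_k=%d); proceeding with those",
            len(with_cases),
            config.top_k,
        )
    top = with_cases.head(config.top_k)

    results: list[SignalResult] = []
    for drug in top["drug"]:
        table = build_contingency(
            dataset, drug, ugib_ids, counting_mode=config.counting_mode, pt_set=pt_set
        )
        res = compute_signal(drug, table, prior, ic_mode=config.ic_mode)
        results.append(evaluate_signal(res, config.thresholds))

    venn = consensus_venn(results)
    outcome_table = outcome_death_analysis(dataset, ugib_ids, list(top["drug"]))

    # ranked frame (also what write_signal_table would emit)
    signal_table = _signal_frame(results)

    report = StudyReport(
        study_counts=counts,
        pt_frequency=pt_freq,
        panels=panels,
        signal_results=results,
        signal_table=signal_table,
        venn=venn,
        outcome_table=outcome_table,
        prior=prior,
        config=config,
    )
    if config.output_dir is not None:
        write_study_outputs(report, config.output_dir)
    return report


def _signal_frame(results: list[SignalResult]) -> pd.DataFrame:
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
    df = pd.DataFrame(rows).sort_values(
        ["cases", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "ranking", np.arange(1, len(df) + 1))
    return df


def write_study_outputs(report: StudyReport, directory) -> dict[str, Path]:
    """Write all study artifacts as CSV/JSON files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["signal_table"] = directory / "signal_table.csv"
    io_mod.write_signal_table(report.signal_results, paths["signal_table"])

    paths["pt_frequency"] = directory / "pt_frequency.csv"
    report.pt_frequency.to_csv(paths["pt_frequency"], index=False)

    for panel, frame in report.panels.items():
        p = directory / f"demographics_{panel}.csv"
        frame.to_csv(p, index=False)
        paths[f"demographics_{panel}"] = p

    paths["venn"] = directory / "venn.json"
    paths["venn"].write_text(json.dumps(report.venn, indent=2, sort_keys=True))

    paths["outcomes"] = directory / "outcomes.csv"
    report.outcome_table.to_csv(paths["outcomes"], index=False)

    summary = {
        "n_event_records": report.study_counts.n_event_records,
        "n_patients": report.study_counts.n_patients,
        "top_k": report.config.top_k,
        "counting_mode": report.config.counting_mode,
        "ic_mode": report.config.ic_mode,
        "dedup_enabled": report.config.dedup_enabled,
        "mgps_prior": {
            "alpha1": report.prior.alpha1,
            "beta1": report.prior.beta1,
            "alpha2": report.prior.alpha2,
            "beta2": report.prior.beta2,
            "w": report.prior.w,
            "source": report.prior.source,
        },
        "thresholds": dataclasses.asdict(report.config.thresholds),
        "venn": report.venn,
    }
    paths["study_summary"] = directory / "study_summary.json"
    paths["study_summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    return paths
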