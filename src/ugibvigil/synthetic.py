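"""Synthetic spontaneous-report generator with known ground truth.

The generator emulates the structure a disproportionality analysis
relies on: many reports, each carrying a case identifier (a
configurable fraction re-emitted as an earlier-dated duplicate version
of the same case), coarse demographics and outcome codes, one or more
verbatim drug names, and one or more MedDRA Preferred Terms, with
designated drug-PT pairs reported at an elevated relative reporting
rate (rr) against a multinomial background.

Sampling scheme (per report, all driven by one seeded generator):

1. draw demographics independently from configured categoricals;
2. draw a zero-truncated Poisson number of drug picks, each an i.i.d.
   weighted draw from the drug vocabulary, and keep the distinct set;
3. draw a zero-truncated Poisson number of PT picks from the PT
   vocabulary whose baseline weights are tilted multiplicatively by rr
   for every (drug-on-report, PT) injected pair and renormalized, and
   keep the distinct set.

Collapsing i.i.d. picks to a distinct set keeps every 2x2 cell
probability in closed form (inclusion-exclusion over avoided items),
which makes parameter recovery an exact rather than approximate
acceptance surface: :func:`expected_ror` returns the ROR the generator
targets for any drug against any PT set.

Injected duplicates are strictly earlier-dated versions of sampled
cases, so keep-latest deduplication recovers the original reports
exactly — an end-to-end correctness oracle for the dedup stage.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Dataset, OUTCOME_VALUES
from .terms import builtin_ugib_pt_set

__all__ = [
    "GeneratorConfig",
    "GeneratorError",
    "GroundTruth",
    "default_config",
    "generate",
    "expected_cells",
    "expected_ror",
    "expected_pair_lift",
    "expected_mention_probability",
    "DEFAULT_SIGNAL_DRUGS",
]


class GeneratorError(ValueError):
    """Invalid generator configuration."""


# Drugs used by the default injected-signal experiments; the names are
# the high-frequency suspects a UGIB study revolves around.
DEFAULT_SIGNAL_DRUGS = ("Rivaroxaban", "Aspirin", "Warfarin", "Pradaxa", "Clopidogrel")

_NAMED_DRUGS = (
    "Rivaroxaban",
    "Aspirin",
    "Ibuprofen",
    "Pradaxa",
    "Warfarin",
    "Clopidogrel",
    "Loxoprofen",
    "Apixaban",
    "Bevacizumab",
)

_BACKGROUND_DRUGS = (
    "Metformin", "Lisinopril", "Amlodipine", "Simvastatin", "Omeprazole",
    "Levothyroxine", "Metoprolol", "Losartan", "Gabapentin",
    "Hydrochlorothiazide", "Sertraline", "Furosemide", "Pantoprazole",
    "Prednisone", "Tramadol", "Citalopram", "Fluoxetine", "Montelukast",
    "Rosuvastatin", "Escitalopram", "Alprazolam", "Bupropion", "Cetirizine",
    "Duloxetine", "Venlafaxine", "Zolpidem", "Ranitidine", "Tamsulosin",
    "Atenolol", "Allopurinol", "Carvedilol", "Clonazepam", "Doxycycline",
    "Amoxicillin", "Azithromycin", "Ciprofloxacin", "Cephalexin",
    "Insulin glargine", "Sitagliptin", "Glimepiride", "Pioglitazone",
    "Empagliflozin", "Salbutamol", "Fluticasone", "Budesonide",
    "Paracetamol", "Esomeprazole", "Ondansetron", "Warfarin sodium",
    "Dabigatran", "Ticagrelor",
)

# Relative within-set reporting frequencies of the 17 UGIB PTs, shaped
# like the strongly skewed distribution real reporting shows
# (haematemesis dominant, obstructive/stress ulcer bleeds rare).
_UGIB_REL = {
    10018830: 22731,  # Haematemesis
    10046274: 15224,  # Upper gastrointestinal haemorrhage
    10017788: 10664,  # Gastric haemorrhage
    10017826: 5172,   # Gastric ulcer haemorrhage
    10013839: 2622,   # Duodenal ulcer haemorrhage
    10017866: 1360,   # Gastritis haemorrhagic
    10030172: 1186,   # Oesophageal haemorrhage
    10026712: 1157,   # Mallory-Weiss syndrome
    10034344: 624,    # Peptic ulcer haemorrhage
    10030202: 437,    # Oesophageal ulcer haemorrhage
    10067786: 309,    # Haemorrhagic erosive gastritis
    10030219: 271,    # Oesophagitis haemorrhagic
    10013865: 135,    # Duodenitis haemorrhagic
    10053768: 107,    # Gastroduodenal haemorrhage
    10067855: 28,     # Gastric occult blood positive
    10017829: 10,     # Gastric ulcer haemorrhage, obstructive
    10085612: 4,      # Stress ulcer haemorrhage
}

_BACKGROUND_PTS = (
    "Nausea", "Fatigue", "Headache", "Diarrhoea", "Dizziness", "Vomiting",
    "Dyspnoea", "Rash", "Pruritus", "Arthralgia", "Pyrexia", "Anaemia",
    "Insomnia", "Constipation", "Cough", "Oedema peripheral", "Myalgia",
    "Abdominal pain", "Decreased appetite", "Malaise", "Fall",
    "Hypertension", "Drug ineffective",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic spontaneous-reporting world.

    ``drug_vocabulary`` is ``(name, probability)`` pairs and
    ``pt_vocabulary`` ``(code, name, probability)`` triples; each set of
    probabilities must sum to 1.  ``injected_associations`` lists
    ``(drug, pt_name, rr)`` ground-truth signals: rr multiplies the
    baseline joint drug-PT reporting probability (rr = 1 is the null).
    ``drug_count_rate`` / ``pt_count_rate`` are the rates of the
    zero-truncated Poisson pick counts per report.  ``duplicate_rate``
    is the fraction of reports re-emitted as an earlier-dated version
    of the same case.  Outcome codes are drawn only for the
    ``outcome_known_rate`` fraction of reports; conditional on that,
    each outcome is included independently with its configured
    probability (``other`` is forced when nothing else is drawn, so a
    known-outcome report never ends up empty).
    """

    n_reports: int = 10_000
    drug_vocabulary: tuple = ()
    pt_vocabulary: tuple = ()
    injected_associations: tuple = ()
    drug_count_rate: float = 2.0
    pt_count_rate: float = 1.5
    duplicate_rate: float = 0.10
    sex_probs: tuple = (("male", 0.502), ("female", 0.458), ("unknown", 0.040))
    age_probs: tuple = (
        ("over_65", 0.46),
        ("18_to_65", 0.306),
        ("under_18", 0.05),
        ("unknown", 0.184),
    )
    country_probs: tuple = (
        ("US", 0.47), ("JP", 0.06), ("GB", 0.05), ("CA", 0.04), ("FR", 0.035),
        ("DE", 0.035), ("IT", 0.025), ("ES", 0.02), ("AU", 0.02), ("BR", 0.015),
        ("unknown", 0.23),
    )
    reporter_probs: tuple = (
        ("consumer", 0.332),
        ("physician", 0.261),
        ("pharmacist", 0.10),
        ("other_health_professional", 0.20),
        ("lawyer", 0.007),
        ("unknown", 0.10),
    )
    outcome_known_rate: float = 0.85
    outcome_probs: tuple = (
        ("hospitalization", 0.53),
        ("death", 0.08),
        ("life_threatening", 0.07),
        ("disability", 0.02),
        ("congenital_anomaly", 0.005),
        ("other", 0.25),
    )
    year_range: tuple = (2004, 2024)
    seed: int = 0

    def validate(self) -> None:
        def check_probs(pairs, label, extract=lambda p: p[-1]):
            probs = [extract(p) for p in pairs]
            if any(p < 0 for p in probs):
                raise GeneratorError(f"negative probability in {label}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise GeneratorError(
                    f"{label} probabilities sum to {sum(probs)}, expected 1"
                )

        if self.n_reports < 1:
            raise GeneratorError("n_reports must be positive")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise GeneratorError("duplicate_rate must lie in [0, 1)")
        if not self.drug_vocabulary or not self.pt_vocabulary:
            raise GeneratorError("empty drug or PT vocabulary")
        check_probs(self.drug_vocabulary, "drug_vocabulary")
        check_probs(self.pt_vocabulary, "pt_vocabulary")
        for pairs, label in (
            (self.sex_probs, "sex_probs"),
            (self.age_probs, "age_probs"),
            (self.country_probs, "country_probs"),
            (self.reporter_probs, "reporter_probs"),
        ):
            check_probs(pairs, label)
        if min(self.drug_count_rate, self.pt_count_rate) <= 0:
            raise GeneratorError("count rates must be positive")
        if not (0.0 <= self.outcome_known_rate <= 1.0):
            raise GeneratorError("outcome_known_rate must lie in [0, 1]")
        names = {n for n, _ in self.drug_vocabulary}
        pt_names = {n for _, n, _ in self.pt_vocabulary}
        for drug, pt, rr in self.injected_associations:
            if rr < 0:
                raise GeneratorError(f"negative rr for ({drug}, {pt})")
            if drug not in names:
                raise GeneratorError(f"injected drug {drug!r} not in vocabulary")
            if pt not in pt_names:
                raise GeneratorError(f"injected PT {pt!r} not in vocabulary")
        for name, _ in self.outcome_probs:
            if name not in OUTCOME_VALUES:
                raise GeneratorError(f"unknown outcome {name!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Injected relative reporting rates and the RORs the generator targets."""

    rr: dict = field(default_factory=dict)  # (drug, pt_name) -> rr
    expected_ror: dict = field(default_factory=dict)  # drug -> ROR vs UGIB set

    def rr_of(self, drug: str, pt_name: str) -> float:
        return self.rr.get((drug, pt_name), 1.0)


def default_config(**overrides) -> GeneratorConfig:
    """The default synthetic world: 60 drugs, 40 PTs (17 UGIB + 23 background).

    The UGIB terms jointly take 5% of PT reporting weight, split across
    the 17 terms with the strongly skewed relative frequencies real UGIB
    reporting shows; the named high-frequency suspect drugs carry 1.2%
    marginal weight each.  Keyword overrides replace any config field.
    """
    named_w = 0.012
    n_named = len(_NAMED_DRUGS)
    raw_bg = np.array([1.0 / (i + 3) for i in range(len(_BACKGROUND_DRUGS))])
    bg_w = raw_bg / raw_bg.sum() * (1.0 - named_w * n_named)
    drug_vocab = tuple(
        [(name, named_w) for name in _NAMED_DRUGS]
        + [(name, float(w)) for name, w in zip(_BACKGROUND_DRUGS, bg_w)]
    )

    ugib_total = 0.05
    code_to_name = {code: name for code, name in builtin_ugib_pt_set()}
    rel_sum = sum(_UGIB_REL.values())
    ugib_vocab = [
        (code, code_to_name[code], ugib_total * rel / rel_sum)
        for code, rel in sorted(_UGIB_REL.items(), key=lambda kv: -kv[1])
    ]
    raw_pt = np.array([1.0 / (i + 2) for i in range(len(_BACKGROUND_PTS))])
    pt_w = raw_pt / raw_pt.sum() * (1.0 - ugib_total)
    bg_vocab = [
        (90000001 + i, name, float(w))
        for i, (name, w) in enumerate(zip(_BACKGROUND_PTS, pt_w))
    ]
    pt_vocab = tuple(ugib_vocab + bg_vocab)

    cfg = GeneratorConfig(drug_vocabulary=drug_vocab, pt_vocabulary=pt_vocab)
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


def signal_experiment_config(
    n_reports: int = 200_000, rr: float = 8.0, seed: int = 0, **overrides
) -> GeneratorConfig:
    """Default recovery experiment: five suspect drugs injected on Haematemesis."""
    injected = tuple((d, "Haematemesis", rr) for d in DEFAULT_SIGNAL_DRUGS)
    return default_config(
        n_reports=n_reports, injected_associations=injected, seed=seed, **overrides
    )


# ---------------------------------------------------------------------------
# sampling helpers


def _ztpois_sample(rng: np.random.Generator, rate: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (resample zeros)."""
    x = rng.poisson(rate, size)
    mask = x == 0
    while mask.any():
        x[mask] = rng.poisson(rate, int(mask.sum()))
        mask = x == 0
    return x


def _ztpois_pmf(rate: float, tail: float = 1e-12) -> np.ndarray:
    """pmf over k = 1..kmax of the zero-truncated Poisson, renormalized."""
    kmax = 1
    while stats.poisson.sf(kmax, rate) > tail and kmax < 200:
        kmax += 1
    k = np.arange(1, kmax + 1)
    p = stats.poisson.pmf(k, rate)
    return p / p.sum()


def _categorical(rng, pairs, size):
    labels = np.array([lab for lab, _ in pairs], dtype=object)
    probs = np.array([p for _, p in pairs], dtype=float)
    probs = probs / probs.sum()
    return labels[rng.choice(len(labels), size=size, p=probs)]


def _distinct_pairs(rep_idx: np.ndarray, item_idx: np.ndarray, n_items: int):
    """Collapse (report, item) picks to distinct pairs, sorted by report."""
    key = rep_idx.astype(np.int64) * n_items + item_idx.astype(np.int64)
    uniq = np.unique(key)
    return uniq // n_items, uniq % n_items


# ---------------------------------------------------------------------------
# generation


def generate(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Sample a synthetic dataset; fully reproducible from ``config.seed``."""
    config.validate()
    vocab_pairs = {(code, name) for code, name, _ in config.pt_vocabulary}
    missing = builtin_ugib_pt_set() - vocab_pairs
    if missing:
        raise GeneratorError(
            f"PT vocabulary is missing UGIB terms: {sorted(missing)[:3]} ..."
        )

    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drug_names = np.array([d for d, _ in config.drug_vocabulary], dtype=object)
    w = np.array([p for _, p in config.drug_vocabulary], dtype=float)
    w = w / w.sum()
    pt_codes = np.array([c for c, _, _ in config.pt_vocabulary], dtype=np.int64)
    pt_names = np.array([nm for _, nm, _ in config.pt_vocabulary], dtype=object)
    q = np.array([p for _, _, p in config.pt_vocabulary], dtype=float)
    q = q / q.sum()
    pt_index = {nm: i for i, nm in enumerate(pt_names)}
    drug_index = {nm: i for i, nm in enumerate(drug_names)}

    # --- drug mentions
    k = _ztpois_sample(rng, config.drug_count_rate, n)
    draw = rng.choice(len(w), size=int(k.sum()), p=w)
    rep_idx = np.repeat(np.arange(n), k)
    rep_d, drug_d = _distinct_pairs(rep_idx, draw, len(w))

    # --- PT draws, tilted per report by the injected drugs it carries
    inj_by_drug: dict[str, list[tuple[int, float]]] = {}
    for drug, pt, rr in config.injected_associations:
        inj_by_drug.setdefault(drug, []).append((pt_index[pt], rr))
    inj_drugs = sorted(inj_by_drug)
    pattern = np.zeros(n, dtype=np.int64)
    for bit, drug in enumerate(inj_drugs):
        present = np.zeros(n, dtype=bool)
        present[rep_d[drug_d == drug_index[drug]]] = True
        pattern |= present.astype(np.int64) << bit

    m = _ztpois_sample(rng, config.pt_count_rate, n)
    rep_parts, pt_parts = [], []
    for g in np.unique(pattern):
        reports_g = np.flatnonzero(pattern == g)
        qg = q.copy()
        for bit, drug in enumerate(inj_drugs):
            if g >> bit & 1:
                for pt_i, rr in inj_by_drug[drug]:
                    qg[pt_i] *= rr
        qg = qg / qg.sum()
        m_g = m[reports_g]
        draws_g = rng.choice(len(q), size=int(m_g.sum()), p=qg)
        rep_g = np.repeat(reports_g, m_g)
        rg, pg = _distinct_pairs(rep_g, draws_g, len(q))
        rep_parts.append(rg)
        pt_parts.append(pg)
    rep_p = np.concatenate(rep_parts)
    pt_p = np.concatenate(pt_parts)
    order = np.argsort(rep_p * len(q) + pt_p, kind="stable")
    rep_p, pt_p = rep_p[order], pt_p[order]

    # --- demographics and dates
    sex = _categorical(rng, config.sex_probs, n)
    age = _categorical(rng, config.age_probs, n)
    country = _categorical(rng, config.country_probs, n)
    reporter = _categorical(rng, config.reporter_probs, n)
    y0, y1 = config.year_range
    years = rng.integers(y0, y1 + 1, n)
    days = rng.integers(0, 365, n)
    dates = pd.to_datetime(
        pd.DataFrame({"year": years, "month": 1, "day": 1})
    ) + pd.to_timedelta(days, unit="D")

    # --- outcomes
    known = rng.random(n) < config.outcome_known_rate
    outcome_rows: list[tuple[int, str]] = []
    drawn_any = np.zeros(n, dtype=bool)
    for name, p in config.outcome_probs:
        if name == "other":
            continue
        hit = known & (rng.random(n) < p)
        drawn_any |= hit
        outcome_rows.extend((int(i), name) for i in np.flatnonzero(hit))
    p_other = dict(config.outcome_probs).get("other", 0.0)
    other_hit = known & ((rng.random(n) < p_other) | ~drawn_any)
    outcome_rows.extend((int(i), "other") for i in np.flatnonzero(other_hit))
    outcome_rows.sort()

    report_ids = np.array([f"{i:09d}" for i in range(1, n + 1)], dtype=object)
    case_ids = np.array([f"C{i:09d}" for i in range(1, n + 1)], dtype=object)

    reports = pd.DataFrame(
        {
            "report_id": report_ids,
            "case_id": case_ids,
            "receipt_date": dates,
            "sex": sex,
            "age_group": age,
            "country": country,
            "reporter_type": reporter,
            "year": pd.array(dates.dt.year, dtype="Int64"),
        }
    )
    drugs = pd.DataFrame(
        {
            "report_id": report_ids[rep_d],
            "drug_name": drug_names[drug_d],
            "role": "suspect",
        }
    )
    reactions = pd.DataFrame(
        {
            "report_id": report_ids[rep_p],
            "pt_code": [int(c) for c in pt_codes[pt_p]],
            "pt_name": pt_names[pt_p],
        }
    )
    outcomes = pd.DataFrame(
        {
            "report_id": [report_ids[i] for i, _ in outcome_rows],
            "outcome": [o for _, o in outcome_rows],
        },
        columns=["report_id", "outcome"],
    )

    # --- duplicate case versions (strictly earlier-dated)
    n_dup = int(math.floor(config.duplicate_rate * n))
    if n_dup:
        src = np.sort(rng.choice(n, size=n_dup, replace=False))
        offsets = rng.integers(30, 400, n_dup)
        dup_ids = np.array(
            [f"{n + j + 1:09d}" for j in range(n_dup)], dtype=object
        )
        dup_dates = dates.iloc[src].reset_index(drop=True) - pd.to_timedelta(
            offsets, unit="D"
        )
        dup_reports = reports.iloc[src].reset_index(drop=True).copy()
        dup_reports["report_id"] = dup_ids
        dup_reports["receipt_date"] = dup_dates.to_numpy()
        dup_reports["year"] = pd.array(dup_dates.dt.year, dtype="Int64")
        id_map = dict(zip(report_ids[src], dup_ids))

        def remap(df: pd.DataFrame) -> pd.DataFrame:
            sub = df[df["report_id"].isin(id_map)].copy()
            sub["report_id"] = sub["report_id"].map(id_map)
            return sub

        reports = pd.concat([reports, dup_reports], ignore_index=True)
        drugs = pd.concat([drugs, remap(drugs)], ignore_index=True)
        reactions = pd.concat([reactions, remap(reactions)], ignore_index=True)
        outcomes = pd.concat([outcomes, remap(outcomes)], ignore_index=True)

    dataset = Dataset(
        reports=reports,
        drugs=drugs,
        reactions=reactions,
        outcomes=outcomes,
        provenance=f"synthetic seed={config.seed}",
        deduplicated=False,
    )
    dataset.validate()

    rr_map = {(d, p): r for d, p, r in config.injected_associations}
    ugib_names = {name for _, name in builtin_ugib_pt_set()}
    exp_ror = {
        drug: expected_ror(config, drug, ugib_names) for drug in inj_drugs
    }
    truth = GroundTruth(rr=rr_map, expected_ror=exp_ror)
    return dataset, truth


# ---------------------------------------------------------------------------
# closed-form expectations


def _avoid_prob(total_weight: float, pmf: np.ndarray) -> float:
    """P(no pick hits a weight-``total_weight`` item set), over the count pmf."""
    k = np.arange(1, len(pmf) + 1)
    return float(np.sum(pmf * (1.0 - total_weight) ** k))


def expected_cells(
    config: GeneratorConfig, drug: str, pt_set: Iterable[str]
) -> tuple[float, float, float, float]:
    """Exact per-report 2x2 cell probabilities (p11, p10, p01, p00).

    ``pt_set`` is a collection of PT names; the event is "the report
    carries at least one of them".  The computation enumerates the
    presence pattern of the *relevant* drugs (the target plus every
    drug with an injected association, since any injection perturbs the
    renormalized PT weights), with exact inclusion-exclusion over the
    i.i.d.-pick sampling scheme.  Cell probabilities refer to the
    originally sampled reports (duplicate versions are copies that
    keep-latest deduplication removes).
    """
    config.validate()
    w_map = dict(config.drug_vocabulary)
    total_w = sum(w_map.values())
    if drug not in w_map:
        raise GeneratorError(f"unknown drug {drug!r}")
    pt_w = {name: p for _, name, p in config.pt_vocabulary}
    total_q = sum(pt_w.values())
    pt_set = set(pt_set)
    known_pts = pt_set & set(pt_w)
    if not known_pts and pt_set:
        raise GeneratorError(f"no PT of {sorted(pt_set)[:3]} in vocabulary")

    inj_by_drug: dict[str, list[tuple[str, float]]] = {}
    for d, p, r in config.injected_associations:
        inj_by_drug.setdefault(d, []).append((p, r))
    relevant = [drug] + sorted(set(inj_by_drug) - {drug})
    if len(relevant) > 16:
        raise GeneratorError("too many injected drugs for exact enumeration")

    pmf_k = _ztpois_pmf(config.drug_count_rate)
    pmf_m = _ztpois_pmf(config.pt_count_rate)
    kvals = np.arange(1, len(pmf_k) + 1)

    def pattern_prob(present: tuple[str, ...]) -> float:
        """P(drug picks hit every drug in ``present`` and miss the rest of R)."""
        absent = [d for d in relevant if d not in present]
        w_absent = sum(w_map[d] for d in absent) / total_w
        total = 0.0
        for r_sub in range(len(present) + 1):
            for sub in combinations(present, r_sub):
                w_miss = w_absent + sum(w_map[d] for d in sub) / total_w
                sign = -1.0 if r_sub % 2 else 1.0
                total += sign * float(np.sum(pmf_k * (1.0 - w_miss) ** kvals))
        return total

    def event_prob(present: tuple[str, ...]) -> float:
        tilted = dict(pt_w)
        for d in present:
            for p, r in inj_by_drug.get(d, ()):
                tilted[p] = tilted[p] * r
        z = sum(tilted.values())
        q_u = sum(tilted[p] for p in known_pts) / z
        return 1.0 - _avoid_prob(q_u, pmf_m)

    p11 = p10 = p01 = p00 = 0.0
    for r_sub in range(len(relevant) + 1):
        for present in combinations(relevant, r_sub):
            p_t = pattern_prob(present)
            if p_t <= 0:
                continue
            p_e = event_prob(present)
            if drug in present:
                p11 += p_t * p_e
                p10 += p_t * (1.0 - p_e)
            else:
                p01 += p_t * p_e
                p00 += p_t * (1.0 - p_e)
    return p11, p10, p01, p00


def expected_ror(
    config: GeneratorConfig, drug: str, pt_set: Iterable[str]
) -> float:
    """The ROR the generator targets for ``drug`` against ``pt_set``."""
    p11, p10, p01, p00 = expected_cells(config, drug, pt_set)
    if min(p10, p01) <= 0:
        return math.inf if p11 > 0 else math.nan
    return (p11 * p00) / (p10 * p01)


def expected_pair_lift(config: GeneratorConfig, drug: str, pt_name: str) -> float:
    """Large-sample limit of a/E for the single (drug, PT) pair."""
    p11, p10, p01, _ = expected_cells(config, drug, {pt_name})
    return p11 / ((p11 + p10) * (p11 + p01))


def expected_mention_probability(config: GeneratorConfig, drug: str) -> float:
    """P(a report mentions ``drug``) under the sampling scheme."""
    w_map = dict(config.drug_vocabulary)
    if drug not in w_map:
        raise GeneratorError(f"unknown drug {drug!r}")
    pmf_k = _ztpois_pmf(config.drug_count_rate)
    return 1.0 - _avoid_prob(w_map[drug] / sum(w_map.values()), pmf_k)
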