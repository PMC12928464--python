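"""Disproportionality statistics for drug–event 2x2 tables.

Every method starts from the same 2x2 contingency table over reporting
units (distinct reports by default)::

                      target event    other events
    target drug            a               b
    other drugs            c               d

with ``N = a+b+c+d`` and expected count ``E = (a+b)(a+c)/N`` under
independence.  Four signal-detection statistics are provided:

* **ROR** — reporting odds ratio ``ad/bc`` with the Woolf log-normal
  95% CI ``exp(ln ROR +/- 1.96 sqrt(1/a+1/b+1/c+1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with
  CI ``exp(ln PRR +/- 1.96 sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))`` and the
  Yates-corrected chi-square.
* **BCPNN IC** — information component ``log2((a+1/2)/(E+1/2))`` with a
  2.5% lower credible bound from the Gamma(a+1/2, E+1/2) posterior of
  the reporting ratio (the shrinkage-1/2 formulation; equivalently an
  empirical-Bayes Gamma(1/2, 1/2)-prior model).
* **MGPS EBGM** — DuMouchel's multi-item gamma-Poisson shrinker: counts
  ``a ~ Poisson(lambda E)`` with a two-component gamma mixture prior on
  ``lambda`` fitted across all drug-event pairs by maximum marginal
  likelihood; EBGM is the posterior geometric mean of ``lambda`` and
  EBGM05 its 5th percentile.

An alternative ``paper_compat`` IC mode derives IC from EBGM
(``IC = log2 EBGM``, ``IC025 = IC - 1.67``); see the methods note for
why this reproduction mode exists.

Zero cells are handled by the Haldane–Anscombe correction (+0.5 to all
four cells, applied per statistic and flagged on the result).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .case_processing import match_pt_rows
from .model import Dataset

Z95 = 1.96  # the conventional two-sided 95% multiplier the CI formulas state

METHODS = ("ROR", "PRR", "EBGM", "BCPNN")


# ---------------------------------------------------------------------------
# contingency table


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-by-event counts (reporting units in the margins)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.N <= 0:
            raise ValueError("empty contingency table")

    @property
    def N(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def E(self) -> float:
        """Expected a-cell count under drug/event independence."""
        return (self.a + self.b) * (self.a + self.c) / self.N

    def corrected(self) -> "ContingencyTable":
        """Haldane–Anscombe +0.5 on every cell."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def build_contingency(
    dataset: Dataset,
    drug_name: str,
    ugib_report_ids: set[str],
    counting_mode: str = "patient",
    pt_set=None,
) -> ContingencyTable:
    """Count the 2x2 table for one drug against the target event set.

    ``patient`` mode counts distinct reports (the default); ``event``
    mode counts reaction rows and requires ``pt_set`` to classify them.
    A drug absent from the dataset yields an ``a = 0`` table with a
    warning rather than an error.
    """
    if counting_mode not in ("patient", "event"):
        raise ValueError(f"unknown counting_mode {counting_mode!r}")
    drug_ids = set(
        dataset.drugs.loc[dataset.drugs["drug_name"] == drug_name, "report_id"]
    )
    if not drug_ids:
        warnings.warn(f"drug {drug_name!r} not present in dataset", stacklevel=2)
    if counting_mode == "patient":
        all_ids = set(dataset.reports["report_id"])
        a = len(drug_ids & ugib_report_ids)
        b = len(drug_ids) - a
        c = len(ugib_report_ids) - a
        d = len(all_ids) - a - b - c
        return ContingencyTable(a, b, c, d)
    if pt_set is None:
        raise ValueError("event counting mode requires pt_set")
    rows = dataset.reactions
    is_event = match_pt_rows(rows, pt_set)
    on_drug = rows["report_id"].isin(drug_ids)
    a = int((is_event & on_drug).sum())
    b = int((~is_event & on_drug).sum())
    c = int((is_event & ~on_drug).sum())
    d = int((~is_event & ~on_drug).sum())
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# frequentist statistics


class RatioCI(NamedTuple):
    estimate: float
    lo: float
    hi: float
    corrected: bool


class PrrResult(NamedTuple):
    estimate: float
    lo: float
    hi: float
    chi2: float
    corrected: bool


def _maybe_correct(table: ContingencyTable, zero_correction: bool):
    if table.has_zero_cell:
        if not zero_correction:
            return None, True
        return table.corrected(), True
    return table, False


def ror(table: ContingencyTable, zero_correction: bool = True) -> RatioCI:
    """Reporting odds ratio with Woolf 95% CI.

    With a zero cell and correction disabled the result is the NaN
    sentinel triple.
    """
    t, corrected = _maybe_correct(table, zero_correction)
    if t is None:
        return RatioCI(math.nan, math.nan, math.nan, True)
    est = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return RatioCI(
        est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), corrected
    )


def yates_chi2(table: ContingencyTable) -> float:
    """Continuity-corrected chi-square; floors at 0 when |ad-bc| <= N/2."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.N
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return math.nan
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    return n * num * num / margins


def prr(table: ContingencyTable, zero_correction: bool = True) -> PrrResult:
    """Proportional reporting ratio, 95% CI, and Yates chi-square.

    The chi-square is computed on the uncorrected cells (it has no
    division-by-zero problem); the ratio and CI use Haldane–Anscombe
    cells when a zero cell is present.
    """
    chi2 = yates_chi2(table)
    t, corrected = _maybe_correct(table, zero_correction)
    if t is None:
        return PrrResult(math.nan, math.nan, math.nan, chi2, True)
    est = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    var = 1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d)
    se = math.sqrt(max(var, 0.0))
    return PrrResult(
        est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), chi2, corrected
    )


# ---------------------------------------------------------------------------
# BCPNN information component


class IcResult(NamedTuple):
    ic: float
    ic025: float


def bcpnn_ic(
    table: ContingencyTable,
    mode: str = "standard",
    ebgm_value: Optional[float] = None,
) -> IcResult:
    """Information component and its 2.5% lower credible bound.

    ``standard``: IC = log2((a+1/2)/(E+1/2)); IC025 is log2 of the 2.5%
    quantile of the Gamma(shape a+1/2, rate E+1/2) posterior of the
    reporting ratio.

    ``paper_compat``: IC = log2(EBGM) and IC025 = IC - 1.67, a
    reproduction mode matching published tables that print the
    information component as the base-2 log of EBGM with a constant
    interval offset; requires ``ebgm_value``.
    """
    if mode == "paper_compat":
        if ebgm_value is None or not math.isfinite(ebgm_value) or ebgm_value <= 0:
            return IcResult(math.nan, math.nan)
        ic = math.log2(ebgm_value)
        return IcResult(ic, ic - 1.67)
    if mode != "standard":
        raise ValueError(f"unknown IC mode {mode!r}")
    e = table.E
    if e <= 0:
        return IcResult(math.nan, math.nan)
    shape = table.a + 0.5
    rate = e + 0.5
    ic = math.log2(shape / rate)
    q = stats.gamma.ppf(0.025, shape, scale=1.0 / rate)
    return IcResult(ic, math.log2(q))


# ---------------------------------------------------------------------------
# MGPS / EBGM


class MGPSConvergenceError(RuntimeError):
    """Optimizer failed; carries the best parameters found so far."""

    def __init__(self, message: str, prior: "MGPSPrior"):
        super().__init__(message)
        self.prior = prior


@dataclass(frozen=True)
class MGPSPrior:
    """Two-component gamma mixture prior on the reporting ratio lambda.

    ``lambda ~ w Gamma(alpha1, beta1) + (1-w) Gamma(alpha2, beta2)``
    (shape/rate parameterization).  ``source`` records how the prior was
    obtained: ``fitted``, ``fallback`` (independent Gamma(1/2, 1/2) when
    too few pairs are available to fit), or ``fixed``.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    source: str = "fixed"

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")

    def log_marginal_components(self, a, e):
        """Per-component log marginal P(a | E) (negative-binomial), vectorized."""
        a = np.asarray(a, dtype=float)
        e = np.asarray(e, dtype=float)
        lp1 = stats.nbinom.logpmf(a, self.alpha1, self.beta1 / (self.beta1 + e))
        lp2 = stats.nbinom.logpmf(a, self.alpha2, self.beta2 / (self.beta2 + e))
        return lp1, lp2

    def log_marginal(self, a, e):
        lp1, lp2 = self.log_marginal_components(a, e)
        with np.errstate(divide="ignore"):
            return np.logaddexp(
                np.log(self.w) + lp1 if self.w > 0 else -np.inf + lp1,
                np.log1p(-self.w) + lp2 if self.w < 1 else -np.inf + lp2,
            )

    def posterior_weights(self, a, e):
        """Posterior probability of component 1 given the observed count."""
        lp1, lp2 = self.log_marginal_components(a, e)
        with np.errstate(divide="ignore"):
            l1 = (np.log(self.w) if self.w > 0 else -np.inf) + lp1
            l2 = (np.log1p(-self.w) if self.w < 1 else -np.inf) + lp2
        m = np.maximum(l1, l2)
        q1 = np.exp(l1 - m)
        q2 = np.exp(l2 - m)
        return q1 / (q1 + q2)


DUMOUCHEL_START = MGPSPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0, source="fixed")

FALLBACK_PRIOR = MGPSPrior(0.5, 0.5, 0.5, 0.5, 1.0, source="fallback")


def _neg_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    w = special.expit(theta[4])
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    with np.errstate(divide="ignore"):
        ll = np.logaddexp(np.log(w) + lp1, np.log1p(-w) + lp2)
    total = ll.sum()
    if not np.isfinite(total):
        return 1e300
    return -total


def _neg_loglik_single(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1 = np.exp(theta)
    ll = stats.nbinom.logpmf(a, a1, b1 / (b1 + e)).sum()
    if not np.isfinite(ll):
        return 1e300
    return -ll


def mgps_fit(
    a: Sequence[float],
    e: Sequence[float],
    start: MGPSPrior = DUMOUCHEL_START,
    min_pairs: int = 50,
    single_component: bool = False,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MGPSPrior:
    """Fit the gamma-mixture prior by maximum marginal likelihood.

    ``a`` and ``e`` are the observed and expected counts of every
    drug-event pair (all pairs, not only the ones later reported).
    Optimization is bounded quasi-Newton (L-BFGS-B) on log-shape,
    log-rate and logit-weight from the DuMouchel starting point; pairs
    with ``E <= 0`` are ignored.  With fewer than ``min_pairs`` usable
    pairs the independent Gamma(1/2, 1/2) fallback prior is returned
    (marked ``source='fallback'``).
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    ok = e > 0
    a, e = a[ok], e[ok]
    if len(a) < min_pairs:
        return FALLBACK_PRIOR
    bounds4 = [(-12.0, 12.0)] * 4 + [(-12.0, 12.0)]
    if single_component:
        theta0 = np.log([start.alpha1, start.beta1])
        res = optimize.minimize(
            _neg_loglik_single,
            theta0,
            args=(a, e),
            method="L-BFGS-B",
            bounds=bounds4[:2],
            options={"ftol": tol * 1e-2, "gtol": 1e-9, "maxiter": max_iter},
        )
        a1, b1 = np.exp(res.x)
        prior = MGPSPrior(a1, b1, a1, b1, 1.0, source="fitted")
        if not res.success:
            raise MGPSConvergenceError(res.message, prior)
        return prior
    theta0 = np.array(
        [
            math.log(start.alpha1),
            math.log(start.beta1),
            math.log(start.alpha2),
            math.log(start.beta2),
            special.logit(min(max(start.w, 1e-9), 1 - 1e-9)),
        ]
    )
    # small ensembles of pairs are weakly identified and L-BFGS-B line
    # searches occasionally stall there; a few deterministic extra starts
    # plus a simplex polish make the fit dependable without changing the
    # objective
    jitter_rng = np.random.default_rng(0)
    starts = [theta0]
    for _ in range(3):
        starts.append(theta0 + jitter_rng.normal(0.0, 0.7, size=5))
    best = None
    any_success = False
    for th in starts:
        res = optimize.minimize(
            _neg_loglik,
            th,
            args=(a, e),
            method="L-BFGS-B",
            bounds=bounds4,
            options={"ftol": tol * 1e-2, "gtol": 1e-9, "maxiter": max_iter},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        polish = optimize.minimize(
            _neg_loglik,
            best.x,
            args=(a, e),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": tol, "maxiter": 4000},
        )
        if polish.fun <= best.fun:
            best = polish
        any_success = bool(polish.success)
    x = np.clip(best.x, [b[0] for b in bounds4], [b[1] for b in bounds4])
    a1, b1, a2, b2 = np.exp(x[:4])
    w = float(special.expit(x[4]))
    prior = MGPSPrior(a1, b1, a2, b2, w, source="fitted")
    if not any_success:
        raise MGPSConvergenceError(str(best.message), prior)
    return prior


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float


def _posterior_params(a: float, e: float, prior: MGPSPrior):
    q1 = float(prior.posterior_weights(a, e))
    return (
        (q1, prior.alpha1 + a, prior.beta1 + e),
        (1.0 - q1, prior.alpha2 + a, prior.beta2 + e),
    )


def _mixture_cdf(x: float, comps) -> float:
    return sum(q * special.gammainc(shp, rate * x) for q, shp, rate in comps if q > 0)


def ebgm(table_or_a, prior: MGPSPrior, e: Optional[float] = None) -> EbgmResult:
    """Posterior geometric mean (EBGM) and 5th percentile (EBGM05).

    Accepts either a :class:`ContingencyTable` or an ``(a, e)`` pair.
    The posterior of lambda is a two-component gamma mixture with
    shapes ``alpha_k + a`` and rates ``beta_k + E``; EBGM is
    ``2**E[log2 lambda]`` and EBGM05 solves the mixture CDF at 0.05
    numerically.
    """
    if isinstance(table_or_a, ContingencyTable):
        a_val, e_val = table_or_a.a, table_or_a.E
    else:
        if e is None:
            raise ValueError("ebgm(a, prior, e=...) requires e")
        a_val, e_val = float(table_or_a), float(e)
    if e_val <= 0:
        return EbgmResult(math.nan, math.nan)
    # drop numerically irrelevant components so they cannot spoil the bracket
    comps = [
        (q, shp, rate)
        for q, shp, rate in _posterior_params(a_val, e_val, prior)
        if q > 1e-12
    ]
    total_q = sum(q for q, _, _ in comps)
    comps = [(q / total_q, shp, rate) for q, shp, rate in comps]
    mean_log = sum(
        q * (special.digamma(shp) - math.log(rate)) for q, shp, rate in comps
    )
    point = math.exp(mean_log)
    qs = [stats.gamma.ppf(0.05, shp, scale=1 / rate) for _, shp, rate in comps]
    lo, hi = min(qs), max(qs)
    if math.isclose(lo, hi, rel_tol=1e-12):
        q05 = lo
    else:
        f = lambda x: _mixture_cdf(x, comps) - 0.05
        flo, fhi = f(lo), f(hi)
        # the component quantiles bracket the mixture quantile up to rounding
        for _ in range(60):
            if flo <= 0:
                break
            lo *= 0.99
            flo = f(lo)
        for _ in range(60):
            if fhi >= 0:
                break
            hi *= 1.01
            fhi = f(hi)
        if flo == 0:
            q05 = lo
        elif fhi == 0:
            q05 = hi
        else:
            q05 = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return EbgmResult(point, q05)


def ebgm_many(a, e, prior: MGPSPrior) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EBGM/EBGM05 over pair arrays (loops the quantile solve)."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    points = np.empty(len(a))
    q05s = np.empty(len(a))
    for i in range(len(a)):
        points[i], q05s[i] = ebgm(a[i], prior, e=e[i])
    return points, q05s


# ---------------------------------------------------------------------------
# thresholds, per-drug results, consensus


@dataclass(frozen=True)
class SignalThresholds:
    """Signal-positivity rules (the field-standard defaults, all configurable).

    * ROR: lower 95% CI bound > ``ror_ci_low`` (1)
    * PRR: PRR >= ``prr_min`` (2) and chi2 >= ``chi2_min`` (4) and a >= ``prr_min_a`` (3)
    * BCPNN: IC025 > ``ic025_min`` (0)
    * MGPS: EBGM05 > ``ebgm05_min`` (2)

    ``min_a`` additionally floors every method: below it no flag can be
    positive regardless of the statistics.
    """

    min_a: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    prr_min_a: int = 3
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SignalThresholds":
        kwargs = {}
        for f in ("min_a", "prr_min_a"):
            if f in mapping:
                kwargs[f] = int(mapping[f])
        for f in ("ror_ci_low", "prr_min", "chi2_min", "ic025_min", "ebgm05_min"):
            if f in mapping:
                kwargs[f] = float(mapping[f])
        unknown = set(mapping) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "SignalThresholds":
        """Parse a plain-text ``key = value`` config (``#`` comments allowed)."""
        mapping = {}
        from pathlib import Path

        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            if not value:
                raise ValueError(f"bad threshold line {line!r}")
            mapping[key.strip()] = value.strip()
        return cls.from_mapping(mapping)


@dataclass(frozen=True)
class SignalResult:
    """All four statistics (with interval bounds) and flags for one drug."""

    drug: str
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    corrected: bool = False
    ic_mode: str = "standard"
    flag_ror: Optional[bool] = None
    flag_prr: Optional[bool] = None
    flag_ebgm: Optional[bool] = None
    flag_bcpnn: Optional[bool] = None

    @property
    def flag_all_four(self) -> Optional[bool]:
        flags = (self.flag_ror, self.flag_prr, self.flag_ebgm, self.flag_bcpnn)
        if any(f is None for f in flags):
            return None
        return all(flags)

    def positive_methods(self) -> frozenset:
        out = []
        for name, flag in zip(
            METHODS, (self.flag_ror, self.flag_prr, self.flag_ebgm, self.flag_bcpnn)
        ):
            if flag:
                out.append(name)
        return frozenset(out)


def compute_signal(
    drug: str,
    table: ContingencyTable,
    prior: MGPSPrior,
    ic_mode: str = "standard",
    zero_correction: bool = True,
) -> SignalResult:
    """All four statistics for one drug's 2x2 table (flags left unset)."""
    r = ror(table, zero_correction=zero_correction)
    p = prr(table, zero_correction=zero_correction)
    g = ebgm(table, prior)
    ic = bcpnn_ic(table, mode=ic_mode, ebgm_value=g.ebgm)
    return SignalResult(
        drug=drug,
        a=int(table.a),
        ror=r.estimate,
        ror_lo=r.lo,
        ror_hi=r.hi,
        prr=p.estimate,
        prr_lo=p.lo,
        prr_hi=p.hi,
        chi2=p.chi2,
        ic=ic.ic,
        ic025=ic.ic025,
        ebgm=g.ebgm,
        ebgm05=g.ebgm05,
        corrected=r.corrected or p.corrected,
        ic_mode=ic_mode,
    )


def _gt(x: float, threshold: float) -> bool:
    return bool(math.isfinite(x) and x > threshold)


def evaluate_signal(
    result: SignalResult, thresholds: SignalThresholds = SignalThresholds()
) -> SignalResult:
    """Apply the threshold rules; returns a copy with the four flags set."""
    if result.a < thresholds.min_a:
        return replace(
            result,
            flag_ror=False,
            flag_prr=False,
            flag_ebgm=False,
            flag_bcpnn=False,
        )
    flag_ror = _gt(result.ror_lo, thresholds.ror_ci_low)
    flag_prr = (
        bool(math.isfinite(result.prr) and result.prr >= thresholds.prr_min)
        and bool(math.isfinite(result.chi2) and result.chi2 >= thresholds.chi2_min)
        and result.a >= thresholds.prr_min_a
    )
    flag_bcpnn = _gt(result.ic025, thresholds.ic025_min)
    flag_ebgm = _gt(result.ebgm05, thresholds.ebgm05_min)
    return replace(
        result,
        flag_ror=flag_ror,
        flag_prr=flag_prr,
        flag_ebgm=flag_ebgm,
        flag_bcpnn=flag_bcpnn,
    )


def consensus_venn(results: Iterable[SignalResult]) -> dict[str, int]:
    """Exclusive Venn-region counts over the four method flags.

    Every drug falls in exactly one region, keyed by the sorted method
    names joined with ``+`` (e.g. ``"ROR+PRR"``); drugs positive under no
    method are counted under ``"none"``.  All 16 regions are present.
    """
    results = list(results)
    if not results:
        raise ValueError("consensus_venn: no results")
    keys = ["none"]
    for k in range(1, 5):
        for combo in combinations(METHODS, k):
            keys.append("+".join(combo))
    counts = {k: 0 for k in keys}
    for r in results:
        active = r.positive_methods()
        key = "+".join(m for m in METHODS if m in active) or "none"
        counts[key] += 1
    return counts
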