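# Methods

## The analysis model

Spontaneous-report disproportionality analysis treats a reporting database
as a large contingency structure: for a target drug and a target event set,
reports are cross-classified into the 2×2 table (a, b, c, d) with
N = a+b+c+d and E = (a+b)(a+c)/N, the a-cell count expected if drug and
event were reported independently.  The package computes four statistics
per drug, each with the field-standard positivity rule (all cutoffs
configurable through `SignalThresholds`, plain-text `key = value` files
accepted):

| statistic | definition | interval | default rule |
|---|---|---|---|
| ROR | ad/bc | Woolf: exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | lower bound > 1 |
| PRR | [a/(a+b)]/[c/(c+d)] | exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))) | PRR ≥ 2 ∧ χ²(Yates) ≥ 4 ∧ a ≥ 3 |
| BCPNN IC | log₂((a+½)/(E+½)) | IC025 = log₂ of the 2.5 % quantile of Gamma(a+½, E+½) | IC025 > 0 |
| MGPS EBGM | 2^E[log₂ λ \| a] under the fitted mixture posterior | EBGM05 = 5 % posterior quantile | EBGM05 > 2 |

A global count floor `min_a` (default 3) blanks every flag below it.  The
1.96 multiplier is the literal constant the conventional formulas state,
not the exact 0.975 normal quantile; the difference is below the printed
precision everywhere.

**Zero cells.** The Haldane–Anscombe correction (+0.5 on all four cells) is
applied per statistic whenever any cell is zero, and the result is marked
`corrected`.  With the correction disabled, undefined results are NaN
sentinels, written as `NA` in output tables.

**Yates χ².** N(|ad−bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)], floored at zero
when |ad−bc| ≤ N/2.  It agrees with `scipy.stats.chi2_contingency`
(checked property-wise); the bespoke form exists because the statistic
feeds the PRR rule and must share the table's cell conventions.

**BCPNN.** The shrinkage-½ information component is exactly the posterior
of an empirical-Bayes model with a Gamma(½, ½) prior on the reporting
ratio; IC025 uses the exact gamma quantile rather than a normal
approximation.  A second mode, `paper_compat`, reproduces a convention
seen in published signal tables where the IC column is the base-2 log of
EBGM and IC025 sits at a fixed −1.67 offset below it.  It exists purely so
such tables can be reproduced and cross-checked (the identities
IC = log₂ EBGM and IC025 = IC − 1.67 hold exactly in that mode); it is not
endorsed as BCPNN methodology and `standard` is the default.

**MGPS.** DuMouchel's model: a ~ Poisson(λE) with
λ ~ w·Gamma(α₁, β₁) + (1−w)·Gamma(α₂, β₂).  The marginal likelihood of
each pair is a two-component negative-binomial mixture; the five
hyperparameters are fitted by maximizing the summed log marginal
likelihood over *all* drug–event pairs (not only those later reported),
by bounded L-BFGS-B on (log α, log β, logit w) from the classical starting
point (0.2, 0.1, 2.0, 4.0, 1/3).  Because small ensembles (tens of pairs)
are weakly identified, the fit adds three deterministically jittered
starts and a Nelder–Mead polish before declaring failure; non-convergence
raises an error carrying the best parameters found.  With fewer than 50
usable pairs the fit is refused and the independent Gamma(½, ½) prior is
used instead, labelled `fallback` in all output.  The posterior is the
conjugate two-component gamma mixture; EBGM05 solves the mixture CDF at
0.05 by Brent's method (bracketed by the component quantiles; components
with posterior weight below 1e−12 are dropped as numerically irrelevant).
Hyperparameters themselves are weakly identified — accuracy is asserted on
the EBGM functional, not on the raw five-vector.

## Event definition and case processing

The built-in event set is the 17 MedDRA Preferred Terms for bleeding
sources between the oral cavity and the ligament of Treitz (narrowed from
the "Gastrointestinal Haemorrhage" SMQ by anatomical location; terms that
do not localize the source, such as melaena, are excluded).  PT matching
uses the numeric code when a reaction row carries one, else
case-insensitive exact name — term lists arrive coded, verbatim files
often are not.  Arbitrary PT sets are accepted as `code,name` files.

Deduplication keeps, per case identifier, the version with the latest
receipt date, ties broken by largest report id (lexicographic on the
zero-padded ids); undated versions lose to dated ones.  The operation is
idempotent and invariant to row order.  Sources without versioned cases
are passed through with deduplication disabled.

Two denominators are kept deliberately distinct: PT-frequency shares use
**event records** (reaction rows in the event set; a report with two UGIB
PTs counts twice), demographic shares use **patients** (distinct reports).
Outcome shares use the patients with at least one known outcome code, and
a report contributes to every outcome it lists.  Percentages are rounded
to two decimals in tables.

Drug names are not normalized across brand/generic spellings — published
top-drug tables themselves mix both — so "Pradaxa" and "Dabigatran" rank
separately unless the caller merges them upstream.

## The synthetic world

The generator emulates the structure the analysis depends on, with every
parameter explicit in `GeneratorConfig`:

- **Vocabulary**: 60 drugs (the nine high-frequency UGIB suspects by name
  at 1.2 % marginal weight each, 51 common background drugs on a smoothly
  decaying weight profile) and 40 PTs — the 17 UGIB terms at 5 % total
  weight, split with the strongly skewed relative frequencies real UGIB
  reporting shows (haematemesis dominant), plus 23 background terms.
- **Multiplicity**: per report, zero-truncated Poisson numbers of drug and
  PT picks (rates 2.0 and 1.5), each pick an i.i.d. weighted draw,
  collapsed to the distinct set.  This differs from sequential weighted
  sampling without replacement in one respect only — the distinct-set size
  distribution — and was chosen because it admits *exact* closed-form cell
  probabilities by inclusion–exclusion, making parameter recovery an exact
  rather than hand-wavy acceptance surface.  (Sequential sampling has no
  tractable inclusion probabilities.)
- **Injected signals**: each (drug, PT, rr) association multiplies the
  PT's baseline weight by rr on reports carrying that drug, with
  renormalization.  `expected_cells` / `expected_ror` enumerate the
  presence pattern of all injected drugs exactly, so the generator states
  the ROR it targets.  Note rr is a *joint-probability tilt*, not the
  resulting ROR: renormalization, the multi-PT event set, and
  contamination of the comparator margin all dilute it (e.g. the default
  five-drug experiment at rr = 8 targets ROR ≈ 3.6 against the UGIB set).
- **Duplicates**: a configured fraction of reports is re-emitted as a new
  report id with the same case id and a receipt date 30–400 days earlier,
  so keep-latest deduplication must recover the original set exactly — an
  end-to-end oracle used by the tests.
- **Demographics**: independent categoricals roughly matching the
  population structure of real UGIB reporting (46 % over 65, 50.2 % male,
  consumers and physicians the dominant reporters, US the dominant
  country).  Outcomes are two-stage: 85 % of reports carry known outcome
  codes; conditional on that, each outcome is included independently
  (death 0.08, hospitalization 0.53, ...) with `other` as a catch-all, so
  the configured death probability is exactly the death share among
  known-outcome reports.
- **Determinism**: one seeded `numpy` generator drives everything; a seed
  reproduces the dataset byte for byte.

What the generator does **not** emulate: channeling bias, polypharmacy
correlation structure, reporting-rate drift over calendar time, duplicate
reports that differ between versions, or free-text drug-name noise.
Passing recovery tests therefore demonstrate correctness of the pipeline's
arithmetic and inference under a known sampling law — not robustness to
real-world confounding.

## Study conditions and problem sizes

The default recovery experiment injects five suspect drugs on
haematemesis at rr = 8 in 200,000 reports; the null calibration run uses
100,000 reports; the MGPS recovery simulation uses 5,000 pairs drawn from
the known prior (0.5, 0.5, 3, 3, 0.4) with log-normal exposures.  Routine
unit tests use 1,500–20,000-report worlds.  The null CI-calibration check
runs 50 replicates of 3,000 reports and requires ≥ 43 to cover ROR = 1 — a
99.9 % binomial band around the nominal 95 % coverage, fixed before the
test was first run, so a calibration failure (coverage collapsing to,
say, 80 %) is detected while ordinary binomial noise is not flagged.

## Numerical choices

- Quantile solves (EBGM05) converge the bracketing iteration to machine
  tolerance; agreement with direct quadrature of prior × likelihood is
  asserted to 1e−6 on a fixed grid in the tests.
- Marginal-frequency convergence is asserted against the generator's own
  closed-form mention probabilities, because report-level inclusion
  probabilities under any min-1 multi-draw scheme are not proportional to
  the configured per-pick weights.
- Ranking ties (equal case counts) break alphabetically by drug name
  everywhere a table is ordered.
- Signal tables round to two decimals on disk; full precision stays on the
  in-memory objects.

## Limitations

- Stratified MGPS (by age/sex/year) and multiplicity correction across
  drugs are out of scope.
- The dedup rule is the keep-latest convention; databases with conflicting
  version semantics need upstream handling.
- `paper_compat` IC is a reproduction device; its −1.67 offset is not a
  standard BCPNN quantity and should not be used for inference.
- Country strings are taken verbatim; no ISO harmonization beyond what the
  input provides.
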