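# Methods

## Data model

The unit of analysis is an aggregated report count, not an individual
case record.  A dataset holds one profile per drug: an all-cause report
total `total_adrs` (spanning every system organ class) and a list of
per-preferred-term counts, each optionally carrying fatal and
not-recovered/not-resolved (NR/NS) outcome tallies.  Counts are treated
as independent report tallies; no deduplication, weighting or
patient-level linkage is attempted, because none is possible from
aggregated exports.  Totals are *carried*, never derived, since a drug's
dosing-error terms are a tiny subset of its reports.

Outcome labels collapse to three classes — `fatal`,
`not_recovered_not_resolved`, `other` — with `other` absorbing
recovered/recovering/resolved/unknown.  Outcome tallies may be unknown
(`None`); every statistic that needs them raises on unknowns rather than
imputing zero, so a missing tally can never masquerade as an observed
zero.

## Taxonomy

Dosing-error preferred terms are partitioned into improper dose,
overdose and underdose.  Matching is case-insensitive with internal
whitespace collapsed: MedDRA casing is not semantically meaningful and
portal exports vary in spacing.  Two asymmetric mechanisms govern
non-members:

* **Exclusion** — names containing a marker from `excluded_markers`
  (default: `intentional` only) raise `ExcludedTermError` regardless of
  map contents.  Intentional overdose/underdose is not a medication
  error; raising, rather than returning "unclassified", makes it
  impossible to count such terms by accident.  Misuse/abuse/off-label
  terms are simply absent from the map rather than actively excluded —
  the exclusion semantics are scoped to intent.
* **Absence** — any other unknown term classifies to `None` and is
  ignored by the tallies (surfaced as a validation warning).

The embedded default is exactly the 24 PTs with anticoagulant
dosing-error reports (12 improper dose, 4 overdose, 8 underdose).  "Drug
dose omission" (without a qualifier) is deliberately *not* in the default
map even though the "dose omission ⇒ underdose" convention would cover
it: fidelity to the observed 24-term vocabulary wins, and extension is a
one-line YAML edit.  The full ~91-term medication-error candidate
vocabulary is not distributed; the taxonomy is config-extensible instead.

## Descriptive statistics

Shares are percentages of the grand dosing-error total along one axis
(category or drug); percent-of-total relates a (drug, category) cell to
the drug's all-cause total; outcome proportions divide a cell's outcome
tally by the cell's dosing-error count (not by total ADRs — the
back-derivable published fatal counts confirm this denominator).

Percentages round **half-up to two decimals** via decimal arithmetic,
matching how published pharmacovigilance tables are typeset; unrounded
values (`ndigits=None`) sum to exactly 100 along the chosen axis, rounded
ones to 100 ± 0.02.  The reference counts contain one well-known
typesetting artifact: the overdose share computes to 18.53% from its own
counts (1265/6825 = 18.5348%) though it circulates as 18.54%; this
package reports the recomputed 18.53.  Likewise the rivaroxaban overdose
percent-of-total computes to 0.32% (415/131,182), not the 0.60%
also seen in prose.

Correlation uses the sample Pearson coefficient (via `scipy`), with the
two-sided p from t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom — the
exact small-sample test, essential here because n is the number of drugs
(4 in the reference data; df = 2 reproduces the published second-row
values, which is how that unlabeled row was identified as two-sided
p-values).  `correlation_table` attempts five series (three categories,
fatal, NR/NS) against total ADR counts and returns `None` for any series
with unknown tallies instead of silently shrinking the sample: on the
reference data the fatal and NR/NS series are therefore `None`, since
only 8 of 12 fatal and 4 of 12 NR/NS cell tallies are uniquely
recoverable from published percentages.

## Disproportionality

The 2×2 case/non-case table for (target, comparator, category) uses
cases a = the target's reports carrying a PT of that category and
non-cases b = `total_adrs` − a (same for the comparator).  Then

* ROR = (a·d)/(b·c);
* Woolf log-normal CI: exp(ln ROR ± z·SE), SE = √(1/a+1/b+1/c+1/d),
  z = 1.959964 at α = 0.05 (the conventional six-figure value used by
  standard odds-ratio calculators; other α use the exact normal
  quantile);
* p: two-sided normal tail of |ln ROR|/SE — the unique test dual to this
  interval, so `ci_low > 1 ⇔ p < α` by construction.

Zero cells follow the `zero_policy`: `haldane` adds 0.5 to **all four**
cells (Haldane–Anscombe) and flags the result `corrected`; `reject`
raises.  The EMA signal rule — `n_cases ≥ 5` and `ci_low > 1` — applies
the case floor to the *uncorrected* case count, so a corrected table
with 4 real cases can never signal at the default floor.

Significance stars follow the conventional four tiers (\* p<0.05,
\*\* p≤0.01, \*\*\* p≤0.001, \*\*\*\* p≤0.0001).  No multiplicity
adjustment is applied across a comparator panel — each contrast is a
separate screening hypothesis, which is the established (and
acknowledged) practice for this statistic.  PRR, Bayesian shrinkage
estimators and stratified RORs are out of scope.

The default comparator panel holds 37 drugs from the shared therapeutic
area — 24 anticoagulants (heparins, vitamin K antagonists, parenteral
direct inhibitors, heparinoids) and 13 antiplatelet agents, with the two
fixed combinations carried as distinct drug ids.  Comparators absent
from a dataset are reported as skipped findings, never silently dropped.

## Synthetic data

The generator emulates the statistical shape of an aggregated
spontaneous-report extraction:

* per drug and PT, the event count is Binomial(total_reports, p) with
  p obtained by multiplying the PT's baseline **odds** by the planted
  per-(drug, category) multiplier — odds-scale planting makes the
  implied odds ratio exact at any baseline, so `SimTruth` can state it
  in closed form (for a category aggregating several PTs the truth is
  the odds ratio of the summed event probabilities);
* outcome labels are one multinomial draw per (drug, PT) cell;
* defaults in the examples and checks: two drugs of 20,000 reports, one
  overdose PT at baseline probability 0.005 (≈100 expected cases — the
  order of magnitude real dosing-error PTs show for widely used drugs),
  outcome vector (0.05, 0.15, 0.80).  Monte-Carlo sizes: 2,000
  replicates for coverage and null calibration, 300–500 for bias/power,
  a 2,500→40,000 doubling ladder for consistency.

All randomness flows through NumPy's PCG64 generator seeded explicitly;
per-replicate seeds are spawned from the experiment seed via
`SeedSequence`, so every experiment is bit-reproducible and the
CLI pipeline (simulate → describe → ror) is byte-identical across runs
at a fixed seed.

What the generator does **not** emulate: reporting dynamics over time,
duplicate and incomplete reports, under-reporting, drug–drug
interaction structure, or report-level covariates.  Passing
calibration/coverage checks on this generator therefore validates the
estimator arithmetic and the signal rule's statistical behaviour under
the stated sampling model — not robustness to real-world reporting
biases, which no disproportionality method escapes.

## Reference fixture

`reference_fixture()` encodes the published DOAC dosing-error counts:
all-cause totals (dabigatran 57,627; rivaroxaban 131,182; apixaban
70,424; edoxaban 9,318; a pooled 158,767 for other anticoagulants),
per-category dosing-error counts for each drug, and outcome tallies
*only* where uniquely back-derivable from published percentage/denominator
pairs (e.g. dabigatran overdose fatal = 31 of 312 from 9.94%); all other
tallies are unknown.  Each category count rides on one representative PT
because the per-PT breakdown behind the published category totals is not
public — every statistic in this package consumes category aggregates,
so the choice of representative is immaterial.  Comparator-drug case
counts were never published, which is why disproportionality is checked
by simulation properties rather than by reproducing published panels.

## Numerical and design choices

* Thousands separators and the Unicode minus are normalized on read;
  validation collects *all* violations before failing.
* Result CSVs sort rows by (drug/target, category, comparator) and fix
  float precision (4 decimals for ROR/CI/r, 2 for percentages,
  scientific notation for p < 1e-4), so outputs are byte-stable.
* `pearson_p` returns exactly 0 at |r| = 1 and 1 at r = 0.
* Degenerate inputs (zero denominators, constant vectors, empty cells)
  raise typed errors rather than returning NaN.
* CLI exit codes: 0 success, 2 user/config/data error, 1 internal.

## Limitations

Spontaneous-report counts carry no exposure denominator: shares and RORs
describe *reporting*, not incidence or risk, and a signal is a screening
flag, not a causal finding.  The correlation analysis has n = number of
drugs, so it is descriptive at best.  Aggregated counts cannot be
deduplicated or stratified; any PT missing from the taxonomy is simply
not counted (visible as a validation warning).
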