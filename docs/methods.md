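# Methods

## Problem and scope

`faers_signals` implements disproportionality-based signal detection for
spontaneous adverse-event reporting data in the FAERS ASCII dialect
(quarterly dollar-delimited DEMO / DRUG / REAC / THER / INDI / OUTC tables).
The pipeline was built around the standard mepolizumab-style biologic
surveillance workflow: clean and deduplicate the raw tables, select reports
where the drug of interest is the primary suspect, screen every preferred
term (PT) and system organ class (SOC) with four disproportionality
statistics, characterise time to onset, and contrast reporting between
demographic strata and between sexes with FDR control.  Because real FAERS
extracts (and the licensed MedDRA dictionary) cannot be redistributed, the
package ships a synthetic-bundle generator with known ground truth; every
claim the test suite makes is a recovery claim against that truth or an
exact re-derivation from published summary counts.

## Statistics

For a drug–event pair, with `a` = reports with both drug and event, `b` =
drug with other events, `c` = other drugs with the event, `d` = neither, and
`n = a+b+c+d`:

- **ROR** `= ad/bc`, 95% CI `exp(ln ROR ± 1.96·sqrt(1/a+1/b+1/c+1/d))`
  (Woolf).  Signal: CI lower bound > 1 and `a ≥ 3`.
- **PRR** `= a(c+d) / (c(a+b))` with the uncorrected Pearson
  `χ² = (ad−bc)²·n / ((a+b)(c+d)(a+c)(b+d))`.  Signal: PRR ≥ 2, χ² ≥ 4,
  `a ≥ 3`.
- **BCPNN information component** `IC = log2(a·n/((a+c)(a+b)))`.  The
  credibility bound uses the classic closed-form posterior moments
  (Dirichlet/Beta margins with all prior parameters 1, joint prior mass
  `γ = (n+2)²/((a+b+1)(a+c+1))`), and `IC025 = E(IC) − 2·sqrt(V(IC))`.
  Signal: IC025 > 0.  The prior is configurable.
- **EBGM** `= a·n/((a+c)(a+b))` — the relative reporting ratio — with a
  log-normal interval of the same Woolf form; its lower bound is reported
  as EBGM05.  Signal: EBGM05 > 2.  This is the simplified closed form:
  no two-component gamma-Poisson mixture prior is fitted, so no shrinkage
  is applied; at the `a ≥ 3` screening floor used throughout, the
  difference matters mainly for very small counts, which the floor already
  guards.  Against a shrunk MGPS the identity `EBGM = 2^IC` would not
  hold; with this closed form it holds exactly, and the tests assert it.

A **combined signal** requires all four criteria; an **any-of-four** flag is
also emitted (conventionally used at SOC level).  Zero cells: no continuity
correction is applied — a statistic whose formula divides by a zero cell is
reported not-evaluable (NaN) and its criterion fails.  A not-evaluable
statistic can therefore never create a signal, only suppress one.

Counting unit: unique (report, event-label) pairs.  One report contributes
at most 1 to any `a` cell, and at most once per SOC even if several of its
PTs map there.  Whether `n` should count reports or report–event pairs is a
genuine convention choice in this field; pair counting is used here because
it makes the margins self-consistent at both PT and SOC level, and it is
stated in the output metadata.

Monotonicity caveat: ROR and PRR are strictly increasing in `a` (b, c, d
fixed); IC/EBGM are not globally so, because `a` also inflates both margins
of `a·n/((a+c)(a+b))`.  The property tests assert strictness only on the
regime `b, c ≥ 3a` where it provably holds (the regime of a large
database).

## Cleaning rules

- **Deduplication**: keep, per CASEID, the version with the most recent
  FDA_DT, breaking ties by the higher PRIMARYID.  FDA_DT is compared as an
  integer YYYYMMDD; unparseable dates rank lowest so the rule is total.
  Child-table rows of discarded versions are dropped.  The operation is
  idempotent; on synthetic bundles it recovers the generator's intended
  survivor set exactly.
- **Target selection**: exact match of uppercased, trimmed DRUGNAME or
  PROD_AI against a configurable synonym list, restricted to role PS by
  default.  No substring matching — "NUCALA 100MG" is not "NUCALA"; users
  add trade-name variants to the synonym file instead.
- **Indication removal**: PTs that also appear as the target drug's
  recorded indication (joined via the drug-sequence number within target
  reports; the "Product used for unknown indication" placeholder excluded)
  are removed from target reports' events before PT-level screening, so the
  treated disease is not mined as an adverse event.  The indication set is
  derived from the data itself, not from a fixed label-derived list.
- **Units**: AGE_COD decades/years/months/weeks/days/hours to years;
  WT_COD pounds to kilograms (1 lb = 0.453592 kg).
- **Strata**: age <18 / 18–64 / >64 / unknown and weight <80 / 80–100 /
  >100 kg / unknown, with the middle stratum closed on both ends (ages 18
  and 64 both fall in 18–64; weights 80 and 100 in 80–100).  OCCP_COD
  MD/PH/HP/OT map to "health professional", CN (and LW) to "consumer",
  anything else to "unknown".

## Time to onset

Onset = EVENT_DT − earliest valid START_DT of the suspect drug's therapy
rows (joined on the drug sequence).  Only full 8-digit strings that parse as
real calendar dates qualify; partial dates, blanks and negative intervals
are dropped and counted.  One observation per report by default (the
alternative per-(report, PT) unit is behind a flag).  Summaries use
linear-interpolation (type-7) quantiles and right-closed bins 0–30, 31–60,
61–90, 91–180, 181–360, >360 days — monthly early, coarser later, matching
how onset histograms are conventionally displayed.

## Stratified and gender analysis

Subgroup screens rerun the full disproportionality pipeline with both
target and comparator reports restricted to one stratum, so per-stratum `a`
cells sum exactly to the unstratified ones.  The gender contrast is a
within-drug case/non-case odds ratio between female and male target
reports per PT (not a between-drug reporting odds ratio), with a Woolf CI,
a two-sided Fisher exact p-value (robust at small stratum counts; mid-p not
used), and Benjamini–Hochberg adjustment across the screened PTs
(statsmodels' step-up implementation; verified exactly against a
sort/scale/cummin oracle).  Volcano labels use adjusted p < 0.05 and an
effect floor of 0 on log2 OR by default; both are configurable, as no
universal convention exists.  Reports of unknown sex are excluded from the
contrast only.

## Cohort description

Percentages are exact rationals rounded half away from zero to 2 decimals.
Demographics and indications are denominated by all target reports; serious
outcomes by the count of reports carrying at least one outcome code, with
each such report assigned a single category by severity priority
DE > LT > HO > DS > other (CA/RI/OT), and "unknown" when the code is blank.
That single-category convention is what makes outcome counts sum exactly to
their denominator, as descriptive tables in this literature do.

## Synthetic bundles: what they emulate, and what they do not

Background PT frequencies follow a Zipf law with exponent 1.2 over 200
terms by default — spontaneous-report event tables are heavy-tailed, but
the exact law of any real database is not claimed.  Event sampling is
per-report Bernoulli inclusion with probability `q·p_k` (`q` scaled so
reports average ~3.5 PTs, the ratio seen in large biologic extracts);
planted signals multiply this rate for target-drug reports (and again for
female reports when a female multiplier is set).  Because null terms have
identical rates under target and comparator drugs, the no-signal null is
exactly true for them, which is what makes the false-positive-control tests
meaningful.

A planted relative rate `r` does **not** produce EBGM ≈ `r` downstream: the
target drug holds a share `s` of the database, so its own excess
contaminates the event margin, giving asymptotically
`EBGM ≈ r(1+sδ)/((1+δ)(s·r+1−s))` with `δ` the total planted excess mass
(≈ 5.0 for `r = 10`, `s = 0.1`).  This masking effect is a real feature of
disproportionality statistics, not an artefact; the package exposes the
analytic expectation (`synthetic.expected_ebgm`) and the tests assert
recovery against it.  One consequence: a planted `r = 2` excess cannot
satisfy EBGM05 > 2 or PRR ≥ 2 — its true relative reporting ratio is below
2 — so the all-four combined criterion is structurally insensitive to
2-fold excesses at these sizes, while ROR and IC025 do flag them.

Demographic defaults mimic consumer-heavy biologic reporting: age unknown
97.42%, weight unknown 92.83%, sex unknown 18.03%, ~74% consumer reporters,
~78% of reports carrying an outcome code.  Onsets are exponential with mean
120 days; dates degrade (blank / YYYYMM / YYYY) at a configurable rate,
FDA_DT is always complete.  Duplicate cases receive 1–2 extra versions with
non-decreasing FDA_DT (some ties, exercising the PRIMARYID tiebreak).
Determinism is byte-level: identical config and seed give identical files.

Not emulated: report narratives, dosage text, drug interactions, MedDRA
hierarchy beyond a flat PT→SOC map, secular reporting trends,
masking/competition between multiple signal drugs, and correlated event
co-reporting.  Passing recovery tests therefore show the *pipeline* is
correct under a known sampling law — they say nothing about reporting
biases (under-/over-reporting, stimulated reporting) that dominate real
spontaneous data.

## Problem sizes and numerical choices

Recovery experiments use bundles of 20,000 reports (10% target share, three
seeds) — large enough that planted counts sit in the hundreds and binomial
noise on recovered statistics stays within a few percent, small enough that
the whole suite runs in minutes on one core.  Display rounding is half away
from zero to 2 decimals; internal precision is full double.  Quantiles are
type-7.  Ties in ranked tables break lexicographically by event label.
Degenerate inputs (empty tables, zero reports, all-duplicate bundles)
produce empty outputs with headers rather than errors.
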