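# Methods

## Data model and case selection

A spontaneous-report database is a set of cases, each carrying demographics,
one or more drug exposures with FAERS role codes (PS primary suspect, SS
secondary suspect, C concomitant, I interacting), one or more reaction
preferred terms (PTs), outcome codes ({DE, LT, HO, DS, CA, RI, OT}), and
therapy dates that may be partial (year or year–month). FAERS ships revised
versions of a case under new `primaryid`s; we deduplicate by keeping, per
`caseid`, the version with the highest FDA receipt date, ties broken by the
higher `primaryid`. Both the current (`primaryid`-keyed) and legacy
(ISR-keyed) header dialects are accepted and normalised.

Drug-name normalisation matches dictionary variants (brand and generic names
of the eight checkpoint inhibitors) by case-insensitive containment in the
verbatim `drugname`, longest variant first — FAERS drug names routinely carry
dose and formulation suffixes, so exact equality would miss most rows. A case
enters the study cohort when at least one study drug has role PS *and* at
least one reaction PT is in the 24-term arrhythmia catalog (case-insensitive
exact string match; no MedDRA hierarchy traversal).

Regimens are classified from the distinct study substances among
suspect-role (PS/SS) drugs: one substance → monotherapy with class anti-PD-1
{nivolumab, pembrolizumab, cemiplimab}, anti-PD-L1 {atezolizumab, avelumab,
durvalumab} or anti-CTLA-4 {ipilimumab, tremelimumab}; two or more → a
combination, matched against the four named pairs (ipilimumab+nivolumab,
ipilimumab+pembrolizumab, tremelimumab+durvalumab,
pembrolizumab+atezolizumab), otherwise "Other combination". Case-level
co-suspicion is the only combination evidence a spontaneous report carries.

**Time to onset (TTO)** is event date minus the earliest *complete*
(YYYYMMDD) start date of a suspect study drug, in whole days. Partial dates
yield a missing TTO rather than an imputed one; negative intervals are
treated as data-entry errors, excluded and counted. Exclusion counters are
part of the run log, never silent.

## Disproportionality statistics

For each drug-selector × event-selector pair the 2×2 table (a, b, c, d) is
counted in one of two units:

* **record** (default for signal detection): one unit per (case, reaction-PT)
  pair, so a case with two qualifying PTs contributes 2 to the event column.
  This is why record-level Ns exceed unique-case cohort sizes.
* **case** (used for cohort work and comparative contrasts): one unit per
  case, event-positive when any reaction qualifies.

Statistics:

* ROR = ad/bc with Wald CI exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)); when any cell
  is zero all four cells get +0.5 (Haldane–Anscombe), flagged in the output.
* PRR = [a/(a+b)]/[c/(c+d)]; a=0 gives PRR 0, c=0 with a>0 gives a +inf
  sentinel. The companion χ² is the Yates-corrected Pearson statistic
  N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)] (uncorrected available by config) —
  Yates is the customary choice in PRR-based screening.
* IC = log₂((a+0.5)/(E+0.5)) with E=(a+b)(a+c)/N, the shrinkage
  observed-to-expected information component. Credible bounds use the exact
  quantiles of the Gamma(a+0.5) posterior on the shrunk observed count
  (divided by E+0.5). The familiar closed-form offsets
  IC ∓ [3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/4)] are available as
  `ic_method="approx"`, but against the gamma posterior they understate the
  lower-tail width by ~0.35 log₂-units at a=10 and ~0.7 at a=5, which makes
  IC025 anti-conservative exactly where screening decisions are hardest; the
  exact quantiles are therefore the default. A seeded Monte-Carlo sampler of
  the same posterior serves as an independent check in the tests.

**Composite criterion.** With n = a reports, a pair is flagged when n ≥ 3 and
(ROR025 > 1, or PRR > 1 with χ² > 4, or IC025 > 0). The n ≥ 3 floor is
applied to all three clauses, including IC, for consistency (configurable
off). All thresholds live in `SignalCriteria`.

Comparative RORs restrict the table to two disjoint exposure groups (rows =
group A vs group B, columns = event vs non-event); swapping groups inverts
the estimate and interval exactly. The signal spectrum computes one result
per (regimen, PT) with at least one co-report against the full-database
background; cells below the case floor carry all-false flags.

Monotonicity caveat: ROR and PRR are strictly increasing in a with b, c, d
fixed; the IC is too in the margin-dominated screening regime (a small
relative to its margins, background dominating), but not for degenerate
tables where a dominates its own margins — there the expected count grows as
fast as the observed one.

## Cohort analyses

Characteristics tables report counts and percent-of-cohort per stratum,
percentages rounded half-up to two decimals (the convention of published
tables). Quantiles (median, IQR) use linear interpolation between order
statistics. Fatal vs non-fatal contrasts use a Pearson χ² on the
level × outcome contingency, excluding "unknown" levels from the test while
retaining them in the summaries; age and TTO, being right-skewed, use
two-sided Wilcoxon rank-sum tests, and the cross-regimen omnibus is
Kruskal–Wallis over regimens with ≥ 5 known onset times. Case-fatality
proportions are deaths over reports per stratum — a reporting proportion, not
a mortality rate, since spontaneous data have no exposure denominator. For
fatality by event group, a case contributes to *every* group among its
qualifying PTs (so group Ns can exceed the case total); this multi-attribution
is deliberate and matches how multi-PT cases are tabulated.

A case's `died` flag is exactly "DE among its outcome codes"; the displayed
single outcome per case is the most serious code under the order
DE > LT > DS > HO > RI > CA > OT, with "NS" (non-serious) when none is coded.

## Synthetic data generator

Each case draws one regimen from a marginal distribution over fourteen
profiles (seven ICI monotherapies, one ICI combination, six background
oncology/comedication drugs), then each of fifteen PTs (nine arrhythmia, six
frequent non-cardiac) independently with probability background × multiplier,
where the multiplier (default 1) is the planted association strength for that
(substance, PT) pair; probabilities that cap at 1 raise a warning. Cases with
no drawn PT receive a fallback PT outside the catalog so reaction lists stay
non-empty without distorting planted counts. Deaths are drawn per-regimen
(ICI profiles 0.24–0.34, background 0.05–0.12); TTO is log-normal with fatal
cases given a smaller log-mean (μ 3.20 vs 3.50 log-days, σ 1.15/1.25),
mirroring earlier fatal onset. Demographics: sex 58/36/6% male/female/unknown,
age normal(66, 12) clipped to [0, 120], continents roughly 43/33/21% for
America/Europe/Asia. A configurable fraction of therapy start dates is
emitted year–month only (default 35%, which leaves roughly 40% of onset
intervals unknown), and a configurable fraction of cases carries a planted
superseded earlier version for the deduplication stage. All sampling flows
from one `numpy` generator, so identical config + seed gives byte-identical
files.

What the generator does *not* emulate: reporter-level biases (stimulated
reporting, secular trends), drug–drug interaction terms, PT–PT dependence
beyond the shared drug, country-specific coding habits, and free-text
messiness beyond dose suffixes. Passing tests therefore demonstrate that the
statistics and pipeline behave correctly under the stated sampling model, not
that real FAERS extracts are this clean.

## The published-margins cohort

`table1_fixture()` builds a deterministic 1945-case cohort (507 fatal, 1438
non-fatal) whose per-arm margins match a published characteristics table for
checkpoint-inhibitor-associated arrhythmias. Within each arm, every
characteristic is assigned independently by case position, so margins (and
hence every percent) are exact while the joint structure beyond
arm × characteristic is arbitrary but reproducible. Onset bands are realised
by one representative value per band (15/45/75/135/200 days), ages by one
value per band — medians computed from the fixture are coarse by design. The
source table's indication rows are internally inconsistent by a few counts
(fatal + non-fatal ≠ printed total for three rows); the fixture follows the
fatal and non-fatal columns, which every percentage we verify is computed
from.

## Operating-characteristic experiments

`icivigil.experiments` sizes two replicated studies to run in minutes on one
core (sizes are package defaults, stated here as the design choice):

* **Null calibration** — 200 databases of 6000 reports with every multiplier
  1; the per-cell ROR-criterion false-flag rate is scored for cells whose
  expected co-report count is ≥ 3 (four cells at these sizes). The nominal
  one-sided level of "ROR025 > 1" is 2.5%; the acceptance bound of 7.5%
  allows Monte-Carlo slack and small-count discreteness. Observed maxima run
  4–5%.
* **Planted recovery** — 200 databases of 15000 reports with a single planted
  multiplier of 2 on nivolumab × atrial fibrillation (nivolumab marginal
  raised to 0.08, so the expected co-report count is 48). At that depth the
  composite criterion's analytic power is ~99%, so the ≥ 95% recovery check
  tests the implementation rather than boundary sampling noise: at the
  shallow end of the detectable regime (expected count ~20–29) the true union
  power of the three clauses is only ~90–93%, and no correct implementation
  clears 95% there. Each replicate also checks that the case-level
  comparative-ROR interval covers the true planted odds ratio (~2.04);
  nominal coverage is 95%, the check requires ≥ 90%.

## Numerical and degenerate-input choices

* Zero cells: +0.5 on all four cells for ROR only, flagged; PRR uses exact
  0 / +inf sentinels; the IC shrinkage handles a = 0 natively.
* Empty background (c + d = 0) is a hard error instructing the caller to
  supply full-database denominators; an empty cohort summarises to an empty
  table without division by zero; characteristics with one observed level are
  skipped (and marked) in contrasts rather than tested.
* Deduplication sorts stably, so the kept version is deterministic even for
  non-numeric identifiers (numeric comparison when possible, lexicographic
  fallback).
* Rounding is half-up (not banker's) for published-style percentages.
* Pipeline outputs use fixed column orders and fixed decimal formatting
  (two decimals for ratio-scale statistics), making reruns byte-identical.

## Known limitations

Signals are reporting associations, not causal or incidence statements; no
multiplicity correction is applied across the spectrum (deliberately, to
match screening practice); duplicate detection across distinct `caseid`s
(probabilistic record linkage) is out of scope; the indication keyword map is
a coarse bundled resource meant to be replaced by users with their own
coding; and the bundled country→continent table covers common FAERS codes,
mapping unknown codes to "Unknown".
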