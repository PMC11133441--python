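# Methods

## Data model and counting units

A FAERS *case* may be present as several report versions sharing `CASE_ID`;
all counting happens after deduplication, which keeps per case the version
with the largest FDA receipt date (`FDA_DT`), breaking ties by the largest
`PRIMARY_ID` (compared numerically when both identifiers are digit strings,
lexicographically otherwise). The rule is idempotent and independent of
input order; output is sorted by case identifier.

Three units are kept distinct throughout:

- **report** — one deduplicated case (denominator of demographic tables);
- **event** — one distinct (report, PT) pair. A PT repeated within one
  report counts once; the verbatim casing reported most often is used for
  display while matching is done on trimmed, case-folded strings;
- **outcome instance** — one distinct (report, outcome-code) pair. All
  seven FAERS outcome codes (DE, LT, HO, DS, CA, RI, OT) count as severe-
  outcome instances, and the outcome table's denominator is the instance
  total, not the report total.

The cohort is the set of deduplicated reports with at least one drug row
whose role code equals the requested role (default PS, primary suspect) and
whose verbatim name or active-ingredient field contains any search string
case-insensitively; substring matching is used because FAERS names embed
doses and salts. Reports matching only in SS/C/I roles are background. The
background for the 2×2 contrast is *all* other deduplicated reports in the
extract, with no exclusion of reports mentioning the target drug in
non-primary roles — the alternative (excluding them) changes c by a few per
mille in realistic extracts and would require a judgement the screening
thresholds do not depend on.

## Parsing conventions

The dollar-delimited FAERS dialect has no quoting, so the writer rejects
field values containing `$`; the parser is header-driven (column order in
the file is irrelevant), accepts the superset of columns across quarterly
layout revisions, and requires only the columns the analysis uses. Input is
decoded as Latin-1 with replacement, since legacy quarters are not UTF-8
clean. Empty fields, whitespace-only fields and literal `NULL` are missing.
Per-record problems — wrong field count, invalid calendar date, negative or
unparseable number, unknown role/outcome code — skip that record and are
reported with line numbers; a parse is total: records + reported lines =
data lines.

Units are normalised at parse time: ages to years (`MON`/12, `DY`/365.25;
other codes become missing because they cannot be banded), weights to
kilograms (`LBS` × 0.453592; codes other than KG/KGS/LBS become missing).

## Descriptive tables

Percentages are computed round-half-up via decimal arithmetic (banker's
rounding would disagree with printed tables on exact ties): 1 decimal for
demographic and outcome tables, 2 decimals for PT/SOC tables. Age bands are
18–64 and ≥65 with an explicit N/A row; under-18 ages go to N/A with a
logged warning rather than being dropped, since the banding has no
pediatric row. Weight bands are <80, 80–100 (both ends closed) and >100 kg.
Zero denominators raise instead of producing silent NaN.

The PT→SOC mapping is user-supplied (MedDRA is licensed); each PT maps to
exactly one SOC (primary-SOC convention) and conflicting duplicates are a
fatal load error. Events whose PT is absent from the map are excluded from
the SOC denominator and reported as an unmapped count, so the SOC event
total is generally smaller than the PT event total.

## Disproportionality

ROR = ad/bc with the Woolf interval exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)),
z = 1.96 by default. PRR = [a/(a+b)]/[c/(c+d)] — the standard orientation
in which the target drug's event share is compared with the background's;
under this orientation PRR ≤ ROR whenever reporting is elevated, which is
the pattern published signal tables show. χ² is the uncorrected Pearson
statistic in its closed 2×2 form; no Yates correction.

With any zero cell the estimates are undefined (`nan`) rather than raised,
and undefined estimates never satisfy a threshold; the optional
Haldane–Anscombe correction (+0.5 to every cell) is available behind a flag
for exploratory use on sparse synthetic data. Thresholds: a ≥ 3 (non-strict)
gates both rules; CI lower bound > 1, PRR > 2 and χ² > 4 are strict.
Ranking sorts flagged PTs descending by ROR (or PRR, or a), ties broken by
larger a then alphabetically. No multiple-testing adjustment is applied —
the two-rule screen is the conventional practice this package reproduces —
and every pipeline run logs a disclaimer to that effect.

## Synthetic data generator

The generator emulates the statistical structure the pipeline is sensitive
to, with defaults chosen as a realistic four-year oncology extract:

| parameter | default | meaning |
|---|---|---|
| `n_cases` | 20,000 | independent cases |
| `target_drug_prob` | 0.05 | case's PS drug is the target |
| `events_per_case` | 4.0 | mean of K ~ 1 + Poisson(3) distinct PTs |
| `duplicate_prob` | 0.21 | case emits an extra earlier report version |
| `planted_signals` | two PTs at ρ = 10 | target-case PT weights × ρ |
| `missing_rates` | sex 0.697, age 0.98, weight 0.871 | demographic masking |
| `date_range` | 2019-07-01 … 2023-06-30 | FDA receipt dates |

The PT vocabulary (80 terms) is Zipf-weighted (weight ∝ 1/rank); per case,
K distinct PTs are drawn by Gumbel top-K weighted sampling without
replacement, with planted PTs re-weighted by ρ for target cases only.
Duplicate versions differ *only* in `FDA_DT` and `PRIMARY_ID` so they
exercise exactly the deduplication rule. A fraction of non-target cases
mentions the target drug in an SS role to exercise role filtering.
Outcomes, countries and occupations come from small fixed vocabularies with
configurable weights. One root seed is spawned into fixed per-purpose
streams (case structure, demographics, reactions, outcomes, duplicates,
auxiliary tables), so identical (config, seed) is byte-identical and
extending one table never perturbs another.

What the generator does **not** emulate: drug co-prescription structure,
temporal reporting trends, masking/competition bias, correlated PT clusters
within reports, and verbatim-name noise. Passing tests therefore show the
pipeline's counting and estimation are correct under the stated sampling
model, not that real-FAERS idiosyncrasies are handled beyond the parsing
and deduplication conventions above.

`expected_contingency` gives the analytic expected 2×2 cells per
deduplicated case. Exact inclusion probabilities for weighted sampling
without replacement are intractable, so the calibrated-thinning (Hájek)
approximation is used: π_j = 1 − exp(−t·w_j) with t solved by bisection so
that Σπ_j equals the number of draws, mixed over the distribution of K.
Monte-Carlo checks at 30,000 cases put all four cells within ~5% of the
approximation (the planted cell within ~15%, being the smallest). The ROR
of a planted PT converges to the odds ratio implied by these expected cells
— which is below ρ unless the PT is rare in the background — and the median
estimate over seeds at 50,000 cases agrees with it within 10%.

## Problem sizes used in checks

The recovery check runs 100 seeds at 20,000 cases (a planted ρ = 10 PT must
be flagged by both rules in ≥95 of them); estimator-consistency checks use
30,000–50,000 cases and a handful of seeds; the null-model false-flag share
(no planted signals) is recorded as a regression metric, typically ~2% of
vocabulary PTs, and is not asserted against any published value. The
exhaustive estimator/oracle grid covers all 2×2 tables with cells in 1..6.

## Known limitations

- Drug identification is substring search over verbatim fields; no RxNorm
  or ingredient-dictionary normalisation.
- Deduplication is exactly the FDA field rule; no probabilistic record
  linkage.
- Only frequentist ROR/PRR screening; no Bayesian shrinkage (BCPNN/IC,
  EBGM/MGPS) and no stratified or time-partitioned variants.
- The SGM/XML FAERS dialect is out of scope; only the quarterly ASCII
  tables are read.
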