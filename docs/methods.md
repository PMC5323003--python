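# Methods

This note records the models, rules and numerical choices implemented in
`ehrkit`, in enough detail to audit any number the toolkit produces.

## The schema registry

Every operation resolves column names through an `EHRSchema` value rather
than hard-coding them. The bundled CPRD GOLD dialect maps the eight date
roles (event, system entry, last collection, up-to-standard, first and
current registration, transfer out, death) onto
`eventdate, sysdate, lcd, uts, frd, crd, tod, deathdate`, sets the
patient/practice identifiers to `patid`/`practid`, and records the raw
birth-year origin (1800 — CPRD extracts store year of birth as an offset).
Cohort start criteria are `crd` and `uts`; end criteria are `tod`,
`deathdate` and `lcd`, and the two sets must be disjoint. Schemas are
plain values (operations never mutate a global; a process-wide default
exists only as a CLI convenience) and round-trip through YAML so that
other dialects are configuration, not code.

## Storage conventions

Dates are stored in SQLite as ISO-8601 *text* and compared
lexicographically, which for ISO strings is identical to date order; this
keeps every query free of date-parsing logic and makes `'2006-01-01'`
literals in where clauses exact. Missing values become SQL NULL. Date
conversion at import parses the declared input format and falls back to
accepting already-ISO values, so conversion is idempotent; an unparseable
value aborts the import naming file, row and column. Part-files of one
table type are concatenated verbatim — duplicate rows across monthly
part-files are deliberately not de-duplicated, since row identity cannot
be decided at import time.

## The where-clause mini-language

Queries accept a closed grammar — comparisons, `%in%`, `&`/`|`,
parentheses, `IS [NOT] NULL`, quoted literals, and `.()` interpolation
slots resolved against a caller-supplied environment (with `$` as mapping
access, e.g. `.(CASE$yob)`). It is parsed to an AST that renders either to
a SQL fragment or to a boolean mask over an in-memory DataFrame, so
database-side and memory-side filtering (used by matching) share one
semantics. The grammar is deliberately *not* host-language `eval`:
interpolated strings are escaped (quotes doubled), a bare `=` is a parse
error, and nothing outside the supplied environment is reachable.
Comparisons involving NULL are false, as in SQL's three-valued logic
collapsed to a filter.

`first_events`/`last_events` group by patient and keep the extreme event
date; ties on the date are broken by the lowest store rowid, making
results deterministic under any insertion order.

## Year windows and longitudinal extraction

`standard_years` is 1 January – 31 December; `qof_years` follows the UK
financial-year convention, 1 April – 31 March of the following year (the
Quality and Outcomes Framework reporting year); `qof_15_months` runs
1 January – 31 March of the following year. `build_date_fn` generalises
to any (year-offset, month, day) pair. `select_by_year` substitutes the
window's quoted ISO dates for the `STARTDATE`/`ENDDATE` macros *textually*
in the where template before translation; the comparison operators around
the macros belong to the caller, so inclusivity is the caller's choice.
With `cores > 1` each year runs in its own worker with its own database
connection (temporary tables are connection-local, hence single-core only
when they are queried), and results are ordered by year regardless of
completion order; serial and parallel runs are row-for-row identical.

## Prevalence and incidence

With year window [s, e], first-event date d, transfer-out t and death m
(missing t or m meaning "did not happen"):

| term                  | rule                                   |
|-----------------------|----------------------------------------|
| incident numerator    | d ∈ [s, e] and t > d                   |
| incident denominator  | (no d before s) and t > s              |
| prevalent numerator   | d ≤ e and t > d                        |
| prevalent denominator | t > s                                  |
| follow-up             | max(0, min(e, t, m) − s) / 365.25 years |

All comparisons are strict where shown; a transfer-out exactly on the year
start excludes the patient from that year's denominators and clips
follow-up to zero. Death shortens follow-up but does not appear in the
`>` eligibility tests, which name only the transfer-out date — implemented
verbatim. Two readings of the prevalent numerator circulate ("event within
the year" versus "earliest event on or before the year end"); the
cumulative reading is the default and `prevalent_rule="within_year"`
selects the other, so the choice is explicit rather than silent. The
person-time divisor is 365.25 days/year. Rates are 100 × numerator /
(person-years of denominator members); a zero denominator yields a missing
rate, never a division error. Denominator person-time is additive over any
partition of the grouping keys (pinned by test).

## Cohort construction

`build_cohort` keeps patients in the numerator or denominator of the
chosen cohort type, collapses to one row per patient (the earliest year's
row carries covariates), and computes `start_date` as the maximum of the
cohort start, every start-criteria date, and — for cases, when requested —
the diagnosis date; `end_date` as the minimum of the cohort end and every
end-criteria date present. `start`/`end` are integer day offsets from the
cohort start; rows with `start_date > end_date` (e.g. transfer-out before
the cohort opens) are dropped.

## Episode splitting

`cut_tv` works on closed integer-day intervals `[entry, exit]`. For cut
time t: missing or t > exit leaves the row unchanged; t ≤ entry updates
the state on the single row; entry < t ≤ exit replaces the row with
`[entry, t−1]` (old state) and `[t, exit]` (new state). A new state
column starts at 0 with post-cut state 1; an existing column is toggled
0↔1 (`flip`, for start/stop pairs) or incremented (`inc`, for staged
progression). Consequences of the closed-interval convention: t == entry
produces no zero-length pre-episode, and t == exit produces
`[entry, exit−1]` + `[exit, exit]`. Every non-constructed column —
including any event indicator — is replicated verbatim onto both halves;
re-attributing an event flag to the final episode is left to the caller,
because which episode "owns" the event depends on the outcome definition.
Episodes always tile the original interval exactly (person-time is
conserved by every call), and chained cuts at distinct times into distinct
columns commute.

## Matching

Eligibility is equality on every `match_vars` column plus an optional
extra-conditions template evaluated in memory with `CASE` bound to the
current case row. Incidence-density (risk-set) sampling additionally
requires the control's diagnosis date to be missing or strictly after the
case's; the pool is not depleted, so one subject may serve several cases —
the property that keeps hazard-ratio estimates from matched risk sets
unbiased. Exact matching removes matched controls from the pool, so later
cases (processed in input order, which is therefore part of the contract)
may receive fewer than requested. Within a case, sampling is uniform
without replacement using a per-case random stream spawned from the seed,
so a fixed seed reproduces the match table bit-for-bit regardless of how
cases are distributed across workers. The caller supplies cases and pool;
the pool is taken as given (a case present in its own pool is the caller's
filtering responsibility).

Dummy-index matching reads per-practice consultation files (as written by
`export_flat_files`), requires a same-practice control with a consultation
within `index_diff_limit` days — inclusive — of the case's index date, and
assigns the qualifying consultation closest to the index date (ties:
earliest date, then lowest patient id) as the control's dummy index. A
very large limit reduces this to exact matching on practice plus
`match_vars`.

## Code lists

A definition is a set of AND groups per search kind (terms, codes, tests,
drugs, drug codes); groups are OR-ed, a leading `-` marks a group as an
exclusion applied *after* inclusion, and underscores are read as spaces.
Term matching is case-insensitive **substring** containment of every
conjunct, in any order, on whitespace-normalised descriptions — so
`diabetes` does not match `diabetic`. Whole-word or stemmed matching was
considered and rejected: draft lists are for human review, and substring
semantics are predictable and transparent; reviewers should include
morphological variants explicitly. Codes match by prefix; a range `A-B`
matches codes lexically between the endpoints (byte-wise string order,
which follows Read-code conventions). Adding an exclusion group can never
increase a hit count.

## HbA1c standardisation

Records restricted to HbA1c/fructosamine entities get a `hba1c_score` in
IFCC mmol/mol. Unit inference uses an explicit unit code when present,
otherwise value-magnitude windows (defaults: 2.5–25 read as DCCT %,
25–250 as mmol/mol, 100–1500 µmol/L for fructosamine). Conversions use
the NGSP↔IFCC master equation, IFCC = (% − 2.15) × 10.929, and the common
fructosamine approximation % = 0.017 × µmol/L + 1.61. Values that are
non-positive, fall in no window, or convert outside the plausible range
(default 10–195 mmol/mol) are removed and counted. Every bound and
coefficient is configuration — the defaults are standard literature
values, and clinical use should confirm them against local assay
conventions.

## The synthetic-data generator

The generator emulates the *structure* of a CPRD GOLD extract, not any
real population. Defaults: 10 practices, Poisson(50) patients each, study
window 1995–2015; five comorbidities (hypertension 25%, asthma 15%,
diabetes 12%, CHD 10%, atrial fibrillation 8%) assigned independently,
each with a medcode pool and a death-hazard ratio (1.1–2.0); survival
after registration is exponential with hazard 0.01/yr × the product of
assigned ratios, transfer-out an independent exponential at 0.02/yr;
condition-coded events are Poisson (0.5/person-year per condition) with
dates uniform over the active interval; consultations Poisson at
4/person-year; prescriptions at 2/person-year per condition. These sizes
keep a full simulate→import→extract→match cycle fast while leaving every
table non-trivially populated; they were fixed once and are not tuned.
Patient ids encode the practice (`patid = serial × 1000 + practid`), and
birth years are written to flat files in raw offset form so imports
exercise the year-origin conversion. A fixed seed yields byte-identical
files; per-table sub-seeds are spawned from it.

What the generator does **not** emulate — and therefore what passing
tests cannot show about real data: correlated comorbidities, age- and
sex-dependent incidence, registration churn, coding practice variation
between practices, or measurement/coding error. Tests against synthetic
data validate the *mechanics* of the pipeline (set membership, date
arithmetic, sampling semantics), not epidemiological realism.

`surv_sims` draws exponential event times at the given hazard with
independent exponential censoring — the textbook case where the mean
observed time under no censoring estimates 1/hazard, used as a
closed-form check of the random machinery.

## Numerical and testing choices

* Dates compared as ISO text; person-time divisor 365.25 days/year.
* Statistical tests of the generator use fixed seeds chosen up front. The
  prevalence-recovery check pools three replicate simulations
  (≈ 5 600 patients) and applies binomial 99% bounds at the pooled size;
  when all five conditions are checked simultaneously, the per-condition
  bound is Bonferroni-corrected (z = 3.09) to keep 99% family-wise
  confidence. Survival means are checked within four standard errors at
  n = 10⁵.
* Tie-breaks are documented wherever sampling or extremes could be
  ambiguous (store rowid for event ties, earliest-then-lowest-id for
  consultation ties, input order for exact-matching depletion).
* Known limitations: the where grammar excludes joins (use raw SQL);
  matching is single-threaded in this implementation (the per-case seed
  streams make parallelisation safe but it has not been needed at these
  problem sizes); the code-range rule is lexical, which can surprise on
  codes of unequal length; `cut_tv` is row-wise over episodes and intended
  for cohort-sized (not extract-sized) tables.
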