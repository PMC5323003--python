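# ehrkit

Cohort extraction, matching and episode splitting for CPRD-style
electronic health records.

UK primary-care databases (CPRD GOLD, THIN, QResearch, ...) hold coded
longitudinal records — diagnoses, prescriptions, referrals, consultations —
for millions of patients, delivered to researchers as large tab-delimited
flat-file extracts. Getting from those files to an analysis-ready dataset
(a prevalence table, a survival cohort, a matched case-control set) is a
long chain of fiddly, error-prone steps. `ehrkit` packages that chain:

* **Import** flat files (plain or zipped, split into part-files) into a
  single-file SQLite store, with dates normalised to ISO-8601 text and raw
  birth-year offsets resolved.
* **Query** through a safe where-clause mini-language
  (`"medcode %in% .(codes) & eventdate < '2006-01-01'"`) with `.()`
  interpolation from the calling environment; convenience selectors for the
  first/last event per patient; temporary-table helpers for extractions too
  large for memory.
* **Longitudinal extraction**: one selection run per year window (calendar,
  UK financial/QOF, or custom), with `STARTDATE`/`ENDDATE` macros
  substituted per window and results stacked with a `year` column.
* **Prevalence and incidence** per person-time. For year window
  \[*s*, *e*\], event date *d*, transfer-out *t* and death *m*:
  the incident numerator requires *d* ∈ \[*s*, *e*\] and *t* > *d*; the
  incident denominator requires no event before *s* and *t* > *s*; the
  prevalent numerator requires *d* ≤ *e* and *t* > *d*; the prevalent
  denominator requires *t* > *s*; and follow-up is
  (min(*e*, *t*, *m*) − *s*) / 365.25 person-years. Rates are reported per
  100 person-years.
* **Cohort construction**: collapse the patient-year table to one row per
  patient with `start`/`end` integer day offsets, ready for
  `Surv(start, end, event)`-style survival models.
* **Episode splitting** (`cut_tv`) on time-varying covariates over closed
  integer-day intervals, supporting chronic onsets, start/stop flips and
  incremental disease stages, chained call after call.
* **Matching**: incidence-density (risk-set) sampling — controls drawn,
  with reuse across cases, from subjects diagnosis-free at each case's
  diagnosis date; exact matching with pool depletion; and dummy-index-date
  matching against per-practice consultation files.
* **Code lists**: keyword/code searches (AND groups, OR between groups,
  exclusions, prefix and lexical code ranges) against medical and drug
  lookup tables, producing draft lists for clinical review.
* **HbA1c standardisation** to IFCC mmol/mol with configurable detection
  bounds and conversion coefficients.
* **Synthetic data**: a generator for CPRD-shaped Practice / Patient /
  Clinical / Referral / Therapy / Consultation tables with exponential
  survival driven by per-comorbidity hazard ratios, so the entire pipeline
  is testable without licensed data.

## Worked example

```python
import tempfile, os
import ehrkit as ek

# a synthetic world: 10 practices, ~50 patients each, 1995-2015
tables = ek.simulate_ehr(ek.SimConfig(), seed=42)
tmp = tempfile.mkdtemp()
ek.write_flat_files(tables, tmp, prefix="ehr")

db = ek.Database(os.path.join(tmp, "ehr.sqlite"))
ek.import_flat_files(db, tmp)
print(ek.head_db(db, table="Clinical").to_string(index=False))
```

```
 patid  eventdate  constype  consid  medcode  comorbidity  practid
  3001 1997-08-17         0       1    16059 hypertension        1
  3001 1999-08-06         1       2    12948 hypertension        1
  3001 2001-10-27         0       3    69753 hypertension        1
  ...
```

Patients registered before each year's start, merged with each patient's
first diabetes-coded event, give the prevalence series:

```python
codes = [273, 277, 293, 351, 257]          # diabetes medcodes
reg = ek.select_by_year(db, "Patient",
    ["patid", "practid", "gender", "yob", "crd", "tod", "deathdate"],
    "crd < STARTDATE", year_range=range(2008, 2013))
inc = ek.select_by_year(db, ["Clinical", "Referral"],
    ["patid", "eventdate", "medcode"],
    "medcode %in% .(codes) & eventdate <= ENDDATE",
    year_range=range(2008, 2013), selector_fn=ek.first_events,
    env={"codes": codes})
inc = inc.sort_values("eventdate").drop_duplicates(["patid", "year"])
dat = reg.merge(inc[["patid", "year", "eventdate"]],
                on=["patid", "year"], how="left")
terms = ek.prev_terms(dat)
print(ek.prev_totals(terms)["prevalence"]["year_counts"].to_string(index=False))
```

```
 year  numerator  denominator  prevalence
 2008         48   291.811088   16.448998
 2009         49   300.511978   16.305506
 2010         53   303.808350   17.445208
 2011         53   315.468857   16.800391
 2012         57   321.653662   17.720924
```

So in this simulated population 48 patients carried a diabetes code by the
end of 2008, over 291.8 person-years of eligible follow-up — a prevalence
of 16.4 per 100 person-years, drifting up to 17.7 by 2012 as the prevalent
pool accumulates. The same table collapses to a survival cohort and a
matched case-control set:

```python
practices = ek.select_events(db, "Practice")
cohort = ek.build_cohort(terms.merge(practices, on="practid", how="left"),
                         "prev", "2006-01-01", "2012-12-31", "eventdate")
matched = ek.get_matches(cohort[cohort.case == 1], cohort[cohort.case == 0],
                         ["gender", "region"], n_controls=4, seed=1)
print(len(cohort), int(cohort.case.sum()), len(matched))
```

```
390 53 212
```

390 patients enter the cohort, 53 of them cases; risk-set sampling finds
212 gender- and region-matched controls (4 per case, one case short of a
full set in its stratum).

A thin CLI mirrors the library — `ehr simulate`, `ehr import`, `ehr query`,
`ehr extract`, `ehr prevalence`, `ehr cutv`, `ehr match`,
`ehr codelist build`, `ehr units hba1c`, `ehr schema show`, `ehr export` —
see `ehr --help`.

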