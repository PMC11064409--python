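# Data dictionary

A cohort is five delimited tables in one directory (CSV; `.csv.gz`
accepted).  Dates and timestamps are ISO-8601, timezone-naive.  A bare
date in a timestamp column is read as midnight; a bare date in an
encounter `end` column is read as spanning the whole day (the following
midnight).  All events must fall within `[birth, birth + 1095 days]`;
later rows are dropped at load time with a log line.

## children.csv

| column | type | notes |
|---|---|---|
| child_id | string | unique |
| mother_id | string | |
| birth_date | date | |
| gestational_age_days | integer | must be in [140, 315]; < 259 (37 completed weeks) is pre-term |
| death_date | date, optional | ≥ birth_date |

## encounters.csv

| column | type | notes |
|---|---|---|
| encounter_id | string | unique |
| child_id | string | must exist in children |
| encounter_class | enum | `inpatient`, `emergency`, `outpatient`, `icu`, `cticu`, `specialist_visit` |
| specialty | string, optional | required iff class is `specialist_visit` |
| start | timestamp | |
| end | timestamp, optional | ≥ start; empty means open-ended (censored at the window) |
| discharge_disposition | string, optional | death dispositions: `expired`, `funeral home`, `morgue`, `organ harvest` |

## diagnoses.csv

| column | type | notes |
|---|---|---|
| child_id | string | |
| icd_code | string | matched against configured code sets (prefix by default) |
| date | date | |
| encounter_id | string | must resolve to an encounter of the same child |

## procedures.csv

| column | type | notes |
|---|---|---|
| child_id | string | |
| code | string | |
| name | string | free text; matched by keyword rules |
| date | date | |
| status | enum | `completed`, `cancelled`, `preliminary`, `final`; cancelled orders are never considered |
| is_surgical | 0/1 | anchors the respiratory-support perioperative window |
| is_cardiothoracic | 0/1 | identifies heart surgeries |

## lab_orders.csv

| column | type | notes |
|---|---|---|
| child_id | string | |
| category | enum | `genetic_test`, `metabolic_test`, `imaging_ct`, `imaging_mri`, `other` |
| date | date | |
| status | enum | as for procedures |

## truth.csv (synthetic cohorts only)

One row per child: `child_id`, `term_status`, `has_disorder`, plus the 13
intended criterion flags named by criterion id.  This latent table is
never read by the criteria engine.
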