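# Methods

## The phenotype

`pheindex` implements a computable phenotype for children aged 0–3 whose
pattern of healthcare utilization suggests an undiagnosed rare genetic
disorder.  The phenotype is deliberately *global*: rather than matching
disease-specific codes (most rare disorders have none), it scores
thirteen expert-defined criteria covering multi-system specialist care,
hospital utilization, intensive support, diagnostic work-up and death.
Each criterion is a deterministic rule over structured EMR events in the
child's first 1095 days; five are major (score 3) and eight minor (score
1–2).  The severity score is the sum over met criteria; the binary
classification is positive when ≥ 2 majors, ≥ 1 major + ≥ 1 minor, ≥ 5
minors, or death.  The a→b→c→d trigger precedence is reporting-only and
never changes the binary outcome.

A note on the score range: the criterion scores sum to 25 for full-term
children (5×3 + 2×2 + 6×1) and 22 pre-term, although the phenotype is
often described with a 0–24 range.  We follow the per-criterion score
arithmetic — the constants live in the versioned config
(`pheindex/data/criteria.yaml`), not in code.

## Rule semantics and edge cases

* **Term status.** Pre-term is gestational age < 259 days (37 completed
  weeks), the clinical standard; the threshold is a config value.  Four
  rules are term-specific; the NICU rule is defined only for full-term
  children, because pre-term infants stay in the NICU for prematurity
  itself.
* **NICU inference.** De-identified extracts rarely carry a NICU flag, so
  a NICU admission is inferred as an ICU-class encounter starting within
  7 days of birth (start ≤ birth + 7 d).  This inference is the main known
  source of extraction error for that criterion.
* **Hospitalization episodes.** Overlapping or contiguous (zero-gap)
  inpatient encounters are merged into one episode — a transfer is not a
  new hospitalization.  Whether the source phenotype merged transfers is
  not specified; merging is our choice and avoids double-counting.
  Episodes are eligible when ≥ 48 h long and admitted after 245 days
  (35 weeks) postmenstrual age; the first newborn encounter is excluded
  outright when it begins before 245 days PMA, even if it extends past it
  (a literal reading of the rule).  Open-ended stays are censored at the
  observation limit and flagged.
* **Perioperative ventilation.** A tracheostomy/ventilation/CPAP event on
  day *d* qualifies only if, for *every* surgery day *s*, d ≤ s−1 or
  d ≥ s+5.  "1 day before" is read as *at least* one day before.  Heart
  surgeries (CTICU encounters or cardiothoracic procedures) anchor the
  window along with any procedure flagged surgical.  This is the one rule
  that is not monotone under adding events: a new surgery can invalidate
  a previously qualifying ventilation event.
* **Counting conventions.** Specialist types are counted, not visits,
  over a closed 20-type taxonomy (the combined gastroenterology/hepatology
  service is represented as two labels, Pediatric GI and Pediatric Liver,
  to keep the canonical count of twenty); Pediatric Infectious Disease is
  excluded because infections are predominantly environmental.
  Developmental-delay ICD occurrences are counted on distinct calendar
  dates (guards against same-day duplicate coding); metabolic-disease
  codes on distinct encounters; ER visits as distinct emergency
  encounters with no same-day collapsing (no collapsing rule is given).
* **Cancelled orders** are never considered, anywhere.
* **first-met ages.** Each met criterion records the age at which its
  condition first became true given the record up to that day — e.g. the
  admission of the second qualifying hospitalization plus 48 h, or an ICU
  admission plus the 4-day minimum stay.
* **Censoring.** Events after day 1095 are dropped at load time;
  censoring is idempotent.

## Vocabularies

Code-based rules are grounded in configurable code sets (two-column CSV,
exact or prefix matching).  Prefix matching is the default so a curated
stem matches all child codes regardless of ICD-9/10 depth.  The shipped
lists (`*.synthetic.csv`) are clinically plausible placeholders that make
the package runnable and testable — they are **not** validated clinical
code lists, and real deployments must supply their own.  Keyword rules
are OR-of-AND case-insensitive substring clauses over procedure names
(e.g. feeding support: "nasogastric", or "gastrostomy"+"feed", or
"gastrostomy"+"tube").

## Validation machinery

Chart-review gold labels are `has_disease` / `no_disease` / `unknown`;
unknowns are excluded before confusion counting.  Metrics are reported
rounded to the nearest integer percent (exact fractions retained);
zero-denominator metrics are `None` and flagged, never silently 0.  The
prevalence-adjusted PPV uses the standard Bayes correction
sens·p / (sens·p + (1−spec)(1−p)); at 90%/97% and 3% prevalence this
gives 48.1%.  The chart-review sampler draws a fixed number of
classified-positive and classified-negative children whose scores span
each stratum's range (decile-binned round-robin, remainder uniform,
deterministic given a seed).

## The synthetic generator

The generator emulates the study conditions of a large urban delivery
cohort: 12.5% pre-term births, a latent disorder prevalence of 3%, and
per-criterion population frequencies — ER visits 4.2%, developmental
delay 3.4%, multiple specialists 3.3%, feeding support 0.14%, metabolic
ICD 0.09% are set to reported utilization rates; the remaining
frequencies (imaging 2%, hospitalizations 1.2%, genetic tests 0.8%,
metabolic tests 0.6%, NICU 0.6% of full-term, respiratory support 0.3%,
heart surgery 0.4%, death 0.2%) are plausible interpolations fixed once
at design time.  Disorder-carrying children have each criterion rate
multiplied (6–60×, hardest for the most disorder-specific criteria); the
per-arm rates are back-solved so the *population marginal* of each
criterion equals its configured frequency exactly.  Under the defaults
this yields ≈1% classification-positive children, ≈86% with zero criteria
and ≈98% with score ≤ 2, and a population sensitivity against the latent
disorder of ≈0.27 with specificity ≈0.997 — a flag rate of roughly a
third of true prevalence, consistent with a phenotype that detects only
children already presenting with illness.

Event emission is *minimal witness + decoys*: an intended criterion gets
the smallest event pattern its rule provably detects; an unintended one
gets only sub-threshold noise (four ER visits, an ICU stay outside the
birth window or under 4 days, a cancelled gastrostomy order,
perioperative-only ventilation, a single developmental-delay date, one
routine pre-term birth hospitalization beginning before 35 w PMA, ...).
This keeps every rule's boundary permanently exercised and makes the
engine-vs-generator contract exact: at zero noise, `evaluate_all`
recovers every intent.

Criterion co-occurrence beyond the shared latent disorder is induced by
marginal-preserving membership swaps: for a configured (a, b, target-J)
pair, b-positives outside a's positive set are exchanged for b-negatives
inside it until the Jaccard index reaches the target (feasible maximum
and a warning otherwise).  The default pair couples heart surgery and
NICU stay at J = 0.44 in the full-term stratum; the full-term NICU and
heart-surgery marginals (0.6% and 0.4%) were chosen, absent reported
values, so that this target is feasible (J cannot exceed
min(n_a, n_b)/max(n_a, n_b)).

Because intents are conditionally independent Bernoullis given (term,
disorder), the expected sensitivity/specificity/positive-rate implied by
a config can be computed exactly by enumerating the 2^13 intent patterns
(`expected_classification_rates`); parameter-recovery tests compare
simulation against this closed-form oracle (with pairwise coupling
disabled, since coupling breaks conditional independence).

Documentation noise (`inject_documentation_noise`) flips the
engine-visible status of a criterion for a configured fraction of
children — intended criteria lose their witness events, unintended ones
gain a minimal witness — mimicking the incomplete documentation of orders
seen in real EMRs.  Flips are applied among children for whom the
criterion is applicable and expressible (NICU: full-term children), so
criterion-accuracy experiments are run on the applicable stratum; with a
0.19 NICU flip rate the measured NICU extraction accuracy is ≈81%, and
the default error-rate profile (`DOCUMENTATION_ERROR_RATES`) yields a
mean per-criterion accuracy of ≈94%.  Cross-criterion side effects of a
flip (an added heart surgery shifting the perioperative window) make the
realised rate approximate rather than exact.

### What the generator does not emulate

Real demographic structure, insurance/socioeconomic fields, mother-side
clinical data, clinical narratives, seasonal/calendar effects,
competing-risk censoring of events after death, and realistic ICD
co-coding patterns.  Passing tests therefore demonstrate that the rule
engine, scoring, analytics and validation machinery are correct with
respect to the stated rule semantics — not that the phenotype's clinical
performance transfers to any particular health system's data.

## Problem sizes and numerical choices

Default experiment sizes are 5,000 children for documentation-noise
experiments and 20,000 for rate-recovery and co-occurrence experiments —
large enough that 3-SE binomial bands are a few tenths of a percent while
a full pipeline run stays in seconds.  Stochastic checks use 3-SD/3-SE
bands throughout and fixed seeds.  Percentages are reported to two
decimals; undefined Jaccard pairs (empty union) are NaN rather than 0;
curves are right-continuous empirical CDFs normalized among met children.
Dates are ISO-8601 without time zones; durations are computed on
timestamps, with bare-date encounter ends interpreted as spanning the
whole day.

## Known limitations

* The shipped code sets are placeholders; criterion behaviour on real
  data depends entirely on the curated lists supplied.
* The NICU criterion inherits the ICU-within-7-days inference and is the
  least reliable extraction in practice.
* The prevalence-adjusted PPV uses the standard Bayes correction; other
  published adjustment variants can differ by a few tenths of a percent
  at the upper prevalence end.
* The generator's unlisted criterion frequencies and multipliers are
  design choices, not measured quantities; cohort-level outputs (e.g.
  fraction with zero criteria) are properties of those choices.
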