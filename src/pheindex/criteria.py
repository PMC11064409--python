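"""The 13-criterion phenotyping engine.

Each criterion is a deterministic rule over one child's structured event
streams (encounters, diagnoses, procedures, lab orders) restricted to the
first three years of life.  Five criteria are *major* (score 3): prolonged
NICU stay, prolonged/multiple hospitalizations, in-hospital death,
metabolic-disease diagnosis codes, heart surgery.  The remaining eight are
*minor*: feeding support and respiratory support score 2, the rest score 1.
Four rules are term-specific (thresholds differ for pre-term vs full-term
children), and the NICU rule is defined only for full-term children —
pre-term infants routinely stay in the NICU for prematurity itself, so a
long NICU stay carries no signal about an underlying genetic disorder.

Every evaluator returns a :class:`CriterionResult` carrying the met flag,
the number of supporting events, and the age in days at which the rule
first became satisfiable given the record up to that day.

Cancelled orders are never considered, matching how order data are cleaned
upstream of the rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd
import yaml

from .emr import (
    ChildBundle,
    Cohort,
    Episode,
    OK_STATUSES,
    TermStatus,
    hospitalization_episodes,
    postmenstrual_age,
)
from .vocabulary import Vocabulary, default_vocabulary

__all__ = [
    "CRITERIA",
    "MAJOR_CRITERIA",
    "MINOR_CRITERIA",
    "CriterionSpec",
    "CriterionResult",
    "CriteriaProfile",
    "load_criteria_config",
    "default_specs",
    "evaluate_all",
    "evaluate_cohort",
    "max_score",
]

#: Canonical criterion order (used everywhere a criterion vector appears).
CRITERIA: tuple[str, ...] = (
    "nicu_stay",
    "hospitalizations",
    "multiple_specialists",
    "er_visits",
    "feeding_support",
    "respiratory_support",
    "imaging",
    "genetic_tests",
    "metabolic_tests",
    "death",
    "developmental_delay",
    "metabolic_icd",
    "heart_surgery",
)

MAJOR_CRITERIA = frozenset(
    {"nicu_stay", "hospitalizations", "death", "metabolic_icd", "heart_surgery"}
)
MINOR_CRITERIA = frozenset(CRITERIA) - MAJOR_CRITERIA


@dataclass(frozen=True)
class CriterionSpec:
    id: str
    tier: str  # "major" | "minor"
    score: int
    thresholds: Mapping[str, object] = field(default_factory=dict)

    def threshold(self, name: str, term_status: TermStatus | None = None):
        value = self.thresholds[name]
        if isinstance(value, Mapping):
            if term_status is None:
                raise KeyError(f"{self.id}.{name} is term-specific")
            return value[term_status.value]
        return value


@dataclass(frozen=True)
class CriterionResult:
    id: str
    met: bool
    first_met_age: float | None = None
    evidence_count: int = 0

    def __post_init__(self) -> None:
        if self.met and self.first_met_age is None:
            raise ValueError(f"{self.id}: met without a first_met_age")
        if not self.met and self.first_met_age is not None:
            raise ValueError(f"{self.id}: first_met_age on an unmet criterion")


@dataclass(frozen=True)
class CriteriaProfile:
    child_id: str
    term_status: TermStatus
    results: Mapping[str, CriterionResult]

    def __post_init__(self) -> None:
        if set(self.results) != set(CRITERIA):
            raise ValueError("profile must hold exactly the 13 criterion results")
        if self.term_status is TermStatus.PRE_TERM and self.results["nicu_stay"].met:
            raise ValueError("NICU criterion is not applicable to pre-term children")

    def met_ids(self) -> set[str]:
        return {cid for cid, r in self.results.items() if r.met}


def load_criteria_config(path: str | Path | None = None) -> dict[str, CriterionSpec]:
    """Load criterion tiers/scores/thresholds from a YAML config (the
    package's versioned default when ``path`` is omitted)."""
    if path is None:
        path = Path(resources.files("pheindex").joinpath("data", "criteria.yaml"))  # type: ignore[arg-type]
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = {}
    for cid, entry in raw["criteria"].items():
        if cid not in CRITERIA:
            raise ValueError(f"unknown criterion id {cid!r} in {path}")
        specs[cid] = CriterionSpec(
            id=cid,
            tier=entry["tier"],
            score=int(entry["score"]),
            thresholds=entry.get("thresholds") or {},
        )
    missing = set(CRITERIA) - set(specs)
    if missing:
        raise ValueError(f"criteria config missing {sorted(missing)}")
    return specs


def default_specs() -> dict[str, CriterionSpec]:
    return load_criteria_config()


def max_score(term_status: TermStatus, specs: Mapping[str, CriterionSpec] | None = None) -> int:
    """Sum of applicable criterion scores (25 full-term, 22 pre-term with
    the default config — the NICU criterion does not apply pre-term)."""
    specs = specs or default_specs()
    total = sum(s.score for s in specs.values())
    if term_status is TermStatus.PRE_TERM:
        total -= specs["nicu_stay"].score
    return total


# ---------------------------------------------------------------------------
# Individual criterion evaluators


def _not_met(cid: str) -> CriterionResult:
    return CriterionResult(id=cid, met=False)


def _age(bundle: ChildBundle, when: pd.Timestamp) -> float:
    return bundle.age_days(when)


def evaluate_nicu_stay(bundle: ChildBundle, spec: CriterionSpec) -> CriterionResult:
    """Full-term children only: an ICU-class encounter starting within 7
    days of birth with a stay of at least 4 days.  NICU admissions are
    inferred from early ICU encounters because de-identified EMR extracts
    typically carry no explicit NICU flag."""
    if bundle.term_status is TermStatus.PRE_TERM:
        return _not_met("nicu_stay")
    window = pd.Timedelta(days=spec.threshold("admit_window_days"))
    min_stay = pd.Timedelta(days=spec.threshold("min_stay_days"))
    birth = bundle.child.birth_date
    hits = []
    for e in bundle.encounters:
        if e.encounter_class != "icu":
            continue
        if e.start > birth + window:
            continue
        end = e.end if e.end is not None else bundle.observation_end
        if end - e.start >= min_stay:
            hits.append(e)
    if not hits:
        return _not_met("nicu_stay")
    first = min(_age(bundle, e.start) for e in hits) + spec.threshold("min_stay_days")
    return CriterionResult("nicu_stay", True, first_met_age=first, evidence_count=len(hits))


def _eligible_episodes(bundle: ChildBundle, spec: CriterionSpec) -> list[Episode]:
    episodes = hospitalization_episodes(bundle.encounters, bundle.observation_end)
    min_hours = spec.threshold("min_episode_hours")
    pma_floor = spec.threshold("pma_floor_days")
    eligible = []
    for i, ep in enumerate(episodes):
        pma = postmenstrual_age(bundle.child, ep.start)
        if i == 0 and pma < pma_floor:
            # the first newborn encounter, beginning before 35 weeks PMA,
            # is excluded even if it extends past 35 weeks
            continue
        if pma <= pma_floor:
            continue
        if ep.duration_hours >= min_hours:
            eligible.append(ep)
    return eligible


def evaluate_hospitalizations(bundle: ChildBundle, spec: CriterionSpec) -> CriterionResult:
    """Either one prolonged hospitalization (>= 14 days) or at least 2
    (full-term) / 3 (pre-term) hospitalizations of >= 48 h, counting only
    stays admitted after 35 weeks postmenstrual age and excluding the
    birth hospitalization of very pre-term infants."""
    eligible = _eligible_episodes(bundle, spec)
    if not eligible:
        return _not_met("hospitalizations")
    prolonged_days = spec.threshold("prolonged_days")
    need = spec.threshold("min_count", bundle.term_status)
    times: list[float] = []
    for ep in eligible:
        if ep.duration_hours >= prolonged_days * 24:
            times.append(_age(bundle, ep.start) + prolonged_days)
    if len(eligible) >= need:
        qualify_ages = sorted(
            _age(bundle, ep.start) + spec.threshold("min_episode_hours") / 24.0
            for ep in eligible
        )
        times.append(qualify_ages[need - 1])
    if not times:
        return _not_met("hospitalizations")
    return CriterionResult(
        "hospitalizations",
        True,
        first_met_age=min(times),
        evidence_count=len(eligible),
    )


def evaluate_multiple_specialists(
    bundle: ChildBundle, spec: CriterionSpec, vocab: Vocabulary
) -> CriterionResult:
    """At least 3 (full-term) / 4 (pre-term) distinct specialist *types*
    visited, over a closed taxonomy; excluded specialties never count."""
    need = spec.threshold("min_types", bundle.term_status)
    visits = sorted(
        (e for e in bundle.encounters if e.encounter_class == "specialist_visit"),
        key=lambda e: e.start,
    )
    seen: set[str] = set()
    first_age = None
    for e in visits:
        if e.specialty is None or not vocab.taxonomy.counts(e.specialty):
            continue
        if e.specialty not in seen:
            seen.add(e.specialty)
            if len(seen) == need:
                first_age = _age(bundle, e.start)
    if len(seen) < need:
        return CriterionResult("multiple_specialists", False, evidence_count=len(seen))
    return CriterionResult(
        "multiple_specialists", True, first_met_age=first_age, evidence_count=len(seen)
    )


def evaluate_er_visits(bundle: ChildBundle, spec: CriterionSpec) -> CriterionResult:
    """At least 5 (full-term) / 7 (pre-term) emergency encounters; distinct
    encounters on one day all count."""
    need = spec.threshold("min_visits", bundle.term_status)
    visits = sorted(
        (e for e in bundle.encounters if e.encounter_class == "emergency"),
        key=lambda e: e.start,
    )
    if len(visits) < need:
        return CriterionResult("er_visits", False, evidence_count=len(visits))
    return CriterionResult(
        "er_visits",
        True,
        first_met_age=_age(bundle, visits[need - 1].start),
        evidence_count=len(visits),
    )


def evaluate_feeding_support(
    bundle: ChildBundle, spec: CriterionSpec, vocab: Vocabulary
) -> CriterionResult:
    """A feeding-support diagnosis code, or a non-cancelled procedure whose
    name mentions nasogastric / gastrostomy feeding or a gastrostomy tube."""
    dates = []
    for d in bundle.diagnoses:
        if vocab.feeding_codes.matches(d.icd_code):
            dates.append(d.date)
    for p in bundle.procedures:
        if p.status == "cancelled":
            continue
        if vocab.feeding_rule.matches(p.name):
            dates.append(p.date)
    if not dates:
        return _not_met("feeding_support")
    return CriterionResult(
        "feeding_support",
        True,
        first_met_age=_age(bundle, min(dates)),
        evidence_count=len(dates),
    )


def _surgery_dates(bundle: ChildBundle) -> list[pd.Timestamp]:
    dates = [
        p.date.normalize()
        for p in bundle.procedures
        if p.is_surgical and p.status != "cancelled"
    ]
    # cardiothoracic-ICU encounters stand in for heart surgeries
    dates += [
        e.start.normalize() for e in bundle.encounters if e.encounter_class == "cticu"
    ]
    return sorted(set(dates))


def evaluate_respiratory_support(
    bundle: ChildBundle, spec: CriterionSpec, vocab: Vocabulary
) -> CriterionResult:
    """Tracheostomy / ventilation (incl. CPAP) outside the perioperative
    window: the event date d must satisfy, for *every* surgery date s,
    d <= s - days_before or d >= s + days_after.  With no surgeries, any
    such event qualifies.  This is the one rule that is not monotone under
    adding events — a new surgery can invalidate a previously-qualifying
    ventilation event."""
    before = pd.Timedelta(days=spec.threshold("days_before"))
    after = pd.Timedelta(days=spec.threshold("days_after"))
    events = []
    for p in bundle.procedures:
        if p.status == "cancelled":
            continue
        if vocab.respiratory_rule.matches(p.name) or vocab.respiratory_codes.matches(p.code):
            events.append(p.date.normalize())
    for d in bundle.diagnoses:
        if vocab.respiratory_codes.matches(d.icd_code):
            events.append(d.date.normalize())
    surgeries = _surgery_dates(bundle)
    qualifying = [
        d
        for d in events
        if all(d <= s - before or d >= s + after for s in surgeries)
    ]
    if not qualifying:
        return CriterionResult("respiratory_support", False, evidence_count=len(events))
    return CriterionResult(
        "respiratory_support",
        True,
        first_met_age=_age(bundle, min(qualifying)),
        evidence_count=len(qualifying),
    )


_ORDER_CATEGORIES = {
    "imaging": ("imaging_ct", "imaging_mri"),
    "genetic_tests": ("genetic_test",),
    "metabolic_tests": ("metabolic_test",),
}


def evaluate_order_criterion(
    bundle: ChildBundle, spec: CriterionSpec, category: str
) -> CriterionResult:
    """Imaging (CT/MRI), genetic or metabolic diagnostic tests: at least
    one order with completed / preliminary / final status, regardless of
    the test result."""
    if category not in _ORDER_CATEGORIES:
        raise ValueError(f"unknown order criterion {category!r}")
    wanted = _ORDER_CATEGORIES[category]
    dates = [
        o.date
        for o in bundle.lab_orders
        if o.category in wanted and o.status in OK_STATUSES
    ]
    if not dates:
        return _not_met(category)
    return CriterionResult(
        category, True, first_met_age=_age(bundle, min(dates)), evidence_count=len(dates)
    )


def evaluate_death(
    bundle: ChildBundle, spec: CriterionSpec, vocab: Vocabulary
) -> CriterionResult:
    """In-hospital death: a death discharge disposition (expired, funeral
    home / morgue, organ harvest) or an explicit death date in the window."""
    dates = []
    for e in bundle.encounters:
        if vocab.is_death_disposition(e.discharge_disposition):
            dates.append(e.end if e.end is not None else e.start)
    dd = bundle.child.death_date
    if dd is not None and dd <= bundle.observation_end:
        dates.append(dd)
    if not dates:
        return _not_met("death")
    return CriterionResult(
        "death", True, first_met_age=_age(bundle, min(dates)), evidence_count=len(dates)
    )


def evaluate_developmental_delay(
    bundle: ChildBundle, spec: CriterionSpec, vocab: Vocabulary
) -> CriterionResult:
    """A developmental-pediatrician visit, or developmental-delay ICD codes
    on at least two distinct calendar dates."""
    visit_ages = [
        _age(bundle, e.start)
        for e in bundle.encounters
        if e.encounter_class == "specialist_visit"
        and e.specialty == vocab.developmental_specialty
    ]
    icd_dates = sorted(
        {
            d.date.normalize()
            for d in bundle.diagnoses
            if vocab.developmental_delay_codes.matches(d.icd_code)
        }
    )
    need = spec.threshold("min_icd_dates")
    times = []
    if visit_ages:
        times.append(min(visit_ages))
    if len(icd_dates) >= need:
        times.append(_age(bundle, icd_dates[need - 1]))
    count = len(visit_ages) + len(icd_dates)
    if not times:
        return CriterionResult("developmental_delay", False, evidence_count=count)
    return CriterionResult(
        "developmental_delay", True, first_met_age=min(times), evidence_count=count
    )


def evaluate_metabolic_icd(
    bundle: ChildBundle, spec: CriterionSpec, vocab: Vocabulary
) -> CriterionResult:
    """Metabolic-disease diagnosis codes appearing in at least two distinct
    encounters."""
    need = spec.threshold("min_encounters")
    hits = sorted(
        (d for d in bundle.diagnoses if vocab.metabolic_codes.matches(d.icd_code)),
        key=lambda d: d.date,
    )
    seen: set[str] = set()
    first_age = None
    for d in hits:
        if d.encounter_id not in seen:
            seen.add(d.encounter_id)
            if len(seen) == need:
                first_age = _age(bundle, d.date)
    if len(seen) < need:
        return CriterionResult("metabolic_icd", False, evidence_count=len(seen))
    return CriterionResult(
        "metabolic_icd", True, first_met_age=first_age, evidence_count=len(seen)
    )


def evaluate_heart_surgery(bundle: ChildBundle, spec: CriterionSpec) -> CriterionResult:
    """Cardiothoracic surgery: a CTICU encounter or a non-cancelled
    procedure flagged cardiothoracic-surgical."""
    dates = [e.start for e in bundle.encounters if e.encounter_class == "cticu"]
    dates += [
        p.date
        for p in bundle.procedures
        if p.is_cardiothoracic and p.status != "cancelled"
    ]
    if not dates:
        return _not_met("heart_surgery")
    return CriterionResult(
        "heart_surgery", True, first_met_age=_age(bundle, min(dates)), evidence_count=len(dates)
    )


# ---------------------------------------------------------------------------
# Composition


def evaluate_all(
    bundle: ChildBundle,
    specs: Mapping[str, CriterionSpec] | None = None,
    vocab: Vocabulary | None = None,
) -> CriteriaProfile:
    """Evaluate all 13 criteria for one child."""
    specs = specs or default_specs()
    vocab = vocab or default_vocabulary()
    results = {
        "nicu_stay": evaluate_nicu_stay(bundle, specs["nicu_stay"]),
        "hospitalizations": evaluate_hospitalizations(bundle, specs["hospitalizations"]),
        "multiple_specialists": evaluate_multiple_specialists(
            bundle, specs["multiple_specialists"], vocab
        ),
        "er_visits": evaluate_er_visits(bundle, specs["er_visits"]),
        "feeding_support": evaluate_feeding_support(bundle, specs["feeding_support"], vocab),
        "respiratory_support": evaluate_respiratory_support(
            bundle, specs["respiratory_support"], vocab
        ),
        "imaging": evaluate_order_criterion(bundle, specs["imaging"], "imaging"),
        "genetic_tests": evaluate_order_criterion(bundle, specs["genetic_tests"], "genetic_tests"),
        "metabolic_tests": evaluate_order_criterion(
            bundle, specs["metabolic_tests"], "metabolic_tests"
        ),
        "death": evaluate_death(bundle, specs["death"], vocab),
        "developmental_delay": evaluate_developmental_delay(
            bundle, specs["developmental_delay"], vocab
        ),
        "metabolic_icd": evaluate_metabolic_icd(bundle, specs["metabolic_icd"], vocab),
        "heart_surgery": evaluate_heart_surgery(bundle, specs["heart_surgery"]),
    }
    return CriteriaProfile(
        child_id=bundle.child.child_id,
        term_status=bundle.term_status,
        results=results,
    )


def profile_frame(profiles: list[CriteriaProfile]) -> pd.DataFrame:
    """Tabulate profiles: one row per child, boolean criterion columns plus
    ``first_met_<criterion>`` ages (NaN where unmet)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "child_id": p.child_id,
            "term_status": p.term_status.value,
        }
        for cid in CRITERIA:
            r = p.results[cid]
            row[cid] = bool(r.met)
            row[f"first_met_{cid}"] = (
                float(r.first_met_age) if r.first_met_age is not None else float("nan")
            )
        rows.append(row)
    cols = (
        ["child_id", "term_status"]
        + list(CRITERIA)
        + [f"first_met_{c}" for c in CRITERIA]
    )
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def evaluate_cohort(
    cohort: Cohort,
    specs: Mapping[str, CriterionSpec] | None = None,
    vocab: Vocabulary | None = None,
) -> pd.DataFrame:
    """Evaluate every child in a cohort; returns the tabulated profiles."""
    specs = specs or default_specs()
    vocab = vocab or default_vocabulary()
    profiles = [evaluate_all(b, specs, vocab) for b in cohort.bundles()]
    return profile_frame(profiles)
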