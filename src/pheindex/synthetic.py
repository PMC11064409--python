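"""Synthetic mother–child EMR cohort generator.

The generator emulates the study conditions the phenotyping pipeline is
meant for: a birth cohort with a ~12.5% pre-term fraction, a latent rare
genetic-disorder status at ~3% prevalence, per-criterion population
frequencies on the order observed in large delivery cohorts (multiple ER
visits ~4.2%, developmental delay ~3.4%, multiple specialists ~3.3%,
metabolic diagnosis codes ~0.09%, feeding support ~0.14%), and criterion
co-occurrence induced both by the shared latent disorder and by explicit
pairwise coupling (heart surgery × prolonged NICU stay, Jaccard 0.44 in
the full-term stratum).

Generation is "minimal witness + decoys": for each criterion a child is
intended to meet, the smallest event pattern that the corresponding rule
provably detects is emitted; for criteria the child is not intended to
meet, only sub-threshold noise is emitted (four ER visits, a cancelled
gastrostomy order, an ICU stay outside the 7-day birth window, ...), so
the boundary behaviour of every rule is exercised constantly.

The latent truth (disorder status and intended criterion vector) is
returned separately and never surfaces in the EMR tables, enabling
parameter-recovery experiments.  Base rates are population marginals: the
per-arm Bernoulli rates are back-solved from the disorder multiplier so
the emitted marginal equals the configured frequency.

``inject_documentation_noise`` degrades the emitted record so the engine's
extraction disagrees with the latent truth at a configured per-criterion
rate, mimicking incomplete documentation of orders in real EMRs and
enabling chart-review-style per-criterion accuracy experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .criteria import CRITERIA, CriterionSpec, default_specs
from .emr import (
    Cohort,
    OBSERVATION_LIMIT_DAYS,
    TermStatus,
    normalize_table,
)
from .scoring import classify_matrix
from .vocabulary import Vocabulary, default_vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "inject_documentation_noise",
    "expected_classification_rates",
    "DEFAULT_BASE_RATES",
    "DEFAULT_MULTIPLIERS",
    "DOCUMENTATION_ERROR_RATES",
]

#: Population marginal frequency of each criterion (full-term stratum for
#: the NICU criterion, which does not exist pre-term).  The ER-visit,
#: developmental-delay, multiple-specialist, metabolic-ICD and
#: feeding-support values follow reported cohort frequencies; the rest are
#: plausible interpolations chosen once (see the methods note) — they are
#: not reported values.
DEFAULT_BASE_RATES: dict[str, float] = {
    "nicu_stay": 0.006,
    "hospitalizations": 0.012,
    "multiple_specialists": 0.033,
    "er_visits": 0.042,
    "feeding_support": 0.0014,
    "respiratory_support": 0.003,
    "imaging": 0.020,
    "genetic_tests": 0.008,
    "metabolic_tests": 0.006,
    "death": 0.002,
    "developmental_delay": 0.034,
    "metabolic_icd": 0.0009,
    "heart_surgery": 0.004,
}

#: Rate multiplier applied to children carrying the latent disorder.
#: Major/high-specificity criteria are boosted hardest so that criteria
#: co-occur in the disorder subpopulation.
DEFAULT_MULTIPLIERS: dict[str, float] = {
    "nicu_stay": 25.0,
    "hospitalizations": 30.0,
    "multiple_specialists": 12.0,
    "er_visits": 6.0,
    "feeding_support": 40.0,
    "respiratory_support": 40.0,
    "imaging": 10.0,
    "genetic_tests": 30.0,
    "metabolic_tests": 30.0,
    "death": 20.0,
    "developmental_delay": 12.0,
    "metabolic_icd": 60.0,
    "heart_surgery": 40.0,
}

#: Per-criterion EMR documentation error rates patterned on the agreement
#: typically observed between structured-data extraction and manual chart
#: review (NICU stays are the hardest to recover from de-identified data
#: because the NICU flag must be inferred from early ICU encounters).
DOCUMENTATION_ERROR_RATES: dict[str, float] = {
    "nicu_stay": 0.19,
    "hospitalizations": 0.02,
    "multiple_specialists": 0.07,
    "er_visits": 0.06,
    "feeding_support": 0.04,
    "respiratory_support": 0.10,
    "imaging": 0.03,
    "genetic_tests": 0.04,
    "metabolic_tests": 0.04,
    "death": 0.02,
    "developmental_delay": 0.07,
    "metabolic_icd": 0.03,
    "heart_surgery": 0.03,
}

# Decoy (sub-threshold noise) emission probabilities.
_DECOY_P = {
    "nicu": 0.02,
    "preterm_routine_nicu": 0.5,
    "preterm_birth_stay": 0.5,
    "hosp": 0.04,
    "short_stay": 0.03,
    "specialists": 0.12,
    "infectious_disease_visit": 0.04,
    "surgery": 0.05,
    "feeding": 0.015,
    "resp_periop": 0.3,
    "order_cancelled": 0.02,
    "dev_single": 0.03,
    "metabolic_single_encounter": 0.008,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_children: int = 1000
    preterm_fraction: float = 0.125
    disorder_prevalence: float = 0.03
    base_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    disorder_rate_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    co_occurrence_pairs: tuple[tuple[str, str, float], ...] = (
        ("heart_surgery", "nicu_stay", 0.44),
    )
    documentation_flip_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    start_date: str = "2015-01-01"
    observation_limit_days: int = OBSERVATION_LIMIT_DAYS

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        for name, v in (
            ("preterm_fraction", self.preterm_fraction),
            ("disorder_prevalence", self.disorder_prevalence),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for cid, v in self.base_rates.items():
            if cid not in CRITERIA:
                raise ValueError(f"unknown criterion in base_rates: {cid!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"base rate for {cid} must be in [0, 1]")
        for cid, v in self.disorder_rate_multipliers.items():
            if v < 1.0:
                raise ValueError(f"multiplier for {cid} must be >= 1")
        for cid, v in self.documentation_flip_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"flip rate for {cid} must be in [0, 1]")


def _rate_vector(config: GeneratorConfig, term: TermStatus, disorder: bool) -> np.ndarray:
    """Per-criterion Bernoulli intent rates for one (term, disorder) arm.

    Solves base = (1-p)*r0 + p*m*r0 for r0 so the population marginal of
    each criterion equals its configured base rate.
    """
    p = config.disorder_prevalence
    rates = np.zeros(len(CRITERIA))
    for k, cid in enumerate(CRITERIA):
        f = config.base_rates.get(cid, 0.0)
        m = config.disorder_rate_multipliers.get(cid, 1.0)
        r0 = f / (1.0 - p + p * m)
        r = min(1.0, m * r0) if disorder else r0
        if cid == "nicu_stay" and term is TermStatus.PRE_TERM:
            r = 0.0
        rates[k] = r
    return rates


def _adjust_cooccurrence(
    intents: np.ndarray,
    term: np.ndarray,
    pairs: Sequence[tuple[str, str, float]],
    rng: np.random.Generator,
) -> None:
    """Marginal-preserving pairwise coupling.

    For each (a, b, target-J) pair, membership in criterion b is swapped
    from children outside a's positive set into it until the Jaccard index
    reaches the target (or the feasible maximum, with a warning).  Both
    criterion marginals are preserved exactly.  Pairs involving the NICU
    criterion are adjusted within the full-term stratum only.
    """
    idx = {c: k for k, c in enumerate(CRITERIA)}
    for a, b, target in pairs:
        ka, kb = idx[a], idx[b]
        if "nicu_stay" in (a, b):
            stratum = term == TermStatus.FULL_TERM.value
        else:
            stratum = np.ones(len(intents), dtype=bool)
        A = intents[:, ka] & stratum
        B = intents[:, kb] & stratum
        inter = int((A & B).sum())
        union = int((A | B).sum())
        if union == 0:
            logger.warning("co-occurrence pair (%s, %s): no positives, skipped", a, b)
            continue
        current = inter / union
        if current >= target:
            continue
        need = int(np.ceil((target * union - inter) / (1.0 + target)))
        donors = np.flatnonzero(B & ~A)  # b-positives to move
        receivers = np.flatnonzero(A & ~B)
        k = min(need, len(donors), len(receivers))
        if k > 0:
            take = rng.choice(donors, size=k, replace=False)
            give = rng.choice(receivers, size=k, replace=False)
            intents[take, kb] = False
            intents[give, kb] = True
        achieved = (inter + k) / (union - k) if union > k else float("nan")
        if k < need:
            logger.warning(
                "co-occurrence pair (%s, %s): target J=%.2f infeasible, achieved %.2f",
                a,
                b,
                target,
                achieved,
            )


# ---------------------------------------------------------------------------
# Event emission


class _Builder:
    """Accumulates table rows and hands out identifiers."""

    def __init__(self) -> None:
        self.children: list[tuple] = []
        self.encounters: list[tuple] = []
        self.diagnoses: list[tuple] = []
        self.procedures: list[tuple] = []
        self.lab_orders: list[tuple] = []
        self._enc_n = 0

    def enc_id(self) -> str:
        self._enc_n += 1
        return f"E{self._enc_n:08d}"

    def add_encounter(
        self,
        child_id: str,
        enc_class: str,
        start: pd.Timestamp,
        end: pd.Timestamp | None,
        specialty: str | None = None,
        disposition: str | None = None,
    ) -> str:
        eid = self.enc_id()
        self.encounters.append((eid, child_id, enc_class, specialty, start, end, disposition))
        return eid

    def add_diagnosis(self, child_id: str, code: str, date: pd.Timestamp, enc_id: str) -> None:
        self.diagnoses.append((child_id, code, date, enc_id))

    def add_procedure(
        self,
        child_id: str,
        code: str,
        name: str,
        date: pd.Timestamp,
        status: str = "completed",
        is_surgical: bool = False,
        is_cardiothoracic: bool = False,
    ) -> None:
        self.procedures.append(
            (child_id, code, name, date, status, is_surgical, is_cardiothoracic)
        )

    def add_lab(self, child_id: str, category: str, date: pd.Timestamp, status: str) -> None:
        self.lab_orders.append((child_id, category, date, status))


@dataclass
class _ChildCtx:
    child_id: str
    birth: pd.Timestamp
    ga: int
    term: TermStatus
    surgery_days: list[int] = field(default_factory=list)
    inpatient_spans: list[tuple[float, float]] = field(default_factory=list)

    def day(self, d: float) -> pd.Timestamp:
        return self.birth + pd.Timedelta(days=float(d))


def _alloc_inpatient(
    ctx: _ChildCtx, rng: np.random.Generator, lo: float, hi: float, dur_days: float
) -> float:
    """Pick a start day in [lo, hi] whose stay does not touch (within a
    2-day buffer) any existing inpatient span; falls back to stacking after
    the last span."""
    hi = max(lo, hi)
    for _ in range(50):
        start = float(rng.integers(int(lo), int(hi) + 1))
        if all(
            start + dur_days + 2 <= s or start >= e + 2 for s, e in ctx.inpatient_spans
        ):
            ctx.inpatient_spans.append((start, start + dur_days))
            return start
    start = max([e for _, e in ctx.inpatient_spans], default=lo) + 3
    ctx.inpatient_spans.append((start, start + dur_days))
    return start


def _pick_code(codes: Sequence[str], rng: np.random.Generator) -> str:
    """Draw a code from a prefix code set, sometimes refining the stem with
    an extra digit so prefix matching is exercised."""
    code = codes[int(rng.integers(0, len(codes)))]
    if rng.random() < 0.5:
        digit = str(int(rng.integers(0, 10)))
        code = code + digit if "." in code else code + "." + digit
    return code


_FEEDING_WITNESS_NAMES = (
    "Gastrostomy tube placement",
    "Nasogastric feeding tube insertion",
    "Percutaneous gastrostomy tube change",
)
_RESPIRATORY_WITNESS_NAMES = (
    "Mechanical ventilation",
    "CPAP initiation",
    "Tracheostomy care",
)


def _emit_heart_surgery(b, ctx, rng, met):
    if met:
        if rng.random() < 0.5:
            day = int(rng.integers(0, 900))
            dur = int(rng.integers(2, 10))
            b.add_encounter(
                ctx.child_id, "cticu", ctx.day(day), ctx.day(day + dur)
            )
            ctx.surgery_days.append(day)
        else:
            day = int(rng.integers(0, 950))
            b.add_procedure(
                ctx.child_id,
                "CTS01",
                "Cardiothoracic surgery - congenital defect repair",
                ctx.day(day),
                is_surgical=True,
                is_cardiothoracic=True,
            )
            ctx.surgery_days.append(day)


def _emit_surgery_decoy(b, ctx, rng):
    if rng.random() < _DECOY_P["surgery"]:
        day = int(rng.integers(20, 1000))
        b.add_procedure(
            ctx.child_id,
            "GS001",
            "Inguinal hernia repair",
            ctx.day(day),
            is_surgical=True,
        )
        ctx.surgery_days.append(day)


def _emit_nicu(b, ctx, rng, met, spec: CriterionSpec):
    if ctx.term is TermStatus.PRE_TERM:
        # routine prematurity NICU stay: long, from birth — never a
        # criterion hit because the rule is full-term only
        if rng.random() < _DECOY_P["preterm_routine_nicu"]:
            dur = int(rng.integers(7, 70))
            b.add_encounter(ctx.child_id, "icu", ctx.birth, ctx.day(dur))
        return
    if met:
        day = int(rng.integers(0, spec.threshold("admit_window_days")))
        hour = int(rng.integers(0, 24))
        dur = int(rng.integers(spec.threshold("min_stay_days"), 22))
        start = ctx.day(day) + pd.Timedelta(hours=hour)
        b.add_encounter(ctx.child_id, "icu", start, start + pd.Timedelta(days=dur))
    elif rng.random() < _DECOY_P["nicu"]:
        if rng.random() < 0.5:  # outside the 7-day birth window
            day = int(rng.integers(9, 40))
            dur = int(rng.integers(4, 10))
            b.add_encounter(ctx.child_id, "icu", ctx.day(day), ctx.day(day + dur))
        else:  # inside the window but too short
            day = int(rng.integers(0, 7))
            hours = int(rng.integers(24, 90))
            start = ctx.day(day)
            b.add_encounter(ctx.child_id, "icu", start, start + pd.Timedelta(hours=hours))


def _emit_hospitalizations(b, ctx, rng, met, spec: CriterionSpec):
    lo = max(0, spec.threshold("pma_floor_days") + 1 - ctx.ga)
    if ctx.term is TermStatus.PRE_TERM and ctx.ga <= 230:
        if rng.random() < _DECOY_P["preterm_birth_stay"]:
            dur = int(min(40, lo - 3))
            if dur >= 5:
                dur = int(rng.integers(5, dur + 1))
                ctx.inpatient_spans.append((0.0, float(dur)))
                b.add_encounter(ctx.child_id, "inpatient", ctx.birth, ctx.day(dur))
    if met:
        if rng.random() < 0.4:  # one prolonged stay
            dur = int(rng.integers(spec.threshold("prolonged_days"), 29))
            start = _alloc_inpatient(ctx, rng, lo, 1050 - dur, dur)
            b.add_encounter(ctx.child_id, "inpatient", ctx.day(start), ctx.day(start + dur))
        else:  # the required count of >= 48 h stays
            need = spec.threshold("min_count", ctx.term)
            for _ in range(need):
                dur = int(rng.integers(2, 7))
                start = _alloc_inpatient(ctx, rng, lo, 1000, dur)
                b.add_encounter(
                    ctx.child_id, "inpatient", ctx.day(start), ctx.day(start + dur)
                )
    else:
        if rng.random() < _DECOY_P["hosp"]:
            # below the count threshold
            need = spec.threshold("min_count", ctx.term)
            for _ in range(int(rng.integers(1, need))):
                dur = int(rng.integers(2, 7))
                start = _alloc_inpatient(ctx, rng, lo, 1000, dur)
                b.add_encounter(
                    ctx.child_id, "inpatient", ctx.day(start), ctx.day(start + dur)
                )
        if rng.random() < _DECOY_P["short_stay"]:  # under 48 h, never eligible
            hours = int(rng.integers(10, 40))
            start = _alloc_inpatient(ctx, rng, lo, 1050, hours / 24.0)
            s = ctx.day(start)
            b.add_encounter(ctx.child_id, "inpatient", s, s + pd.Timedelta(hours=hours))


def _emit_specialists(b, ctx, rng, met, spec: CriterionSpec, vocab: Vocabulary):
    included = sorted(vocab.taxonomy.included)
    need = spec.threshold("min_types", ctx.term)
    if met:
        k = need
    elif rng.random() < _DECOY_P["specialists"]:
        k = int(rng.integers(1, need))
    else:
        k = 0
    if k:
        types = rng.choice(len(included), size=k, replace=False)
        for t in types:
            day = int(rng.integers(0, 1000))
            start = ctx.day(day) + pd.Timedelta(hours=10)
            b.add_encounter(
                ctx.child_id,
                "specialist_visit",
                start,
                start + pd.Timedelta(hours=1),
                specialty=included[int(t)],
            )
    if rng.random() < _DECOY_P["infectious_disease_visit"]:
        day = int(rng.integers(0, 1000))
        start = ctx.day(day) + pd.Timedelta(hours=9)
        b.add_encounter(
            ctx.child_id,
            "specialist_visit",
            start,
            start + pd.Timedelta(hours=1),
            specialty="Pediatric Infectious Disease",
        )


def _emit_er(b, ctx, rng, met, spec: CriterionSpec):
    need = spec.threshold("min_visits", ctx.term)
    n = need if met else int(min(rng.poisson(0.35), need - 1))
    for _ in range(n):
        day = int(rng.integers(0, 1090))
        start = ctx.day(day) + pd.Timedelta(hours=int(rng.integers(0, 24)))
        b.add_encounter(ctx.child_id, "emergency", start, start + pd.Timedelta(hours=4))


def _emit_feeding(b, ctx, rng, met, vocab: Vocabulary):
    if met:
        if rng.random() < 0.6:
            name = _FEEDING_WITNESS_NAMES[int(rng.integers(0, len(_FEEDING_WITNESS_NAMES)))]
            b.add_procedure(ctx.child_id, "FS001", name, ctx.day(int(rng.integers(0, 1000))))
        else:
            code = _pick_code(sorted(vocab.feeding_codes.codes), rng)
            date = ctx.day(int(rng.integers(0, 1000)))
            eid = b.add_encounter(
                ctx.child_id, "outpatient", date + pd.Timedelta(hours=9),
                date + pd.Timedelta(hours=10),
            )
            b.add_diagnosis(ctx.child_id, code, date, eid)
    elif rng.random() < _DECOY_P["feeding"]:
        if rng.random() < 0.5:
            b.add_procedure(
                ctx.child_id,
                "FS001",
                "Gastrostomy tube placement",
                ctx.day(int(rng.integers(0, 1000))),
                status="cancelled",
            )
        else:
            b.add_procedure(
                ctx.child_id,
                "FS002",
                "Gastrostomy revision",
                ctx.day(int(rng.integers(0, 1000))),
            )


def _emit_respiratory(b, ctx, rng, met, spec: CriterionSpec):
    before = spec.threshold("days_before")
    after = spec.threshold("days_after")
    if met:
        if ctx.surgery_days:
            day = max(ctx.surgery_days) + after + int(rng.integers(0, 30))
        else:
            day = int(rng.integers(0, 1000))
        day = min(day, 1090)
        name = _RESPIRATORY_WITNESS_NAMES[int(rng.integers(0, len(_RESPIRATORY_WITNESS_NAMES)))]
        b.add_procedure(ctx.child_id, "RS001", name, ctx.day(day))
    else:
        if ctx.surgery_days and rng.random() < _DECOY_P["resp_periop"]:
            # perioperative ventilation: inside [s - before + 1, s + after - 1]
            s = ctx.surgery_days[int(rng.integers(0, len(ctx.surgery_days)))]
            day = s + int(rng.integers(-before + 1, after))
            if day >= 0:
                b.add_procedure(ctx.child_id, "RS001", "Mechanical ventilation", ctx.day(day))


def _emit_order(b, ctx, rng, met, category: str):
    cats = {
        "imaging": ("imaging_ct", "imaging_mri"),
        "genetic_tests": ("genetic_test",),
        "metabolic_tests": ("metabolic_test",),
    }[category]
    if met:
        cat = cats[int(rng.integers(0, len(cats)))]
        status = ("completed", "preliminary", "final")[int(rng.integers(0, 3))]
        b.add_lab(ctx.child_id, cat, ctx.day(int(rng.integers(0, 1090))), status)
    elif rng.random() < _DECOY_P["order_cancelled"]:
        cat = cats[int(rng.integers(0, len(cats)))]
        b.add_lab(ctx.child_id, cat, ctx.day(int(rng.integers(0, 1090))), "cancelled")


def _emit_death(b, ctx, rng, met, vocab: Vocabulary):
    if not met:
        return None
    day = int(rng.integers(30, 1090))
    mode = rng.random()
    death_date = ctx.day(day)
    dispo = sorted(vocab.death_dispositions)[int(rng.integers(0, len(vocab.death_dispositions)))]
    if mode < 0.2:  # date only
        return death_date
    start = ctx.day(day) - pd.Timedelta(hours=12)
    b.add_encounter(
        ctx.child_id, "inpatient", start, death_date, disposition=dispo
    )
    if mode < 0.5:  # disposition only
        return None
    return death_date


def _emit_dev_delay(b, ctx, rng, met, spec: CriterionSpec, vocab: Vocabulary):
    need = spec.threshold("min_icd_dates")
    if met:
        if rng.random() < 0.5:
            day = int(rng.integers(0, 1000))
            start = ctx.day(day) + pd.Timedelta(hours=11)
            b.add_encounter(
                ctx.child_id,
                "specialist_visit",
                start,
                start + pd.Timedelta(hours=1),
                specialty=vocab.developmental_specialty,
            )
        else:
            days = sorted(rng.choice(1000, size=need, replace=False))
            code = _pick_code(sorted(vocab.developmental_delay_codes.codes), rng)
            for d in days:
                date = ctx.day(int(d))
                eid = b.add_encounter(
                    ctx.child_id, "outpatient", date + pd.Timedelta(hours=9),
                    date + pd.Timedelta(hours=10),
                )
                b.add_diagnosis(ctx.child_id, code, date, eid)
    elif rng.random() < _DECOY_P["dev_single"]:
        code = _pick_code(sorted(vocab.developmental_delay_codes.codes), rng)
        date = ctx.day(int(rng.integers(0, 1000)))
        eid = b.add_encounter(
            ctx.child_id, "outpatient", date + pd.Timedelta(hours=9),
            date + pd.Timedelta(hours=10),
        )
        b.add_diagnosis(ctx.child_id, code, date, eid)


def _emit_metabolic_icd(b, ctx, rng, met, spec: CriterionSpec, vocab: Vocabulary):
    code = _pick_code(sorted(vocab.metabolic_codes.codes), rng)
    need = spec.threshold("min_encounters")
    if met:
        days = sorted(rng.choice(1000, size=need, replace=False))
        for d in days:
            date = ctx.day(int(d))
            eid = b.add_encounter(
                ctx.child_id, "outpatient", date + pd.Timedelta(hours=9),
                date + pd.Timedelta(hours=10),
            )
            b.add_diagnosis(ctx.child_id, code, date, eid)
    elif rng.random() < _DECOY_P["metabolic_single_encounter"]:
        date = ctx.day(int(rng.integers(0, 1000)))
        eid = b.add_encounter(
            ctx.child_id, "outpatient", date + pd.Timedelta(hours=9),
            date + pd.Timedelta(hours=10),
        )
        b.add_diagnosis(ctx.child_id, code, date, eid)
        b.add_diagnosis(ctx.child_id, code, date, eid)


def _emit_child(
    b: _Builder,
    ctx: _ChildCtx,
    intents: Mapping[str, bool],
    rng: np.random.Generator,
    specs: Mapping[str, CriterionSpec],
    vocab: Vocabulary,
) -> pd.Timestamp | None:
    """Emit one child's event stream; returns the death date (if any)."""
    # surgeries first so the respiratory rule's perioperative window is known
    _emit_heart_surgery(b, ctx, rng, intents["heart_surgery"])
    _emit_surgery_decoy(b, ctx, rng)
    _emit_nicu(b, ctx, rng, intents["nicu_stay"], specs["nicu_stay"])
    _emit_hospitalizations(b, ctx, rng, intents["hospitalizations"], specs["hospitalizations"])
    _emit_specialists(b, ctx, rng, intents["multiple_specialists"], specs["multiple_specialists"], vocab)
    _emit_er(b, ctx, rng, intents["er_visits"], specs["er_visits"])
    _emit_feeding(b, ctx, rng, intents["feeding_support"], vocab)
    _emit_respiratory(b, ctx, rng, intents["respiratory_support"], specs["respiratory_support"])
    _emit_order(b, ctx, rng, intents["imaging"], "imaging")
    _emit_order(b, ctx, rng, intents["genetic_tests"], "genetic_tests")
    _emit_order(b, ctx, rng, intents["metabolic_tests"], "metabolic_tests")
    death_date = _emit_death(b, ctx, rng, intents["death"], vocab)
    _emit_dev_delay(b, ctx, rng, intents["developmental_delay"], specs["developmental_delay"], vocab)
    _emit_metabolic_icd(b, ctx, rng, intents["metabolic_icd"], specs["metabolic_icd"], vocab)
    return death_date


def _tables_from_builder(b: _Builder) -> dict[str, pd.DataFrame]:
    children = pd.DataFrame(
        b.children,
        columns=["child_id", "mother_id", "birth_date", "gestational_age_days", "death_date"],
    )
    encounters = pd.DataFrame(
        b.encounters,
        columns=[
            "encounter_id",
            "child_id",
            "encounter_class",
            "specialty",
            "start",
            "end",
            "discharge_disposition",
        ],
    )
    diagnoses = pd.DataFrame(
        b.diagnoses, columns=["child_id", "icd_code", "date", "encounter_id"]
    )
    procedures = pd.DataFrame(
        b.procedures,
        columns=["child_id", "code", "name", "date", "status", "is_surgical", "is_cardiothoracic"],
    )
    lab_orders = pd.DataFrame(b.lab_orders, columns=["child_id", "category", "date", "status"])
    return {
        "children": children,
        "encounters": encounters,
        "diagnoses": diagnoses,
        "procedures": procedures,
        "lab_orders": lab_orders,
    }


def generate_cohort(
    config: GeneratorConfig,
    specs: Mapping[str, CriterionSpec] | None = None,
    vocab: Vocabulary | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a synthetic cohort plus its latent truth table.

    Returns ``(cohort, truth)`` where ``truth`` has one row per child:
    ``child_id``, ``term_status``, ``has_disorder`` and the 13 intended
    criterion flags (named by criterion id).  Deterministic given
    ``config.seed``.
    """
    specs = specs or default_specs()
    vocab = vocab or default_vocabulary()
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    preterm = rng.random(n) < config.preterm_fraction
    ga = np.where(
        preterm, rng.integers(175, 259, size=n), rng.integers(259, 295, size=n)
    ).astype(int)
    disorder = rng.random(n) < config.disorder_prevalence
    term_labels = np.where(preterm, TermStatus.PRE_TERM.value, TermStatus.FULL_TERM.value)

    # intent draws, arm by arm
    intents = np.zeros((n, len(CRITERIA)), dtype=bool)
    U = rng.random((n, len(CRITERIA)))
    for t in TermStatus:
        for dis in (False, True):
            mask = (term_labels == t.value) & (disorder == dis)
            if mask.any():
                intents[mask] = U[mask] < _rate_vector(config, t, dis)
    _adjust_cooccurrence(intents, term_labels, config.co_occurrence_pairs, rng)

    base = pd.Timestamp(config.start_date)
    birth_offsets = rng.integers(0, 1461, size=n)

    b = _Builder()
    death_dates: list[pd.Timestamp | None] = []
    for i in range(n):
        child_id = f"C{i + 1:06d}"
        birth = base + pd.Timedelta(days=int(birth_offsets[i]))
        ctx = _ChildCtx(
            child_id=child_id,
            birth=birth,
            ga=int(ga[i]),
            term=TermStatus(term_labels[i]),
        )
        child_intents = {cid: bool(intents[i, k]) for k, cid in enumerate(CRITERIA)}
        death_date = _emit_child(b, ctx, child_intents, rng, specs, vocab)
        death_dates.append(death_date)
        b.children.append(
            (child_id, f"M{i + 1:06d}", birth, int(ga[i]), death_date)
        )

    tables = {name: normalize_table(df, name) for name, df in _tables_from_builder(b).items()}
    cohort = Cohort(observation_limit_days=config.observation_limit_days, **tables)

    truth = pd.DataFrame(
        {
            "child_id": [f"C{i + 1:06d}" for i in range(n)],
            "term_status": term_labels,
            "has_disorder": disorder,
            **{cid: intents[:, k] for k, cid in enumerate(CRITERIA)},
        }
    )
    n_pos = int(
        (classify_matrix(intents, specs)["classification"] == "positive").sum()
    )
    logger.info(
        "generated %d children (%d pre-term, %d with latent disorder, %d intent-positive)",
        n,
        int(preterm.sum()),
        int(disorder.sum()),
        n_pos,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Documentation noise


def _drop_criterion_events(
    tables: dict[str, pd.DataFrame],
    cid: str,
    child_ids: set[str],
    vocab: Vocabulary,
    specs: Mapping[str, CriterionSpec],
) -> None:
    """Remove (in place) the events that let the engine detect ``cid`` for
    the given children."""
    enc = tables["encounters"]
    dx = tables["diagnoses"]
    px = tables["procedures"]
    labs = tables["lab_orders"]
    kids = tables["children"]
    in_set_enc = enc["child_id"].isin(child_ids)
    in_set_dx = dx["child_id"].isin(child_ids)
    in_set_px = px["child_id"].isin(child_ids)

    if cid == "nicu_stay":
        drop = in_set_enc & (enc["encounter_class"] == "icu")
        tables["encounters"] = enc[~drop]
    elif cid == "hospitalizations":
        birth = kids.set_index("child_id")["birth_date"]
        ga_map = kids.set_index("child_id")["gestational_age_days"]
        dur = enc["end"] - enc["start"]
        dur_ok = dur.isna() | (dur >= pd.Timedelta(hours=48))
        pma = (
            (enc["start"].dt.normalize() - enc["child_id"].map(birth)).dt.days
            + enc["child_id"].map(ga_map)
        )
        floor = specs["hospitalizations"].threshold("pma_floor_days")
        drop = (
            in_set_enc
            & (enc["encounter_class"] == "inpatient")
            & dur_ok
            & (pma > floor)
        )
        tables["encounters"] = enc[~drop]
    elif cid == "multiple_specialists":
        drop = (
            in_set_enc
            & (enc["encounter_class"] == "specialist_visit")
            & enc["specialty"].isin(vocab.taxonomy.included)
        )
        tables["encounters"] = enc[~drop]
    elif cid == "er_visits":
        drop = in_set_enc & (enc["encounter_class"] == "emergency")
        tables["encounters"] = enc[~drop]
    elif cid == "feeding_support":
        drop_px = in_set_px & px["name"].map(vocab.feeding_rule.matches)
        tables["procedures"] = px[~drop_px]
        drop_dx = in_set_dx & dx["icd_code"].map(vocab.feeding_codes.matches)
        tables["diagnoses"] = dx[~drop_dx]
    elif cid == "respiratory_support":
        drop_px = in_set_px & (
            px["name"].map(vocab.respiratory_rule.matches)
            | px["code"].map(vocab.respiratory_codes.matches)
        )
        tables["procedures"] = px[~drop_px]
        drop_dx = in_set_dx & dx["icd_code"].map(vocab.respiratory_codes.matches)
        tables["diagnoses"] = dx[~drop_dx]
    elif cid in ("imaging", "genetic_tests", "metabolic_tests"):
        cats = {
            "imaging": ("imaging_ct", "imaging_mri"),
            "genetic_tests": ("genetic_test",),
            "metabolic_tests": ("metabolic_test",),
        }[cid]
        drop = labs["child_id"].isin(child_ids) & labs["category"].isin(cats)
        tables["lab_orders"] = labs[~drop]
    elif cid == "death":
        mask = kids["child_id"].isin(child_ids)
        kids = kids.copy()
        kids.loc[mask, "death_date"] = pd.NaT
        tables["children"] = kids
        enc = enc.copy()
        is_death = in_set_enc & enc["discharge_disposition"].map(
            vocab.is_death_disposition
        )
        enc.loc[is_death, "discharge_disposition"] = "home"
        tables["encounters"] = enc
    elif cid == "developmental_delay":
        drop_enc = (
            in_set_enc
            & (enc["encounter_class"] == "specialist_visit")
            & (enc["specialty"] == vocab.developmental_specialty)
        )
        tables["encounters"] = enc[~drop_enc]
        drop_dx = in_set_dx & dx["icd_code"].map(vocab.developmental_delay_codes.matches)
        tables["diagnoses"] = tables["diagnoses"][
            ~(
                tables["diagnoses"]["child_id"].isin(child_ids)
                & tables["diagnoses"]["icd_code"].map(
                    vocab.developmental_delay_codes.matches
                )
            )
        ]
    elif cid == "metabolic_icd":
        drop_dx = in_set_dx & dx["icd_code"].map(vocab.metabolic_codes.matches)
        tables["diagnoses"] = dx[~drop_dx]
    elif cid == "heart_surgery":
        drop_enc = in_set_enc & (enc["encounter_class"] == "cticu")
        tables["encounters"] = enc[~drop_enc]
        px = tables["procedures"]
        drop_px = px["child_id"].isin(child_ids) & px["is_cardiothoracic"].astype(bool)
        tables["procedures"] = px[~drop_px]
    else:
        raise ValueError(f"unknown criterion {cid!r}")


_ADD_EMITTERS = {
    "nicu_stay": lambda b, ctx, rng, specs, vocab: _emit_nicu(b, ctx, rng, True, specs["nicu_stay"]),
    "hospitalizations": lambda b, ctx, rng, specs, vocab: _emit_hospitalizations(
        b, ctx, rng, True, specs["hospitalizations"]
    ),
    "multiple_specialists": lambda b, ctx, rng, specs, vocab: _emit_specialists(
        b, ctx, rng, True, specs["multiple_specialists"], vocab
    ),
    "er_visits": lambda b, ctx, rng, specs, vocab: _emit_er(b, ctx, rng, True, specs["er_visits"]),
    "feeding_support": lambda b, ctx, rng, specs, vocab: _emit_feeding(b, ctx, rng, True, vocab),
    "respiratory_support": lambda b, ctx, rng, specs, vocab: _emit_respiratory(
        b, ctx, rng, True, specs["respiratory_support"]
    ),
    "imaging": lambda b, ctx, rng, specs, vocab: _emit_order(b, ctx, rng, True, "imaging"),
    "genetic_tests": lambda b, ctx, rng, specs, vocab: _emit_order(
        b, ctx, rng, True, "genetic_tests"
    ),
    "metabolic_tests": lambda b, ctx, rng, specs, vocab: _emit_order(
        b, ctx, rng, True, "metabolic_tests"
    ),
    "developmental_delay": lambda b, ctx, rng, specs, vocab: _emit_dev_delay(
        b, ctx, rng, True, specs["developmental_delay"], vocab
    ),
    "metabolic_icd": lambda b, ctx, rng, specs, vocab: _emit_metabolic_icd(
        b, ctx, rng, True, specs["metabolic_icd"], vocab
    ),
    "heart_surgery": lambda b, ctx, rng, specs, vocab: _emit_heart_surgery(b, ctx, rng, True),
}


def inject_documentation_noise(
    cohort: Cohort,
    truth: pd.DataFrame,
    flip_rates: Mapping[str, float],
    seed: int,
    specs: Mapping[str, CriterionSpec] | None = None,
    vocab: Vocabulary | None = None,
) -> Cohort:
    """Return a copy of ``cohort`` whose record disagrees with the latent
    truth on each criterion at approximately the configured rate.

    For each criterion, a ``flip_rates[cid]`` fraction of children (among
    those for whom the criterion is applicable — NICU flips only full-term
    children) have their record altered: intended criteria lose their
    witness events; unintended ones gain a minimal witness.  Cross-criterion
    side effects (e.g. an added heart surgery shifting the respiratory
    perioperative window) make the realised rate approximate rather than
    exact.
    """
    specs = specs or default_specs()
    vocab = vocab or default_vocabulary()
    rng = np.random.default_rng(seed)
    tables = {
        "children": cohort.children.copy(),
        "encounters": cohort.encounters.copy(),
        "diagnoses": cohort.diagnoses.copy(),
        "procedures": cohort.procedures.copy(),
        "lab_orders": cohort.lab_orders.copy(),
    }
    truth = truth.set_index("child_id")
    kids = cohort.children.set_index("child_id")
    b = _Builder()
    b._enc_n = len(cohort.encounters) + 10_000_000  # fresh id space

    for cid in CRITERIA:
        rate = flip_rates.get(cid, 0.0)
        if rate <= 0:
            continue
        applicable = truth.index.to_numpy()
        if cid == "nicu_stay":
            applicable = truth.index[truth["term_status"] == TermStatus.FULL_TERM.value].to_numpy()
        flipped = applicable[rng.random(len(applicable)) < rate]
        if len(flipped) == 0:
            continue
        was_true = [c for c in flipped if truth.loc[c, cid]]
        was_false = [c for c in flipped if not truth.loc[c, cid]]
        if was_true:
            _drop_criterion_events(tables, cid, set(was_true), vocab, specs)
        if cid == "death" and was_false:
            # engine-visible death needs a disposition; emit it here
            for c in was_false:
                birth = kids.loc[c, "birth_date"]
                day = int(rng.integers(30, 1090))
                b.add_encounter(
                    c,
                    "inpatient",
                    birth + pd.Timedelta(days=day) - pd.Timedelta(hours=12),
                    birth + pd.Timedelta(days=day),
                    disposition="expired",
                )
        elif was_false:
            emit = _ADD_EMITTERS[cid]
            for c in was_false:
                ctx = _ChildCtx(
                    child_id=c,
                    birth=kids.loc[c, "birth_date"],
                    ga=int(kids.loc[c, "gestational_age_days"]),
                    term=TermStatus(truth.loc[c, "term_status"]),
                )
                # existing context the emitters must respect
                enc = tables["encounters"]
                mine = enc[enc["child_id"] == c]
                inpt = mine[mine["encounter_class"] == "inpatient"]
                for s, e in zip(inpt["start"], inpt["end"]):
                    s_d = (s - ctx.birth) / pd.Timedelta(days=1)
                    e_d = (e - ctx.birth) / pd.Timedelta(days=1) if pd.notna(e) else s_d + 1
                    ctx.inpatient_spans.append((float(s_d), float(e_d)))
                cticu = mine[mine["encounter_class"] == "cticu"]
                ctx.surgery_days.extend(
                    int((s - ctx.birth).days) for s in cticu["start"]
                )
                px = tables["procedures"]
                surg = px[(px["child_id"] == c) & px["is_surgical"].astype(bool) & (px["status"] != "cancelled")]
                ctx.surgery_days.extend(int((d - ctx.birth).days) for d in surg["date"])
                emit(b, ctx, rng, specs, vocab)

    new = _tables_from_builder(b)
    out = {}
    for name in tables:
        base_df = tables[name].reset_index(drop=True)
        add_df = new[name]
        if name == "children" or not len(add_df):
            out[name] = normalize_table(base_df, name)
        else:
            add_df = normalize_table(add_df, name)
            out[name] = pd.concat([base_df, add_df], ignore_index=True)
    # diagnoses whose encounter was removed are no longer documented either
    enc_ids = set(out["encounters"]["encounter_id"])
    dx = out["diagnoses"]
    out["diagnoses"] = dx[dx["encounter_id"].isin(enc_ids)].reset_index(drop=True)
    return Cohort(observation_limit_days=cohort.observation_limit_days, **out)


# ---------------------------------------------------------------------------
# Analytic oracle for classification rates implied by a config


def expected_classification_rates(
    config: GeneratorConfig, specs: Mapping[str, CriterionSpec] | None = None
) -> dict[str, float]:
    """Exact expected sensitivity/specificity of the classification against
    the latent disorder, and the expected positive rate, implied by a
    config with conditionally independent criterion intents.

    Computed by enumerating all 2^13 intent patterns and weighting each by
    its Bernoulli probability within each (term, disorder) arm.  Valid only
    when pairwise co-occurrence coupling is disabled.
    """
    specs = specs or default_specs()
    k = len(CRITERIA)
    bits = (np.arange(2**k)[:, None] >> np.arange(k)[None, :]) & 1
    positive = (
        classify_matrix(bits.astype(bool), specs)["classification"] == "positive"
    ).to_numpy()

    def arm_positive_prob(term: TermStatus, disorder: bool) -> float:
        p = np.clip(_rate_vector(config, term, disorder), 1e-12, 1 - 1e-12)
        logp = bits @ np.log(p) + (1 - bits) @ np.log1p(-p)
        w = np.exp(logp)
        return float(w[positive].sum() / w.sum())

    ft = 1.0 - config.preterm_fraction
    prev = config.disorder_prevalence
    sens = ft * arm_positive_prob(TermStatus.FULL_TERM, True) + (
        1 - ft
    ) * arm_positive_prob(TermStatus.PRE_TERM, True)
    fpr = ft * arm_positive_prob(TermStatus.FULL_TERM, False) + (
        1 - ft
    ) * arm_positive_prob(TermStatus.PRE_TERM, False)
    return {
        "sensitivity": sens,
        "specificity": 1.0 - fpr,
        "positive_rate": prev * sens + (1 - prev) * fpr,
    }
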