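"""Independent brute-force re-implementations of the 13 rules and the
classification conditions, used only as test oracles.

Deliberately naive: plain loops over the raw event lists, no shared logic
with the package beyond the data classes, so agreement is meaningful.
"""

import pandas as pd

PRETERM = 259


def _age(bundle, ts):
    return (ts - bundle.child.birth_date) / pd.Timedelta(days=1)


def _is_preterm(bundle):
    return bundle.child.gestational_age_days < PRETERM


def nicu(bundle):
    if _is_preterm(bundle):
        return False
    for e in bundle.encounters:
        if e.encounter_class != "icu":
            continue
        if _age(bundle, e.start) > 7:
            continue
        end = e.end if e.end is not None else bundle.observation_end
        if (end - e.start) >= pd.Timedelta(days=4):
            return True
    return False


def _merged_inpatient(bundle):
    stays = sorted(
        (
            (e.start, e.end if e.end is not None else bundle.observation_end)
            for e in bundle.encounters
            if e.encounter_class == "inpatient"
        ),
        key=lambda t: t,
    )
    merged = []
    for s, t in stays:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t)
        else:
            merged.append([s, t])
    return merged


def hospitalizations(bundle):
    ga = bundle.child.gestational_age_days
    eligible = []
    for i, (s, t) in enumerate(_merged_inpatient(bundle)):
        pma = ga + (s.normalize() - bundle.child.birth_date.normalize()).days
        if pma <= 245:
            continue
        if i == 0 and pma < 245:
            continue
        if (t - s) >= pd.Timedelta(hours=48):
            eligible.append((s, t))
    if any((t - s) >= pd.Timedelta(days=14) for s, t in eligible):
        return True
    need = 3 if _is_preterm(bundle) else 2
    return len(eligible) >= need


def specialists(bundle, vocab):
    types = {
        e.specialty
        for e in bundle.encounters
        if e.encounter_class == "specialist_visit" and e.specialty in vocab.taxonomy.included
    }
    need = 4 if _is_preterm(bundle) else 3
    return len(types) >= need


def er(bundle):
    n = sum(1 for e in bundle.encounters if e.encounter_class == "emergency")
    return n >= (7 if _is_preterm(bundle) else 5)


def feeding(bundle, vocab):
    for d in bundle.diagnoses:
        if vocab.feeding_codes.matches(d.icd_code):
            return True
    for p in bundle.procedures:
        if p.status != "cancelled" and vocab.feeding_rule.matches(p.name):
            return True
    return False


def respiratory(bundle, vocab):
    surgeries = {
        p.date.normalize()
        for p in bundle.procedures
        if p.is_surgical and p.status != "cancelled"
    } | {e.start.normalize() for e in bundle.encounters if e.encounter_class == "cticu"}
    events = [
        p.date.normalize()
        for p in bundle.procedures
        if p.status != "cancelled"
        and (vocab.respiratory_rule.matches(p.name) or vocab.respiratory_codes.matches(p.code))
    ] + [
        d.date.normalize() for d in bundle.diagnoses if vocab.respiratory_codes.matches(d.icd_code)
    ]
    one = pd.Timedelta(days=1)
    five = pd.Timedelta(days=5)
    for d in events:
        if all(d <= s - one or d >= s + five for s in surgeries):
            return True
    return False


def order(bundle, cats):
    return any(
        o.category in cats and o.status in ("completed", "preliminary", "final")
        for o in bundle.lab_orders
    )


def death(bundle, vocab):
    for e in bundle.encounters:
        if e.discharge_disposition and e.discharge_disposition.strip().lower() in vocab.death_dispositions:
            return True
    dd = bundle.child.death_date
    return dd is not None and dd <= bundle.observation_end


def dev_delay(bundle, vocab):
    for e in bundle.encounters:
        if e.encounter_class == "specialist_visit" and e.specialty == vocab.developmental_specialty:
            return True
    dates = {
        d.date.normalize()
        for d in bundle.diagnoses
        if vocab.developmental_delay_codes.matches(d.icd_code)
    }
    return len(dates) >= 2


def metabolic_icd(bundle, vocab):
    encs = {
        d.encounter_id for d in bundle.diagnoses if vocab.metabolic_codes.matches(d.icd_code)
    }
    return len(encs) >= 2


def heart(bundle):
    if any(e.encounter_class == "cticu" for e in bundle.encounters):
        return True
    return any(p.is_cardiothoracic and p.status != "cancelled" for p in bundle.procedures)


def all_rules(bundle, vocab):
    return {
        "nicu_stay": nicu(bundle),
        "hospitalizations": hospitalizations(bundle),
        "multiple_specialists": specialists(bundle, vocab),
        "er_visits": er(bundle),
        "feeding_support": feeding(bundle, vocab),
        "respiratory_support": respiratory(bundle, vocab),
        "imaging": order(bundle, ("imaging_ct", "imaging_mri")),
        "genetic_tests": order(bundle, ("genetic_test",)),
        "metabolic_tests": order(bundle, ("metabolic_test",)),
        "death": death(bundle, vocab),
        "developmental_delay": dev_delay(bundle, vocab),
        "metabolic_icd": metabolic_icd(bundle, vocab),
        "heart_surgery": heart(bundle),
    }


MAJORS = {"nicu_stay", "hospitalizations", "death", "metabolic_icd", "heart_surgery"}


def classify_literal(met: dict) -> bool:
    """Literal restatement of the positivity conditions."""
    n_major = sum(1 for c in MAJORS if met[c])
    n_minor = sum(1 for c in met if c not in MAJORS and met[c])
    condition_a = n_major >= 2
    condition_b = n_major >= 1 and n_minor >= 1
    condition_c = n_minor >= 5
    condition_d = met["death"]
    return condition_a or condition_b or condition_c or condition_d
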