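import pandas as pd
import pytest

from pheindex.criteria import default_specs
from pheindex.emr import ChildBundle, ChildRecord, DiagnosisRecord, Encounter, LabOrder, ProcedureRecord
from pheindex.vocabulary import default_vocabulary

BIRTH = pd.Timestamp("2015-06-01")


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


def day(d, hours=0):
    return BIRTH + pd.Timedelta(days=d, hours=hours)


def enc(cls, start_day, *, dur_days=None, dur_hours=None, specialty=None, dispo=None, eid=None, start_hours=0):
    start = day(start_day, start_hours)
    end = None
    if dur_days is not None:
        end = start + pd.Timedelta(days=dur_days)
    elif dur_hours is not None:
        end = start + pd.Timedelta(hours=dur_hours)
    return Encounter(
        encounter_id=eid or f"E{start_day}-{cls}-{specialty or ''}-{dur_days}-{dur_hours}",
        child_id="X1",
        encounter_class=cls,
        start=start,
        end=end,
        specialty=specialty,
        discharge_disposition=dispo,
    )


def dx(code, d, eid="E0"):
    return DiagnosisRecord(child_id="X1", icd_code=code, date=day(d), encounter_id=eid)


def px(name, d, status="completed", code="P1", surgical=False, cardio=False):
    return ProcedureRecord(
        child_id="X1",
        code=code,
        name=name,
        date=day(d),
        status=status,
        is_surgical=surgical,
        is_cardiothoracic=cardio,
    )


def lab(category, d, status="completed"):
    return LabOrder(child_id="X1", category=category, date=day(d), status=status)


def make_bundle(ga=280, death_day=None, encounters=(), diagnoses=(), procedures=(), labs=()):
    child = ChildRecord(
        child_id="X1",
        mother_id="M1",
        birth_date=BIRTH,
        gestational_age_days=ga,
        death_date=None if death_day is None else day(death_day),
    )
    return ChildBundle(
        child=child,
        encounters=list(encounters),
        diagnoses=list(diagnoses),
        procedures=list(procedures),
        lab_orders=list(labs),
    )
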