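"""Structured-EMR data model: tables, readers/writers and derived temporal
quantities.

A :class:`Cohort` is five pandas tables (children, encounters, diagnoses,
procedures, lab orders) tied together by ``child_id``, plus an observation
window (default three years = 1095 days).  Conventions:

* dates and timestamps are ISO-8601, timezone-naive;
* ages are measured in days since birth; durations in hours;
* gestational age at birth is an integer number of days; term status is
  pre-term below 259 days (37 completed weeks, the clinical standard);
* postmenstrual age (PMA) at a date is gestational age at birth plus
  chronological age — used to filter hospitalizations before 35 weeks PMA;
* an encounter whose ``end`` is given as a bare date spans the whole day
  (end interpreted as the following midnight);
* events dated after the observation window are dropped at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TermStatus",
    "ChildRecord",
    "Encounter",
    "DiagnosisRecord",
    "ProcedureRecord",
    "LabOrder",
    "Episode",
    "ChildBundle",
    "Cohort",
    "CohortError",
    "OBSERVATION_LIMIT_DAYS",
    "PRETERM_CUTOFF_DAYS",
    "GESTATIONAL_AGE_RANGE",
    "derive_term_status",
    "postmenstrual_age",
    "hospitalization_episodes",
    "read_cohort",
    "write_cohort",
]

OBSERVATION_LIMIT_DAYS = 1095  # three years of age
PRETERM_CUTOFF_DAYS = 259  # 37 completed weeks
GESTATIONAL_AGE_RANGE = (140, 315)

ENCOUNTER_CLASSES = frozenset(
    {"inpatient", "emergency", "outpatient", "icu", "cticu", "specialist_visit"}
)
ORDER_STATUSES = frozenset({"completed", "cancelled", "preliminary", "final"})
OK_STATUSES = frozenset({"completed", "preliminary", "final"})
LAB_CATEGORIES = frozenset(
    {"genetic_test", "metabolic_test", "imaging_ct", "imaging_mri", "other"}
)


class CohortError(ValueError):
    """Raised when cohort tables violate the data dictionary."""


class TermStatus(str, Enum):
    PRE_TERM = "pre_term"
    FULL_TERM = "full_term"


def derive_term_status(gestational_age_days: int) -> TermStatus:
    """Pre-term below 259 days (37 completed weeks), full-term otherwise."""
    lo, hi = GESTATIONAL_AGE_RANGE
    if not lo <= gestational_age_days <= hi:
        raise CohortError(
            f"gestational age {gestational_age_days} d outside plausible "
            f"range [{lo}, {hi}]"
        )
    if gestational_age_days < PRETERM_CUTOFF_DAYS:
        return TermStatus.PRE_TERM
    return TermStatus.FULL_TERM


@dataclass(frozen=True)
class ChildRecord:
    child_id: str
    mother_id: str
    birth_date: pd.Timestamp
    gestational_age_days: int
    death_date: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        lo, hi = GESTATIONAL_AGE_RANGE
        if not lo <= self.gestational_age_days <= hi:
            raise CohortError(
                f"child {self.child_id}: gestational age "
                f"{self.gestational_age_days} d outside [{lo}, {hi}]"
            )
        if self.death_date is not None and self.death_date < self.birth_date:
            raise CohortError(f"child {self.child_id}: death before birth")

    @property
    def term_status(self) -> TermStatus:
        return derive_term_status(self.gestational_age_days)


@dataclass(frozen=True)
class Encounter:
    encounter_id: str
    child_id: str
    encounter_class: str
    start: pd.Timestamp
    end: pd.Timestamp | None = None
    specialty: str | None = None
    discharge_disposition: str | None = None


@dataclass(frozen=True)
class DiagnosisRecord:
    child_id: str
    icd_code: str
    date: pd.Timestamp
    encounter_id: str


@dataclass(frozen=True)
class ProcedureRecord:
    child_id: str
    code: str
    name: str
    date: pd.Timestamp
    status: str
    is_surgical: bool = False
    is_cardiothoracic: bool = False


@dataclass(frozen=True)
class LabOrder:
    child_id: str
    category: str
    date: pd.Timestamp
    status: str


@dataclass(frozen=True)
class Episode:
    """A merged inpatient hospitalization episode."""

    start: pd.Timestamp
    end: pd.Timestamp
    censored: bool = False

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


def postmenstrual_age(child: ChildRecord, date: pd.Timestamp) -> int:
    """Gestational age at birth plus chronological age, in days."""
    days = (pd.Timestamp(date).normalize() - child.birth_date.normalize()).days
    if days < 0:
        raise CohortError(f"child {child.child_id}: date {date} precedes birth")
    return child.gestational_age_days + days


def hospitalization_episodes(
    encounters: list[Encounter],
    observation_end: pd.Timestamp | None = None,
) -> list[Episode]:
    """Merge inpatient encounters into episodes.

    Overlapping or contiguous (zero-gap) inpatient encounters are merged
    into one episode — a transfer is not a new hospitalization.  An
    open-ended stay is censored at ``observation_end`` and flagged.
    """
    stays = []
    for e in encounters:
        if e.encounter_class != "inpatient":
            continue
        end = e.end
        censored = False
        if end is None or (isinstance(end, float) and pd.isna(end)) or pd.isna(end):
            if observation_end is None:
                raise CohortError(
                    f"encounter {e.encounter_id}: open-ended inpatient stay "
                    "and no observation end to censor at"
                )
            end = observation_end
            censored = True
        if end < e.start:
            raise CohortError(f"encounter {e.encounter_id}: end before start")
        stays.append((e.start, end, censored))
    stays.sort(key=lambda s: (s[0], s[1]))
    episodes: list[Episode] = []
    for start, end, censored in stays:
        if episodes and start <= episodes[-1].end:
            prev = episodes[-1]
            episodes[-1] = Episode(
                start=prev.start,
                end=max(prev.end, end),
                censored=prev.censored or censored,
            )
        else:
            episodes.append(Episode(start=start, end=end, censored=censored))
    return episodes


@dataclass
class ChildBundle:
    """All of one child's clinical events, censored to the observation
    window — the unit the criteria engine works on."""

    child: ChildRecord
    encounters: list[Encounter] = field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    procedures: list[ProcedureRecord] = field(default_factory=list)
    lab_orders: list[LabOrder] = field(default_factory=list)
    observation_limit_days: int = OBSERVATION_LIMIT_DAYS

    @property
    def term_status(self) -> TermStatus:
        return self.child.term_status

    @property
    def observation_end(self) -> pd.Timestamp:
        return self.child.birth_date + pd.Timedelta(days=self.observation_limit_days)

    def age_days(self, when: pd.Timestamp) -> float:
        return (when - self.child.birth_date) / pd.Timedelta(days=1)


# ---------------------------------------------------------------------------
# Tabular cohort container


CHILD_COLUMNS = ["child_id", "mother_id", "birth_date", "gestational_age_days", "death_date"]
ENCOUNTER_COLUMNS = [
    "encounter_id",
    "child_id",
    "encounter_class",
    "specialty",
    "start",
    "end",
    "discharge_disposition",
]
DIAGNOSIS_COLUMNS = ["child_id", "icd_code", "date", "encounter_id"]
PROCEDURE_COLUMNS = [
    "child_id",
    "code",
    "name",
    "date",
    "status",
    "is_surgical",
    "is_cardiothoracic",
]
LAB_COLUMNS = ["child_id", "category", "date", "status"]

TABLE_COLUMNS: Mapping[str, list[str]] = {
    "children": CHILD_COLUMNS,
    "encounters": ENCOUNTER_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "procedures": PROCEDURE_COLUMNS,
    "lab_orders": LAB_COLUMNS,
}


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})


@dataclass
class Cohort:
    """Five event tables keyed by ``child_id`` plus the observation window."""

    children: pd.DataFrame
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    lab_orders: pd.DataFrame
    observation_limit_days: int = OBSERVATION_LIMIT_DAYS

    def __len__(self) -> int:
        return len(self.children)

    @classmethod
    def empty(cls) -> "Cohort":
        return cls(*(normalize_table(_empty_table(n), n) for n in TABLE_COLUMNS))

    def validate(self) -> None:
        """Check the data dictionary: columns, enums, referential integrity,
        date sanity.  Raises :class:`CohortError` naming the offence."""
        for name in TABLE_COLUMNS:
            df = getattr(self, name)
            missing = set(TABLE_COLUMNS[name]) - set(df.columns)
            if missing:
                raise CohortError(f"{name}: missing columns {sorted(missing)}")
            unknown = set(df.columns) - set(TABLE_COLUMNS[name])
            if unknown:
                raise CohortError(f"{name}: unknown columns {sorted(unknown)}")
        kids = self.children
        if kids["child_id"].duplicated().any():
            dup = kids.loc[kids["child_id"].duplicated(), "child_id"].iloc[0]
            raise CohortError(f"children: duplicate child_id {dup!r}")
        known = set(kids["child_id"])
        for name in ("encounters", "diagnoses", "procedures", "lab_orders"):
            df = getattr(self, name)
            if len(df):
                bad = ~df["child_id"].isin(known)
                if bad.any():
                    row = df.index[bad][0]
                    raise CohortError(
                        f"{name} row {row}: unknown child_id "
                        f"{df.loc[row, 'child_id']!r}"
                    )
        if len(kids):
            ga = kids["gestational_age_days"]
            lo, hi = GESTATIONAL_AGE_RANGE
            bad = (ga < lo) | (ga > hi)
            if bad.any():
                cid = kids.loc[bad, "child_id"].iloc[0]
                raise CohortError(f"children: child {cid!r} gestational age out of range")
            died = kids["death_date"].notna()
            if (kids.loc[died, "death_date"] < kids.loc[died, "birth_date"]).any():
                raise CohortError("children: death_date before birth_date")
        enc = self.encounters
        if len(enc):
            bad_class = ~enc["encounter_class"].isin(ENCOUNTER_CLASSES)
            if bad_class.any():
                row = enc.index[bad_class][0]
                raise CohortError(
                    f"encounters row {row}: unknown class "
                    f"{enc.loc[row, 'encounter_class']!r}"
                )
            spec_needed = enc["encounter_class"] == "specialist_visit"
            if enc.loc[spec_needed, "specialty"].isna().any():
                raise CohortError("encounters: specialist_visit rows must carry a specialty")
            both = enc["end"].notna()
            if (enc.loc[both, "end"] < enc.loc[both, "start"]).any():
                raise CohortError("encounters: end before start")
        if len(self.diagnoses):
            enc_ids = set(enc["encounter_id"]) if len(enc) else set()
            bad = ~self.diagnoses["encounter_id"].isin(enc_ids)
            if bad.any():
                row = self.diagnoses.index[bad][0]
                raise CohortError(
                    f"diagnoses row {row}: dangling encounter_id "
                    f"{self.diagnoses.loc[row, 'encounter_id']!r}"
                )
        for name, col in (("procedures", "status"), ("lab_orders", "status")):
            df = getattr(self, name)
            if len(df):
                bad = ~df[col].isin(ORDER_STATUSES)
                if bad.any():
                    row = df.index[bad][0]
                    raise CohortError(f"{name} row {row}: unknown status {df.loc[row, col]!r}")
        if len(self.lab_orders):
            bad = ~self.lab_orders["category"].isin(LAB_CATEGORIES)
            if bad.any():
                row = self.lab_orders.index[bad][0]
                raise CohortError(
                    f"lab_orders row {row}: unknown category "
                    f"{self.lab_orders.loc[row, 'category']!r}"
                )

    def censored(self) -> "Cohort":
        """Drop events dated after each child's observation window.

        Idempotent: censoring an already-censored cohort is a no-op.
        """
        kids = self.children
        birth = kids.set_index("child_id")["birth_date"]
        limit = birth + pd.Timedelta(days=self.observation_limit_days)

        def _keep(df: pd.DataFrame, col: str) -> pd.DataFrame:
            if not len(df):
                return df.copy()
            cutoff = df["child_id"].map(limit)
            keep = df[col] <= cutoff
            dropped = int((~keep).sum())
            if dropped:
                logger.info("dropping %d rows beyond the observation window", dropped)
            return df.loc[keep].reset_index(drop=True)

        return Cohort(
            children=kids.copy(),
            encounters=_keep(self.encounters, "start"),
            diagnoses=_keep(self.diagnoses, "date"),
            procedures=_keep(self.procedures, "date"),
            lab_orders=_keep(self.lab_orders, "date"),
            observation_limit_days=self.observation_limit_days,
        )

    def bundles(self) -> Iterator[ChildBundle]:
        """Iterate per-child event bundles (events pre-grouped in one pass)."""
        enc_by, dx_by, px_by, lab_by = {}, {}, {}, {}
        for row in self.encounters.itertuples(index=False):
            enc_by.setdefault(row.child_id, []).append(
                Encounter(
                    encounter_id=row.encounter_id,
                    child_id=row.child_id,
                    encounter_class=row.encounter_class,
                    specialty=None if pd.isna(row.specialty) else row.specialty,
                    start=row.start,
                    end=None if pd.isna(row.end) else row.end,
                    discharge_disposition=(
                        None
                        if pd.isna(row.discharge_disposition)
                        else row.discharge_disposition
                    ),
                )
            )
        for row in self.diagnoses.itertuples(index=False):
            dx_by.setdefault(row.child_id, []).append(
                DiagnosisRecord(row.child_id, row.icd_code, row.date, row.encounter_id)
            )
        for row in self.procedures.itertuples(index=False):
            px_by.setdefault(row.child_id, []).append(
                ProcedureRecord(
                    row.child_id,
                    row.code,
                    row.name,
                    row.date,
                    row.status,
                    bool(row.is_surgical),
                    bool(row.is_cardiothoracic),
                )
            )
        for row in self.lab_orders.itertuples(index=False):
            lab_by.setdefault(row.child_id, []).append(
                LabOrder(row.child_id, row.category, row.date, row.status)
            )
        for row in self.children.itertuples(index=False):
            child = ChildRecord(
                child_id=row.child_id,
                mother_id=row.mother_id,
                birth_date=row.birth_date,
                gestational_age_days=int(row.gestational_age_days),
                death_date=None if pd.isna(row.death_date) else row.death_date,
            )
            yield ChildBundle(
                child=child,
                encounters=enc_by.get(child.child_id, []),
                diagnoses=dx_by.get(child.child_id, []),
                procedures=px_by.get(child.child_id, []),
                lab_orders=lab_by.get(child.child_id, []),
                observation_limit_days=self.observation_limit_days,
            )


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_datetime(series: pd.Series, *, table: str, column: str, date_only_spans_day: bool = False) -> pd.Series:
    raw = series.astype("string")
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = raw.notna() & (raw.str.strip() != "") & parsed.isna()
    if bad.any():
        row = series.index[bad][0]
        raise CohortError(f"{table} row {row}: unparseable {column} {series[row]!r}")
    if date_only_spans_day:
        date_only = raw.notna() & raw.str.fullmatch(r"\d{4}-\d{2}-\d{2}")
        parsed = parsed.where(~date_only, parsed + pd.Timedelta(days=1))
    return parsed


def normalize_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    """Coerce a raw table to canonical dtypes, validating parse errors."""
    df = df.copy()
    missing = set(TABLE_COLUMNS[name]) - set(df.columns)
    if missing:
        raise CohortError(f"{name}: missing columns {sorted(missing)}")
    unknown = set(df.columns) - set(TABLE_COLUMNS[name])
    if unknown:
        raise CohortError(f"{name}: unknown columns {sorted(unknown)}")
    df = df[TABLE_COLUMNS[name]]
    for col in df.columns:
        if col in ("birth_date", "death_date", "date"):
            df[col] = _parse_datetime(df[col], table=name, column=col)
        elif col == "start":
            df[col] = _parse_datetime(df[col], table=name, column=col)
        elif col == "end":
            df[col] = _parse_datetime(df[col], table=name, column=col, date_only_spans_day=True)
        elif col == "gestational_age_days":
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        elif col in ("is_surgical", "is_cardiothoracic"):
            _flags = {True: 1, False: 0, None: 0, "True": 1, "False": 0, "1": 1, "0": 0, 1: 1, 0: 0}

            def _flag(v, _m=_flags, _name=name, _col=col):
                try:
                    return _m[v]
                except (KeyError, TypeError):
                    if pd.isna(v):
                        return 0
                    raise CohortError(f"{_name}: bad boolean {v!r} in {_col}")

            df[col] = df[col].map(_flag).astype(bool)
        else:

            def _clean(v):
                if pd.isna(v):
                    return None
                v = str(v).strip()
                return v if v else None

            df[col] = df[col].map(_clean)
    return df.reset_index(drop=True)


def read_cohort(
    directory: str | Path,
    observation_limit_days: int = OBSERVATION_LIMIT_DAYS,
    validate: bool = True,
    censor: bool = True,
) -> Cohort:
    """Read the five delimited tables from ``directory`` (gzip accepted)."""
    directory = Path(directory)
    tables = {}
    for name in TABLE_COLUMNS:
        path = directory / f"{name}.csv"
        if not path.exists() and (directory / f"{name}.csv.gz").exists():
            path = directory / f"{name}.csv.gz"
        if not path.exists():
            raise CohortError(f"missing table file {path}")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        raw = raw.replace({"": None})
        tables[name] = normalize_table(raw, name)
    cohort = Cohort(observation_limit_days=observation_limit_days, **tables)
    if validate:
        cohort.validate()
    if censor:
        cohort = cohort.censored()
    return cohort


def _format_dt(series: pd.Series) -> pd.Series:
    def fmt(v):
        if pd.isna(v):
            return ""
        ts = pd.Timestamp(v)
        if ts == ts.normalize():
            return ts.strftime("%Y-%m-%d")
        return ts.strftime("%Y-%m-%dT%H:%M:%S")

    return series.map(fmt)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the five tables as CSV; returns the paths written.

    Note the whole-day convention: an ``end`` timestamp at exactly midnight
    is written back as a bare date (and re-read as spanning that prior day),
    making ``read(write(c))`` the identity on normalized cohorts.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TABLE_COLUMNS:
        df = getattr(cohort, name).copy()
        for col in df.columns:
            if col in ("birth_date", "death_date", "date", "start"):
                df[col] = _format_dt(df[col])
            elif col == "end":
                # invert the whole-day reading convention
                def fmt_end(v):
                    if pd.isna(v):
                        return ""
                    ts = pd.Timestamp(v)
                    if ts == ts.normalize():
                        return (ts - pd.Timedelta(days=1)).strftime("%Y-%m-%d")
                    return ts.strftime("%Y-%m-%dT%H:%M:%S")

                df[col] = df[col].map(fmt_end)
            elif col in ("is_surgical", "is_cardiothoracic"):
                df[col] = df[col].astype(int)
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
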