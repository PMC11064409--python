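"""Configurable vocabularies grounding the code-based phenotyping criteria.

Three primitives are defined here:

* :class:`CodeSet` — a named set of diagnosis/procedure codes with either
  exact or prefix matching.  Prefix matching is the default for ICD code
  sets so that a configured stem (``E71``) matches every child code
  (``E71.0``, ``E71.311`` ...), which keeps a code list robust to the
  granularity at which it was curated.
* :class:`KeywordRule` — an OR-of-AND rule over case-insensitive substrings
  of a free-text label (used for procedure names such as feeding-support
  and ventilation orders).
* :class:`SpecialtyTaxonomy` — the closed list of pediatric specialties
  counted by the multiple-specialists criterion, plus explicit exclusions
  (Pediatric Infectious Disease is excluded because infections are
  predominantly environmental rather than genetic in origin).

The code sets shipped with the package (``data/*.synthetic.csv``) are
synthetic placeholders: clinically plausible ICD-10 stems chosen so the
package is runnable end-to-end, not validated clinical code lists.  Real
deployments must supply their own curated lists via :func:`load_codeset`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CodeSet",
    "KeywordRule",
    "SpecialtyTaxonomy",
    "Vocabulary",
    "VocabularyError",
    "load_codeset",
    "keyword_match",
    "default_taxonomy",
    "default_vocabulary",
]


class VocabularyError(ValueError):
    """Raised for malformed or empty vocabulary configuration."""


def _normalize_code(code: str) -> str:
    return code.strip().upper()


@dataclass(frozen=True)
class CodeSet:
    """A named set of codes with a fixed matching mode.

    ``match_mode`` is ``"prefix"`` (a stored code matches any code it is a
    prefix of) or ``"exact"``.
    """

    name: str
    codes: frozenset[str]
    match_mode: str = "prefix"

    def __post_init__(self) -> None:
        if self.match_mode not in ("exact", "prefix"):
            raise VocabularyError(
                f"codeset {self.name!r}: match_mode must be 'exact' or "
                f"'prefix', got {self.match_mode!r}"
            )
        if not self.codes:
            raise VocabularyError(f"codeset {self.name!r} is empty")

    def matches(self, code: str) -> bool:
        code = _normalize_code(code)
        if not code:
            return False
        if self.match_mode == "exact":
            return code in self.codes
        return any(code.startswith(stem) for stem in self.codes)

    def __contains__(self, code: str) -> bool:
        return self.matches(code)


def load_codeset(
    path: str | Path, match_mode: str = "prefix", name: str | None = None
) -> CodeSet:
    """Load a code set from a delimited file (``code[,description]`` rows).

    A header row whose first cell is ``code`` is skipped.  Duplicate codes
    are silently deduplicated; an empty file or a row with an empty code
    cell is a configuration error naming the offending line.
    """
    path = Path(path)
    codes: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            first = row[0].strip()
            if lineno == 1 and first.lower() == "code":
                continue
            if first.startswith("#"):
                continue
            if not first:
                raise VocabularyError(f"{path}:{lineno}: empty code cell")
            codes.add(_normalize_code(first))
    if not codes:
        raise VocabularyError(f"{path}: no codes loaded")
    return CodeSet(name=name or path.stem, codes=frozenset(codes), match_mode=match_mode)


@dataclass(frozen=True)
class KeywordRule:
    """OR-of-AND substring rule: satisfied if, for some clause, every
    substring in the clause occurs in the lower-cased text."""

    clauses: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise VocabularyError("keyword rule needs at least one clause")
        for clause in self.clauses:
            if not clause or any(not s for s in clause):
                raise VocabularyError("keyword clauses must hold non-empty substrings")

    @classmethod
    def from_clauses(cls, clauses: Sequence[Iterable[str]]) -> "KeywordRule":
        return cls(tuple(frozenset(s.lower() for s in clause) for clause in clauses))

    def matches(self, text: str) -> bool:
        if not text:
            return False
        low = text.lower()
        return any(all(sub in low for sub in clause) for clause in self.clauses)


def keyword_match(text: str, rule: KeywordRule) -> bool:
    """Functional form of :meth:`KeywordRule.matches`."""
    return rule.matches(text)


@dataclass(frozen=True)
class SpecialtyTaxonomy:
    """Specialty labels counted by the multiple-specialists criterion."""

    included: frozenset[str]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.included & self.excluded
        if overlap:
            raise VocabularyError(f"specialties both included and excluded: {sorted(overlap)}")
        if not self.included:
            raise VocabularyError("taxonomy has no included specialties")

    def counts(self, specialty: str) -> bool:
        return specialty in self.included


# The 20 counted specialty types.  The combined gastroenterology/hepatology
# service is represented as two labels (Pediatric GI, Pediatric Liver).
DEFAULT_INCLUDED_SPECIALTIES: tuple[str, ...] = (
    "Medical Genetics",
    "Neurosurgery",
    "Pediatric Allergy and Immunology",
    "Pediatric Cardiology",
    "Pediatric Dermatology",
    "Pediatric Endocrinology",
    "Pediatric GI",
    "Pediatric Liver",
    "Pediatric Hematology/Oncology",
    "Pediatric Nephrology",
    "Pediatric Neurology",
    "Pediatric Ophthalmology",
    "Pediatric Orthopedics",
    "Pediatric Otolaryngology",
    "Pediatric Pulmonology",
    "Pediatric Rheumatology",
    "Pediatric Surgery",
    "Pediatric Urology",
    "Transplant",
    "Plastic Surgery",
)

DEFAULT_EXCLUDED_SPECIALTIES: tuple[str, ...] = ("Pediatric Infectious Disease",)

#: Specialty label identifying a developmental-pediatrician visit (used by
#: the developmental-delay criterion, not part of the counted taxonomy).
DEVELOPMENTAL_SPECIALTY = "Developmental Pediatrics"

#: Discharge dispositions indicating in-hospital death.
DEFAULT_DEATH_DISPOSITIONS: frozenset[str] = frozenset(
    {"expired", "funeral home", "morgue", "organ harvest"}
)

# Procedure-name rules, written exactly as OR-of-AND substring clauses.
FEEDING_KEYWORDS = KeywordRule.from_clauses(
    [["nasogastric"], ["gastrostomy", "feed"], ["gastrostomy", "tube"]]
)
RESPIRATORY_KEYWORDS = KeywordRule.from_clauses(
    [["tracheostomy"], ["ventilation"], ["ventilator"], ["cpap"]]
)


def default_taxonomy() -> SpecialtyTaxonomy:
    return SpecialtyTaxonomy(
        included=frozenset(DEFAULT_INCLUDED_SPECIALTIES),
        excluded=frozenset(DEFAULT_EXCLUDED_SPECIALTIES),
    )


@dataclass(frozen=True)
class Vocabulary:
    """Bundle of every vocabulary object the criteria engine consumes."""

    feeding_codes: CodeSet
    developmental_delay_codes: CodeSet
    metabolic_codes: CodeSet
    respiratory_codes: CodeSet
    feeding_rule: KeywordRule = FEEDING_KEYWORDS
    respiratory_rule: KeywordRule = RESPIRATORY_KEYWORDS
    taxonomy: SpecialtyTaxonomy = field(default_factory=default_taxonomy)
    death_dispositions: frozenset[str] = DEFAULT_DEATH_DISPOSITIONS
    developmental_specialty: str = DEVELOPMENTAL_SPECIALTY

    def is_death_disposition(self, disposition: str | None) -> bool:
        if disposition is None or not isinstance(disposition, str) or not disposition:
            return False
        return disposition.strip().lower() in self.death_dispositions


def _data_path(filename: str) -> Path:
    return Path(resources.files("pheindex").joinpath("data", filename))  # type: ignore[arg-type]


def default_vocabulary() -> Vocabulary:
    """Vocabulary built from the synthetic placeholder code lists shipped
    with the package.  Suitable for simulation and testing only."""
    return Vocabulary(
        feeding_codes=load_codeset(_data_path("feeding_support.synthetic.csv"), "prefix"),
        developmental_delay_codes=load_codeset(
            _data_path("developmental_delay.synthetic.csv"), "prefix"
        ),
        metabolic_codes=load_codeset(_data_path("metabolic_disease.synthetic.csv"), "prefix"),
        respiratory_codes=load_codeset(
            _data_path("respiratory_support.synthetic.csv"), "prefix"
        ),
    )
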