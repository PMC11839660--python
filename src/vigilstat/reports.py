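"""Domain model for spontaneous adverse-event reports.

A spontaneous report (an Individual Case Safety Report) carries one or more
suspected or co-administered drugs, one or more adverse-event terms coded at
the MedDRA preferred-term (PT) level, patient demographics, the reporter's
occupation, and seriousness outcome codes.  This module defines the in-memory
record types plus the case-level operations a disproportionality workflow
needs before any counting happens: case-version deduplication, restriction to
reports where a target drug combination holds the primary-suspect role, and
removal of indication-related event terms.
"""

from __future__ import annotations

import datetime as _dt
import enum
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("vigilstat")

__all__ = [
    "DrugRole",
    "Sex",
    "Occupation",
    "Outcome",
    "DrugEntry",
    "ReportRecord",
    "ReportSet",
    "normalize_drug_name",
    "deduplicate",
    "filter_first_suspect",
    "exclude_terms",
]


class DrugRole(enum.Enum):
    """FAERS drug characterisation codes."""

    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"
    INTERACTING = "I"


class Sex(enum.Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "UNK"


class Occupation(enum.Enum):
    DOCTOR = "MD"
    PHARMACIST = "PH"
    OTHER_MEDICAL = "OT"
    LAWYER = "LW"
    CONSUMER_NONMEDICAL = "CN"
    UNKNOWN = "UNK"


class Outcome(enum.Enum):
    """Serious-outcome codes attached to a report."""

    DEATH = "DE"
    HOSPITALIZATION = "HO"
    CONGENITAL_ANOMALY = "CA"
    DISABLING = "DS"
    LIFE_THREATENING = "LT"


#: Conventional severity ordering, most severe first; used when a report
#: must be counted once under a single outcome class.
OUTCOME_PRIORITY: tuple[Outcome, ...] = (
    Outcome.DEATH,
    Outcome.LIFE_THREATENING,
    Outcome.HOSPITALIZATION,
    Outcome.DISABLING,
    Outcome.CONGENITAL_ANOMALY,
)

_WS = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Case-fold, trim, and collapse internal whitespace.

    No salt/brand resolution is attempted; callers pre-map names to a
    common generic form if their source mixes synonyms.
    """
    return _WS.sub(" ", name.strip()).casefold()


def normalize_pt(pt: str) -> str:
    """Normalise a preferred-term string for set membership (trim + casefold)."""
    return _WS.sub(" ", pt.strip()).casefold()


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report, with its suspected-role code."""

    name: str
    role: DrugRole

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_drug_name(self.name))
        if not self.name:
            raise ValueError("drug name must be non-empty")
        if not isinstance(self.role, DrugRole):
            raise ValueError(f"invalid drug role: {self.role!r}")


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report after parsing.

    ``reactions`` is a set of PT strings (duplicates within one report
    collapse); MedDRA validity is not enforced.  ``age_years`` is ``None``
    when unknown and must be < 150 when known.
    """

    case_id: str
    case_version: int
    drugs: tuple[DrugEntry, ...]
    reactions: frozenset[str]
    sex: Sex = Sex.UNKNOWN
    age_years: float | None = None
    occupation: Occupation = Occupation.UNKNOWN
    outcomes: frozenset[Outcome] = frozenset()
    receipt_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.case_version < 0:
            raise ValueError("case_version must be non-negative")
        if not self.drugs:
            raise ValueError(f"report {self.case_id}: at least one drug required")
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "reactions", frozenset(self.reactions))
        if not self.reactions:
            raise ValueError(f"report {self.case_id}: at least one reaction required")
        object.__setattr__(self, "outcomes", frozenset(self.outcomes))
        if self.age_years is not None:
            if not (0 <= self.age_years < 150):
                raise ValueError(
                    f"report {self.case_id}: age {self.age_years} outside [0, 150)"
                )

    def has_primary_suspect(self, name: str) -> bool:
        norm = normalize_drug_name(name)
        return any(
            d.name == norm and d.role is DrugRole.PRIMARY_SUSPECT for d in self.drugs
        )

    def has_suspect(self, name: str) -> bool:
        """True when the drug appears with a suspect role (PS or SS)."""
        norm = normalize_drug_name(name)
        return any(
            d.name == norm
            and d.role in (DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT)
            for d in self.drugs
        )

    def primary_outcome(self) -> Outcome | None:
        """Highest-priority serious outcome, or None for a non-serious report."""
        for o in OUTCOME_PRIORITY:
            if o in self.outcomes:
                return o
        return None


@dataclass
class ReportSet:
    """An ordered collection of reports plus a provenance trail.

    After :func:`deduplicate` the ``case_id`` values are unique; readers and
    the synthetic generator may legitimately carry several versions of one
    case until then.
    """

    reports: list[ReportRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        return self.reports == other.reports

    def case_ids(self) -> set[str]:
        return {r.case_id for r in self.reports}

    def with_note(self, note: str) -> "ReportSet":
        return ReportSet(self.reports, [*self.provenance, note])

    def all_pts(self) -> set[str]:
        out: set[str] = set()
        for r in self.reports:
            out |= r.reactions
        return out


def deduplicate(rs: ReportSet) -> ReportSet:
    """Keep one record per case_id: highest version, then latest receipt date.

    FAERS re-submits a case as a new version when it is amended; only the
    most recent version should be counted.  Ties on version are broken by
    the latest receipt date, then by last occurrence in input order.
    Output preserves first-occurrence order of the surviving case ids.
    """
    best: dict[str, tuple[int, ReportRecord]] = {}
    order: list[str] = []
    for idx, rec in enumerate(rs.reports):
        if rec.case_id not in best:
            order.append(rec.case_id)
            best[rec.case_id] = (idx, rec)
            continue
        _, cur = best[rec.case_id]
        if _dedup_key(rec, idx) >= _dedup_key(cur, best[rec.case_id][0]):
            best[rec.case_id] = (idx, rec)
    kept = [best[cid][1] for cid in order]
    dropped = len(rs.reports) - len(kept)
    return ReportSet(
        kept, [*rs.provenance, f"deduplicate: kept {len(kept)}, dropped {dropped}"]
    )


def _dedup_key(rec: ReportRecord, idx: int) -> tuple[int, _dt.date, int]:
    date = rec.receipt_date or _dt.date.min
    return (rec.case_version, date, idx)


def filter_first_suspect(
    rs: ReportSet,
    drug_names: Iterable[str],
    *,
    allow_secondary: bool = False,
) -> ReportSet:
    """Retain reports where every target drug holds a suspect role.

    The default reading is strict: each name in ``drug_names`` must appear
    on the report with the primary-suspect role.  ``allow_secondary=True``
    relaxes the requirement to any suspect role (PS or SS).
    """
    names = [normalize_drug_name(n) for n in drug_names]
    if not names:
        raise ValueError("drug_names must be non-empty")
    check = ReportRecord.has_suspect if allow_secondary else ReportRecord.has_primary_suspect
    kept = [r for r in rs.reports if all(check(r, n) for n in names)]
    note = (
        f"filter_first_suspect({sorted(names)}, allow_secondary={allow_secondary}): "
        f"{len(rs.reports)} -> {len(kept)}"
    )
    return ReportSet(kept, [*rs.provenance, note])


def exclude_terms(rs: ReportSet, exclusion_pts: Iterable[str]) -> ReportSet:
    """Remove indication-related PTs from every report.

    Event terms that merely restate the treated disease (the drug's
    indication or a concomitant condition) are not adverse events; they are
    stripped from each report's reaction set, and a report left with no
    reactions is dropped.  Matching is case-insensitive after normalisation.
    """
    excl = {normalize_pt(p) for p in exclusion_pts}
    kept: list[ReportRecord] = []
    removed_mentions = 0
    dropped = 0
    for rec in rs.reports:
        remaining = frozenset(p for p in rec.reactions if normalize_pt(p) not in excl)
        removed_mentions += len(rec.reactions) - len(remaining)
        if not remaining:
            dropped += 1
            continue
        if remaining == rec.reactions:
            kept.append(rec)
        else:
            kept.append(replace(rec, reactions=remaining))
    note = (
        f"exclude_terms({len(excl)} PTs): removed {removed_mentions} mentions, "
        f"dropped {dropped} emptied reports, {len(rs.reports)} -> {len(kept)}"
    )
    return ReportSet(kept, [*rs.provenance, note])
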