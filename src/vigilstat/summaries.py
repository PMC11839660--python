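"""Counts-and-percentages rollups over report cohorts and signal lists.

Covers the descriptive side of a pharmacovigilance study: the demographic
and seriousness composition of the retained cohort, aggregation of detected
signals to MedDRA System Organ Class (SOC) level, and flagging which signal
PTs are already documented in the product labels.  Percentages are rounded
half-up to two decimals, the convention used in published report tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import SignalResult
from .reports import (
    OUTCOME_PRIORITY,
    Occupation,
    Outcome,
    ReportSet,
    Sex,
    normalize_pt,
)

logger = logging.getLogger("vigilstat")

__all__ = [
    "SocMap",
    "LabelList",
    "SummaryRow",
    "SummaryTable",
    "round_percent",
    "demographics_summary",
    "soc_rollup",
    "annotate_labels",
]

UNMAPPED = "Unmapped"

#: Age bands as printed in demographic tables; edges inclusive as labelled.
AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("<18", 0.0, 18.0),       # [0, 18)
    ("18-44", 18.0, 45.0),    # [18, 45)
    ("45-64", 45.0, 65.0),    # [45, 65)
    ("65-74", 65.0, 75.0),    # [65, 75)
    (">=75", 75.0, 150.0),    # [75, ...)
)

_SEX_LABELS = {Sex.MALE: "Male", Sex.FEMALE: "Female", Sex.UNKNOWN: "Unknown"}
_OCC_LABELS = {
    Occupation.DOCTOR: "Doctor",
    Occupation.PHARMACIST: "Pharmacist",
    Occupation.OTHER_MEDICAL: "Other medical staff",
    Occupation.LAWYER: "Lawyer",
    Occupation.CONSUMER_NONMEDICAL: "Consumer or non-medical staff",
    Occupation.UNKNOWN: "Unknown",
}
_OUT_LABELS = {
    Outcome.DEATH: "Death",
    Outcome.HOSPITALIZATION: "Hospitalization",
    Outcome.CONGENITAL_ANOMALY: "Congenital anomalies",
    Outcome.DISABLING: "Disabling",
    Outcome.LIFE_THREATENING: "Life threatening",
}


def round_percent(count: float, denominator: float) -> float:
    """100*count/denominator rounded half-up to 2 decimals."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryRow:
    block: str
    label: str
    count: int
    percent: float


@dataclass
class SummaryTable:
    """Blocks of (label, count, percent) rows sharing one denominator."""

    rows: list[SummaryRow]
    denominator: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [r.block for r in self.rows],
                "label": [r.label for r in self.rows],
                "count": [r.count for r in self.rows],
                "percent": [r.percent for r in self.rows],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def lookup(self, block: str, label: str) -> SummaryRow:
        for r in self.rows:
            if r.block == block and r.label == label:
                return r
        raise KeyError((block, label))


def demographics_summary(rs: ReportSet) -> SummaryTable:
    """Cohort composition: sex, age bands, reporter occupation, seriousness.

    Each block shares the cohort size as denominator.  For seriousness a
    report is counted once under its highest-priority outcome (death >
    life-threatening > hospitalization > disabling > congenital anomaly),
    and a derived "Serious total" row counts reports with any serious
    outcome.
    """
    n = len(rs.reports)
    rows: list[SummaryRow] = []

    sex_counts = {s: 0 for s in (Sex.MALE, Sex.FEMALE, Sex.UNKNOWN)}
    for rec in rs.reports:
        sex_counts[rec.sex] += 1
    for s, c in sex_counts.items():
        rows.append(SummaryRow("Gender", _SEX_LABELS[s], c, round_percent(c, n)))

    band_counts = {label: 0 for label, _, _ in AGE_BANDS}
    age_unknown = 0
    for rec in rs.reports:
        if rec.age_years is None:
            age_unknown += 1
            continue
        for label, lo, hi in AGE_BANDS:
            if lo <= rec.age_years < hi:
                band_counts[label] += 1
                break
    for label, _, _ in AGE_BANDS:
        c = band_counts[label]
        rows.append(SummaryRow("Age, years", label, c, round_percent(c, n)))
    rows.append(
        SummaryRow("Age, years", "Unknown", age_unknown, round_percent(age_unknown, n))
    )

    occ_counts = {o: 0 for o in _OCC_LABELS}
    for rec in rs.reports:
        occ_counts[rec.occupation] += 1
    for o, label in _OCC_LABELS.items():
        c = occ_counts[o]
        rows.append(SummaryRow("Occupation", label, c, round_percent(c, n)))

    out_counts = {o: 0 for o in OUTCOME_PRIORITY}
    serious_total = 0
    for rec in rs.reports:
        top = rec.primary_outcome()
        if top is not None:
            out_counts[top] += 1
            serious_total += 1
    for o in (
        Outcome.DEATH,
        Outcome.HOSPITALIZATION,
        Outcome.CONGENITAL_ANOMALY,
        Outcome.DISABLING,
        Outcome.LIFE_THREATENING,
    ):
        c = out_counts[o]
        rows.append(
            SummaryRow("Serious adverse events", _OUT_LABELS[o], c, round_percent(c, n))
        )
    rows.append(
        SummaryRow(
            "Serious adverse events",
            "Serious total",
            serious_total,
            round_percent(serious_total, n),
        )
    )
    return SummaryTable(rows, n)


@dataclass
class SocMap:
    """PT -> System Organ Class mapping supplied by the user.

    MedDRA itself is licensed and not redistributed; the map is read from a
    two-column TSV (PT, SOC).  Unmapped PTs resolve to the sentinel
    ``"Unmapped"``.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {normalize_pt(k): v for k, v in self.entries.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SocMap":
        entries: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for ln in fh:
                ln = ln.rstrip("\n")
                if not ln.strip() or ln.startswith("#"):
                    continue
                parts = ln.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: expected 'PT<TAB>SOC', got {ln!r}")
                entries[parts[0]] = parts[1].strip()
        return cls(entries)

    def soc_of(self, pt: str) -> str:
        return self.entries.get(normalize_pt(pt), UNMAPPED)


@dataclass
class LabelList:
    """Set of PTs documented in the combined product labels."""

    terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.terms = {normalize_pt(t) for t in self.terms}

    @classmethod
    def from_file(cls, path: str | Path) -> "LabelList":
        with open(path, encoding="utf-8") as fh:
            terms = {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}
        return cls(terms)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.terms


def soc_rollup(
    signals: Sequence[SignalResult], soc: SocMap, total_reports: int
) -> SummaryTable:
    """Aggregate per-PT report counts to SOC level.

    count(SOC) = sum of a over member PTs; percent uses the cohort size as
    denominator.  Rows sorted by count descending (ties alphabetical).
    Cell counts are conserved: the SOC counts sum to the PT counts.
    """
    seen: set[str] = set()
    soc_counts: dict[str, int] = {}
    for s in signals:
        if s.pt in seen:
            raise ValueError(f"PT {s.pt!r} appears more than once in the signal list")
        seen.add(s.pt)
        name = soc.soc_of(s.pt)
        if name == UNMAPPED:
            logger.warning("PT %r not in SOC map, grouped under %r", s.pt, UNMAPPED)
        soc_counts[name] = soc_counts.get(name, 0) + s.a
    rows = [
        SummaryRow("SOC", name, c, round_percent(c, total_reports))
        for name, c in sorted(soc_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return SummaryTable(rows, total_reports)


def annotate_labels(
    signals: Sequence[SignalResult], labels: LabelList
) -> tuple[list[tuple[SignalResult, bool]], dict[str, int]]:
    """Flag each signal PT as listed/unlisted in the product labels.

    Returns the annotated list plus summary counts of listed/unlisted PTs
    among the rows with ``is_signal`` set.
    """
    annotated = [(s, s.pt in labels) for s in signals]
    listed = sum(1 for s, flag in annotated if flag and s.is_signal)
    unlisted = sum(1 for s, flag in annotated if not flag and s.is_signal)
    return annotated, {"listed": listed, "unlisted": unlisted}
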