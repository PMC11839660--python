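"""Model/Results objects for signal detection on report cohorts.

`DisproportionalityModel` compares an exposed cohort (reports where the
target drug combination is suspect) against a background cohort (all other
reports) and, per preferred term, computes PRR, ROR and the BCPNN
information component with the joint signal criterion

    a >= 3  and  PRR 95% CI lower bound > 1
            and  ROR 95% CI lower bound > 1
            and  IC - 2SD > 0.

`SexStratifiedROR` looks *within* the exposed cohort and asks, per PT,
whether female patients are over-represented among its reporters: an odds
ratio (a_f·b_m)/(b_f·a_m) > 1 means the event is reported relatively more
often for women.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

from .contingency import (
    DEFAULT_BCPNN,
    BcpnnParams,
    RatioResult,
    TwoByTwo,
    bcpnn_stat,
    prr_stat,
    ror_stat,
    Z_95,
)
from .reports import ReportSet, Sex

__all__ = [
    "SignalResult",
    "DisproportionalityModel",
    "DisproportionalityResults",
    "count_pt_pairs",
    "top_n_events",
    "SexStratum2x2",
    "SexStratifiedROR",
    "SexStratifiedRORResults",
]

CountingMode = Literal["event_pairs", "reports"]
CriteriaMode = Literal["conjunction", "disjunction"]


def count_pt_pairs(
    exposed: ReportSet,
    background: ReportSet,
    *,
    counting: CountingMode = "event_pairs",
) -> dict[str, TwoByTwo]:
    """Build one 2x2 table per PT occurring in the exposed cohort.

    The counting unit is a distinct (report, PT) pair: a report listing k
    PTs contributes k to its cohort margin, so b counts the exposed pairs
    whose PT is *not* the one tabulated.  ``counting="reports"`` instead
    counts each report once per cell (b = exposed reports without the PT).
    PTs seen only in the background never get a table.
    """
    overlap = exposed.case_ids() & background.case_ids()
    if overlap:
        raise ValueError(
            f"exposed and background share case ids, e.g. {sorted(overlap)[:3]}"
        )
    exp_counts = _pt_counts(exposed)
    bg_counts = _pt_counts(background)
    if counting == "event_pairs":
        exp_total = sum(exp_counts.values())
        bg_total = sum(bg_counts.values())
    elif counting == "reports":
        exp_total = len(exposed)
        bg_total = len(background)
    else:
        raise ValueError(f"unknown counting mode {counting!r}")
    tables: dict[str, TwoByTwo] = {}
    for pt, a in exp_counts.items():
        c = bg_counts.get(pt, 0)
        tables[pt] = TwoByTwo(a=a, b=exp_total - a, c=c, d=bg_total - c)
    return tables


def _pt_counts(rs: ReportSet) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in rs.reports:
        for pt in rec.reactions:
            counts[pt] = counts.get(pt, 0) + 1
    return counts


def top_n_events(tables: Mapping[str, TwoByTwo], n: int) -> list[str]:
    """The n most-reported PTs: a descending, ties broken alphabetically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(tables, key=lambda pt: (-tables[pt].a, pt))
    return ranked[:n]


@dataclass(frozen=True)
class SignalResult:
    """Per-PT statistics bundle with criterion flags."""

    pt: str
    a: int
    report_fraction: float
    prr: RatioResult
    ror: RatioResult
    eic: float
    vic: float
    ic_minus_2sd: float
    passes_prr: bool
    passes_ror: bool
    passes_bcpnn: bool
    is_signal: bool
    table: TwoByTwo


class DisproportionalityModel:
    """Signal-detection model over an exposed/background cohort split.

    Parameters
    ----------
    exposed, background
        Disjoint report sets (case ids must not overlap).  ``exposed``
        typically comes out of the suspect-drug filter, ``background`` is
        everything else in the database extract.
    counting
        ``"event_pairs"`` (default) or ``"reports"``; see
        :func:`count_pt_pairs`.
    bcpnn_params
        Prior constants for the information component.
    """

    def __init__(
        self,
        exposed: ReportSet,
        background: ReportSet,
        *,
        counting: CountingMode = "event_pairs",
        bcpnn_params: BcpnnParams = DEFAULT_BCPNN,
    ) -> None:
        self.exposed = exposed
        self.background = background
        self.counting = counting
        self.bcpnn_params = bcpnn_params
        self.tables = count_pt_pairs(exposed, background, counting=counting)

    def fit(
        self,
        n_top: int = 250,
        *,
        criteria: CriteriaMode = "conjunction",
        min_a: int = 3,
    ) -> "DisproportionalityResults":
        """Compute all three statistics for the ``n_top`` most-reported PTs.

        ``criteria`` controls the joint flag: ``"conjunction"`` requires all
        three methods to pass, ``"disjunction"`` any one of them.
        """
        order = top_n_events(self.tables, n_top)
        total_reports = len(self.exposed)
        rows: list[SignalResult] = []
        for pt in order:
            t = self.tables[pt]
            prr = prr_stat(t)
            ror = ror_stat(t)
            ic = bcpnn_stat(t, self.bcpnn_params)
            passes_prr = bool(t.a >= min_a and prr.defined and prr.ci_low > 1)
            passes_ror = bool(t.a >= min_a and ror.defined and ror.ci_low > 1)
            passes_bcpnn = bool(ic.ic_minus_2sd > 0)
            flags = (passes_prr, passes_ror, passes_bcpnn)
            is_signal = all(flags) if criteria == "conjunction" else any(flags)
            rows.append(
                SignalResult(
                    pt=pt,
                    a=t.a,
                    report_fraction=t.a / total_reports if total_reports else math.nan,
                    prr=prr,
                    ror=ror,
                    eic=ic.eic,
                    vic=ic.vic,
                    ic_minus_2sd=ic.ic_minus_2sd,
                    passes_prr=passes_prr,
                    passes_ror=passes_ror,
                    passes_bcpnn=passes_bcpnn,
                    is_signal=is_signal,
                    table=t,
                )
            )
        return DisproportionalityResults(self, rows, criteria=criteria, min_a=min_a)


@dataclass
class DisproportionalityResults:
    """Fitted per-PT signal statistics, ordered by report count."""

    model: DisproportionalityModel
    signals: list[SignalResult]
    criteria: CriteriaMode = "conjunction"
    min_a: int = 3

    def __iter__(self):
        return iter(self.signals)

    def __len__(self) -> int:
        return len(self.signals)

    @property
    def n_signals(self) -> int:
        return sum(s.is_signal for s in self.signals)

    def flagged(self) -> list[SignalResult]:
        return [s for s in self.signals if s.is_signal]

    def to_frame(self) -> pd.DataFrame:
        """Full-precision results table, one row per PT in rank order."""
        return pd.DataFrame(
            {
                "pt": [s.pt for s in self.signals],
                "a": [s.a for s in self.signals],
                "percent": [100 * s.report_fraction for s in self.signals],
                "prr": [s.prr.estimate for s in self.signals],
                "prr_ci_low": [s.prr.ci_low for s in self.signals],
                "prr_ci_high": [s.prr.ci_high for s in self.signals],
                "ror": [s.ror.estimate for s in self.signals],
                "ror_ci_low": [s.ror.ci_low for s in self.signals],
                "ror_ci_high": [s.ror.ci_high for s in self.signals],
                "eic": [s.eic for s in self.signals],
                "ic_minus_2sd": [s.ic_minus_2sd for s in self.signals],
                "passes_prr": [s.passes_prr for s in self.signals],
                "passes_ror": [s.passes_ror for s in self.signals],
                "passes_bcpnn": [s.passes_bcpnn for s in self.signals],
                "is_signal": [s.is_signal for s in self.signals],
            }
        )

    def to_display_frame(self) -> pd.DataFrame:
        """Rounded 2-decimal display variant: PRR (CI) / ROR (CI) / IC (IC−2SD)."""
        rows = []
        for s in self.signals:
            rows.append(
                {
                    "pt": s.pt,
                    "reports": s.a,
                    "percent": f"{100 * s.report_fraction:.2f}%",
                    "prr_95ci": _fmt_ratio(s.prr),
                    "ror_95ci": _fmt_ratio(s.ror),
                    "ic_ic2sd": f"{s.eic:.2f} ({s.ic_minus_2sd:.2f})",
                    "signal": "Yes" if s.is_signal else "No",
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        head = (
            f"Disproportionality analysis: {len(self.model.exposed)} exposed reports, "
            f"{len(self.model.background)} background reports\n"
            f"Counting unit: {self.model.counting}; criterion: {self.criteria} "
            f"(a >= {self.min_a}, CI lower bound > 1, IC-2SD > 0)\n"
            f"PTs evaluated: {len(self.signals)}; signals: {self.n_signals}\n\n"
        )
        return head + self.to_display_frame().to_string(index=False)


def _fmt_ratio(r: RatioResult) -> str:
    if not r.defined:
        return "NA"
    return f"{r.estimate:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})"


# --------------------------------------------------------------------------
# Gender-stratified ROR within the exposed cohort


@dataclass(frozen=True)
class SexStratum2x2:
    """Report-level sex-by-PT table; unknown-sex reports are excluded."""

    a_f: int  # female reports with the PT
    b_f: int  # female reports without the PT
    a_m: int  # male reports with the PT
    b_m: int  # male reports without the PT

    def __post_init__(self) -> None:
        if min(self.a_f, self.b_f, self.a_m, self.b_m) < 0:
            raise ValueError("cell counts must be non-negative")


def _sex_stratum(exposed: ReportSet, pt: str) -> SexStratum2x2:
    a_f = b_f = a_m = b_m = 0
    for rec in exposed.reports:
        if rec.sex is Sex.FEMALE:
            if pt in rec.reactions:
                a_f += 1
            else:
                b_f += 1
        elif rec.sex is Sex.MALE:
            if pt in rec.reactions:
                a_m += 1
            else:
                b_m += 1
    return SexStratum2x2(a_f, b_f, a_m, b_m)


def _sex_ror_from_stratum(s: SexStratum2x2) -> RatioResult:
    if 0 in (s.a_f, s.b_f, s.a_m, s.b_m):
        return RatioResult(math.nan, math.nan, math.nan)
    ror = (s.a_f * s.b_m) / (s.b_f * s.a_m)
    se = math.sqrt(1 / s.a_f + 1 / s.b_f + 1 / s.a_m + 1 / s.b_m)
    return RatioResult(ror, ror * math.exp(-Z_95 * se), ror * math.exp(Z_95 * se))


def sex_ror(exposed: ReportSet, pt: str) -> tuple[RatioResult, int]:
    """Female-vs-male reporting odds ratio for one PT.

    Counting is report-wise (a report counts once when the PT is in its
    reaction set); unknown-sex reports are excluded from all cells.  An OR
    above 1 means the event is reported relatively more often for female
    patients.  Returns (ratio result, a_f + a_m).  Any zero cell yields an
    undefined (NaN) result.
    """
    if not exposed.reports:
        raise ValueError("exposed cohort is empty")
    s = _sex_stratum(exposed, pt)
    return _sex_ror_from_stratum(s), s.a_f + s.a_m


class SexStratifiedROR:
    """Gender-difference model over the exposed cohort only."""

    def __init__(self, exposed: ReportSet) -> None:
        if not exposed.reports:
            raise ValueError("exposed cohort is empty")
        self.exposed = exposed

    def fit(self, k: int = 10) -> "SexStratifiedRORResults":
        """Sex-stratified ROR for the k most-reported PTs.

        PT ranking counts reports of any sex (including unknown), matching
        the overall most-frequent list; the odds ratio itself then uses
        only known-sex reports.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        counts: dict[str, int] = {}
        for rec in self.exposed.reports:
            for pt in rec.reactions:
                counts[pt] = counts.get(pt, 0) + 1
        ranked = sorted(counts, key=lambda pt: (-counts[pt], pt))[:k]
        rows = []
        for pt in ranked:
            stratum = _sex_stratum(self.exposed, pt)
            rows.append(
                {
                    "pt": pt,
                    "reports": counts[pt],
                    "stratum": stratum,
                    "ror": _sex_ror_from_stratum(stratum),
                }
            )
        return SexStratifiedRORResults(self, rows)


@dataclass
class SexStratifiedRORResults:
    model: SexStratifiedROR
    rows: list[dict]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pt": [r["pt"] for r in self.rows],
                "reports": [r["reports"] for r in self.rows],
                "ror": [r["ror"].estimate for r in self.rows],
                "ror_ci_low": [r["ror"].ci_low for r in self.rows],
                "ror_ci_high": [r["ror"].ci_high for r in self.rows],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        head = (
            f"Sex-stratified ROR on {len(self.model.exposed)} exposed reports "
            f"(OR > 1: reported more often for female patients)\n\n"
        )
        disp = pd.DataFrame(
            {
                "pt": [r["pt"] for r in self.rows],
                "reports": [r["reports"] for r in self.rows],
                "ror_95ci": [_fmt_ratio(r["ror"]) for r in self.rows],
            }
        )
        return head + disp.to_string(index=False)
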