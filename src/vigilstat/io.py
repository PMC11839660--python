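"""Readers and writers for the two supported report-file dialects.

Flat dialect
    A single CSV with one row per report.  Multi-valued fields (drug names,
    drug roles, reaction PTs, outcome codes) are packed into one cell with a
    ``|`` separator.  Dates are ISO-8601.  Column names can be remapped via
    a dialect dictionary.

FAERS-like ASCII dialect
    Four ``$``-delimited tables mirroring the quarterly FAERS extract
    layout: DEMO (one row per case), DRUG, REAC and OUTC (one row per drug /
    reaction / outcome mention, joined on the case identifier).  Role codes
    are PS/SS/C/I and outcome codes DE/HO/CA/DS/LT; dates are YYYYMMDD.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from pathlib import Path
from typing import Mapping, Sequence

from .reports import (
    DrugEntry,
    DrugRole,
    Occupation,
    Outcome,
    ReportRecord,
    ReportSet,
    Sex,
)

logger = logging.getLogger("vigilstat")

__all__ = [
    "FormatError",
    "FLAT_COLUMNS",
    "read_flat_csv",
    "write_flat_csv",
    "read_faers_ascii",
    "write_faers_ascii",
]


class FormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


MULTI_SEP = "|"

FLAT_COLUMNS: tuple[str, ...] = (
    "case_id",
    "case_version",
    "drugs",
    "roles",
    "reactions",
    "sex",
    "age",
    "occupation",
    "outcomes",
    "receipt_date",
)

_ROLE_CODES = {r.value: r for r in DrugRole}
_SEX_CODES = {s.value: s for s in Sex}
_OCC_CODES = {o.value: o for o in Occupation}
_OUT_CODES = {o.value: o for o in Outcome}


def _decode(mapping: Mapping[str, object], token: str, unknown, what: str, ctx: str):
    token = token.strip().upper()
    if not token:
        return unknown
    if token in mapping:
        return mapping[token]
    logger.warning("%s: unknown %s code %r mapped to unknown", ctx, what, token)
    return unknown


def _parse_date(token: str, fmt: str, ctx: str) -> _dt.date | None:
    token = token.strip()
    if not token:
        return None
    try:
        return _dt.datetime.strptime(token, fmt).date()
    except ValueError:
        logger.warning("%s: unparseable date %r treated as unknown", ctx, token)
        return None


def _parse_age(token: str, ctx: str) -> float | None:
    token = token.strip()
    if not token:
        return None
    try:
        age = float(token)
    except ValueError:
        logger.warning("%s: unparseable age %r treated as unknown", ctx, token)
        return None
    if not (0 <= age < 150):
        logger.warning("%s: implausible age %r treated as unknown", ctx, token)
        return None
    return age


def read_flat_csv(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> ReportSet:
    """Read the one-row-per-report CSV dialect.

    ``dialect`` maps canonical column names (the ``FLAT_COLUMNS`` entries)
    to the header names actually present in the file.  Rows with an empty
    reaction field are skipped; the skip count lands in the provenance.
    """
    path = Path(path)
    colmap = {c: c for c in FLAT_COLUMNS}
    if dialect:
        colmap.update(dialect)
    reports: list[ReportRecord] = []
    skipped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canonical, actual in colmap.items():
            if actual not in header:
                raise FormatError(
                    f"{path}: missing mandatory column {actual!r} (for {canonical})"
                )
        for lineno, row in enumerate(reader, start=2):
            ctx = f"{path}:{lineno}"
            reactions = _split(row[colmap["reactions"]])
            if not reactions:
                skipped += 1
                logger.warning("%s: empty reaction field, row skipped", ctx)
                continue
            names = _split(row[colmap["drugs"]])
            roles = _split(row[colmap["roles"]])
            if len(roles) != len(names):
                raise FormatError(
                    f"{ctx}: {len(names)} drugs but {len(roles)} roles"
                )
            drugs = tuple(
                DrugEntry(n, _decode(_ROLE_CODES, r, DrugRole.CONCOMITANT, "role", ctx))
                for n, r in zip(names, roles)
            )
            outcomes = frozenset(
                o
                for tok in _split(row[colmap["outcomes"]])
                if (o := _decode(_OUT_CODES, tok, None, "outcome", ctx)) is not None
            )
            reports.append(
                ReportRecord(
                    case_id=row[colmap["case_id"]].strip(),
                    case_version=int(row[colmap["case_version"]] or 0),
                    drugs=drugs,
                    reactions=frozenset(reactions),
                    sex=_decode(_SEX_CODES, row[colmap["sex"]], Sex.UNKNOWN, "sex", ctx),
                    age_years=_parse_age(row[colmap["age"]], ctx),
                    occupation=_decode(
                        _OCC_CODES,
                        row[colmap["occupation"]],
                        Occupation.UNKNOWN,
                        "occupation",
                        ctx,
                    ),
                    outcomes=outcomes,
                    receipt_date=_parse_date(
                        row[colmap["receipt_date"]], "%Y-%m-%d", ctx
                    ),
                )
            )
    return ReportSet(
        reports,
        [f"read_flat_csv({path}): {len(reports)} reports, {skipped} rows skipped"],
    )


def _split(cell: str | None) -> list[str]:
    if cell is None:
        return []
    return [tok.strip() for tok in cell.split(MULTI_SEP) if tok.strip()]


def write_flat_csv(rs: ReportSet, path: str | Path) -> None:
    """Write the flat dialect deterministically (rows sorted by case id).

    ``read_flat_csv(write_flat_csv(rs))`` reproduces all typed fields.
    """
    path = Path(path)
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(FLAT_COLUMNS)
            for rec in sorted(rs.reports, key=lambda r: (r.case_id, r.case_version)):
                writer.writerow(_flat_row(rec))
    except OSError as exc:
        raise OSError(f"cannot write flat CSV to {path}: {exc}") from exc


def _flat_row(rec: ReportRecord) -> list[str]:
    return [
        rec.case_id,
        str(rec.case_version),
        MULTI_SEP.join(d.name for d in rec.drugs),
        MULTI_SEP.join(d.role.value for d in rec.drugs),
        MULTI_SEP.join(sorted(rec.reactions)),
        rec.sex.value,
        "" if rec.age_years is None else _fmt_age(rec.age_years),
        rec.occupation.value,
        MULTI_SEP.join(sorted(o.value for o in rec.outcomes)),
        "" if rec.receipt_date is None else rec.receipt_date.isoformat(),
    ]


def _fmt_age(age: float) -> str:
    return str(int(age)) if float(age).is_integer() else repr(age)


# --------------------------------------------------------------------------
# FAERS-like ASCII ($-delimited multi-table) dialect

DEMO_COLUMNS = ("primaryid", "caseid", "caseversion", "sex", "age", "occp_cod", "rept_dt")
DRUG_COLUMNS = ("primaryid", "drugname", "role_cod")
REAC_COLUMNS = ("primaryid", "pt")
OUTC_COLUMNS = ("primaryid", "outc_cod")


def _read_dollar_table(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].strip():
        raise FormatError(f"{path}: missing header line")
    header = [h.strip().lower() for h in lines[0].split("$")]
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    rows = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        cells = ln.split("$")
        rows.append({h: (cells[i] if i < len(cells) else "") for i, h in enumerate(header)})
    return rows


def read_faers_ascii(
    demo: str | Path, drug: str | Path, reac: str | Path, outc: str | Path
) -> ReportSet:
    """Join the four ``$``-delimited tables into a ReportSet.

    DEMO defines the case universe; the join key is ``primaryid`` (the
    case identifier with its version suffix, as in the quarterly extract).
    DRUG/REAC/OUTC rows referencing a primaryid absent from DEMO are
    orphans and are dropped with a warning.  Cases with no reaction rows
    are dropped (a report must carry at least one event term); an empty
    OUTC table simply means no serious outcomes.
    """
    demo_rows = _read_dollar_table(demo, DEMO_COLUMNS)
    drug_rows = _read_dollar_table(drug, DRUG_COLUMNS)
    reac_rows = _read_dollar_table(reac, REAC_COLUMNS)
    outc_rows = _read_dollar_table(outc, OUTC_COLUMNS)

    known = {r["primaryid"].strip() for r in demo_rows}
    orphans = 0

    drugs_by_case: dict[str, list[DrugEntry]] = {}
    for row in drug_rows:
        cid = row["primaryid"].strip()
        if cid not in known:
            orphans += 1
            logger.warning("DRUG row for unknown case %r dropped", cid)
            continue
        role = _decode(_ROLE_CODES, row["role_cod"], DrugRole.CONCOMITANT, "role", cid)
        drugs_by_case.setdefault(cid, []).append(DrugEntry(row["drugname"], role))

    reac_by_case: dict[str, set[str]] = {}
    for row in reac_rows:
        cid = row["primaryid"].strip()
        if cid not in known:
            orphans += 1
            logger.warning("REAC row for unknown case %r dropped", cid)
            continue
        pt = row["pt"].strip()
        if pt:
            reac_by_case.setdefault(cid, set()).add(pt)

    outc_by_case: dict[str, set[Outcome]] = {}
    for row in outc_rows:
        cid = row["primaryid"].strip()
        if cid not in known:
            orphans += 1
            logger.warning("OUTC row for unknown case %r dropped", cid)
            continue
        o = _decode(_OUT_CODES, row["outc_cod"], None, "outcome", cid)
        if o is not None:
            outc_by_case.setdefault(cid, set()).add(o)

    reports: list[ReportRecord] = []
    no_reaction = 0
    for row in demo_rows:
        cid = row["primaryid"].strip()
        reactions = reac_by_case.get(cid)
        if not reactions:
            no_reaction += 1
            logger.warning("case %r has no reaction rows, dropped", cid)
            continue
        drugs = drugs_by_case.get(cid)
        if not drugs:
            no_reaction += 1
            logger.warning("case %r has no drug rows, dropped", cid)
            continue
        reports.append(
            ReportRecord(
                case_id=row["caseid"].strip() or cid,
                case_version=int(row["caseversion"] or 0),
                drugs=tuple(drugs),
                reactions=frozenset(reactions),
                sex=_decode(_SEX_CODES, row["sex"], Sex.UNKNOWN, "sex", cid),
                age_years=_parse_age(row["age"], cid),
                occupation=_decode(
                    _OCC_CODES, row["occp_cod"], Occupation.UNKNOWN, "occupation", cid
                ),
                outcomes=frozenset(outc_by_case.get(cid, set())),
                receipt_date=_parse_date(row["rept_dt"], "%Y%m%d", cid),
            )
        )
    return ReportSet(
        reports,
        [
            f"read_faers_ascii({Path(demo).name},...): {len(reports)} reports, "
            f"{no_reaction} incomplete cases dropped, {orphans} orphan rows dropped"
        ],
    )


def write_faers_ascii(
    rs: ReportSet,
    demo: str | Path,
    drug: str | Path,
    reac: str | Path,
    outc: str | Path,
) -> None:
    """Emit the four ``$``-delimited tables (rows sorted by case id)."""
    recs = sorted(rs.reports, key=lambda r: (r.case_id, r.case_version))

    def pid(r):
        return f"{r.case_id}-{r.case_version}"

    with open(demo, "w", encoding="utf-8") as fh:
        fh.write("$".join(DEMO_COLUMNS) + "\n")
        for r in recs:
            fh.write(
                "$".join(
                    [
                        pid(r),
                        r.case_id,
                        str(r.case_version),
                        r.sex.value,
                        "" if r.age_years is None else _fmt_age(r.age_years),
                        r.occupation.value,
                        "" if r.receipt_date is None else r.receipt_date.strftime("%Y%m%d"),
                    ]
                )
                + "\n"
            )
    with open(drug, "w", encoding="utf-8") as fh:
        fh.write("$".join(DRUG_COLUMNS) + "\n")
        for r in recs:
            for d in r.drugs:
                fh.write("$".join([pid(r), d.name, d.role.value]) + "\n")
    with open(reac, "w", encoding="utf-8") as fh:
        fh.write("$".join(REAC_COLUMNS) + "\n")
        for r in recs:
            for pt in sorted(r.reactions):
                fh.write("$".join([pid(r), pt]) + "\n")
    with open(outc, "w", encoding="utf-8") as fh:
        fh.write("$".join(OUTC_COLUMNS) + "\n")
        for r in recs:
            for code in sorted(o.value for o in r.outcomes):
                fh.write("$".join([pid(r), code]) + "\n")
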