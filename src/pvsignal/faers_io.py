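"""Reading FAERS-dialect ASCII archives and collapsing duplicate case versions.

FAERS quarters ship as six ``$``-delimited ASCII tables (DEMO, DRUG, REAC,
OUTC, THER, INDI).  Two dialects exist: the modern one keyed by PRIMARYID /
CASEID and the legacy (pre-2012Q3) one keyed by ISR / CASE.  Both are parsed
into one internal schema; legacy ISR lands in ``primaryid`` and legacy CASE
in ``caseid`` so downstream code never branches on dialect.

The format has no quoting or escaping, so lines are split on the literal
delimiter; a data line whose field count differs from the header is recorded
in a rejects log and skipped, never silently dropped.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

DELIMITER = "$"

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")
DIALECTS = ("modern", "legacy")

#: report-key column per dialect
KEY_COLUMN = {"modern": "PRIMARYID", "legacy": "ISR"}
#: case-key column per dialect
CASE_COLUMN = {"modern": "CASEID", "legacy": "CASE"}

ROLE_CODES = ("PS", "SS", "C", "I")

#: AGE × factor → years; week and hour divisors follow the 365.25-day year.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

OCCUPATION_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other_health_professional",
    "LW": "lawyer",
    "CN": "consumer",
}

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

HEALTH_PROFESSIONAL = ("physician", "pharmacist", "other_health_professional")


# ---------------------------------------------------------------------------
# partial dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=False)
class PartialDate:
    """A FAERS date token: possibly only a year, or a year-month.

    FAERS dates are YYYYMMDD, YYYYMM, YYYY or blank.  ``precision`` records
    how much of the triple is meaningful; impossible calendar content
    degrades to ``precision='none'`` rather than raising.
    """

    year: int | None = None
    month: int | None = None
    day: int | None = None
    precision: str = "none"  # none | year | month | day

    def to_date(self) -> _dt.date | None:
        """The exact calendar date, or None unless precision is 'day'."""
        if self.precision != "day":
            return None
        return _dt.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        """Total order used for latest-version selection; unknown parts
        sort before any known value."""
        return (self.year or 0, self.month or 0, self.day or 0)

    def format(self) -> str:
        """Inverse of :func:`parse_partial_date` for non-``none`` precisions."""
        if self.precision == "day":
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.precision == "month":
            return f"{self.year:04d}{self.month:02d}"
        if self.precision == "year":
            return f"{self.year:04d}"
        return ""

    @property
    def is_dated(self) -> bool:
        return self.precision != "none"


def parse_partial_date(token: str) -> PartialDate:
    """Parse a FAERS date token into a :class:`PartialDate`.

    Total function: blanks, non-digit strings, odd lengths and impossible
    calendar dates all map to precision ``'none'``.
    """
    token = (token or "").strip()
    if not token.isdigit():
        return PartialDate()
    if len(token) == 8:
        y, m, d = int(token[:4]), int(token[4:6]), int(token[6:8])
        if y >= 1 and 1 <= m <= 12 and 1 <= d <= calendar.monthrange(y, m)[1]:
            return PartialDate(y, m, d, "day")
        return PartialDate()
    if len(token) == 6:
        y, m = int(token[:4]), int(token[4:6])
        if 1 <= m <= 12 and y >= 1:
            return PartialDate(y, m, None, "month")
        return PartialDate()
    if len(token) == 4:
        y = int(token)
        if y >= 1:
            return PartialDate(y, None, None, "year")
        return PartialDate()
    return PartialDate()


# ---------------------------------------------------------------------------
# raw tables
# ---------------------------------------------------------------------------

@dataclass
class Reject:
    """One skipped or orphaned input row, kept for the audit trail."""

    table: str
    line_number: int | None
    reason: str
    content: str


@dataclass
class RawRecordSet:
    table_name: str
    rows: list[dict[str, str]]
    quarter_label: str
    dialect: str
    rejects: list[Reject] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table_name not in TABLE_NAMES:
            raise ValueError(f"unknown table name {self.table_name!r}")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")


def parse_ascii_table(
    stream: str | io.TextIOBase,
    table_name: str,
    dialect: str = "modern",
    quarter_label: str = "",
) -> RawRecordSet:
    """Parse one ``$``-delimited FAERS table.

    The first line is the header.  Column names are upper-cased and values
    whitespace-trimmed; empty values are preserved as empty strings.  Lines
    whose field count differs from the header go to the rejects log.

    Raises ``ValueError`` if the header lacks the dialect's report-key
    column (PRIMARYID or ISR).
    """
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{table_name}: empty stream, no header line")
    header = [h.strip().upper() for h in lines[0].split(DELIMITER)]
    key_col = KEY_COLUMN[dialect]
    if key_col not in header:
        raise ValueError(
            f"{table_name}: header is missing required key column {key_col!r}"
        )
    n_fields = len(header)
    rows: list[dict[str, str]] = []
    rejects: list[Reject] = []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(DELIMITER)
        if len(parts) != n_fields:
            rejects.append(
                Reject(table_name, i, f"expected {n_fields} fields, got {len(parts)}", line)
            )
            continue
        row = {col: val.strip() for col, val in zip(header, parts)}
        if not row.get(key_col):
            rejects.append(Reject(table_name, i, f"empty {key_col}", line))
            continue
        rows.append(row)
    return RawRecordSet(table_name, rows, quarter_label, dialect, rejects)


# ---------------------------------------------------------------------------
# assembled reports
# ---------------------------------------------------------------------------

@dataclass
class DrugEntry:
    """One DRUG row: the reported product with its role and route."""

    drug_seq: str
    verbatim_name: str
    normalized_ingredient: str
    role_code: str  # PS | SS | C | I
    route: str
    route_class: str  # intravenous | intraocular | other | unspecified

    @property
    def is_primary_suspect(self) -> bool:
        return self.role_code == "PS"


def classify_route(route: str) -> str:
    """Map a verbatim FAERS route string to a coarse route class.

    Anything starting with INTRAVENOUS (covers "INTRAVENOUS DRIP",
    "INTRAVENOUS (NOT OTHERWISE SPECIFIED)") is intravenous; intravitreal
    and ophthalmic administration are intraocular; a blank route is
    unspecified.
    """
    norm = (route or "").strip().upper()
    if not norm:
        return "unspecified"
    if norm.startswith("INTRAVENOUS"):
        return "intravenous"
    if norm.startswith("INTRAVITREAL") or norm.startswith("OPHTHALMIC") or norm.startswith("INTRAOCULAR"):
        return "intraocular"
    return "other"


@dataclass
class SafetyReport:
    """One (possibly still duplicated) safety report joined across tables."""

    primaryid: str
    caseid: str
    fda_date: PartialDate = field(default_factory=PartialDate)
    event_date: PartialDate = field(default_factory=PartialDate)
    sex: str = "unknown"  # F | M | unknown
    age_years: float | None = None
    reporter_qualification: str = "unknown"
    country: str = ""
    outcome_codes: frozenset[str] = frozenset()
    drugs: list[DrugEntry] = field(default_factory=list)
    reaction_pts: frozenset[str] = frozenset()
    indications: list[tuple[str, str]] = field(default_factory=list)
    therapy_start: PartialDate = field(default_factory=PartialDate)

    @property
    def fatal(self) -> bool:
        return "DE" in self.outcome_codes

    def primary_suspect_entries(self) -> list[DrugEntry]:
        return [d for d in self.drugs if d.is_primary_suspect]


def _convert_age(age: str, age_cod: str) -> float | None:
    age = (age or "").strip()
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    code = (age_cod or "").strip().upper() or "YR"  # blank unit: assume years
    factor = AGE_UNIT_TO_YEARS.get(code)
    if factor is None:
        return None
    years = value * factor
    if not (0 <= years < 150):
        return None
    return years


def _first(row: Mapping[str, str], *names: str) -> str:
    for n in names:
        if n in row:
            return row[n]
    return ""


def assemble_reports(
    record_sets: Iterable[RawRecordSet],
) -> tuple[list[SafetyReport], list[Reject]]:
    """Join the six FAERS tables on the report key into SafetyReport records.

    One report per DEMO row.  DRUG/REAC/OUTC/THER/INDI rows whose key matches
    no DEMO row are returned in the rejects list.  Ages are converted to
    years from AGE + AGE_COD; reporter qualification is mapped from
    OCC_COD / OCCP_COD; the therapy start attached to a report is the
    earliest dated START_DT among THER rows of its primary-suspect drug(s).
    """
    by_table: dict[str, list[RawRecordSet]] = {t: [] for t in TABLE_NAMES}
    for rs in record_sets:
        by_table[rs.table_name].append(rs)
    if not by_table["DEMO"]:
        raise ValueError("assemble_reports requires at least one DEMO record set")

    def key_of(rs: RawRecordSet, row: Mapping[str, str]) -> str:
        return row.get(KEY_COLUMN[rs.dialect], "")

    reports: dict[str, SafetyReport] = {}
    rejects: list[Reject] = []

    for rs in by_table["DEMO"]:
        for row in rs.rows:
            pid = key_of(rs, row)
            caseid = row.get(CASE_COLUMN[rs.dialect], "")
            occ = _first(row, "OCC_COD", "OCCP_COD").strip().upper()
            reports[pid] = SafetyReport(
                primaryid=pid,
                caseid=caseid,
                fda_date=parse_partial_date(_first(row, "FDA_DT")),
                event_date=parse_partial_date(_first(row, "EVENT_DT")),
                sex={"F": "F", "M": "M"}.get(_first(row, "SEX", "GNDR_COD").strip().upper(), "unknown"),
                age_years=_convert_age(row.get("AGE", ""), row.get("AGE_COD", "")),
                reporter_qualification=OCCUPATION_CODES.get(occ, "unknown"),
                country=_first(row, "REPORTER_COUNTRY", "OCCR_COUNTRY").strip().upper(),
            )

    def attach(table: str, fn) -> None:
        for rs in by_table[table]:
            for row in rs.rows:
                pid = key_of(rs, row)
                rep = reports.get(pid)
                if rep is None:
                    rejects.append(
                        Reject(table, None, "report key matches no DEMO row", str(dict(row)))
                    )
                    continue
                fn(rep, row)

    def add_drug(rep: SafetyReport, row: Mapping[str, str]) -> None:
        route = row.get("ROUTE", "")
        role = row.get("ROLE_COD", "").strip().upper()
        if role not in ROLE_CODES:
            role = "C"
        name = row.get("DRUGNAME", "").strip().upper()
        ingredient = row.get("PROD_AI", "").strip().upper() or name
        rep.drugs.append(
            DrugEntry(
                drug_seq=row.get("DRUG_SEQ", "").strip(),
                verbatim_name=name,
                normalized_ingredient=ingredient,
                role_code=role,
                route=route.strip(),
                route_class=classify_route(route),
            )
        )

    def add_reaction(rep: SafetyReport, row: Mapping[str, str]) -> None:
        pt = row.get("PT", "").strip().upper()
        if pt:
            rep.reaction_pts = rep.reaction_pts | {pt}

    def add_outcome(rep: SafetyReport, row: Mapping[str, str]) -> None:
        code = row.get("OUTC_COD", "").strip().upper()
        if code in OUTCOME_CODES:
            rep.outcome_codes = rep.outcome_codes | {code}

    ther_rows: dict[str, list[Mapping[str, str]]] = {}

    def add_therapy(rep: SafetyReport, row: Mapping[str, str]) -> None:
        ther_rows.setdefault(rep.primaryid, []).append(row)

    def add_indication(rep: SafetyReport, row: Mapping[str, str]) -> None:
        pt = row.get("INDI_PT", "").strip().upper()
        if pt:
            rep.indications.append((row.get("INDI_DRUG_SEQ", "").strip(), pt))

    attach("DRUG", add_drug)
    attach("REAC", add_reaction)
    attach("OUTC", add_outcome)
    attach("THER", add_therapy)
    attach("INDI", add_indication)

    # therapy start: earliest dated START_DT among rows for the PS drug(s);
    # multiple therapy episodes therefore resolve to the first one.
    for pid, rows in ther_rows.items():
        rep = reports[pid]
        ps_seqs = {d.drug_seq for d in rep.primary_suspect_entries()}
        starts = [
            parse_partial_date(row.get("START_DT", ""))
            for row in rows
            if row.get("DSG_DRUG_SEQ", "").strip() in ps_seqs
        ]
        dated = [s for s in starts if s.is_dated]
        if dated:
            rep.therapy_start = min(dated, key=PartialDate.sort_key)

    return list(reports.values()), rejects


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def deduplicate(
    reports: Sequence[SafetyReport],
) -> tuple[list[SafetyReport], list[Reject]]:
    """Collapse case versions to one report per case.

    The survivor for each caseid is the version with the latest FDA receipt
    date, ties broken by numerically largest primaryid — the latest-version
    rule recommended by the FDA for its quarterly extracts.  Reports with an
    empty caseid cannot be grouped and are kept as flagged singletons.
    Output is sorted by caseid; the input is not modified.  Idempotent.
    """

    def version_key(r: SafetyReport) -> tuple[tuple[int, int, int], int]:
        try:
            pid_num = int(re.sub(r"\D", "", r.primaryid) or 0)
        except ValueError:  # pragma: no cover - regex guarantees digits
            pid_num = 0
        return (r.fda_date.sort_key(), pid_num)

    groups: dict[str, list[SafetyReport]] = {}
    flagged: list[Reject] = []
    singletons: list[SafetyReport] = []
    for r in reports:
        if not r.caseid:
            singletons.append(r)
            flagged.append(
                Reject("DEMO", None, "empty caseid; kept as singleton", r.primaryid)
            )
            continue
        groups.setdefault(r.caseid, []).append(r)

    survivors = [max(vs, key=version_key) for vs in groups.values()]
    survivors.sort(key=lambda r: r.caseid)
    singletons.sort(key=lambda r: r.primaryid)
    return survivors + singletons, flagged


# ---------------------------------------------------------------------------
# archive discovery and interchange output
# ---------------------------------------------------------------------------

_FILE_RE = re.compile(r"^(DEMO|DRUG|REAC|OUTC|THER|INDI).*\.(txt|TXT)$")


def read_archive(
    directory: str | Path, dialect: str = "modern"
) -> tuple[list[RawRecordSet], list[Reject]]:
    """Read every FAERS table file under ``directory`` (recursively).

    Files are recognised by name prefix (e.g. DEMO23Q1.txt); the parent
    directory name is used as the quarter label when it looks like one.
    """
    directory = Path(directory)
    sets: list[RawRecordSet] = []
    rejects: list[Reject] = []
    for path in sorted(directory.rglob("*")):
        if not path.is_file():
            continue
        m = _FILE_RE.match(path.name)
        if not m:
            continue
        quarter = path.parent.name if re.match(r"^\d{4}Q[1-4]$", path.parent.name) else ""
        rs = parse_ascii_table(path.read_text(), m.group(1), dialect, quarter)
        rejects.extend(rs.rejects)
        sets.append(rs)
    if not sets:
        raise FileNotFoundError(f"no FAERS table files found under {directory}")
    return sets, rejects


def reports_to_frames(reports: Sequence[SafetyReport]) -> dict[str, pd.DataFrame]:
    """Columnar interchange form: one parent table plus drug/reaction children."""
    parent = pd.DataFrame(
        {
            "primaryid": [r.primaryid for r in reports],
            "caseid": [r.caseid for r in reports],
            "fda_date": [r.fda_date.format() for r in reports],
            "event_date": [r.event_date.format() for r in reports],
            "sex": [r.sex for r in reports],
            "age_years": [r.age_years for r in reports],
            "reporter_qualification": [r.reporter_qualification for r in reports],
            "country": [r.country for r in reports],
            "outcome_codes": [",".join(sorted(r.outcome_codes)) for r in reports],
            "therapy_start": [r.therapy_start.format() for r in reports],
        }
    )
    drugs = pd.DataFrame(
        [
            {
                "primaryid": r.primaryid,
                "drug_seq": d.drug_seq,
                "verbatim_name": d.verbatim_name,
                "normalized_ingredient": d.normalized_ingredient,
                "role_code": d.role_code,
                "route": d.route,
                "route_class": d.route_class,
            }
            for r in reports
            for d in r.drugs
        ],
        columns=[
            "primaryid", "drug_seq", "verbatim_name", "normalized_ingredient",
            "role_code", "route", "route_class",
        ],
    )
    reactions = pd.DataFrame(
        [
            {"primaryid": r.primaryid, "pt": pt}
            for r in reports
            for pt in sorted(r.reaction_pts)
        ],
        columns=["primaryid", "pt"],
    )
    return {"reports": parent, "drugs": drugs, "reactions": reactions}


def write_reports_tsv(reports: Sequence[SafetyReport], out_dir: str | Path) -> list[Path]:
    """Serialize deduplicated reports as TSV with a stable column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in reports_to_frames(reports).items():
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def write_rejects_log(rejects: Sequence[Reject], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("table\tline_number\treason\tcontent\n")
        for rej in rejects:
            line = "" if rej.line_number is None else str(rej.line_number)
            fh.write(f"{rej.table}\t{line}\t{rej.reason}\t{rej.content}\n")
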