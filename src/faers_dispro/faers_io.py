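"""Reading and writing FAERS-style quarterly ASCII tables.

The FAERS quarterly extract ships seven dollar-delimited text tables:
demographics (DEMO), drugs (DRUG), reactions (REAC), outcomes (OUTC),
indications (INDI), therapy dates (THER) and report sources (RPSR).  The
dialect has a single header line, one record per line, fields separated by
``$`` and no quoting mechanism; legacy quarters are not UTF-8 clean, so input
is decoded as Latin-1.

Parsing is schema-driven and column-order independent: the header is matched
case-insensitively against the required columns of each table kind, extra
columns are ignored (file layouts changed across quarterly revisions), and
per-record problems (wrong field count, malformed dates or numbers, unknown
role/outcome codes) are collected into a parse report with line numbers
rather than aborting the run.

Units are normalised at parse time: ages to years (MON/12, DY/365.25) and
weights to kilograms (LBS x 0.453592); values in other unit codes become
missing.  Empty fields, whitespace-only fields and the literal ``NULL`` are
all treated as missing.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

DELIMITER = "$"
ENCODING = "latin-1"

LBS_TO_KG = 0.453592

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
OCCUPATION_CODES = frozenset({"MD", "PH", "HP", "CN", "OT", "LW"})


class TableKind(str, Enum):
    """The seven FAERS quarterly ASCII tables."""

    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    OUTC = "OUTC"
    INDI = "INDI"
    THER = "THER"
    RPSR = "RPSR"


class SchemaError(ValueError):
    """A required column is absent from a table header."""


@dataclass(frozen=True, slots=True)
class DemoRecord:
    """One report version from the DEMO table, units normalised."""

    primary_id: str
    case_id: str
    fda_dt: int
    sex: Optional[str] = None
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    reporter_occupation: Optional[str] = None
    reporter_country: Optional[str] = None

    @property
    def event_year(self) -> int:
        return self.fda_dt // 10000


@dataclass(frozen=True, slots=True)
class DrugRecord:
    """One drug mention linked to a report version by ``primary_id``."""

    primary_id: str
    drug_seq: int
    role_code: str
    drug_name: Optional[str] = None
    active_ingredient: Optional[str] = None


@dataclass(frozen=True, slots=True)
class ReactionRecord:
    """One (report version, MedDRA Preferred Term) pair."""

    primary_id: str
    pt: str


@dataclass(frozen=True, slots=True)
class OutcomeRecord:
    """One (report version, outcome code) pair."""

    primary_id: str
    outcome_code: str


@dataclass(frozen=True, slots=True)
class IndiRecord:
    primary_id: str
    drug_seq: int
    indication_pt: Optional[str] = None


@dataclass(frozen=True, slots=True)
class TherRecord:
    primary_id: str
    drug_seq: int
    start_dt: Optional[int] = None


@dataclass(frozen=True, slots=True)
class RpsrRecord:
    primary_id: str
    source_code: Optional[str] = None


AnyRecord = Union[
    DemoRecord, DrugRecord, ReactionRecord, OutcomeRecord, IndiRecord, TherRecord, RpsrRecord
]

RECORD_TYPES = {
    TableKind.DEMO: DemoRecord,
    TableKind.DRUG: DrugRecord,
    TableKind.REAC: ReactionRecord,
    TableKind.OUTC: OutcomeRecord,
    TableKind.INDI: IndiRecord,
    TableKind.THER: TherRecord,
    TableKind.RPSR: RpsrRecord,
}

# Canonical FAERS header names required per table kind (matched case-insensitively;
# extra columns in the file are accepted and ignored).
REQUIRED_COLUMNS = {
    TableKind.DEMO: (
        "primaryid",
        "caseid",
        "fda_dt",
        "sex",
        "age",
        "age_cod",
        "wt",
        "wt_cod",
        "occp_cod",
        "reporter_country",
    ),
    TableKind.DRUG: ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    TableKind.REAC: ("primaryid", "pt"),
    TableKind.OUTC: ("primaryid", "outc_cod"),
    TableKind.INDI: ("primaryid", "indi_drug_seq", "indi_pt"),
    TableKind.THER: ("primaryid", "dsg_drug_seq", "start_dt"),
    TableKind.RPSR: ("primaryid", "rpsr_cod"),
}


@dataclass(frozen=True, slots=True)
class ParseIssue:
    """One skipped input line: its number, table and the reason."""

    line_no: int
    table: str
    reason: str


@dataclass(slots=True)
class ParseResult:
    """Typed records plus the report of lines that could not be parsed.

    ``len(records) + len(issues)`` equals the number of data lines read.
    """

    records: list
    issues: list

    def write_issue_report(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("line\ttable\treason\n")
            for issue in self.issues:
                fh.write(f"{issue.line_no}\t{issue.table}\t{issue.reason}\n")


class _FieldError(ValueError):
    """Internal: a malformed field value within one record."""


def _missing(raw: str) -> bool:
    stripped = raw.strip()
    return stripped == "" or stripped.upper() == "NULL"


def _clean(raw: str) -> Optional[str]:
    return None if _missing(raw) else raw.strip()


def _parse_number(raw: str, name: str) -> float:
    try:
        value = float(raw.strip())
    except ValueError:
        raise _FieldError(f"malformed number in {name}: {raw.strip()!r}") from None
    if value < 0:
        raise _FieldError(f"negative value in {name}: {raw.strip()!r}")
    return value


def _parse_date(raw: str, name: str) -> int:
    text = raw.strip()
    if len(text) != 8 or not text.isdigit():
        raise _FieldError(f"malformed date in {name}: {text!r}")
    year, month, day = int(text[:4]), int(text[4:6]), int(text[6:8])
    try:
        datetime.date(year, month, day)
    except ValueError:
        raise _FieldError(f"invalid calendar date in {name}: {text!r}") from None
    return int(text)


def _parse_int(raw: str, name: str) -> int:
    text = raw.strip()
    if not text.lstrip("-").isdigit():
        raise _FieldError(f"malformed integer in {name}: {text!r}")
    return int(text)


def _age_to_years(value_raw: str, unit_raw: str) -> Optional[float]:
    if _missing(value_raw):
        return None
    value = _parse_number(value_raw, "age")
    unit = (_clean(unit_raw) or "").upper()
    if unit in ("YR", "YEAR", ""):
        # FAERS leaves the unit blank on many year-valued ages
        return value
    if unit == "MON":
        return value / 12.0
    if unit == "DY":
        return value / 365.25
    return None  # unsupported unit (DEC, WK, HR): not comparable to year bands


def _weight_to_kg(value_raw: str, unit_raw: str) -> Optional[float]:
    if _missing(value_raw):
        return None
    value = _parse_number(value_raw, "weight")
    unit = (_clean(unit_raw) or "").upper()
    if unit in ("KG", "KGS"):
        return value
    if unit == "LBS":
        return value * LBS_TO_KG
    return None  # unknown or absent unit code: weight unusable for kg bands


def _build_demo(get, seen_primary_ids: set) -> DemoRecord:
    primary_id = _clean(get("primaryid"))
    case_id = _clean(get("caseid"))
    if primary_id is None:
        raise _FieldError("empty primaryid")
    if primary_id in seen_primary_ids:
        raise _FieldError(f"duplicate primaryid {primary_id!r}")
    if case_id is None:
        raise _FieldError("empty caseid")
    fda_dt = _parse_date(get("fda_dt"), "fda_dt")
    sex = _clean(get("sex"))
    if sex is not None:
        sex = sex.upper()
        if sex not in ("M", "F"):
            sex = None
    occp = _clean(get("occp_cod"))
    if occp is not None:
        occp = occp.upper()
        if occp not in OCCUPATION_CODES:
            occp = None
    record = DemoRecord(
        primary_id=primary_id,
        case_id=case_id,
        fda_dt=fda_dt,
        sex=sex,
        age_years=_age_to_years(get("age"), get("age_cod")),
        weight_kg=_weight_to_kg(get("wt"), get("wt_cod")),
        reporter_occupation=occp,
        reporter_country=_clean(get("reporter_country")),
    )
    seen_primary_ids.add(primary_id)
    return record


def _build_drug(get) -> DrugRecord:
    primary_id = _clean(get("primaryid"))
    if primary_id is None:
        raise _FieldError("empty primaryid")
    role = (_clean(get("role_cod")) or "").upper()
    if role not in ROLE_CODES:
        raise _FieldError(f"unknown role code {role!r}")
    return DrugRecord(
        primary_id=primary_id,
        drug_seq=_parse_int(get("drug_seq"), "drug_seq"),
        role_code=role,
        drug_name=_clean(get("drugname")),
        active_ingredient=_clean(get("prod_ai")),
    )


def _build_reac(get) -> ReactionRecord:
    primary_id = _clean(get("primaryid"))
    pt = _clean(get("pt"))
    if primary_id is None:
        raise _FieldError("empty primaryid")
    if pt is None:
        raise _FieldError("empty pt")
    return ReactionRecord(primary_id=primary_id, pt=pt)


def _build_outc(get) -> OutcomeRecord:
    primary_id = _clean(get("primaryid"))
    if primary_id is None:
        raise _FieldError("empty primaryid")
    code = (_clean(get("outc_cod")) or "").upper()
    if code not in OUTCOME_CODES:
        raise _FieldError(f"unknown outcome code {code!r}")
    return OutcomeRecord(primary_id=primary_id, outcome_code=code)


def _build_indi(get) -> IndiRecord:
    primary_id = _clean(get("primaryid"))
    if primary_id is None:
        raise _FieldError("empty primaryid")
    return IndiRecord(
        primary_id=primary_id,
        drug_seq=_parse_int(get("indi_drug_seq"), "indi_drug_seq"),
        indication_pt=_clean(get("indi_pt")),
    )


def _build_ther(get) -> TherRecord:
    primary_id = _clean(get("primaryid"))
    if primary_id is None:
        raise _FieldError("empty primaryid")
    start_raw = get("start_dt")
    return TherRecord(
        primary_id=primary_id,
        drug_seq=_parse_int(get("dsg_drug_seq"), "dsg_drug_seq"),
        start_dt=None if _missing(start_raw) else _parse_date(start_raw, "start_dt"),
    )


def _build_rpsr(get) -> RpsrRecord:
    primary_id = _clean(get("primaryid"))
    if primary_id is None:
        raise _FieldError("empty primaryid")
    code = _clean(get("rpsr_cod"))
    return RpsrRecord(primary_id=primary_id, source_code=None if code is None else code.upper())


_BUILDERS = {
    TableKind.DRUG: _build_drug,
    TableKind.REAC: _build_reac,
    TableKind.OUTC: _build_outc,
    TableKind.INDI: _build_indi,
    TableKind.THER: _build_ther,
    TableKind.RPSR: _build_rpsr,
}


def parse_table(path, table_kind: Union[TableKind, str]) -> ParseResult:
    """Parse one FAERS ASCII table into typed records.

    Parameters
    ----------
    path : path-like
        Dollar-delimited text file with a header line.
    table_kind : TableKind or str
        Which of the seven tables the file contains.

    Returns
    -------
    ParseResult
        ``records`` in file order; ``issues`` lists every skipped line with
        its 1-based line number and reason.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SchemaError
        If the header lacks a column the schema requires.
    """
    table_kind = TableKind(table_kind)
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"{table_kind.value} table not found: {path}")

    with open(path, "r", encoding=ENCODING, errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file, no header line")

    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    required = REQUIRED_COLUMNS[table_kind]
    positions = {}
    for col in required:
        try:
            positions[col] = header.index(col)
        except ValueError:
            raise SchemaError(
                f"{path}: {table_kind.value} header is missing required column {col!r}"
            ) from None
    n_fields = len(header)

    records: list = []
    issues: list = []
    seen_demo_ids: set = set()
    for line_no, line in enumerate(lines[1:], start=2):
        if line.strip() == "":
            continue
        parts = line.split(DELIMITER)
        if len(parts) != n_fields:
            issues.append(
                ParseIssue(
                    line_no,
                    table_kind.value,
                    f"expected {n_fields} fields, found {len(parts)}",
                )
            )
            continue

        def get(col: str, _parts=parts) -> str:
            return _parts[positions[col]]

        try:
            if table_kind is TableKind.DEMO:
                records.append(_build_demo(get, seen_demo_ids))
            else:
                records.append(_BUILDERS[table_kind](get))
        except _FieldError as err:
            issues.append(ParseIssue(line_no, table_kind.value, str(err)))
    return ParseResult(records=records, issues=issues)


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):  # bool is an int subclass; be explicit
        return str(int(value))
    if isinstance(value, float):
        return repr(value)  # shortest representation that round-trips exactly
    return str(value)


def _demo_row(rec: DemoRecord) -> list:
    return [
        rec.primary_id,
        rec.case_id,
        rec.fda_dt,
        rec.sex,
        rec.age_years,
        None if rec.age_years is None else "YR",
        rec.weight_kg,
        None if rec.weight_kg is None else "KG",
        rec.reporter_occupation,
        rec.reporter_country,
    ]


_ROW_BUILDERS = {
    TableKind.DEMO: _demo_row,
    TableKind.DRUG: lambda r: [r.primary_id, r.drug_seq, r.role_code, r.drug_name, r.active_ingredient],
    TableKind.REAC: lambda r: [r.primary_id, r.pt],
    TableKind.OUTC: lambda r: [r.primary_id, r.outcome_code],
    TableKind.INDI: lambda r: [r.primary_id, r.drug_seq, r.indication_pt],
    TableKind.THER: lambda r: [r.primary_id, r.drug_seq, r.start_dt],
    TableKind.RPSR: lambda r: [r.primary_id, r.source_code],
}


def write_table(records: Sequence[AnyRecord], path, table_kind: Union[TableKind, str]) -> None:
    """Write typed records in the same dollar-delimited dialect parse_table reads.

    The dialect has no quoting, so a field value containing ``$`` is rejected
    with ``ValueError``.  ``parse_table(write_table(records))`` reproduces the
    records field for field (ages re-emitted in years, weights in kilograms).
    """
    table_kind = TableKind(table_kind)
    expected_type = RECORD_TYPES[table_kind]
    rows = []
    for rec in records:
        if not isinstance(rec, expected_type):
            raise TypeError(
                f"expected {expected_type.__name__} for {table_kind.value}, got {type(rec).__name__}"
            )
        row = [_format_value(v) for v in _ROW_BUILDERS[table_kind](rec)]
        for cell in row:
            if DELIMITER in cell:
                raise ValueError(
                    f"field value contains the {DELIMITER!r} delimiter and cannot be "
                    f"written in the unquoted FAERS dialect: {cell!r}"
                )
        rows.append(row)
    with open(path, "w", encoding=ENCODING, errors="replace", newline="\n") as fh:
        fh.write(DELIMITER.join(REQUIRED_COLUMNS[table_kind]) + "\n")
        for row in rows:
            fh.write(DELIMITER.join(row) + "\n")


class PtSocMap:
    """Mapping from normalised Preferred Term to its primary System Organ Class.

    MedDRA itself is licensed, so the mapping is user-supplied as a two-column
    file.  Keys are trimmed and case-folded; each PT maps to exactly one SOC.
    """

    def __init__(self, entries: dict):
        self.entries = dict(entries)

    @staticmethod
    def normalize(pt: str) -> str:
        return " ".join(pt.split()).casefold()

    def lookup(self, pt: str) -> Optional[str]:
        return self.entries.get(self.normalize(pt))

    def __contains__(self, pt: str) -> bool:
        return self.normalize(pt) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_pt_soc_map(path, delimiter: str = "\t") -> PtSocMap:
    """Load a two-column (PT, SOC) delimited file into a :class:`PtSocMap`.

    A header line is optional (detected by the literal first column ``pt``).
    Duplicate PT keys are allowed only when they agree on the SOC; a
    conflicting duplicate raises ``ValueError`` naming the PT.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"PT->SOC map not found: {path}")
    entries: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            parts = line.rstrip("\n").split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns (PT, SOC)")
            pt_raw, soc = parts[0].strip(), parts[1].strip()
            if line_no == 1 and pt_raw.lower() in ("pt", "preferred_term"):
                continue
            if pt_raw == "" or soc == "":
                raise ValueError(f"{path}:{line_no}: empty PT or SOC")
            key = PtSocMap.normalize(pt_raw)
            if key in entries and entries[key] != soc:
                raise ValueError(
                    f"PT {pt_raw!r} maps to conflicting SOCs: {entries[key]!r} and {soc!r}"
                )
            entries[key] = soc
    return PtSocMap(entries)
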