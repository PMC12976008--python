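"""Reader/writer for FAERS-style quarterly ASCII tables.

The FDA Adverse Event Reporting System (FAERS) publishes quarterly extracts
as ``$``-delimited text files, one table per record type: DEMO (report-level
demographics), DRUG (one row per drug per report, with a role code), REAC
(one row per reported MedDRA preferred term), THER (therapy episodes with
start/end dates), INDI (indications per drug) and OUTC (seriousness
outcomes).  This module models only the columns the analysis pipeline uses.

Dates in spontaneous reports are frequently partial (year only, or year and
month); they are kept as :class:`PartialDate` values carrying both the raw
string and the resolved precision, so downstream code can state which
precisions it accepts instead of silently imputing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

log = logging.getLogger(__name__)

DELIMITER = "$"

#: date precision levels
DAY, MONTH, YEAR, INVALID = "day", "month", "year", "invalid"

SEX_CODES = frozenset({"M", "F", "UNK"})
AGE_UNITS = frozenset({"YR", "MON", "WK", "DY", "HR", "DEC", "UNK"})
REPORTER_CODES = frozenset({"CN", "MD", "HP", "PH", "OT", "UNK"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: age-unit → years conversion factors (ages are analysed in years)
AGE_FACTORS = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
    "DEC": 10.0,
}


@dataclass(frozen=True)
class PartialDate:
    """A calendar date of possibly partial precision.

    ``raw`` is the original digit string (``YYYYMMDD``, ``YYYYMM``, ``YYYY``
    or anything else, in which case precision is ``invalid``).
    """

    raw: str
    precision: str
    year: int | None = None
    month: int | None = None
    day: int | None = None

    @property
    def is_valid(self) -> bool:
        return self.precision != INVALID

    @property
    def is_day(self) -> bool:
        return self.precision == DAY

    def to_date(self) -> date:
        if self.precision != DAY:
            raise ValueError(f"date {self.raw!r} has precision {self.precision}, not day")
        return date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        """Chronological key; invalid dates sort before everything."""
        if not self.is_valid:
            return (-1, 0, 0)
        return (self.year, self.month or 0, self.day or 0)

    @classmethod
    def from_date(cls, d: date) -> "PartialDate":
        return cls(f"{d.year:04d}{d.month:02d}{d.day:02d}", DAY, d.year, d.month, d.day)

    @classmethod
    def missing(cls) -> "PartialDate":
        return cls("", INVALID)


def parse_partial_date(raw: str) -> PartialDate:
    """Parse a FAERS date string into a :class:`PartialDate`.

    8 digits → day precision, 6 → month, 4 → year; anything else (including
    impossible calendar dates) → invalid, with the raw string retained.
    """
    s = (raw or "").strip()
    if s.isdigit():
        if len(s) == 8:
            y, m, d = int(s[:4]), int(s[4:6]), int(s[6:])
            try:
                date(y, m, d)
            except ValueError:
                return PartialDate(s, INVALID)
            return PartialDate(s, DAY, y, m, d)
        if len(s) == 6:
            y, m = int(s[:4]), int(s[4:])
            if 1 <= m <= 12:
                return PartialDate(s, MONTH, y, m)
            return PartialDate(s, INVALID)
        if len(s) == 4:
            return PartialDate(s, YEAR, int(s))
    return PartialDate(s, INVALID)


def age_to_years(value: float | None, unit: str) -> float | None:
    """Normalize an age to years; unknown unit or missing value → None."""
    if value is None:
        return None
    factor = AGE_FACTORS.get(unit)
    if factor is None:
        return None
    return value * factor


def normalize_term(pt: str) -> str:
    """Case/whitespace normalization for event terms (lower-cased)."""
    return " ".join(pt.split()).lower()


# ---------------------------------------------------------------------------
# record types


@dataclass
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: PartialDate
    event_dt: PartialDate = field(default_factory=PartialDate.missing)
    sex: str = "UNK"
    age_value: float | None = None
    age_unit: str = "UNK"
    reporter: str = "UNK"
    country: str = ""

    @property
    def event_year(self) -> int | None:
        return self.fda_dt.year if self.fda_dt.is_valid else None

    @property
    def age_years(self) -> float | None:
        return age_to_years(self.age_value, self.age_unit)


@dataclass
class DrugRecord:
    primaryid: str
    drug_seq: int
    role: str
    drugname: str
    #: populated by the THER-table join during case assembly, never serialized
    start_dt: PartialDate | None = None


@dataclass
class ReactionRecord:
    primaryid: str
    pt: str

    def __post_init__(self) -> None:
        self.pt = normalize_term(self.pt)


@dataclass
class OutcomeRecord:
    primaryid: str
    outcome_code: str


@dataclass
class IndicationRecord:
    primaryid: str
    drug_seq: int
    indication_pt: str


@dataclass
class TherapyRecord:
    primaryid: str
    drug_seq: int
    start_dt: PartialDate = field(default_factory=PartialDate.missing)
    end_dt: PartialDate = field(default_factory=PartialDate.missing)


# ---------------------------------------------------------------------------
# table schemas: column name ↔ record field, with converters

def _fmt_num(v: float | int | None) -> str:
    if v is None:
        return ""
    return format(v, "g")


def _parse_float(s: str) -> float | None:
    s = s.strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _parse_enum(s: str, allowed: frozenset, default: str = "UNK") -> str:
    s = s.strip().upper()
    return s if s in allowed else default


class _Col:
    def __init__(self, name, getter, setter):
        self.name, self.get, self.set = name, getter, setter


def _date_col(name, attr):
    return _Col(name, lambda r: getattr(r, attr).raw, lambda s: parse_partial_date(s))


_SCHEMAS: dict[str, tuple[type, list[_Col]]] = {
    "DEMO": (DemoRecord, [
        _Col("primaryid", lambda r: r.primaryid, str.strip),
        _Col("caseid", lambda r: r.caseid, str.strip),
        _date_col("fda_dt", "fda_dt"),
        _date_col("event_dt", "event_dt"),
        _Col("sex", lambda r: r.sex, lambda s: _parse_enum(s, SEX_CODES)),
        _Col("age", lambda r: _fmt_num(r.age_value), _parse_float),
        _Col("age_cod", lambda r: r.age_unit, lambda s: _parse_enum(s, AGE_UNITS)),
        _Col("occp_cod", lambda r: r.reporter, lambda s: _parse_enum(s, REPORTER_CODES)),
        _Col("reporter_country", lambda r: r.country, str.strip),
    ]),
    "DRUG": (DrugRecord, [
        _Col("primaryid", lambda r: r.primaryid, str.strip),
        _Col("drug_seq", lambda r: str(r.drug_seq), lambda s: int(s)),
        _Col("role_cod", lambda r: r.role, lambda s: _parse_enum(s, ROLE_CODES, "C")),
        _Col("drugname", lambda r: r.drugname, str.strip),
    ]),
    "REAC": (ReactionRecord, [
        _Col("primaryid", lambda r: r.primaryid, str.strip),
        _Col("pt", lambda r: r.pt, str.strip),
    ]),
    "OUTC": (OutcomeRecord, [
        _Col("primaryid", lambda r: r.primaryid, str.strip),
        _Col("outc_cod", lambda r: r.outcome_code, lambda s: _parse_enum(s, OUTCOME_CODES, "OT")),
    ]),
    "INDI": (IndicationRecord, [
        _Col("primaryid", lambda r: r.primaryid, str.strip),
        _Col("indi_drug_seq", lambda r: str(r.drug_seq), lambda s: int(s)),
        _Col("indi_pt", lambda r: r.indication_pt, str.strip),
    ]),
    "THER": (TherapyRecord, [
        _Col("primaryid", lambda r: r.primaryid, str.strip),
        _Col("dsg_drug_seq", lambda r: str(r.drug_seq), lambda s: int(s)),
        _date_col("start_dt", "start_dt"),
        _date_col("end_dt", "end_dt"),
    ]),
}

TABLE_KINDS = tuple(_SCHEMAS)


def _read_text(path: Path) -> str:
    data = Path(path).read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        # real FAERS files mix encodings; latin-1 never fails
        return data.decode("latin-1")


def read_table(path, table_kind: str) -> list:
    """Read one ``$``-delimited FAERS table into records of the matching type.

    Unknown columns are ignored; rows yield exactly one record each (dates
    that fail to parse are retained with ``invalid`` precision rather than
    dropped).  A missing required column is a hard error naming the column.
    """
    if table_kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {table_kind!r}; expected one of {TABLE_KINDS}")
    rec_type, cols = _SCHEMAS[table_kind]
    text = _read_text(Path(path))
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file, expected a header line")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    positions = {}
    for col in cols:
        if col.name not in header:
            raise ValueError(f"{path}: required column {col.name!r} missing from header")
        positions[col.name] = header.index(col.name)
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        parts = line.split(DELIMITER)
        kwargs = {}
        for col, attr in zip(cols, _field_names(table_kind)):
            idx = positions[col.name]
            raw = parts[idx] if idx < len(parts) else ""
            kwargs[attr] = col.set(raw)
        records.append(rec_type(**kwargs))
    return records


_FIELD_NAMES = {
    "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "sex",
             "age_value", "age_unit", "reporter", "country"],
    "DRUG": ["primaryid", "drug_seq", "role", "drugname"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outcome_code"],
    "INDI": ["primaryid", "drug_seq", "indication_pt"],
    "THER": ["primaryid", "drug_seq", "start_dt", "end_dt"],
}


def _field_names(table_kind: str) -> list[str]:
    return _FIELD_NAMES[table_kind]


def write_table(records: Sequence, path, table_kind: str) -> Path:
    """Write records as a ``$``-delimited table; exact inverse of read_table.

    FAERS ASCII has no quoting convention, so a field containing the
    delimiter cannot be represented and is rejected.
    """
    if table_kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    rec_type, cols = _SCHEMAS[table_kind]
    for r in records:
        if not isinstance(r, rec_type):
            raise TypeError(f"expected {rec_type.__name__} records, got {type(r).__name__}")
    path = Path(path)
    lines = [DELIMITER.join(c.name for c in cols)]
    for r in records:
        values = []
        for c in cols:
            v = c.get(r)
            if DELIMITER in v:
                raise ValueError(
                    f"field {c.name!r} of record {r!r} contains the {DELIMITER!r} "
                    f"delimiter and cannot be written")
            values.append(v)
        lines.append(DELIMITER.join(values))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
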