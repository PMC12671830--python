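"""Readers for FAERS-style quarterly ASCII archives.

FAERS quarterly packages ship seven '$'-delimited text tables (DEMO, DRUG,
REAC, OUTC, THER, INDI, RPSR) with a single header row, plus — since 2004Q1 —
a list of deleted case identifiers.  This module parses one quarter into a
:class:`QuarterBundle` of pandas DataFrames, validating enumerated fields and
logging (not silently dropping) every malformed row with its line number.

Dates in FAERS are bare digit strings (``YYYYMMDD``, ``YYYYMM`` or ``YYYY``);
:func:`parse_date` returns a :class:`ParsedDate` that keeps the precision
explicit so downstream steps can refuse to impute missing components.
"""

from __future__ import annotations

import calendar
import csv
import datetime as _dt
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "ParsedDate",
    "parse_date",
    "QuarterBundle",
    "FaersFormatError",
    "read_quarter",
    "read_quarters",
    "quarter_index",
    "TABLE_NAMES",
    "ROLE_CODES",
    "OUTCOME_CODES",
    "AGE_CODES",
]

TABLE_NAMES = ("demo", "drug", "reac", "outc", "ther", "indi", "rpsr")
REQUIRED_TABLES = ("demo", "drug", "reac")

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "DS", "HO", "CA", "RI", "OT"})
AGE_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})
SEX_CODES = frozenset({"M", "F", "UNK"})

#: canonical column set per table (post alias-normalisation)
TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "occp_cod", "reporter_country"),
    "drug": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "reac": ("primaryid", "caseid", "pt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "ther": ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"),
    "indi": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "rpsr": ("primaryid", "caseid", "rpsr_cod"),
}

#: legacy (LAERS-era, pre-2012Q4) and variant column names mapped onto the
#: canonical schema; user-extensible via ``read_quarter(aliases=...)``.
DEFAULT_COLUMN_ALIASES: dict[str, str] = {
    "isr": "primaryid",
    "case": "caseid",
    "case_num": "caseid",
    "gndr_cod": "sex",
    "outc_code": "outc_cod",
}

_QUARTER_RE = re.compile(r"^\d{4}Q[1-4]$")


@dataclass(frozen=True)
class ParsedDate:
    """A calendar date carrying an explicit precision (day, month or year)."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def sort_key(self) -> tuple[int, int, int]:
        """Total order with missing components treated as lowest."""
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> _dt.date:
        if self.precision != "day":
            raise ValueError(f"date {self} has {self.precision} precision")
        return _dt.date(self.year, self.month, self.day)

    def quarter(self) -> Optional[str]:
        if self.month is None:
            return None
        return f"{self.year}Q{(self.month - 1) // 3 + 1}"

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"


def parse_date(raw: str | None) -> Optional[ParsedDate]:
    """Parse a FAERS digit-string date; impossible calendar values -> None.

    Accepts 8 digits (day precision), 6 (month) or 4 (year).  Empty or
    whitespace input parses to None (absent), as do non-digit strings and
    out-of-range components such as month 13 or day 32.
    """
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    if not raw.isdigit() or len(raw) not in (4, 6, 8):
        return None
    year = int(raw[:4])
    if year == 0:
        return None
    if len(raw) == 4:
        return ParsedDate(year)
    month = int(raw[4:6])
    if not 1 <= month <= 12:
        return None
    if len(raw) == 6:
        return ParsedDate(year, month)
    day = int(raw[6:8])
    if not 1 <= day <= calendar.monthrange(year, month)[1]:
        return None
    return ParsedDate(year, month, day)


def quarter_index(quarter_id: str) -> int:
    """Map 'YYYYQn' to a monotone integer (year*4 + quarter-1)."""
    if not _QUARTER_RE.match(quarter_id):
        raise ValueError(f"bad quarter label: {quarter_id!r}")
    return int(quarter_id[:4]) * 4 + int(quarter_id[5]) - 1


class FaersFormatError(RuntimeError):
    """A quarter is structurally unusable (e.g. a required table is missing)."""


@dataclass
class QuarterBundle:
    """All tables of one FAERS quarter plus the deleted-case list.

    Each table is a pandas DataFrame of strings in the canonical column
    order (extra archive columns are preserved after the canonical ones).
    Rows whose primaryid does not appear in DEMO carry ``orphan=True``; they
    are kept here and dropped at curation so attrition stays auditable.
    """

    quarter_id: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    deleted_caseids: set[str] = field(default_factory=set)
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not _QUARTER_RE.match(self.quarter_id):
            raise ValueError(f"bad quarter_id {self.quarter_id!r}")

    def __getattr__(self, name: str):
        if name in TABLE_NAMES:
            return self.tables.get(name, _empty_table(name))
        raise AttributeError(name)

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables.items()}

    def malformed(self) -> list[dict]:
        return [e for e in self.log if e.get("kind") == "malformed"]


def _empty_table(name: str) -> pd.DataFrame:
    cols = list(TABLE_COLUMNS[name])
    if name != "demo":
        cols.append("orphan")
    return pd.DataFrame(columns=cols)


def _decode(path: Path, log: list[dict]) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        log.append({"kind": "encoding_fallback", "file": path.name,
                    "encoding": "latin-1"})
        return data.decode("latin-1")


def _validate_row(table: str, row: dict) -> Optional[str]:
    """Return a reason string if the row violates its enumerated domain."""
    if not row.get("primaryid"):
        return "empty primaryid"
    if table == "reac" and not row.get("pt", "").strip():
        return "empty pt"
    if table == "drug":
        if row.get("role_cod", "") not in ROLE_CODES:
            return f"role_cod {row.get('role_cod')!r} not in {{PS,SS,C,I}}"
        seq = row.get("drug_seq", "")
        if seq and (not seq.isdigit() or int(seq) < 1):
            return f"drug_seq {seq!r} not a positive integer"
    if table == "outc" and row.get("outc_cod", "") not in OUTCOME_CODES:
        return f"outc_cod {row.get('outc_cod')!r} not a FAERS outcome code"
    if table == "demo":
        age_cod = row.get("age_cod", "")
        if row.get("age") and not age_cod:
            return "age present without age_cod"
        if age_cod and age_cod not in AGE_CODES:
            return f"age_cod {age_cod!r} unknown"
    return None


def _read_table(path: Path, table: str, aliases: Mapping[str, str],
                log: list[dict]) -> pd.DataFrame:
    text = _decode(path, log)
    reader = csv.reader(io.StringIO(text), delimiter="$",
                        quoting=csv.QUOTE_NONE)
    try:
        header_raw = next(reader)
    except StopIteration:
        raise FaersFormatError(f"{path.name}: empty file, no header row")
    header = [aliases.get(h.strip().lower(), h.strip().lower())
              for h in header_raw]
    canonical = TABLE_COLUMNS[table]
    missing = [c for c in ("primaryid",) if c not in header]
    if missing:
        raise FaersFormatError(
            f"{path.name}: header lacks required column(s) {missing}")
    rows: list[dict] = []
    for fields_ in reader:
        if not fields_ or (len(fields_) == 1 and not fields_[0].strip()):
            continue
        if len(fields_) != len(header):
            log.append({"kind": "malformed", "table": table,
                        "line": reader.line_num,
                        "reason": f"expected {len(header)} fields, "
                                  f"got {len(fields_)}"})
            continue
        row = {h: v.strip() for h, v in zip(header, fields_)}
        reason = _validate_row(table, row)
        if reason is not None:
            log.append({"kind": "malformed", "table": table,
                        "line": reader.line_num, "reason": reason})
            continue
        rows.append(row)
    extra = [c for c in header if c not in canonical]
    df = pd.DataFrame(rows, columns=list(canonical) + extra, dtype=str)
    return df.fillna("")


def _find_table_file(path: Path, table: str) -> Optional[Path]:
    hits = []
    for p in sorted(path.iterdir()):
        name = p.name.upper()
        if "DELET" in name:
            continue
        if name.startswith(table.upper()) and p.is_file():
            hits.append(p)
    return hits[0] if hits else None


def _find_deleted_file(path: Path) -> Optional[Path]:
    for p in sorted(path.iterdir()):
        if "DELET" in p.name.upper() and p.is_file():
            return p
    return None


def read_quarter(path: str | Path, quarter_id: str,
                 aliases: Mapping[str, str] | None = None) -> QuarterBundle:
    """Parse one quarterly directory of '$'-delimited tables.

    Parameters
    ----------
    path:
        Directory containing ``DEMO*.txt``, ``DRUG*.txt``, ... files and an
        optional deleted-case list (any file whose name contains "DELET",
        one caseid per line).
    quarter_id:
        Label of the quarter, e.g. ``"2012Q3"``.
    aliases:
        Extra column-name aliases merged over the built-in LAERS-era table.

    Raises
    ------
    FaersFormatError
        If DEMO, DRUG or REAC is absent — a quarter without them cannot
        contribute reports.
    """
    if not isinstance(path, _VirtualQuarter):
        path = Path(path)
    if not path.is_dir():
        raise FaersFormatError(f"quarter path {path} is not a directory")
    alias_map = dict(DEFAULT_COLUMN_ALIASES)
    if aliases:
        alias_map.update({k.lower(): v.lower() for k, v in aliases.items()})

    log: list[dict] = []
    tables: dict[str, pd.DataFrame] = {}
    for table in TABLE_NAMES:
        fp = _find_table_file(path, table)
        if fp is None:
            if table in REQUIRED_TABLES:
                raise FaersFormatError(
                    f"required table {table.upper()} missing in {path}")
            tables[table] = _empty_table(table)
            continue
        tables[table] = _read_table(fp, table, alias_map, log)

    deleted: set[str] = set()
    dfp = _find_deleted_file(path)
    if dfp is not None:
        for line in _decode(dfp, log).splitlines():
            cid = line.strip()
            if cid:
                deleted.add(cid)

    # flag orphans (rows referencing a primaryid absent from DEMO)
    demo_ids = set(tables["demo"]["primaryid"])
    for table in TABLE_NAMES:
        if table == "demo":
            continue
        df = tables[table]
        if "orphan" not in df.columns:
            df["orphan"] = (~df["primaryid"].isin(demo_ids)
                            if len(df) else pd.Series([], dtype=bool))
        n_orphan = int(df["orphan"].sum()) if len(df) else 0
        if n_orphan:
            log.append({"kind": "orphan", "table": table, "count": n_orphan})

    bundle = QuarterBundle(quarter_id=quarter_id, tables=tables,
                           deleted_caseids=deleted, log=log)
    log.append({"kind": "counts", "quarter": quarter_id,
                **{t: len(tables[t]) for t in TABLE_NAMES}})
    return bundle


_DEMO_FILE_RE = re.compile(r"^DEMO(\d{2})Q([1-4])", re.IGNORECASE)


def read_quarters(root: str | Path,
                  aliases: Mapping[str, str] | None = None) -> list[QuarterBundle]:
    """Read every quarter under ``root``.

    Two layouts are accepted: one subdirectory per quarter named ``YYYYQn``,
    or a flat directory of ``DEMOyyQq.txt``-style files split into per-quarter
    virtual bundles by filename.  Returns bundles sorted by quarter.
    """
    root = Path(root)
    subdirs = [p for p in sorted(root.iterdir()) if p.is_dir()
               and _QUARTER_RE.match(p.name)]
    if subdirs:
        return [read_quarter(p, p.name, aliases=aliases) for p in subdirs]
    # flat layout: infer quarters from DEMO file names
    quarters = []
    for p in sorted(root.iterdir()):
        m = _DEMO_FILE_RE.match(p.name)
        if m:
            yy, q = m.groups()
            year = 2000 + int(yy) if int(yy) < 70 else 1900 + int(yy)
            quarters.append(f"{year}Q{q}")
    if not quarters:
        raise FaersFormatError(f"no quarters found under {root}")
    bundles = []
    for qid in sorted(set(quarters)):
        tag = f"{qid[2:4]}Q{qid[5]}"
        qdir = _VirtualQuarter(root, tag)
        bundles.append(read_quarter(qdir, qid, aliases=aliases))
    return bundles


class _VirtualQuarter:
    """Path-like view selecting only one quarter's files in a flat directory."""

    def __init__(self, root: Path, tag: str):
        self._root = root
        self._tag = tag.upper()

    def is_dir(self) -> bool:
        return True

    def iterdir(self):
        for p in sorted(self._root.iterdir()):
            if self._tag in p.name.upper():
                yield p

    def __str__(self) -> str:  # pragma: no cover - error paths only
        return f"{self._root}[{self._tag}]"

    def __fspath__(self) -> str:  # pragma: no cover
        return str(self._root)
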