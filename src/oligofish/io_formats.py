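"""Typed records and tabular I/O for the FISH polysomy pipeline.

Two plain-text table formats are used throughout:

* ``cells.tsv`` — tab-separated per-nucleus spot counts, one row per
  (sample, assay, nucleus) with the red (target-arm) and green
  (control-arm) counts.  Machine-written and potentially large.
* ``patients.csv`` — comma-separated clinical metadata, one row per
  patient, hand-editable.  Missing optional fields are encoded as the
  empty string and recorded as unknown (``None``).

Reports are versioned JSON documents that round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable

__all__ = [
    "ProbeAssay",
    "CellSignal",
    "PatientRecord",
    "FormatError",
    "read_cell_table",
    "write_cell_table",
    "read_patient_table",
    "write_patient_table",
    "write_report",
    "read_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised when an input table violates its format contract."""


class ProbeAssay(enum.Enum):
    """The three dual-colour probe assays.

    Each assay pairs a red target probe with a green control probe:
    1p36 against 1q25, 19q13 against 19p13, and CDKN2A (9p21) against
    the chromosome-9 centromere.
    """

    CHR1 = ("1p36", "1q25")
    CHR19 = ("19q13", "19p13")
    CDKN2A = ("9p21", "CEP9")

    def __init__(self, target_label: str, control_label: str) -> None:
        self.target_label = target_label
        self.control_label = control_label


@dataclass(frozen=True)
class CellSignal:
    """One nucleus's red (target) and green (control) spot counts."""

    sample_id: str
    assay: ProbeAssay
    cell_id: str
    red_count: int
    green_count: int

    def __post_init__(self) -> None:
        for name in ("red_count", "green_count"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


# Allowed levels for the categorical clinical fields.  ``None`` (encoded
# as the empty string on disk) is accepted everywhere and means unknown.
_CATEGORICAL_LEVELS: dict[str, frozenset[str]] = {
    "grade": frozenset({"O2", "O3"}),
    "sex": frozenset({"male", "female"}),
    "site": frozenset({"frontal", "parietal", "temporal", "occipital", "cingular"}),
    "treatment": frozenset({"none", "chemo", "radio", "chemo_radio"}),
    "mitoses_class": frozenset({"le5", "gt5"}),
    "mvp": frozenset({"endocrinoid", "glomeruloid"}),
    "mib1_class": frozenset({"le17", "gt17"}),
}


@dataclass
class PatientRecord:
    """Clinical/histological covariates plus EFS/OS outcome data.

    ``efs_months`` is time from diagnosis to first recurrence (or
    censoring), ``os_months`` time to death or last follow-up.  When both
    events occurred the recurrence cannot postdate death.
    """

    patient_id: str
    grade: str
    efs_months: float
    efs_event: bool
    os_months: float
    os_event: bool
    sex: str | None = None
    age_years: float | None = None
    site: str | None = None
    recurrent_flag: bool | None = None
    treatment: str | None = None
    mitoses_class: str | None = None
    mvp: str | None = None
    necrosis: bool | None = None
    calcification: bool | None = None
    mib1_class: str | None = None

    def __post_init__(self) -> None:
        for name, levels in _CATEGORICAL_LEVELS.items():
            v = getattr(self, name)
            if v is not None and v not in levels:
                raise ValueError(
                    f"field {name!r}: value {v!r} not in allowed levels {sorted(levels)}"
                )
        if self.efs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be non-negative")
        if self.efs_event and self.os_event and self.efs_months > self.os_months:
            raise ValueError(
                f"patient {self.patient_id}: efs_months ({self.efs_months}) exceeds "
                f"os_months ({self.os_months}) with both events recorded"
            )


_CELL_COLUMNS = ("sample_id", "assay", "cell_id", "red_count", "green_count")


def read_cell_table(path: str | Path) -> list[CellSignal]:
    """Read a tab-separated per-cell spot-count table.

    The header must contain the columns ``sample_id``, ``assay``,
    ``cell_id``, ``red_count`` and ``green_count``; extra columns are
    ignored.  Assay strings must name a :class:`ProbeAssay` member.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file, header row required")
        cols = header.split("\t")
        index = {c: i for i, c in enumerate(cols)}
        for col in _CELL_COLUMNS:
            if col not in index:
                raise FormatError(f"{path}: missing required column {col!r}")
        cells: list[CellSignal] = []
        seen: set[tuple[str, str, str]] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < len(cols):
                raise FormatError(f"{path}:{lineno}: expected {len(cols)} fields")
            row = {c: parts[index[c]] for c in _CELL_COLUMNS}
            try:
                assay = ProbeAssay[row["assay"]]
            except KeyError:
                raise FormatError(
                    f"{path}:{lineno}: unknown assay code {row['assay']!r}"
                ) from None
            try:
                red = int(row["red_count"])
                green = int(row["green_count"])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer spot count "
                    f"({row['red_count']!r}, {row['green_count']!r})"
                ) from None
            key = (row["sample_id"], row["assay"], row["cell_id"])
            if key in seen:
                raise FormatError(f"{path}:{lineno}: duplicate cell {key}")
            seen.add(key)
            cells.append(CellSignal(row["sample_id"], assay, row["cell_id"], red, green))
    return cells


def write_cell_table(cells: Iterable[CellSignal], path: str | Path) -> None:
    """Write cells as a tab-separated table (inverse of :func:`read_cell_table`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_CELL_COLUMNS) + "\n")
        for c in cells:
            fh.write(
                f"{c.sample_id}\t{c.assay.name}\t{c.cell_id}\t{c.red_count}\t{c.green_count}\n"
            )


_PATIENT_COLUMNS = (
    "patient_id",
    "grade",
    "sex",
    "age_years",
    "site",
    "recurrent_flag",
    "treatment",
    "mitoses_class",
    "mvp",
    "necrosis",
    "calcification",
    "mib1_class",
    "efs_months",
    "efs_event",
    "os_months",
    "os_event",
)

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _parse_optional_bool(value: str, field_name: str, lineno: int) -> bool | None:
    if value == "":
        return None
    try:
        return _BOOL_MAP[value.strip().lower()]
    except KeyError:
        raise FormatError(f"line {lineno}: field {field_name!r}: invalid boolean {value!r}") from None


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read a comma-separated patient metadata table.

    Categorical values are validated against their allowed levels; empty
    strings in optional fields become ``None`` (unknown, excluded
    listwise downstream).
    """
    import csv

    path = Path(path)
    records: list[PatientRecord] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        for col in _PATIENT_COLUMNS:
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = PatientRecord(
                    patient_id=row["patient_id"],
                    grade=row["grade"],
                    sex=row["sex"] or None,
                    age_years=float(row["age_years"]) if row["age_years"] else None,
                    site=row["site"] or None,
                    recurrent_flag=_parse_optional_bool(row["recurrent_flag"], "recurrent_flag", lineno),
                    treatment=row["treatment"] or None,
                    mitoses_class=row["mitoses_class"] or None,
                    mvp=row["mvp"] or None,
                    necrosis=_parse_optional_bool(row["necrosis"], "necrosis", lineno),
                    calcification=_parse_optional_bool(row["calcification"], "calcification", lineno),
                    mib1_class=row["mib1_class"] or None,
                    efs_months=float(row["efs_months"]),
                    efs_event=_parse_optional_bool(row["efs_event"], "efs_event", lineno) or False,
                    os_months=float(row["os_months"]),
                    os_event=_parse_optional_bool(row["os_event"], "os_event", lineno) or False,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_patient_table(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patients as a comma-separated table (inverse of :func:`read_patient_table`)."""
    import csv

    def encode(v: Any) -> str:
        if v is None:
            return ""
        if isinstance(v, bool):
            return "true" if v else "false"
        return str(v)

    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PATIENT_COLUMNS)
        for r in records:
            writer.writerow([encode(getattr(r, c)) for c in _PATIENT_COLUMNS])


def _jsonable(obj: Any) -> Any:
    """Recursively convert records, enums and numpy scalars to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, enum.Enum):
        return obj.name
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):  # numpy scalar
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    raise TypeError(f"cannot serialise {type(obj).__name__} into a report")


def write_report(calls: Any, stats: Any, path: str | Path) -> dict:
    """Write a versioned JSON report with per-sample calls and cohort stats.

    Returns the document that was written so callers can log or test it.
    """
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "calls": _jsonable(calls),
        "stats": _jsonable(stats),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return doc


def read_report(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise FormatError(f"unsupported report schema_version {doc.get('schema_version')!r}")
    return doc
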