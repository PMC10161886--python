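"""Sample spreadsheet: data model, CSV reader and validation.

One CSV row per sample.  Validation is collect-all: every problem is
reported with row and column coordinates so a user can fix the sheet in one
pass, and a sheet with any error blocks the run.

Canonical dialect: UTF-8, comma-separated, header row.  Multi-orientation
(chi, phi) pairs are encoded as ``"(0,0);(20,0)"``.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Tuple

from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .config import AcquisitionDefaults
from .errors import MissingColumn, SpreadsheetInvalid

METHODS = ("standard", "multi_orientation", "serial", "robot_test", "alc_test")
THRESHOLD_MODES = ("default", "strong", "weak", "always_collect")

REQUIRED_COLUMNS = ("puck", "position", "sample", "method")
COLUMNS = (
    "puck", "position", "sample", "method",
    "exposure_time_s", "oscillation_deg", "total_range_deg",
    "transmission", "resolution_a",
    "orientation_pairs", "threshold_mode", "no_centering", "processing",
)

CHI_RANGE = (0.0, 40.0)
PHI_RANGE = (-360.0, 360.0)


class SampleRow(BaseModel):
    """Validated description of one sample: mount address, collection method,
    acquisition parameters and optional multi-orientation (chi, phi) list."""

    puck: str
    position: int = Field(ge=1)
    sample: str
    method: Literal[METHODS] = "standard"
    exposure_time_s: Optional[float] = Field(default=None, gt=0)
    oscillation_deg: Optional[float] = Field(default=None, gt=0)
    total_range_deg: Optional[float] = Field(default=None, gt=0)
    transmission: Optional[float] = Field(default=None, gt=0, le=1)
    resolution_a: Optional[float] = Field(default=None, gt=0)
    orientation_pairs: Optional[List[Tuple[float, float]]] = None
    threshold_mode: Literal[THRESHOLD_MODES] = "default"
    no_centering: bool = False
    processing: str = ""

    @field_validator("orientation_pairs")
    @classmethod
    def _pair_ranges(cls, pairs):
        if pairs:
            for i, (chi, phi) in enumerate(pairs):
                if not (CHI_RANGE[0] <= chi <= CHI_RANGE[1]):
                    raise ValueError(f"pair {i}: chi={chi} outside {CHI_RANGE[0]}-{CHI_RANGE[1]} deg")
                if not (PHI_RANGE[0] <= phi <= PHI_RANGE[1]):
                    raise ValueError(f"pair {i}: phi={phi} outside +/-360 deg")
        return pairs

    @model_validator(mode="after")
    def _pairs_vs_method(self) -> "SampleRow":
        if self.method == "multi_orientation":
            if not self.orientation_pairs:
                raise ValueError("multi_orientation requires orientation_pairs")
        elif self.orientation_pairs:
            raise ValueError(f"orientation_pairs only valid for multi_orientation, not {self.method}")
        return self

    @property
    def address(self) -> Tuple[str, int]:
        return (self.puck, self.position)


@dataclass
class ValidationIssue:
    row: int          # 0-based data-row index
    column: str
    message: str


@dataclass
class ValidationReport:
    rows: List[SampleRow] = field(default_factory=list)
    errors: List[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> List[SampleRow]:
        if not self.ok:
            raise SpreadsheetInvalid(self)
        return self.rows

    def to_text(self) -> str:
        if self.ok:
            return f"OK: {len(self.rows)} sample(s) validated"
        lines = [f"{len(self.errors)} validation error(s):"]
        lines += [f"  row {e.row + 1}, column {e.column!r}: {e.message}" for e in self.errors]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "n_rows": len(self.rows),
                "errors": [
                    {"row": e.row, "column": e.column, "message": e.message}
                    for e in self.errors
                ],
            },
            sort_keys=True,
        )


def parse_pairs(text: str) -> List[Tuple[float, float]]:
    pairs = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if not (chunk.startswith("(") and chunk.endswith(")")):
            raise ValueError(f"malformed pair {chunk!r}, expected '(chi,phi)'")
        a, _, b = chunk[1:-1].partition(",")
        pairs.append((float(a), float(b)))
    return pairs


def format_pairs(pairs: List[Tuple[float, float]]) -> str:
    return ";".join(f"({_fmt(a)},{_fmt(b)})" for a, b in pairs)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    return str(x)


def read(path) -> List[dict]:
    """Header-mapped raw rows, whitespace-trimmed; unknown columns preserved.

    Raises :class:`MissingColumn` if a required header is absent.  An empty
    file (header only, or nothing) yields zero rows and is valid.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        header = [h.strip() for h in reader.fieldnames]
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise MissingColumn(f"required column {col!r} missing from header")
        raws = []
        for rec in reader:
            raws.append({
                (k.strip() if k else k): (v.strip() if isinstance(v, str) else v)
                for k, v in rec.items()
            })
    return raws


_FLOAT_FIELDS = ("exposure_time_s", "oscillation_deg", "total_range_deg",
                 "transmission", "resolution_a")
_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def validate(raws: List[dict], defaults: Optional[AcquisitionDefaults] = None) -> ValidationReport:
    """Coerce and check every raw row, collecting all errors (never
    fail-fast).  Absent acquisition parameters are filled from config
    defaults.  Duplicate mount addresses are reported at every occurrence."""
    defaults = defaults or AcquisitionDefaults()
    report = ValidationReport()
    parsed: List[Optional[SampleRow]] = []

    for i, raw in enumerate(raws):
        data = {}
        row_ok = True
        for key in ("puck", "sample", "method", "threshold_mode", "processing"):
            if raw.get(key):
                data[key] = raw[key]
        if raw.get("position"):
            try:
                data["position"] = int(raw["position"])
            except ValueError:
                report.errors.append(ValidationIssue(i, "position", f"not an integer: {raw['position']!r}"))
                row_ok = False
        for key in _FLOAT_FIELDS:
            val = raw.get(key)
            if val:
                try:
                    data[key] = float(val)
                except ValueError:
                    report.errors.append(ValidationIssue(i, key, f"not a number: {val!r}"))
                    row_ok = False
        if raw.get("orientation_pairs"):
            try:
                data["orientation_pairs"] = parse_pairs(raw["orientation_pairs"])
            except ValueError as exc:
                report.errors.append(ValidationIssue(i, "orientation_pairs", str(exc)))
                row_ok = False
        nc = str(raw.get("no_centering", "")).strip().lower()
        if nc in _TRUTHY:
            data["no_centering"] = True
        elif nc in _FALSY:
            data["no_centering"] = False
        else:
            report.errors.append(ValidationIssue(i, "no_centering", f"not a boolean: {nc!r}"))
            row_ok = False

        if not row_ok:
            parsed.append(None)
            continue
        # fill acquisition defaults for absent parameters
        fills = {
            "exposure_time_s": defaults.exposure_time_s,
            "oscillation_deg": defaults.oscillation_deg,
            "total_range_deg": defaults.total_range_deg,
            "transmission": defaults.transmission,
            "resolution_a": defaults.resolution_a,
        }
        for key, val in fills.items():
            data.setdefault(key, val)
        try:
            parsed.append(SampleRow.model_validate(data))
        except ValidationError as exc:
            parsed.append(None)
            for err in exc.errors():
                loc = err["loc"]
                column = str(loc[0]) if loc else "<row>"
                report.errors.append(ValidationIssue(i, column, err["msg"]))

    # cross-row: mount addresses must be unique
    seen: dict = {}
    for i, row in enumerate(parsed):
        if row is None:
            continue
        seen.setdefault(row.address, []).append(i)
    for addr, where in seen.items():
        if len(where) > 1:
            for i in where:
                report.errors.append(ValidationIssue(
                    i, "position",
                    f"duplicate mount address {addr} also on data row(s) "
                    f"{[j + 1 for j in where if j != i]}",
                ))

    if report.ok:
        report.rows = [r for r in parsed if r is not None]
    return report


def write_csv(rows: List[SampleRow], path) -> None:
    """Write validated rows in the canonical dialect (round-trips exactly)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for row in rows:
            writer.writerow([
                row.puck, row.position, row.sample, row.method,
                _fmt(row.exposure_time_s), _fmt(row.oscillation_deg),
                _fmt(row.total_range_deg), _fmt(row.transmission),
                _fmt(row.resolution_a),
                format_pairs(row.orientation_pairs) if row.orientation_pairs else "",
                row.threshold_mode, _fmt(row.no_centering), row.processing,
            ])
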