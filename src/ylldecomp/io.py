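"""CSV readers/writers and the JSON/CSV decomposition report.

Two instance dialects are supported, both UTF-8 comma-separated with a
"." decimal point:

* **count dialect** — ``age_start, age_end, population, deaths``
* **rate dialect** — ``age_start, age_end, pw, dr_per_1000`` plus a
  header comment ``# total_population = <N>`` from which counts are
  back-filled (``P_i = PW_i * P``, ``D_i = DR_i * P_i / 1000``).

``age_end`` is blank for the open-ended last bin.  The life-table file
has columns ``age_start, le_years``.

Parsing failures raise :class:`InstanceParseError` carrying a
:class:`ValidationReport` whose errors name the offending row and
column.
"""

from __future__ import annotations

import csv
import io as _io
import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import AgeSchedule, Instance, LifeTable, YLLError
from .decomposition import DecompositionResult

__all__ = [
    "ValidationReport",
    "InstanceParseError",
    "read_instance",
    "write_instance",
    "read_lifetable",
    "write_lifetable",
    "write_report",
    "report_schema",
    "validate_report",
]

_COUNT_COLUMNS = ["age_start", "age_end", "population", "deaths"]
_RATE_COLUMNS = ["age_start", "age_end", "pw", "dr_per_1000"]
_LIFETABLE_COLUMNS = ["age_start", "le_years"]
_TOTAL_POP_RE = re.compile(
    r"#\s*total_population\s*[=:]\s*([0-9eE+.\-]+)"
)


@dataclass
class ValidationReport:
    """Row/column-addressed parse problems. ``errors`` holds tuples of
    ``(row, column, message)`` where row counts data rows from 1 (None
    for file-level problems)."""

    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add(self, row: Optional[int], column: Optional[str], message: str) -> None:
        self.errors.append((row, column, message))

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = []
        for row, col, msg in self.errors:
            where = []
            if row is not None:
                where.append(f"row {row}")
            if col is not None:
                where.append(f"column {col!r}")
            prefix = ", ".join(where)
            lines.append(f"{prefix}: {msg}" if prefix else msg)
        return "\n".join(lines)


class InstanceParseError(YLLError):
    """A CSV file failed validation; ``.report`` details every problem."""

    def __init__(self, message: str, report: ValidationReport):
        super().__init__(f"{message}\n{report}")
        self.report = report


def _read_csv(path) -> tuple:
    """Return (DataFrame, comment lines). Blank age_end stays NaN."""
    text = Path(path).read_text(encoding="utf-8")
    comments = [ln for ln in text.splitlines() if ln.lstrip().startswith("#")]
    df = pd.read_csv(
        _io.StringIO(text),
        comment="#",
        skip_blank_lines=True,
        float_precision="round_trip",  # exact write -> read inversion
    )
    df.columns = [str(c).strip() for c in df.columns]
    return df, comments


def _schedule_from_frame(df: pd.DataFrame, report: ValidationReport):
    """Validate bin columns and build the AgeSchedule (or None)."""
    starts = df["age_start"].to_numpy(dtype=float)
    ends_raw = df["age_end"]
    n = len(df)
    ends = np.empty(n)
    for i in range(n):
        v = ends_raw.iloc[i]
        ends[i] = math.inf if pd.isna(v) else float(v)
        if math.isinf(ends[i]) and i != n - 1:
            report.add(i + 1, "age_end", "only the last bin may be open-ended")
    if n and starts[0] < 0:
        report.add(1, "age_start", "ages must be non-negative")
    for i in range(n):
        if not ends[i] > starts[i]:
            report.add(i + 1, "age_end", "bin is empty or inverted")
    for i in range(n - 1):
        if ends[i] > starts[i + 1]:
            report.add(i + 2, "age_start", "bins overlap the previous bin")
        elif ends[i] < starts[i + 1]:
            report.add(i + 2, "age_start", "gap after the previous bin")
    if not report.ok:
        return None
    try:
        return AgeSchedule(tuple(starts), tuple(ends))
    except ValueError as exc:  # anything the row checks above missed
        report.add(None, None, str(exc))
        return None


def read_instance(path, dialect: str = "auto", label: Optional[str] = None) -> Instance:
    """Read an instance CSV in either dialect.

    ``dialect`` is ``"counts"``, ``"rates"`` or ``"auto"`` (sniffed from
    the header).  The instance label defaults to the file stem.
    """
    report = ValidationReport()
    df, comments = _read_csv(path)
    cols = list(df.columns)
    if dialect == "auto":
        if cols == _COUNT_COLUMNS:
            dialect = "counts"
        elif cols == _RATE_COLUMNS:
            dialect = "rates"
        else:
            report.add(
                None,
                None,
                f"unrecognised header {cols}; expected {_COUNT_COLUMNS} "
                f"or {_RATE_COLUMNS}",
            )
            raise InstanceParseError(f"cannot parse {path}", report)
    expected = _COUNT_COLUMNS if dialect == "counts" else _RATE_COLUMNS
    if cols != expected:
        report.add(None, None, f"header {cols} does not match {expected}")
        raise InstanceParseError(f"cannot parse {path}", report)

    for col in expected[2:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        for i, v in enumerate(vals):
            if pd.isna(v):
                report.add(i + 1, col, "not a number")
            elif v < 0:
                report.add(i + 1, col, "negative value")
        df[col] = vals

    schedule = _schedule_from_frame(df, report)
    if not report.ok or schedule is None:
        raise InstanceParseError(f"cannot parse {path}", report)

    name = label if label is not None else Path(path).stem
    try:
        if dialect == "counts":
            return Instance(
                name,
                schedule,
                population=df["population"].to_numpy(dtype=float),
                deaths=df["deaths"].to_numpy(dtype=float),
            )
        total = None
        for ln in comments:
            m = _TOTAL_POP_RE.search(ln)
            if m:
                total = float(m.group(1))
        if total is None:
            report.add(
                None, None,
                "rate dialect needs a '# total_population = N' header comment",
            )
            raise InstanceParseError(f"cannot parse {path}", report)
        return Instance.from_rates(
            name, schedule, pw=df["pw"].to_numpy(dtype=float),
            dr=df["dr_per_1000"].to_numpy(dtype=float), total_population=total,
        )
    except YLLError as exc:
        if isinstance(exc, InstanceParseError):
            raise
        report.add(None, None, str(exc))
        raise InstanceParseError(f"invalid instance in {path}", report) from exc


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def write_instance(instance: Instance, path) -> None:
    """Write the count dialect; read_instance inverts it exactly."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COUNT_COLUMNS)
        for s, e, p, d in zip(
            instance.schedule.starts,
            instance.schedule.ends,
            instance.population,
            instance.deaths,
        ):
            end = "" if math.isinf(e) else _fmt(e)
            w.writerow([_fmt(s), end, _fmt(p), _fmt(d)])


def read_lifetable(path, schedule: Optional[AgeSchedule] = None) -> LifeTable:
    """Read ``age_start, le_years``.

    Without a target ``schedule`` the bins are inferred from the starts
    (last bin open-ended).  With one, LE values are matched to its bin
    starts exactly (the file may hold extra ages).
    """
    report = ValidationReport()
    df, _ = _read_csv(path)
    if list(df.columns) != _LIFETABLE_COLUMNS:
        report.add(
            None, None,
            f"header {list(df.columns)} does not match {_LIFETABLE_COLUMNS}",
        )
        raise InstanceParseError(f"cannot parse {path}", report)
    starts = df["age_start"].to_numpy(dtype=float)
    le = pd.to_numeric(df["le_years"], errors="coerce").to_numpy(dtype=float)
    for i, v in enumerate(le):
        if pd.isna(v):
            report.add(i + 1, "le_years", "not a number")
        elif v <= 0:
            report.add(i + 1, "le_years", "life expectancy must be positive")
    if np.any(np.diff(starts) <= 0):
        report.add(None, "age_start", "start ages must be strictly increasing")
    if not report.ok:
        raise InstanceParseError(f"cannot parse {path}", report)
    try:
        raw = LifeTable(AgeSchedule.from_starts(starts.tolist()), le)
        return raw if schedule is None else raw.reindex(schedule)
    except (ValueError, YLLError) as exc:
        report.add(None, None, str(exc))
        raise InstanceParseError(f"invalid life table in {path}", report) from exc


def write_lifetable(lifetable: LifeTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LIFETABLE_COLUMNS)
        for s, v in zip(lifetable.schedule.starts, lifetable.le):
            w.writerow([_fmt(s), _fmt(v)])


def _sig(x: float) -> str:
    """12 significant digits, the CSV report precision."""
    return f"{float(x):.12g}"


def write_report(result: DecompositionResult, path, format: str = "json") -> None:
    """Write a decomposition report.

    JSON mirrors :meth:`DecompositionResult.to_dict` at full precision.
    CSV renders the four labelled rows of the standard presentation
    (total contribution, partial contribution, residue-free estimate,
    percent contribution) at 12 significant digits, with the headline
    rates as header comments.
    """
    if format == "json":
        Path(path).write_text(
            json.dumps(result.to_dict(), indent=2) + "\n", encoding="utf-8"
        )
        return
    if format != "csv":
        raise ValueError(f"unknown report format {format!r}")
    p, t, rf = result.partial, result.total, result.residue_free
    rows = [
        ("TOTAL Contribution", t.residual, t.d_yll_age, t.d_yll_death_rate,
         t.d_yll_age_at_death),
        ("PARTIAL Contribution", p.residual, p.d_yll_age, p.d_yll_death_rate,
         p.d_yll_age_at_death),
        ("Residue free estimate", p.residual + t.residual, rf.age_structure,
         rf.death_rate, rf.age_at_death),
    ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# baseline = {result.label0}\n")
        fh.write(f"# comparison = {result.label1}\n")
        fh.write(f"# yll0_per_1000 = {_sig(result.yll0)}\n")
        fh.write(f"# yll1_per_1000 = {_sig(result.yll1)}\n")
        fh.write(f"# delta_yll_per_1000 = {_sig(result.delta_yll)}\n")
        w = csv.writer(fh)
        w.writerow(["row", "residual", "age_structure", "death_rate",
                    "age_at_death"])
        for name, *vals in rows:
            w.writerow([name] + [_sig(v) for v in vals])
        if result.percent is None:
            w.writerow(["Contribution in delta YLL (%)", "", "", "", ""])
        else:
            pa, pd_, pda = result.percent
            w.writerow(["Contribution in delta YLL (%)", "",
                        _sig(pa), _sig(pd_), _sig(pda)])


def report_schema() -> dict:
    """The JSON schema shipped with the package for the report object."""
    text = resources.files(__package__).joinpath("report_schema.json").read_text(
        encoding="utf-8"
    )
    return json.loads(text)


def _check_node(obj, schema, path, problems, root=None) -> None:
    root = root if root is not None else schema
    if "$ref" in schema:
        # only local '#/$defs/...' references are used
        node = root
        for part in schema["$ref"].lstrip("#/").split("/"):
            node = node[part]
        _check_node(obj, node, path, problems, root)
        return
    t = schema.get("type")
    types = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "boolean": bool,
    }
    if t == "number" and isinstance(obj, bool):
        problems.append(f"{path}: expected number, got bool")
        return
    if t is not None:
        allowed = t if isinstance(t, list) else [t]
        if obj is None:
            if "null" not in allowed:
                problems.append(f"{path}: unexpected null")
            return
        if not any(isinstance(obj, types[a]) for a in allowed if a != "null"):
            problems.append(f"{path}: expected {t}, got {type(obj).__name__}")
            return
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                problems.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check_node(obj[key], sub, f"{path}.{key}", problems, root)
    if isinstance(obj, list):
        sub = schema.get("items")
        if sub:
            for i, item in enumerate(obj):
                _check_node(item, sub, f"{path}[{i}]", problems, root)


def validate_report(report: dict) -> list:
    """Structurally validate a report dict against the shipped schema;
    returns a list of problem strings (empty when valid)."""
    problems: list = []
    _check_node(report, report_schema(), "$", problems)
    return problems
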