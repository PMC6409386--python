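"""Registered row-local functional transforms, including blinding.

Functional map steps reference host-language callables by name.  Each
callable receives ``(row, args, context)`` and returns the transformed row
(or ``None`` to drop it).  Rows are plain dicts; functions may add or
replace fields.  Registering named callables instead of embedding a script
engine keeps transforms deterministic, sandboxed and unit-testable while
preserving the same row-local expressive power.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass
from datetime import date, datetime, timezone
from typing import Callable

from .errors import ParameterError

#: Reserved row field carrying the source record's identity through a
#: pipeline; injected by the query layer, stripped from final output.
RECORD_ID_FIELD = "_record_id"


@dataclass(frozen=True)
class UserContext:
    """Per-query role and evaluation clock injected into transforms."""

    role: str = "Unblinded"
    now: int = 0  # epoch milliseconds; 0 = wall clock at construction

    def clock_ms(self) -> int:
        return self.now if self.now else int(time.time() * 1000)


# -- date helpers ----------------------------------------------------------

_DATE_FORMATS = ("%Y-%m-%d", "%m/%d/%Y", "%d-%b-%Y", "%Y/%m/%d", "%m-%d-%Y")


def parse_date(value: str) -> date | None:
    for fmt in _DATE_FORMATS:
        try:
            return datetime.strptime(value.strip(), fmt).date()
        except ValueError:
            continue
    return None


def iso_date(value: str) -> str:
    """Convert a date string in a recognized format to ISO-8601; values that
    do not parse are returned unchanged."""
    parsed = parse_date(value)
    return parsed.isoformat() if parsed else value


def study_day(ref: str, when: str) -> str | None:
    """Study day relative to a reference start date: there is no day zero, so
    the reference date itself is day 1 and days before it are negative."""
    ref_d, when_d = parse_date(ref), parse_date(when)
    if ref_d is None or when_d is None:
        return None
    diff = (when_d - ref_d).days
    return str(diff + 1 if diff >= 0 else diff)


def upper_case_trim(value: str) -> str:
    # trim first, then upper-case
    return value.strip().upper()


def iso_to_ms(value: str | int) -> int:
    """Epoch milliseconds from an ISO date/datetime string (UTC) or an
    integer passthrough."""
    if isinstance(value, int):
        return value
    text = str(value).strip()
    if text.isdigit():
        return int(text)
    d = parse_date(text)
    if d is not None:
        return int(datetime(d.year, d.month, d.day, tzinfo=timezone.utc).timestamp() * 1000)
    dt = datetime.fromisoformat(text)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return int(dt.timestamp() * 1000)


# -- blinding --------------------------------------------------------------

def fuzz_value(record_id: str, column: str, salt: str, low: int, high: int) -> str:
    """Deterministic replacement value: uniform integer in ``[low, high)``
    seeded by (record id, column, salt), so a blinded view is stable across
    repeated queries."""
    digest = hashlib.sha256(f"{record_id}\x1f{column}\x1f{salt}".encode()).digest()
    span = high - low
    if span <= 0:
        raise ParameterError("fuzz range must be non-empty")
    return str(low + int.from_bytes(digest[:8], "big") % span)


def apply_blinding(column: str, rule: dict, row: dict, context: UserContext) -> dict:
    """Fuzz ``column`` when the user's role matches the rule and the clock is
    before the unblinding date; otherwise pass the row through unchanged.
    Once the evaluation clock reaches ``end_date`` the data unblinds
    automatically — no map edit required.

    Rule keys: ``role`` (default "Blinded"), ``end_date`` (ISO date or epoch
    ms), ``low``/``high`` (fuzz range, default [0, 3)), ``salt``.
    """
    role = rule.get("role", "Blinded")
    end_ms = iso_to_ms(rule["end_date"])
    if context.role != role or context.clock_ms() >= end_ms:
        return row
    if column not in row:
        return row
    record_id = row.get(RECORD_ID_FIELD)
    if record_id is None:
        # standalone use: fall back to a stable digest of the row itself
        record_id = hashlib.sha256(
            "\x1f".join(f"{k}={v}" for k, v in sorted(row.items())).encode()
        ).hexdigest()
    out = dict(row)
    out[column] = fuzz_value(record_id, column, str(rule.get("salt", "")),
                             int(rule.get("low", 0)), int(rule.get("high", 3)))
    return out


# -- registry --------------------------------------------------------------

TransformFn = Callable[[dict, dict, UserContext], dict | None]


class FunctionRegistry:
    """Name -> row transform lookup used by functional map steps."""

    def __init__(self, include_builtins: bool = True):
        self._fns: dict[str, TransformFn] = {}
        if include_builtins:
            self._register_builtins()

    def register(self, name: str, fn: TransformFn) -> None:
        self._fns[name] = fn

    def get(self, name: str) -> TransformFn:
        if name not in self._fns:
            raise ParameterError(f"unknown function {name!r}; registered: {sorted(self._fns)}")
        return self._fns[name]

    def __contains__(self, name: str) -> bool:
        return name in self._fns

    def _register_builtins(self) -> None:
        reg = self.register

        def _col(args):
            return args["column"]

        def fn_iso_date(row, args, ctx):
            col = _col(args)
            if col in row and row[col] is not None:
                row = dict(row)
                row[col] = iso_date(row[col])
            return row

        def fn_upper_case_trim(row, args, ctx):
            col = _col(args)
            if col in row and row[col] is not None:
                row = dict(row)
                row[col] = upper_case_trim(row[col])
            return row

        def fn_study_day(row, args, ctx):
            ref = row.get(args["ref_column"])
            when = row.get(args["date_column"])
            out = args.get("output", "DY")
            row = dict(row)
            row[out] = study_day(ref, when) if ref and when else None
            return row

        def fn_set_constant(row, args, ctx):
            row = dict(row)
            row[_col(args)] = args["value"]
            return row

        def fn_strip_leading_zeros(row, args, ctx):
            col = _col(args)
            if col in row and row[col]:
                row = dict(row)
                stripped = row[col].lstrip("0")
                row[col] = stripped if stripped else "0"
            return row

        def fn_strip_prefix(row, args, ctx):
            col = _col(args)
            prefix = args["prefix"]
            if col in row and isinstance(row[col], str) and row[col].startswith(prefix):
                row = dict(row)
                row[col] = row[col][len(prefix):]
            return row

        def fn_select_columns(row, args, ctx):
            keep = list(args["columns"])
            out = {k: row.get(k) for k in keep}
            if RECORD_ID_FIELD in row:
                out[RECORD_ID_FIELD] = row[RECORD_ID_FIELD]
            return out

        def fn_drop_columns(row, args, ctx):
            drop = set(args["columns"])
            return {k: v for k, v in row.items() if k not in drop}

        def fn_blind(row, args, ctx):
            return apply_blinding(_col(args), args, row, ctx)

        reg("iso_date", fn_iso_date)
        reg("upper_case_trim", fn_upper_case_trim)
        reg("study_day", fn_study_day)
        reg("set_constant", fn_set_constant)
        reg("strip_leading_zeros", fn_strip_leading_zeros)
        reg("strip_prefix", fn_strip_prefix)
        reg("select_columns", fn_select_columns)
        reg("drop_columns", fn_drop_columns)
        reg("blind", fn_blind)
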