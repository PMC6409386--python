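"""Late-binding transformation algebra and the versioned map registry.

An *output domain* is an ordered pipeline of map steps applied to raw input
records at query time — the raw store is never modified.  Eight step kinds
cover practical SDTM-style standardization: column renames, copies, row
filters, registered functional transforms (dates, study day, case folding,
blinding, ...), code-list dictionaries, pivot/depivot between EAV and wide
layouts, and relational left joins across domains.

Maps are versioned independently of the data: every edit closes the current
version's validity interval and opens a new one, so the exact set of rules
active at any past instant can be reconstructed and replayed against data of
any (other) vintage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .errors import (
    AmbiguousJoinError,
    MapDefinitionError,
    NoActiveMapError,
    PivotCollisionError,
    RetiredMapError,
    StrictColumnError,
)
from .filters import compile_filter
from .functions import RECORD_ID_FIELD, FunctionRegistry, UserContext

logger = logging.getLogger(__name__)

Row = dict
STEP_KINDS = ("rename", "copy", "filter", "functional", "dict",
              "pivot", "depivot", "join")

_REQUIRED_PARAMS = {
    "rename": ("src", "dst"),
    "copy": ("src", "dst"),
    "filter": ("predicate",),
    "functional": ("function",),
    "dict": ("column", "table"),
    "pivot": ("key_cols", "attr_col", "value_col"),
    "depivot": ("key_cols", "measure_cols", "attr_name", "value_name"),
    "join": ("selectedDomain", "joinCols", "colNameTranslations",
             "selectedColumn", "outputColumn"),
}

#: Steps that consume and emit one row at a time (streamable).
ROW_LOCAL_KINDS = frozenset({"rename", "copy", "filter", "functional", "dict"})


@dataclass(frozen=True)
class MapStep:
    """One validated transformation step."""

    step_kind: str
    params: dict

    def __post_init__(self):
        if self.step_kind not in STEP_KINDS:
            raise MapDefinitionError(f"unknown step kind {self.step_kind!r}")
        missing = [p for p in _REQUIRED_PARAMS[self.step_kind] if p not in self.params]
        if missing:
            raise MapDefinitionError(
                f"{self.step_kind} step missing params: {missing}")
        if self.step_kind == "filter":
            # parse errors surface at map creation, never at row time
            object.__setattr__(self, "_compiled",
                               compile_filter(self.params["predicate"]))
        if self.step_kind == "join":
            sel = self.params["selectedColumn"]
            out = self.params["outputColumn"]
            if len(sel) != len(out):
                raise MapDefinitionError(
                    "join selectedColumn and outputColumn must align")
            if not self.params["joinCols"]:
                raise MapDefinitionError("join requires joinCols")
            trans = self.params["colNameTranslations"]
            for jc in self.params["joinCols"]:
                if jc not in trans:
                    raise MapDefinitionError(
                        f"join column {jc!r} lacks a colNameTranslations entry")

    # -- serialization -----------------------------------------------------

    def to_json_obj(self) -> dict:
        return {"kind": self.step_kind, **self.params}

    @classmethod
    def from_json_obj(cls, obj: dict) -> "MapStep":
        params = {k: v for k, v in obj.items() if k != "kind"}
        return cls(step_kind=obj["kind"], params=params)


def flatten_steps(steps) -> list[MapStep]:
    """Depth-first flatten of arbitrarily nested step lists (nesting lets
    reusable groups of maps be spliced into a pipeline)."""
    out: list[MapStep] = []
    for item in steps:
        if isinstance(item, MapStep):
            out.append(item)
        elif isinstance(item, (list, tuple)):
            out.extend(flatten_steps(item))
        else:
            raise MapDefinitionError(f"not a map step: {item!r}")
    return out


@dataclass(frozen=True)
class OutputDomain:
    """Named pipeline producing a standardized view of one input domain."""

    name: str
    input_domain: str
    steps: tuple[MapStep, ...]

    def __init__(self, name: str, input_domain: str, steps: Sequence):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "input_domain", input_domain)
        object.__setattr__(self, "steps", tuple(flatten_steps(steps)))

    def to_json_obj(self) -> dict:
        return {"inputDomain": self.input_domain, "outputDomain": self.name,
                "maps": [s.to_json_obj() for s in self.steps]}

    @classmethod
    def from_json_obj(cls, obj: dict) -> "OutputDomain":
        def build(items):
            return [build(i) if isinstance(i, list) else MapStep.from_json_obj(i)
                    for i in items]
        return cls(name=obj["outputDomain"], input_domain=obj["inputDomain"],
                   steps=build(obj["maps"]))


# -- step application ------------------------------------------------------

def apply_dict(column: str, table: dict, row: Row) -> Row:
    """Replace ``row[column]`` via the code list; unmapped values pass
    through unchanged (code lists are routinely partial)."""
    tbl = {str(k): str(v) for k, v in table.items()}
    if column in row and row[column] is not None:
        value = str(row[column])
        if value in tbl:
            row = dict(row)
            row[column] = tbl[value]
        else:
            logger.warning("dict step: value %r not in code list for %r", value, column)
    return row


def apply_join(rows: list[Row], spec: dict, other_domain_rows: list[Row],
               first_match: bool = False) -> list[Row]:
    """Left join: each row gains ``outputColumn`` values from the matching
    right-hand row's ``selectedColumn``; no match leaves them null.  Keys
    compare by exact string equality after colNameTranslations renames the
    right-hand join columns into left-hand ones."""
    join_cols = list(spec["joinCols"])
    translations = spec["colNameTranslations"]
    selected = list(spec["selectedColumn"])
    output = list(spec["outputColumn"])

    index: dict[tuple, Row] = {}
    ambiguous: set[tuple] = set()
    for other in other_domain_rows:
        key = tuple(other.get(jc) for jc in join_cols)
        if any(k is None for k in key):
            continue
        key = tuple(str(k) for k in key)
        if key in index:
            ambiguous.add(key)
        else:
            index[key] = other

    out_rows = []
    for row in rows:
        key = tuple(row.get(translations[jc]) for jc in join_cols)
        match = None
        if not any(k is None for k in key):
            key = tuple(str(k) for k in key)
            if key in ambiguous and not first_match:
                raise AmbiguousJoinError(
                    f"multiple rows of {spec['selectedDomain']!r} match key {key!r}")
            match = index.get(key)
        new_row = dict(row)
        for sel, out in zip(selected, output):
            new_row[out] = match.get(sel) if match is not None else None
        out_rows.append(new_row)
    return out_rows


def apply_pivot(rows: list[Row], key_cols: Sequence[str], attr_col: str,
                value_col: str) -> list[Row]:
    """EAV -> wide: one output row per key tuple, one column per attribute
    value.  Two input rows sharing (key tuple, attribute) collide."""
    grouped: dict[tuple, Row] = {}
    seen: set[tuple] = set()
    for row in rows:
        key = tuple(row.get(k) for k in key_cols)
        attr = row.get(attr_col)
        if (key, attr) in seen:
            raise PivotCollisionError(key, attr)
        seen.add((key, attr))
        if key not in grouped:
            grouped[key] = {k: row.get(k) for k in key_cols}
        if attr is not None:
            grouped[key][attr] = row.get(value_col)
    return list(grouped.values())


def apply_depivot(rows: list[Row], key_cols: Sequence[str],
                  measure_cols: Sequence[str], attr_name: str,
                  value_name: str) -> list[Row]:
    """Wide -> EAV: one output row per (input row, measure column)."""
    out = []
    for row in rows:
        for m in measure_cols:
            if m not in row:
                continue
            eav = {k: row.get(k) for k in key_cols}
            eav[attr_name] = m
            eav[value_name] = row[m]
            out.append(eav)
    return out


class PipelineRunner:
    """Executes an output domain's steps over a batch of rows.

    ``domain_resolver`` maps a domain name to its rows (raw or previously
    mapped) for join steps; omitting it makes join steps fail fast.
    """

    def __init__(self, functions: FunctionRegistry | None = None,
                 strict_columns: bool = False, join_first_match: bool = False):
        self.functions = functions or FunctionRegistry()
        self.strict_columns = strict_columns
        self.join_first_match = join_first_match

    # row-local steps ------------------------------------------------------

    def _missing_column(self, step: MapStep, column: str) -> None:
        if self.strict_columns:
            raise StrictColumnError(
                f"{step.step_kind} step references missing column {column!r}")
        logger.warning("%s step: column %r absent; row passed through",
                       step.step_kind, column)

    def apply_step_row(self, step: MapStep, row: Row,
                       context: UserContext) -> Row | None:
        kind, params = step.step_kind, step.params
        if kind == "rename":
            src, dst = params["src"], params["dst"]
            if src not in row:
                self._missing_column(step, src)
                return row
            row = dict(row)
            row[dst] = row.pop(src)
            return row
        if kind == "copy":
            src, dst = params["src"], params["dst"]
            if src not in row:
                self._missing_column(step, src)
                return row
            row = dict(row)
            row[dst] = row[src]
            return row
        if kind == "filter":
            return row if step._compiled(row) else None
        if kind == "dict":
            if params["column"] not in row:
                self._missing_column(step, params["column"])
                return row
            return apply_dict(params["column"], params["table"], row)
        if kind == "functional":
            fn = self.functions.get(params["function"])
            args = params.get("args", {})
            try:
                return fn(dict(row), args, context)
            except Exception as exc:  # one bad row must not abort the domain
                flagged = dict(row)
                flagged["_map_error"] = f"{params['function']}: {exc}"
                return flagged
        raise MapDefinitionError(f"{kind} is not row-local")

    # pipeline -------------------------------------------------------------

    def apply_pipeline(self, records: list[Row], output_domain: OutputDomain,
                       context: UserContext | None = None,
                       domain_resolver: Callable[[str], list[Row]] | None = None,
                       ) -> list[Row]:
        context = context or UserContext()
        # validate functional references up front
        for step in output_domain.steps:
            if step.step_kind == "functional" and step.params["function"] not in self.functions:
                raise MapDefinitionError(
                    f"unregistered function {step.params['function']!r}")
        rows = [dict(r) for r in records]
        for step in output_domain.steps:
            if step.step_kind in ROW_LOCAL_KINDS:
                new_rows = []
                for row in rows:
                    result = self.apply_step_row(step, row, context)
                    if result is not None:
                        new_rows.append(result)
                rows = new_rows
            elif step.step_kind == "pivot":
                p = step.params
                rows = apply_pivot(rows, p["key_cols"], p["attr_col"], p["value_col"])
            elif step.step_kind == "depivot":
                p = step.params
                rows = apply_depivot(rows, p["key_cols"], p["measure_cols"],
                                     p["attr_name"], p["value_name"])
            elif step.step_kind == "join":
                if domain_resolver is None:
                    raise MapDefinitionError(
                        "join step requires a domain resolver")
                other = domain_resolver(step.params["selectedDomain"])
                rows = apply_join(rows, step.params, other,
                                  first_match=self.join_first_match)
        return rows


def apply_pipeline(records: list[Row], output_domain: OutputDomain,
                   context: UserContext | None = None,
                   domain_resolver=None, functions=None) -> list[Row]:
    """Functional facade over :class:`PipelineRunner`."""
    runner = PipelineRunner(functions=functions)
    return runner.apply_pipeline(records, output_domain, context, domain_resolver)


# -- map registry with audit trail ----------------------------------------

@dataclass
class MapVersion:
    """One entry of a map's audit trail: the definition plus its validity
    interval (``invalidated_at`` is ``None`` while the version is active)."""

    map_id: str
    version: int
    created_at: int
    invalidated_at: int | None
    definition: OutputDomain
    retired: bool = False

    def active_at(self, t: int) -> bool:
        if t < self.created_at:
            return False
        return self.invalidated_at is None or t < self.invalidated_at


class MapRegistry:
    """Versioned database of mapping rules: every edit invalidates the old
    version and opens a new one, yielding a full as-of reconstructable
    audit trail."""

    def __init__(self):
        self._history: dict[str, list[MapVersion]] = {}

    def create_map(self, map_id: str, definition: OutputDomain, t: int) -> MapVersion:
        if map_id in self._history:
            raise MapDefinitionError(f"map {map_id!r} already exists; use edit_map")
        mv = MapVersion(map_id, 1, t, None, definition)
        self._history[map_id] = [mv]
        return mv

    def edit_map(self, map_id: str, new_definition: OutputDomain, t: int) -> MapVersion:
        history = self._history.get(map_id)
        if not history:
            raise NoActiveMapError(f"unknown map {map_id!r}")
        open_version = history[-1]
        if open_version.retired or open_version.invalidated_at is not None:
            raise RetiredMapError(f"map {map_id!r} is retired")
        if t < open_version.created_at:
            raise MapDefinitionError("edit timestamp precedes current version")
        open_version.invalidated_at = t
        mv = MapVersion(map_id, open_version.version + 1, t, None, new_definition)
        history.append(mv)
        return mv

    def retire_map(self, map_id: str, t: int) -> None:
        history = self._history.get(map_id)
        if not history:
            raise NoActiveMapError(f"unknown map {map_id!r}")
        open_version = history[-1]
        if open_version.retired or open_version.invalidated_at is not None:
            raise RetiredMapError(f"map {map_id!r} is already retired")
        open_version.invalidated_at = t
        open_version.retired = True

    def active_maps_asof(self, t: int) -> dict[str, MapVersion]:
        out = {}
        for map_id, history in self._history.items():
            for mv in history:
                if mv.active_at(t):
                    out[map_id] = mv
                    break
        return out

    def history(self, map_id: str) -> list[MapVersion]:
        return list(self._history.get(map_id, ()))

    def map_ids(self) -> list[str]:
        return sorted(self._history)

    # -- persistence -------------------------------------------------------

    def to_json_obj(self) -> dict:
        return {
            map_id: [
                {"version": mv.version, "created_at": mv.created_at,
                 "invalidated_at": mv.invalidated_at, "retired": mv.retired,
                 "definition": mv.definition.to_json_obj()}
                for mv in history
            ]
            for map_id, history in self._history.items()
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "MapRegistry":
        reg = cls()
        for map_id, entries in obj.items():
            reg._history[map_id] = [
                MapVersion(map_id, e["version"], e["created_at"],
                           e["invalidated_at"],
                           OutputDomain.from_json_obj(e["definition"]),
                           retired=e.get("retired", False))
                for e in entries
            ]
        return reg
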