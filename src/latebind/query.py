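"""Consuming-application surface: mapped-domain retrieval and export.

The defining capability of the late-binding design is that the data
timestamp and the map timestamp are chosen *independently*: historical maps
can be applied to current data or current maps to historical data, and any
(data_as_of, maps_as_of) pair reproduces byte-identical output — raw records
and map versions are both immutable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import IO

from .errors import MapDefinitionError, NoActiveMapError
from .functions import RECORD_ID_FIELD, FunctionRegistry, UserContext
from .ingest import Ingestor
from .mapping import MapRegistry, OutputDomain, PipelineRunner, Row
from .store import RecordStore

LATEST = "latest"


@dataclass
class QuerySpec:
    """A fully mapped-domain request."""

    output_domain: str
    data_as_of: int | str = LATEST
    maps_as_of: int | str = LATEST
    context: UserContext = field(default_factory=UserContext)
    columns: list[str] | None = None
    study_id: str = ""


class Warehouse:
    """Embedded late-binding warehouse: record store + map registry +
    function registry behind one facade."""

    def __init__(self, study_id: str = ""):
        self.study_id = study_id
        self.store = RecordStore()
        self.maps = MapRegistry()
        self.functions = FunctionRegistry()
        self.ingestor = Ingestor(self.store, study_id=study_id)

    # -- map management ----------------------------------------------------

    def define_output_domain(self, definition: OutputDomain, t: int):
        return self.maps.create_map(definition.name, definition, t)

    def edit_output_domain(self, definition: OutputDomain, t: int):
        return self.maps.edit_map(definition.name, definition, t)

    # -- retrieval ---------------------------------------------------------

    def _resolve_ts(self, value: int | str) -> int:
        if value == LATEST:
            return max(self.store.max_ts(), _max_map_ts(self.maps))
        return int(value)

    def get_mapped_domain(self, spec: QuerySpec) -> list[Row]:
        """Apply the pipeline active at ``maps_as_of`` to the raw records
        current at ``data_as_of``.  Join steps resolve other domains at the
        same two timestamps (output domains recursively, raw domains
        directly); cycles among output domains are rejected."""
        data_t = self._resolve_ts(spec.data_as_of)
        maps_t = self._resolve_ts(spec.maps_as_of)
        active = self.maps.active_maps_asof(maps_t)
        if spec.output_domain not in active:
            raise NoActiveMapError(
                f"no active definition for {spec.output_domain!r} at t={maps_t}")

        runner = PipelineRunner(functions=self.functions)

        def raw_rows(domain: str) -> list[Row]:
            rows = []
            for rec in self.store.query_asof(domain, data_t):
                row = dict(rec.data)
                row[RECORD_ID_FIELD] = rec.record_id
                rows.append(row)
            return rows

        def mapped_rows(name: str, in_flight: frozenset) -> list[Row]:
            if name in in_flight:
                raise MapDefinitionError(f"cyclic join through {name!r}")
            definition: OutputDomain = active[name].definition
            return runner.apply_pipeline(
                raw_rows(definition.input_domain), definition, spec.context,
                domain_resolver=lambda d: resolve(d, in_flight | {name}))

        def resolve(domain: str, in_flight: frozenset) -> list[Row]:
            # join targets: raw input domains first; otherwise a previously
            # defined output domain (mapped recursively at the same as-ofs)
            if self.store.record_ids(domain):
                return raw_rows(domain)
            if domain in active:
                return mapped_rows(domain, in_flight)
            return []

        rows = mapped_rows(spec.output_domain, frozenset())
        out = []
        for row in rows:
            row = {k: v for k, v in row.items() if k != RECORD_ID_FIELD}
            if spec.columns is not None:
                row = {k: row.get(k) for k in spec.columns}
            out.append(row)
        return out


def _max_map_ts(registry: MapRegistry) -> int:
    out = 0
    for map_id in registry.map_ids():
        for mv in registry.history(map_id):
            out = max(out, mv.created_at, mv.invalidated_at or 0)
    return out


# -- export ----------------------------------------------------------------

def export(records: list[Row], format: str, sink: IO[str]) -> int:
    """Write mapped rows as CSV (header = union of keys in first-seen order,
    missing values empty) or JSON Lines.  Returns the row count."""
    if format == "jsonl":
        for row in records:
            sink.write(json.dumps(row, sort_keys=False) + "\n")
        return len(records)
    if format == "csv":
        header: list[str] = []
        for row in records:
            for k in row:
                if k not in header:
                    header.append(k)
        writer = csv.writer(sink, lineterminator="\n")
        writer.writerow(header)
        for row in records:
            writer.writerow(["" if row.get(k) is None else row.get(k) for k in header])
        return len(records)
    raise ValueError(f"unknown export format {format!r}")
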