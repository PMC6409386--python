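"""Append-only, timestamped record store with as-of (time-travel) queries.

Raw clinical data is persisted nearly verbatim as flat string-valued records.
Every write creates a new immutable version keyed by ``(record_id,
version_ts)``; deletes are soft (a new version with ``deleted=True``), so the
state of any domain at any past timestamp can be reconstructed exactly.  This
reproduces the row-key/column/timestamp versioning semantics of a
column-store warehouse as a standalone embedded structure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator

from .errors import MissingKeyError, NotFoundError, OutOfOrderWriteError

#: Non-printable unit separator used in the canonical key serialization.
#: Field names and values may legally contain commas, pipes, etc.; US cannot
#: appear in sane clinical data, so the serialization is delimiter-safe.
_UNIT_SEP = "\x1f"


@dataclass(frozen=True)
class KeySpec:
    """Names the fields whose values form a domain's primary key."""

    domain: str
    key_fields: tuple[str, ...]

    def __post_init__(self):
        if not self.key_fields:
            raise ValueError("key_fields must be non-empty")
        object.__setattr__(self, "key_fields", tuple(self.key_fields))


@dataclass(frozen=True)
class StoredRecord:
    """One immutable version of one flattened raw record."""

    study_id: str
    domain: str
    record_id: str
    version_ts: int
    data: dict[str, str]
    deleted: bool = False
    ingest_job_id: str = ""
    config_id: str = ""
    #: Per-store monotone write sequence; breaks ties among equal timestamps.
    seq: int = field(default=0, compare=False)

    def to_json_obj(self) -> dict:
        return {
            "study_id": self.study_id,
            "domain": self.domain,
            "record_id": self.record_id,
            "version_ts": self.version_ts,
            "deleted": self.deleted,
            "ingest_job_id": self.ingest_job_id,
            "config_id": self.config_id,
            "data": dict(self.data),
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "StoredRecord":
        return cls(
            study_id=obj["study_id"],
            domain=obj["domain"],
            record_id=obj["record_id"],
            version_ts=int(obj["version_ts"]),
            data={str(k): str(v) for k, v in obj["data"].items()},
            deleted=bool(obj["deleted"]),
            ingest_job_id=obj.get("ingest_job_id", ""),
            config_id=obj.get("config_id", ""),
        )


def canonical_key_serialization(key_spec: KeySpec, data: dict[str, str]) -> str:
    """Serialize (domain, ordered key fields, values) with unit separators.

    Raises :class:`MissingKeyError` naming the first absent key field.
    """
    parts = [key_spec.domain]
    for f in key_spec.key_fields:
        if f not in data:
            raise MissingKeyError(f)
        parts.append(f)
        parts.append(data[f])
    return _UNIT_SEP.join(parts)


def compute_record_id(key_spec: KeySpec, data: dict[str, str]) -> str:
    """SHA-256 hex digest of the canonical primary-key serialization."""
    serial = canonical_key_serialization(key_spec, data)
    return hashlib.sha256(serial.encode("utf-8")).hexdigest()


class RecordStore:
    """In-memory versioned store; one list of versions per record id.

    Versions are totally ordered by ``(version_ts, seq)`` where ``seq`` is a
    store-wide monotone counter.  Out-of-order writes (``ts`` strictly before
    the record's latest version) are rejected rather than reordered.
    """

    def __init__(self):
        self._versions: dict[str, list[StoredRecord]] = {}
        self._domains: dict[str, set[str]] = {}
        self._seq = 0

    # -- writes ------------------------------------------------------------

    def put_versioned(self, record: StoredRecord, dedup: bool = True) -> StoredRecord | None:
        """Append a new version; with ``dedup`` skip if identical to the
        latest live version.  Returns the version written, or ``None`` when
        skipped."""
        if record.version_ts < 0:
            raise ValueError("version_ts must be >= 0")
        chain = self._versions.get(record.record_id)
        if chain:
            latest = chain[-1]
            if record.version_ts < latest.version_ts:
                raise OutOfOrderWriteError(
                    f"write at ts={record.version_ts} precedes latest "
                    f"ts={latest.version_ts} for record {record.record_id[:12]}"
                )
            if dedup and not latest.deleted and latest.data == record.data and not record.deleted:
                return None
        self._seq += 1
        stored = replace(record, seq=self._seq)
        self._versions.setdefault(record.record_id, []).append(stored)
        self._domains.setdefault(record.domain, set()).add(record.record_id)
        return stored

    def set_deleted(self, record_id: str, ts: int, deleted: bool,
                    ingest_job_id: str = "") -> StoredRecord:
        """Write a new version flipping the soft-delete flag (restore =
        ``deleted=False``); the prior versions are untouched."""
        chain = self._versions.get(record_id)
        if not chain:
            raise NotFoundError(f"unknown record_id {record_id!r}")
        latest = chain[-1]
        candidate = replace(latest, version_ts=ts, deleted=deleted,
                            ingest_job_id=ingest_job_id or latest.ingest_job_id)
        written = self.put_versioned(candidate, dedup=False)
        assert written is not None
        return written

    # -- reads -------------------------------------------------------------

    def latest_version(self, record_id: str) -> StoredRecord | None:
        chain = self._versions.get(record_id)
        return chain[-1] if chain else None

    def version_count(self, record_id: str) -> int:
        return len(self._versions.get(record_id, ()))

    def versions(self, record_id: str) -> list[StoredRecord]:
        return list(self._versions.get(record_id, ()))

    def query_asof(self, domain: str, t: int,
                   include_deleted: bool = False) -> list[StoredRecord]:
        """State of a domain at time ``t``: for each record with any version
        at ``ts <= t``, its latest such version; deleted records omitted
        unless ``include_deleted``.  Unknown domain yields an empty list."""
        out = []
        for rid in self._domains.get(domain, ()):
            visible = [v for v in self._versions[rid] if v.version_ts <= t]
            if not visible:
                continue
            latest = visible[-1]  # chains are append-ordered by (ts, seq)
            if latest.deleted and not include_deleted:
                continue
            out.append(latest)
        out.sort(key=lambda r: r.seq)
        return out

    def domains(self) -> list[str]:
        return sorted(self._domains)

    def record_ids(self, domain: str) -> set[str]:
        return set(self._domains.get(domain, ()))

    def max_ts(self) -> int:
        return max((c[-1].version_ts for c in self._versions.values()), default=0)

    # -- persistence -------------------------------------------------------

    def dump_jsonl(self, sink: IO[str]) -> int:
        """Write every version, in write order, as JSON Lines."""
        all_versions = sorted(
            (v for chain in self._versions.values() for v in chain),
            key=lambda r: r.seq,
        )
        for v in all_versions:
            sink.write(json.dumps(v.to_json_obj(), sort_keys=True) + "\n")
        return len(all_versions)

    @classmethod
    def load_jsonl(cls, source: IO[str] | Iterable[str]) -> "RecordStore":
        store = cls()
        for line in source:
            line = line.strip()
            if not line:
                continue
            store.put_versioned(StoredRecord.from_json_obj(json.loads(line)), dedup=False)
        return store

    def __iter__(self) -> Iterator[StoredRecord]:
        for chain in self._versions.values():
            yield from chain
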