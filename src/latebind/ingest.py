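"""File ingestion: turn incoming CSV and ODM-style XML into stored records.

The only transformation performed at ingest time is structural: CSV rows are
taken verbatim; hierarchical ODM ``ClinicalData`` trees are flattened so that
each ItemGroup instance becomes one flat record (the context attributes —
study, subject, event, form, item group and any repeat keys — travel with the
item values).  ODM is transactional: later files may update, remove or
restore records introduced by earlier files, and fragments of one ItemGroup
split across the stream are assembled before persisting.  All semantic
standardization is deferred to the mapping engine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO
from xml.etree import ElementTree

from .errors import MissingKeyError, TransactionTargetError
from .store import KeySpec, RecordStore, StoredRecord, compute_record_id

#: ODM context attributes promoted into every flattened record, in order.
#: Repeat keys are included only when present on the source element.
ODM_CONTEXT_FIELDS = (
    "StudyOID",
    "MetaDataVersionOID",
    "SubjectKey",
    "LocationOID",
    "StudyEventOID",
    "StudyEventRepeatKey",
    "FormOID",
    "FormRepeatKey",
    "ItemGroupOID",
    "ItemGroupRepeatKey",
)

#: Default ODM primary key: the full context tuple (absent repeat keys
#: contribute empty strings to the key but are not stored as data fields).
ODM_DEFAULT_KEY_FIELDS = ODM_CONTEXT_FIELDS


@dataclass
class IngestJob:
    """Bookkeeping for one ingestion run."""

    job_id: str
    source: str
    format: str
    domain: str | None = None
    inserted: int = 0
    updated: int = 0
    deleted: int = 0
    skipped: int = 0
    errors: list[str] = field(default_factory=list)

    @property
    def processed(self) -> int:
        return self.inserted + self.updated + self.deleted + self.skipped


@dataclass
class OdmFragment:
    """Partially assembled ItemGroup instance within one streamed file."""

    group_key: tuple[str, ...]
    context: dict[str, str]
    items: dict[str, str]
    transaction: str  # insert | update | remove | upsert
    order: int


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


class Ingestor:
    """Applies file ingestion against a :class:`RecordStore`."""

    def __init__(self, store: RecordStore, study_id: str = ""):
        self.store = store
        self.study_id = study_id
        self._job_counter = 0

    def _new_job(self, source: str, fmt: str, domain: str | None = None) -> IngestJob:
        self._job_counter += 1
        return IngestJob(job_id=f"job-{self._job_counter:04d}", source=source,
                         format=fmt, domain=domain)

    # -- CSV ---------------------------------------------------------------

    def ingest_csv(self, stream: IO[str], domain: str, key_spec: KeySpec,
                   ts: int, dedup: bool = True, source: str = "<csv>") -> IngestJob:
        """One stored record per data row; header cells become field names and
        cell values are kept verbatim as strings.  Rows with the wrong arity
        are skipped (the job continues); a missing key field aborts the job."""
        job = self._new_job(source, "csv" if dedup else "bulk_csv", domain)
        reader = csv.reader(stream)
        try:
            header = next(reader)
        except StopIteration:
            job.errors.append("empty file: no header row")
            return job
        missing = [k for k in key_spec.key_fields if k not in header]
        if missing:
            raise MissingKeyError(missing[0])
        for row in reader:
            if not row:
                continue
            if len(row) != len(header):
                job.skipped += 1
                job.errors.append(f"row shape mismatch: expected {len(header)} cells, got {len(row)}")
                continue
            data = dict(zip(header, row))
            rid = compute_record_id(key_spec, data)
            prior = self.store.latest_version(rid)
            written = self.store.put_versioned(
                StoredRecord(study_id=self.study_id, domain=domain, record_id=rid,
                             version_ts=ts, data=data, ingest_job_id=job.job_id),
                dedup=dedup,
            )
            if written is None:
                job.skipped += 1
            elif prior is None:
                job.inserted += 1
            else:
                job.updated += 1
        return job

    def bulk_load_csv(self, stream: IO[str], domain: str, key_spec: KeySpec,
                      ts: int, source: str = "<bulk_csv>") -> IngestJob:
        """Fast path without dedup: every row always writes a new version, so
        loading the same file N times yields N versions per record."""
        return self.ingest_csv(stream, domain, key_spec, ts, dedup=False, source=source)

    # -- ODM ---------------------------------------------------------------

    def ingest_odm(self, stream: IO[str] | str, ts: int,
                   key_specs: dict[str, KeySpec] | None = None,
                   source: str = "<odm>") -> IngestJob:
        """Flatten a ClinicalData tree into ItemGroup records and apply their
        transaction semantics against the store.

        ``key_specs`` optionally overrides the primary key per domain
        (ItemGroupOID); the default key is the full context tuple.
        """
        job = self._new_job(source, "odm")
        fragments = self._collect_fragments(stream)
        for frag in fragments:
            domain = frag.context["ItemGroupOID"]
            spec = (key_specs or {}).get(domain) or KeySpec(domain, ODM_DEFAULT_KEY_FIELDS)
            key_source = {f: frag.context.get(f, "") for f in ODM_CONTEXT_FIELDS}
            key_source.update(frag.items)
            # data stored = context fields actually present + item values
            data = {k: v for k, v in frag.context.items() if v != "" or k not in
                    ("StudyEventRepeatKey", "FormRepeatKey", "ItemGroupRepeatKey")}
            data.update(frag.items)
            rid = compute_record_id(spec, key_source)
            self._apply_transaction(job, domain, rid, data, frag.transaction, ts)
        return job

    def _apply_transaction(self, job: IngestJob, domain: str, rid: str,
                           data: dict[str, str], txn: str, ts: int) -> None:
        prior = self.store.latest_version(rid)
        if txn == "remove":
            if prior is None:
                job.errors.append(f"remove of unseen record {rid[:12]}")
                job.skipped += 1
                return
            self.store.set_deleted(rid, ts, True, ingest_job_id=job.job_id)
            job.deleted += 1
            return
        if txn == "update" and prior is None:
            job.errors.append(f"update of unseen record {rid[:12]}")
            job.skipped += 1
            return
        if txn in ("update", "upsert") and prior is not None:
            # merge incoming fields into the latest version's data
            merged = dict(prior.data)
            merged.update(data)
            data = merged
        written = self.store.put_versioned(
            StoredRecord(study_id=self.study_id, domain=domain, record_id=rid,
                         version_ts=ts, data=data, ingest_job_id=job.job_id),
            dedup=True,
        )
        if written is None:
            job.skipped += 1
        elif prior is None:
            job.inserted += 1
        else:
            job.updated += 1

    def _collect_fragments(self, stream: IO[str] | str) -> list[OdmFragment]:
        if isinstance(stream, str):
            root = ElementTree.fromstring(stream)
        else:
            root = ElementTree.parse(stream).getroot()
        frags: list[OdmFragment] = []
        last_by_key: dict[tuple, OdmFragment] = {}
        order = 0
        clinical_blocks = ([root] if _strip_ns(root.tag) == "ClinicalData"
                           else [el for el in root.iter() if _strip_ns(el.tag) == "ClinicalData"])
        for cd in clinical_blocks:
            study_oid = cd.get("StudyOID", "")
            mdv_oid = cd.get("MetaDataVersionOID", "")
            for subj in (el for el in cd if _strip_ns(el.tag) == "SubjectData"):
                subj_txn = subj.get("TransactionType")
                location = ""
                for child in subj:
                    if _strip_ns(child.tag) == "SiteRef":
                        location = child.get("LocationOID", "")
                for sev in (el for el in subj if _strip_ns(el.tag) == "StudyEventData"):
                    sev_txn = sev.get("TransactionType") or subj_txn
                    for form in (el for el in sev if _strip_ns(el.tag) == "FormData"):
                        form_txn = form.get("TransactionType") or sev_txn
                        for igd in (el for el in form if _strip_ns(el.tag) == "ItemGroupData"):
                            txn = (igd.get("TransactionType") or form_txn or "upsert").lower()
                            context = {
                                "StudyOID": study_oid,
                                "MetaDataVersionOID": mdv_oid,
                                "SubjectKey": subj.get("SubjectKey", ""),
                                "LocationOID": location,
                                "StudyEventOID": sev.get("StudyEventOID", ""),
                                "StudyEventRepeatKey": sev.get("StudyEventRepeatKey", ""),
                                "FormOID": form.get("FormOID", ""),
                                "FormRepeatKey": form.get("FormRepeatKey", ""),
                                "ItemGroupOID": igd.get("ItemGroupOID", ""),
                                "ItemGroupRepeatKey": igd.get("ItemGroupRepeatKey", ""),
                            }
                            items = {
                                item.get("ItemOID", ""): item.get("Value", "")
                                for item in igd if _strip_ns(item.tag) == "ItemData"
                            }
                            gkey = tuple(context[f] for f in ODM_CONTEXT_FIELDS)
                            prev = last_by_key.get(gkey)
                            if prev is not None and prev.transaction == txn:
                                # fragment assembly: pieces of one ItemGroup
                                # split across the file are merged
                                prev.items.update(items)
                            else:
                                order += 1
                                frag = OdmFragment(group_key=gkey, context=context,
                                                   items=items, transaction=txn,
                                                   order=order)
                                frags.append(frag)
                                last_by_key[gkey] = frag
        return frags
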