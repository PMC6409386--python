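"""Synthetic inputs for demonstration and testing.

Three generators, all fully deterministic under their seeds:

* :func:`worked_example` — a two-file micro-study (a central-lab CSV with
  AST/ALT results and an ODM file with demographics and a visit date) plus
  the standardization pipelines that map it into SDTM-style LB/DM/SV views,
  together with the exact raw envelopes and mapped rows the pipeline must
  produce.
* :func:`synth_trial` — randomized multi-file ODM histories (inserts,
  field-level updates, removes, restores) with generator-side bookkeeping of
  the logical state after every file, for time-travel replay testing.
* :func:`synth_lab_panel` — labeled analyte reference panels with replicate
  query columns under non-informative codes, for mapping-suggestion recall
  testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .ingest import ODM_CONTEXT_FIELDS
from .mapping import MapStep, OutputDomain
from .ml import ColumnProfile, ReferencePanel
from .store import KeySpec, compute_record_id

if TYPE_CHECKING:
    from .query import Warehouse

# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------

WORKED_LAB_CSV = """\
subject,site,visit,testcd,value,dat
0001,1,1,AST,5,10/07/2017
0001,1,1,ALT,6,10/07/2017
"""

WORKED_ODM_XML = """\
<ODM FileOID="worked-example" FileType="Transactional">
  <ClinicalData StudyOID="MyStudy" MetaDataVersionOID="1">
    <SubjectData SubjectKey="1">
      <SiteRef LocationOID="1"/>
      <StudyEventData StudyEventOID="V1">
        <FormData FormOID="DM">
          <ItemGroupData ItemGroupOID="DM" TransactionType="Insert">
            <ItemData ItemOID="SEX" Value="M"/>
            <ItemData ItemOID="AGE" Value="31"/>
          </ItemGroupData>
        </FormData>
        <FormData FormOID="SV">
          <ItemGroupData ItemGroupOID="SV" TransactionType="Insert">
            <ItemData ItemOID="VISITDATE" Value="2017-10-05"/>
          </ItemGroupData>
        </FormData>
      </StudyEventData>
    </SubjectData>
  </ClinicalData>
</ODM>
"""

WORKED_LB_KEY = KeySpec("LB", ("subject", "site", "visit", "testcd"))

#: Raw record envelopes ingestion must produce, keyed by input domain.
WORKED_EXPECTED_RAW = {
    "LB": [
        {"subject": "0001", "site": "1", "visit": "1",
         "testcd": "AST", "value": "5", "dat": "10/07/2017"},
        {"subject": "0001", "site": "1", "visit": "1",
         "testcd": "ALT", "value": "6", "dat": "10/07/2017"},
    ],
    "DM": [
        {"StudyOID": "MyStudy", "MetaDataVersionOID": "1", "SubjectKey": "1",
         "LocationOID": "1", "StudyEventOID": "V1", "FormOID": "DM",
         "ItemGroupOID": "DM", "SEX": "M", "AGE": "31"},
    ],
    "SV": [
        {"StudyOID": "MyStudy", "MetaDataVersionOID": "1", "SubjectKey": "1",
         "LocationOID": "1", "StudyEventOID": "V1", "FormOID": "SV",
         "ItemGroupOID": "SV", "VISITDATE": "2017-10-05"},
    ],
}

#: Fully mapped rows the pipelines must produce, keyed by output domain.
WORKED_EXPECTED_MAPPED = {
    "LB": [
        {"STUDYID": "MyStudy", "DOMAIN": "LB", "SUBJID": "1", "SITEID": "1",
         "VISITNUM": "1", "TESTCD": "AST", "ORRES": "5",
         "DTC": "2017-10-07", "DY": "3"},
        {"STUDYID": "MyStudy", "DOMAIN": "LB", "SUBJID": "1", "SITEID": "1",
         "VISITNUM": "1", "TESTCD": "ALT", "ORRES": "6",
         "DTC": "2017-10-07", "DY": "3"},
    ],
    "DM": [
        {"STUDYID": "MyStudy", "DOMAIN": "DM", "SUBJID": "1", "SITEID": "1",
         "VISITNUM": "1", "SEX": "M", "AGE": "31", "RFSTDTC": "2017-10-05"},
    ],
    "SV": [
        {"STUDYID": "MyStudy", "DOMAIN": "SV", "SUBJID": "1", "SITEID": "1",
         "VISITNUM": "1", "DTC": "2017-10-05"},
    ],
}


def _fn(function: str, **args) -> MapStep:
    return MapStep("functional", {"function": function, "args": args})


def _rename(src: str, dst: str) -> MapStep:
    return MapStep("rename", {"src": src, "dst": dst})


def _join_sv_visitdate(out_col: str) -> MapStep:
    # pull the visit date out of raw SV via the reconciled subject id
    return MapStep("join", {
        "selectedDomain": "SV",
        "joinCols": ["SubjectKey"],
        "colNameTranslations": {"SubjectKey": "SUBJID"},
        "selectedColumn": ["VISITDATE"],
        "outputColumn": [out_col],
    })


def worked_example_pipelines() -> list[OutputDomain]:
    """The standardization pipelines of the worked example: SDTM renames,
    STUDYID addition, the SV.VISITDATE joins, ISO date conversion and the
    study-day derivation."""
    lb = OutputDomain("LB", "LB", [
        _fn("set_constant", column="STUDYID", value="MyStudy"),
        _fn("set_constant", column="DOMAIN", value="LB"),
        _rename("subject", "SUBJID"),
        _fn("strip_leading_zeros", column="SUBJID"),
        _rename("site", "SITEID"),
        _rename("visit", "VISITNUM"),
        _rename("testcd", "TESTCD"),
        _rename("value", "ORRES"),
        _rename("dat", "DTC"),
        _fn("iso_date", column="DTC"),
        _join_sv_visitdate("RFSTDTC"),
        _fn("study_day", ref_column="RFSTDTC", date_column="DTC", output="DY"),
        _fn("select_columns", columns=["STUDYID", "DOMAIN", "SUBJID", "SITEID",
                                       "VISITNUM", "TESTCD", "ORRES", "DTC", "DY"]),
    ])
    # shared ODM context standardization, reused by DM and SV (nested list)
    odm_meta = [
        _rename("StudyOID", "STUDYID"),
        _rename("SubjectKey", "SUBJID"),
        _rename("LocationOID", "SITEID"),
        _rename("StudyEventOID", "VISITNUM"),
        _fn("strip_prefix", column="VISITNUM", prefix="V"),
    ]
    dm = OutputDomain("DM", "DM", [
        odm_meta,
        _fn("set_constant", column="DOMAIN", value="DM"),
        _join_sv_visitdate("RFSTDTC"),
        _fn("select_columns", columns=["STUDYID", "DOMAIN", "SUBJID", "SITEID",
                                       "VISITNUM", "SEX", "AGE", "RFSTDTC"]),
    ])
    sv = OutputDomain("SV", "SV", [
        odm_meta,
        _fn("set_constant", column="DOMAIN", value="SV"),
        _rename("VISITDATE", "DTC"),
        _fn("iso_date", column="DTC"),
        _fn("select_columns", columns=["STUDYID", "DOMAIN", "SUBJID", "SITEID",
                                       "VISITNUM", "DTC"]),
    ])
    return [lb, dm, sv]


@dataclass(frozen=True)
class WorkedExample:
    lab_csv: str
    odm_xml: str
    lb_key_spec: KeySpec
    pipelines: list[OutputDomain]
    expected_raw: dict[str, list[dict]]
    expected_mapped: dict[str, list[dict]]


def worked_example() -> WorkedExample:
    return WorkedExample(
        lab_csv=WORKED_LAB_CSV,
        odm_xml=WORKED_ODM_XML,
        lb_key_spec=WORKED_LB_KEY,
        pipelines=worked_example_pipelines(),
        expected_raw={k: [dict(r) for r in v] for k, v in WORKED_EXPECTED_RAW.items()},
        expected_mapped={k: [dict(r) for r in v] for k, v in WORKED_EXPECTED_MAPPED.items()},
    )


def load_worked_example(warehouse: "Warehouse", data_ts: int = 1000,
                        map_ts: int = 1000) -> WorkedExample:
    """Ingest the worked-example files and register its pipelines."""
    import io

    ex = worked_example()
    warehouse.ingestor.ingest_csv(io.StringIO(ex.lab_csv), "LB",
                                  ex.lb_key_spec, ts=data_ts)
    warehouse.ingestor.ingest_odm(ex.odm_xml, ts=data_ts)
    for pipeline in ex.pipelines:
        warehouse.define_output_domain(pipeline, t=map_ts)
    return ex


# ---------------------------------------------------------------------------
# Randomized trial histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSimConfig:
    """Shape of a simulated transactional EDC feed."""

    n_subjects: int = 10
    n_visits: int = 4
    domains: dict = field(default_factory=lambda: {"VS": ("HR", "SBP")})
    n_files: int = 5
    update_rate: float = 0.25
    delete_rate: float = 0.10
    restore_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name, rate in (("update_rate", self.update_rate),
                           ("delete_rate", self.delete_rate),
                           ("restore_rate", self.restore_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class TrialEvent:
    """One logical transaction in the generated history."""

    ts: int
    op: str  # insert | update | remove | upsert
    domain: str
    context: dict[str, str]
    items: dict[str, str]


@dataclass
class SynthTrial:
    files: list[tuple[int, str]]          # (timestamp, ODM XML text)
    events: list[TrialEvent]
    states_after_file: list[dict]         # record_id -> (data, deleted)
    key_spec_fields: tuple[str, ...]

    @property
    def final_state(self) -> dict:
        return self.states_after_file[-1] if self.states_after_file else {}


def _record_context(domain: str, subject: int, visit: int) -> dict[str, str]:
    return {
        "StudyOID": "SIM",
        "MetaDataVersionOID": "1",
        "SubjectKey": f"S{subject:03d}",
        "LocationOID": str(1 + subject % 3),
        "StudyEventOID": f"V{visit}",
        "FormOID": domain,
        "ItemGroupOID": domain,
    }


def _render_odm(events: list[TrialEvent]) -> str:
    # minimal transactional ClinicalData rendering of a batch of events
    lines = ['<ODM FileType="Transactional">',
             '  <ClinicalData StudyOID="SIM" MetaDataVersionOID="1">']
    for ev in events:
        c = ev.context
        lines.append(f'    <SubjectData SubjectKey="{c["SubjectKey"]}">')
        lines.append(f'      <SiteRef LocationOID="{c["LocationOID"]}"/>')
        lines.append(f'      <StudyEventData StudyEventOID="{c["StudyEventOID"]}">')
        lines.append(f'        <FormData FormOID="{c["FormOID"]}">')
        lines.append(f'          <ItemGroupData ItemGroupOID="{c["ItemGroupOID"]}" '
                     f'TransactionType="{ev.op.capitalize()}">')
        for oid, value in ev.items.items():
            lines.append(f'            <ItemData ItemOID="{oid}" Value="{value}"/>')
        lines.append('          </ItemGroupData>')
        lines.append('        </FormData>')
        lines.append('      </StudyEventData>')
        lines.append('    </SubjectData>')
    lines.append('  </ClinicalData>')
    lines.append('</ODM>')
    return "\n".join(lines) + "\n"


def synth_trial(config: TrialSimConfig) -> SynthTrial:
    """Generate a seeded sequence of transactional ODM files plus the exact
    logical state after each file (the generator's own bookkeeping serves as
    the oracle for replay tests)."""
    rng = np.random.default_rng(config.seed)
    universe = [(dom, s, v)
                for dom in config.domains
                for s in range(config.n_subjects)
                for v in range(1, config.n_visits + 1)]
    per_file = max(1, len(universe) // max(1, config.n_files))

    def fresh_items(domain: str) -> dict[str, str]:
        return {f: str(int(rng.integers(40, 200)))
                for f in config.domains[domain]}

    truth: dict[tuple, dict] = {}  # universe key -> {"data":…, "deleted":…}
    events: list[TrialEvent] = []
    files: list[tuple[int, str]] = []
    states: list[dict] = []
    next_insert = 0

    for file_idx in range(config.n_files):
        ts = (file_idx + 1) * 1000
        batch: list[TrialEvent] = []

        def emit(op: str, ukey: tuple, items: dict[str, str]):
            dom, s, v = ukey
            ev = TrialEvent(ts=ts, op=op, domain=dom,
                            context=_record_context(dom, s, v), items=items)
            batch.append(ev)
            events.append(ev)

        # inserts: next slice of the universe
        for ukey in universe[next_insert:next_insert + per_file]:
            items = fresh_items(ukey[0])
            emit("insert", ukey, items)
            truth[ukey] = {"data": dict(items), "deleted": False}
        next_insert += per_file

        existing = sorted(truth)
        for ukey in existing:
            state = truth[ukey]
            if not state["deleted"]:
                if rng.random() < config.update_rate:
                    changed_field = config.domains[ukey[0]][
                        int(rng.integers(len(config.domains[ukey[0]])))]
                    items = {changed_field: str(int(rng.integers(40, 200)))}
                    emit("update", ukey, items)
                    state["data"].update(items)
                if not state["deleted"] and rng.random() < config.delete_rate:
                    emit("remove", ukey, {})
                    state["deleted"] = True
            elif rng.random() < config.restore_rate:
                items = dict(state["data"])
                emit("upsert", ukey, items)
                state["deleted"] = False

        files.append((ts, _render_odm(batch)))
        states.append({
            _ukey_record_id(ukey): (
                {**{k: val for k, val in _record_context(*ukey[:1], ukey[1], ukey[2]).items()},
                 **st["data"]},
                st["deleted"])
            for ukey, st in truth.items()
        })
    return SynthTrial(files=files, events=events, states_after_file=states,
                      key_spec_fields=ODM_CONTEXT_FIELDS)


def _ukey_record_id(ukey: tuple) -> str:
    dom, s, v = ukey
    context = _record_context(dom, s, v)
    key_source = {f: context.get(f, "") for f in ODM_CONTEXT_FIELDS}
    return compute_record_id(KeySpec(dom, ODM_CONTEXT_FIELDS), key_source)


# ---------------------------------------------------------------------------
# Labeled analyte panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalytePanelConfig:
    """Shape of a synthetic lab-analyte panel.

    Analytes are given non-informative codes (mirroring real central-lab
    feeds) and well-separated location/scale by default; ``separation``
    scales the spacing of analyte means in units of their within-analyte
    standard deviation.
    """

    n_analytes: int = 20
    n_samples: int = 30
    replicates: int = 5
    separation: float = 8.0
    base_sd: float = 1.0
    skew_knob: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_analytes < 2:
            raise ValueError("n_analytes must be >= 2")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")


def _draw_sample(rng: np.random.Generator, mean: float, sd: float,
                 skew_knob: float, n: int) -> np.ndarray:
    if skew_knob == 0.0:
        return rng.normal(mean, sd, size=n)
    # simple location-shifted exponential mixture for skewed analytes
    base = rng.normal(0.0, sd, size=n)
    tail = rng.exponential(sd * abs(skew_knob), size=n) * np.sign(skew_knob)
    return mean + base + tail


def synth_lab_panel(config: AnalytePanelConfig,
                    ) -> tuple[ReferencePanel, list[tuple[str, ColumnProfile]]]:
    """Reference sample per analyte plus labeled replicate query columns
    drawn from the same distributions (labels retained for recall scoring)."""
    rng = np.random.default_rng(config.seed)
    entries = []
    queries: list[tuple[str, ColumnProfile]] = []
    for i in range(config.n_analytes):
        code = f"LAB{i:04d}"
        mean = config.separation * config.base_sd * i
        sd = config.base_sd * (1.0 + 0.05 * i)
        ref = _draw_sample(rng, mean, sd, config.skew_knob, config.n_samples)
        entries.append((code, ref))
        for r in range(config.replicates):
            sample = _draw_sample(rng, mean, sd, config.skew_knob,
                                  config.n_samples)
            values = [repr(float(v)) for v in sample]
            if config.missing_rate > 0.0:
                mask = rng.random(len(values)) < config.missing_rate
                values = ["" if m else v for v, m in zip(values, mask)]
            profile = ColumnProfile(field_name=f"Q{i * config.replicates + r:05d}",
                                    values=values)
            queries.append((code, profile))
    return ReferencePanel(entries=entries), queries
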