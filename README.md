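# latebind

An embeddable **late-binding (ELT) clinical data warehouse** for trial
informatics: raw clinical data — central-lab CSV extracts, transactional
CDISC-ODM-style EDC feeds — is loaded nearly verbatim into a versioned
record store, and *all* standardization (SDTM-style renames, code lists,
pivots, relational joins, derived variables, blinding) is applied at query
time by independently versioned transformation pipelines.  A statistical
k-nearest-neighbor assistant suggests mappings for columns that arrive
under non-informative codes.

It is intended for data managers, trial programmers and informatics
engineers who need to stand up standardized views of in-flight trial data
while the mapping specifications are still evolving — and to reproduce any
past view exactly.

## Why late binding

Conventional ETL bakes the mapping into the load, so every specification
change forces revalidation and re-materialization.  Here the raw data is
the only persisted copy.  Each write creates an immutable, timestamped
version (deletes are soft), and each map edit closes the old version's
validity interval and opens a new one.  A query therefore takes two
independent clocks:

```
rows = warehouse.get_mapped_domain(QuerySpec(
    output_domain="LB", data_as_of=t_data, maps_as_of=t_maps))
```

and any combination — historical maps on current data, current maps on
historical data — is valid and byte-reproducible, which is what a
regulatory request to reproduce a prior report requires.

Derived variables work across feeds: the study day
`DY = days(RFSTDTC → observation) + 1` (no day zero) needs the reference
start date from the visit feed joined into the lab feed, which the join
step performs at query time — no pre-joining at load.

For unlabeled columns, the suggester builds a feature vector per column
(mean, SD, skewness, kurtosis; Welch *t*, *F* ratio, Kolmogorov–Smirnov
statistic and IQR ratio against every entry of a curated reference panel;
Bloom-filtered tokens of names/values) and ranks candidate codes by a
standardized KNN distance, returning the top *k* so a human picks among
likely alternatives.

## Worked example

The bundled micro-study has a lab CSV (`subject 0001`, AST/ALT at visit 1)
and an ODM file (demographics SEX/AGE plus the visit date).  End to end
from the shell:

```console
$ latebind fixtures worked-example --out fx
$ latebind --workspace ws ingest fx/lab.csv --format csv --domain LB \
      --keys subject,site,visit,testcd --ts 1000
{"job_id": "job-0001", "inserted": 2, "updated": 0, "deleted": 0, "skipped": 0, "errors": []}
$ latebind --workspace ws ingest fx/dm_sv.xml --format odm --ts 1000
{"job_id": "job-0001", "inserted": 2, "updated": 0, "deleted": 0, "skipped": 0, "errors": []}
$ for d in LB DM SV; do latebind --workspace ws map add fx/map_$d.json --ts 1000; done
$ latebind --workspace ws query --domain LB --format jsonl
{"STUDYID": "MyStudy", "DOMAIN": "LB", "SUBJID": "1", "SITEID": "1", "VISITNUM": "1", "TESTCD": "AST", "ORRES": "5", "DTC": "2017-10-07", "DY": "3"}
{"STUDYID": "MyStudy", "DOMAIN": "LB", "SUBJID": "1", "SITEID": "1", "VISITNUM": "1", "TESTCD": "ALT", "ORRES": "6", "DTC": "2017-10-07", "DY": "3"}
$ latebind --workspace ws query --domain DM --format jsonl
{"STUDYID": "MyStudy", "DOMAIN": "DM", "SUBJID": "1", "SITEID": "1", "VISITNUM": "1", "SEX": "M", "AGE": "31", "RFSTDTC": "2017-10-05"}
```

Reading the output: the four raw records were stored verbatim (the lab date
as `10/07/2017`, subject as `0001`); the pipelines renamed fields to SDTM
names, reconciled identifiers (`0001` → `1`), converted the date to ISO
(`2017-10-07`), joined the visit date out of the SV feed into DM as
`RFSTDTC = 2017-10-05`, and derived the study day
`DY = (2017-10-07 − 2017-10-05) + 1 = 3` in both lab rows.  The raw store
is unchanged by any number of such queries.

The same flow in Python:

```python
from latebind import Warehouse, QuerySpec
from latebind.fixtures import load_worked_example

wh = Warehouse()
load_worked_example(wh)
wh.get_mapped_domain(QuerySpec(output_domain="LB"))
# [{'STUDYID': 'MyStudy', 'DOMAIN': 'LB', ..., 'DTC': '2017-10-07', 'DY': '3'}, ...]
```

## Library layout

| module               | contents |
|----------------------|----------|
| `latebind.store`     | versioned record store, SHA-256 record identity, as-of queries, JSONL dump/load |
| `latebind.ingest`    | CSV rows, ODM flattening + transactional insert/update/remove/upsert, bulk path |
| `latebind.mapping`   | the eight map-step kinds, pipeline runner, versioned map registry |
| `latebind.filters`   | the row-filter predicate mini-grammar |
| `latebind.functions` | registered row transforms (dates, study day, blinding, …), user context |
| `latebind.query`     | `Warehouse`, `QuerySpec`, CSV/JSONL export |
| `latebind.ml`        | column featurization, Bloom filters, KNN suggestions |
| `latebind.fixtures`  | worked micro-study, randomized trial histories, analyte panels |
| `latebind.cli`       | the `latebind` command (`ingest`, `map`, `query`, `suggest`, `fixtures`) |

Design notes, parameter defaults and known limitations are in
[`docs/methods.md`](docs/methods.md).

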