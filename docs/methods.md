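# Methods

## The late-binding model

`latebind` implements an extract–load–transform (ELT) warehouse for clinical
trial data as an embeddable library.  The defining commitment is *late
binding*: raw data is persisted nearly verbatim at load time, and every
standardization step — renames, code lists, pivots, joins, derived
variables, blinding — is applied at query time by transformation pipelines
that are versioned independently of the data.  Two consequences follow:

1. A single raw copy serves any number of output representations, and a
   mapping change never requires re-materializing data.
2. Because raw record versions and map versions are both immutable and
   timestamped, any query is parameterized by two independent clocks —
   `data_as_of` and `maps_as_of` — and any past report is exactly
   reproducible: historical maps against current data, current maps against
   historical data, or both pinned.

The storage contract mirrors a column-store's (row key, column, timestamp)
versioning semantics without reproducing a distributed engine: the store is
a single-node, in-memory structure with JSON-Lines dump/load.  Correctness,
not throughput, is the target.

## Record model and identity

A stored record is a flat map of field name → string value plus metadata
(study, input domain, record id, version timestamp, soft-delete flag, ingest
job id).  Values are kept verbatim as strings; typed interpretation is
deferred to maps.  The record id is a SHA-256 digest of a canonical
serialization of `(domain, key field names, key values)` joined by the
non-printable unit separator (U+001F), which makes the serialization
delimiter-safe for values containing commas, pipes or whitespace and makes
the digest reproducible by any independent implementation.

Versions of one record are totally ordered by `(timestamp, store-wide write
sequence)`; the sequence breaks ties among writes sharing a timestamp (one
ingested file is given a single timestamp).  Writes carrying a timestamp
earlier than a record's latest version are rejected rather than silently
reordered: rejection keeps the as-of semantics equivalent to a simple replay
of the write history, which is also how the tests verify it.  Deletes are
soft — a new version with the flag set — so deletion is as reversible and as
queryable as any other change.  All versions are retained indefinitely.

Deduplicating ingest skips a write only when the incoming data equals the
*latest live* version; re-ingesting data identical to a soft-deleted
version therefore restores the record, which matches the intuition that a
file re-delivery reasserts the record's existence.  The bulk loader skips
the comparison entirely: loading the same file N times yields N versions.

## Ingestion

CSV rows become records directly (header cells as field names, cell values
verbatim, RFC-4180 dialect, whitespace preserved).  ODM-style XML is
flattened: each ItemGroup instance is one record, carrying its context
attributes (StudyOID, MetaDataVersionOID, SubjectKey, LocationOID,
StudyEventOID, FormOID, ItemGroupOID and any repeat keys) alongside its
ItemData values.  Fragments of one ItemGroup split across a streamed file
are assembled before persisting, provided they share the full context tuple
and transaction type.

ODM is transactional.  `Insert` and `Upsert` write (or merge into) records;
`Update` merges incoming fields into the latest version's data and writes a
new version; `Remove` soft-deletes.  A missing TransactionType is treated as
upsert, the common practice for incremental EDC feeds.  Updates or removes
that reference a record never seen are counted and reported on the job but
do not abort it.  The default ODM primary key is the full context tuple;
absent repeat keys contribute empty strings to the key but are not stored as
data fields, keeping stored envelopes minimal.  Per-domain key overrides are
available for feeds with explicit subject/visit keys.

## The transformation algebra

Eight step kinds: `rename`, `copy`, `filter`, `functional`, `dict`,
`pivot`, `depivot`, `join`.  Steps are validated at map creation (including
filter-predicate parsing — a syntax error can never surface per-row) and
executed in order; nested lists of steps flatten depth-first so reusable
groups can be spliced into several pipelines.

* **Filters** use a small predicate grammar (`r.FIELD`, literals, `null`,
  `== != < <= > >=`, `&& || !`, parentheses).  A missing field is `null`;
  two operands that both parse as numbers compare numerically, otherwise
  lexically; ordering comparisons against `null` are false.
* **Functional transforms** are host-language callables registered by name
  and applied row-locally, with read access to the row and the user
  context.  Registering callables rather than embedding a script engine
  keeps transforms deterministic and sandboxed while preserving row-local
  expressive power.  Builtins cover ISO date conversion, trim-then-uppercase
  folding, study-day derivation, constants, prefix/zero stripping, column
  selection and blinding.  A raising function flags the row with a
  `_map_error` field and the pipeline continues: one bad row must not take
  down a whole domain at query time.
* **Study day** follows the no-day-zero convention: the reference date is
  day 1, the day after is day 2, days before the reference are negative.
* **Code lists** (`dict`) replace values by table lookup; unmapped values
  pass through with a warning, since real code lists are routinely partial.
  A strict mode is available.
* **Joins** are left joins with exact string equality on translated key
  columns.  Null keys never match.  More than one matching right-hand row
  raises by default (`first_match` downgrade available): in clinical
  standardization a fan-out join almost always indicates a bad key choice,
  and silent row multiplication is the worst failure mode.  Join targets
  resolve to raw input domains first, then to other output domains (mapped
  recursively at the same pair of as-of clocks, with cycle rejection).
* **Pivot/depivot** convert between EAV and wide layouts; a pivot collision
  (two rows sharing key tuple and attribute) raises with the offending key.

### Blinding

Blinding is a functional transform: when the querying user's role matches
the rule and the evaluation clock is before the unblinding date, the target
column is replaced by a uniform integer drawn from `[0, 3)` by default.
When the clock passes the end date the transform becomes the identity —
unblinding is automatic, with no map edit.  The replacement value is seeded
by `(record id, column, salt)` so a blinded view is stable across repeated
queries and across exports; unseeded randomness would make blinded reports
unreproducible and leak information through value churn.  Pipeline rows
carry the source record id in a reserved `_record_id` field injected by the
query layer and stripped from output; standalone use falls back to a digest
of the row itself.

### Map versioning

Every map edit closes the active version's validity interval at the edit
timestamp and opens a new version; intervals per map are disjoint and
contiguous, and retirement closes the last interval permanently.  The set
of rules active at any instant is reconstructed by interval lookup, which
the tests check against an event-replay oracle on randomized edit
sequences.

## Mapping suggestions (KNN)

Lab feeds often arrive under non-informative test codes, so the values must
carry the signal.  Each column is reduced to a feature vector:

* **moments** — sample mean, sample standard deviation (ddof=1), skewness
  m₃/m₂^1.5 and excess kurtosis m₄/m₂²−3 (biased moment estimators);
* **comparative block** — against every entry of a curated reference panel:
  Welch t statistic, variance ratio F = s²_col/s²_ref, two-sample
  Kolmogorov–Smirnov statistic, and IQR ratio (scipy implementations
  throughout);
* **text bits** — a Bloom filter (m=256 bits, k=3 hashes) over lowercased
  tokens of the field name and, for columns that are less than half
  numeric, the categorical values.  Field-name tokens can be disabled to
  reproduce the values-only configuration appropriate when names are opaque
  codes.

Degenerate statistics are imputed deterministically: fewer than two numeric
values ⇒ moments 0 and comparative entries (0, 1, 0, 1); a zero-variance
reference ⇒ F and IQR ratio set to a large finite sentinel (10⁶) unless the
column is also degenerate, in which case the ratio is 1; a 0/0 t statistic
(two identical constant samples) is 0.

Suggestions are ranked by a combined distance: Euclidean over the numeric
block standardized per-dimension over the training set, plus λ·Jaccard
distance on the Bloom bits (λ=1 default).  Ties break lexicographically by
code for determinism.  Duplicate codes collapse to their best rank; `k=5`
by default.

**Ratio-family normalization.**  The F and IQR-ratio families are scaled by
1/√P per dimension (P = panel size) inside the distance.  Unlike t and KS,
which are genuine pairwise two-sample statistics, each ratio is the query
column's own dispersion divided by a fixed per-entry constant: the family is
rank-one, so repeating it once per panel entry multiplies its perfectly
correlated sampling noise by P while adding no independent information.
The normalization keeps each ratio family's total contribution independent
of panel size.  On synthetic panels this changes top-5 recall from ~0.86 to
1.0 at the default study shape; the weight is configuration, not a tuned
constant, and the structural argument is panel-size-generic.

**Known limitation.**  Mean separation between analytes saturates the t and
KS features but cannot suppress sampling noise in the dispersion features
(sd, F, IQR, skewness, kurtosis).  With small panels, the between-entry
spread of a noise-only dimension can itself be small, and per-dimension
standardization then amplifies that dimension.  Consequently top-1 recall
approaches but is not guaranteed to reach 1 even for arbitrarily separated
analytes (top-5 recall does saturate in practice).  A metric that
standardized by sampling variance rather than between-entry spread would
remove this artifact at the cost of per-statistic variance formulas; it is
deliberately out of scope.

## Synthetic data

Three generators, all deterministic under their seeds:

* **Worked micro-study** — a two-row central-lab CSV (AST/ALT for one
  subject, one visit) and a minimal transactional ODM document carrying a
  demographics ItemGroup (SEX, AGE) and a visit-date ItemGroup, plus the
  three pipelines that standardize them into SDTM-style LB/DM/SV views.
  The expected raw envelopes and mapped rows are fixed as goldens; the lab
  date is stored in US format (`10/07/2017`) precisely so the pipeline's
  ISO conversion step is observable, and subject `0001` vs SubjectKey `1`
  exercises identifier reconciliation.
* **Trial histories** (`synth_trial`) — multi-file transactional ODM feeds
  over a subject×visit universe (defaults: 10 subjects, 4 visits, one
  vitals ItemGroup with two fields, 5 files; update rate 0.25, delete rate
  0.10, restore rate 0.5 per file).  The generator maintains its own
  bookkeeping of the logical state after every file, which serves as the
  oracle for time-travel replay tests.  Files share one timestamp per file
  (1000 ms apart), exercising the within-timestamp write-sequence ordering.
* **Analyte panels** (`synth_lab_panel`) — Gaussian analytes with means
  spaced `separation`·σ apart (default 8, i.e. clearly distinct assays such
  as sodium vs ALT), σ growing 5% per analyte, 20 analytes × 30 samples ×
  5 replicate query columns by default, optional skew and missing-data
  knobs, non-informative codes (`LAB0007`, `Q00031`).

What the generators do *not* emulate: real assays with near-identical
ranges (highly correlated lab tests are the dominant failure mode for
value-based mapping suggestions in production feeds), heavy-tailed or
unit-shifted distributions, realistic
visit schedules, medical coding dictionaries, and malformed vendor files
beyond arity errors.  Green tests on these fixtures demonstrate the
contracts of the machinery — not field performance on production trial
data.

## Problem sizes

Test and demonstration sizes are chosen to keep the whole suite in tens of
seconds: randomized-history replay uses 100 seeded histories of up to a few
hundred events; relational oracles use tables up to 1000 rows; the
suggestion study uses the default 20×30×5 panel shape.  All are set in one
place (the generator configs) and scale up by argument.
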