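# Methods

This note records the models, semantics and parameter choices behind
`pergola`, and what the desk-scale simulation does and does not demonstrate.

## The coordination model

The system's only durable state is a labelled property graph. Every other
component is a stateless service reacting to messages:

1. **storage watcher / delivery** — a file appearing under the watched
   directory (the bucket stand-in) yields an object event carrying path,
   size, checksum and event type (`created`/`updated`);
2. **blob classification** — the path is parsed against the grammar
   `<plate>/<sample>/<datatype-dir>/<name>.<ext>` (configurable in the model
   file); the datatype directory and suffix tables assign an extra label
   (`Fastq`, `Ubam`, `Bam`, `Cram`, `Gvcf`, QC report types, `Checksum`) on
   top of `Blob`, and sequencing metadata (sample, plate, 0-indexed read
   group, mate pair 1/2) is extracted from the filename. Unknown paths
   degrade to bare `Blob` with a warning — unknown data must still be
   tracked;
3. **query service** — the single mutation path into the graph. All writes
   are clause pipelines (match / absence guard / aggregate / merge / set /
   soft-delete) executed at one serialized apply point. After a query runs,
   the metadata of every node it *created or actually changed* is forwarded
   to the trigger checker. Forwarding only on real change is what makes the
   cycle terminate: idempotent re-merges produce no further messages;
4. **trigger checker** — each registered trigger is a conjunction of
   declarative predicates over node metadata (equality / comparison / label
   membership) plus a query builder. Conditions decide whether the node's
   *content* is right; the rendered query decides whether its graph *context*
   is right (all inputs registered, no job already requested);
5. **launchers / executor** — launch-trigger result rows become job
   configurations (task, image tag, command template, inputs, environment)
   submitted to the local executor; job metadata is merged back as a `Job`
   node, whose creation re-enters the trigger cycle to wire
   `WAS_USED_BY`/`GENERATED` provenance;
6. **monitoring** — VM lifecycle events annotate job nodes with start/stop
   logical timestamps and machine metadata (events arriving before their job
   node are parked and flushed when it appears); terminal statuses re-enter
   the trigger cycle so the retry trigger can react; a sweep deactivates
   duplicate jobs.

Time is logical throughout: the broker's delivery-step counter. This makes
every interleaving replayable from a seed.

## Delivery semantics and the duplicate-job race

The broker implements at-least-once delivery with three adversarial knobs,
all driven by one seeded RNG: `duplicate_probability` × `max_extra_deliveries`
(bounded duplicate deliveries per message), `reorder_window` (a delivery may
jump ahead of up to that many older pending deliveries), and per-topic
handler concurrency (default cap 20 for the query topic, mirroring the
production database's instance cap). Causality is preserved — a message is
only ever delivered after its publish — so merges downstream of a write
always observe it.

Job-launching queries are protected by a semaphore node (`JobRequest`) keyed
by task name + SHA-256 digest (16 hex chars) of the sorted input paths. Two
modes:

- **merge (default)** — the query atomically merges the `JobRequest` and
  gates the launch on the merge's `created` flag. Because the whole clause
  pipeline executes at the serialized apply point, concurrent activations
  collapse to exactly one launch under any delivery schedule. This also makes
  replay idempotent: re-delivering any message re-runs a merge that matches.
- **naive (regression)** — the query guards on the *absence* of a
  `JobRequest`, then creates one. The query service executes such queries in
  two phases (read, yield, write), and the scheduler may interleave other
  deliveries into the yield — exactly the stale-read window in which two
  activations both pass the guard, create duplicate request nodes and launch
  duplicate jobs. `JobRequest` deliberately carries no hard uniqueness
  constraint so this failure mode can materialise; deduplication is the
  merge's job, not the constraint system's.

Side-effecting consumers (launchers, completion, relaunch, archive mover,
lifecycle) additionally deduplicate by broker message id — the standard
idempotent-consumer pattern — because a *duplicated message* (as opposed to a
racing query) would otherwise double a side effect that no graph merge can
undo. Graph-mutating consumers are not deduplicated: merges are naturally
idempotent, and the naive regression requires duplicate query processing.

## Uniqueness keys

Registered per label: `Blob` (bucket, path), `Sample`/`Genome` (sample id),
`Person` (person id), `CromwellWorkflow`/`CromwellStep`/`CromwellAttempt`
(their ids), and `Job` (task, input digest, **job id**). The job id is part
of the key on purpose: duplicate launches are *real distinct jobs* and must
be representable as distinct nodes for the monitoring sweep to find, while
re-deliveries of the same launch message still collapse onto one node.

## The packaged workflow

The fixture workflow mirrors a GATK-style pipeline structurally:
align-per-readgroup (scatter per input uBAM, preemptible) → merge →
scatter-variant-call (width configurable, default 50, preemptible) →
gather-gvcf → cram. Steps are chained with `LED_TO` from the workflow node;
every shard attempt is a `CromwellAttempt` chained by `AFTER` in execution
order under its step, so the attempt count per shard is always
1 + its preemption count. Step *outputs* attach to the step via `GENERATED`,
never to attempts — provenance traversals over
`GENERATED`/`WAS_USED_BY`/`LED_TO` therefore can never reach an attempt node.
Each step's graph record is published as a self-contained idempotent query
(it re-merges the workflow node and its predecessor step), so records may
arrive in any order.

## Fault injection

- **Task failures** are modelled as *transient*: an injected failure strikes
  at most the first attempt of a given (task, input-set) — the behaviour of
  the platform-side incident bursts such systems actually see, which a single
  retry resolves. The retry trigger relaunches a failed job once
  (`retry_limit`, default 1), so every injected failure is recoverable by
  construction; the failed node keeps its status and gains `retried: 1`.
- **Preemptions** hit preemptible workflow shards with probability
  `preemption_probability` per draw, capped at `attempt_cap − 1` (default cap
  3) consecutive draws, so a preemption storm lengthens attempt chains but
  never hard-fails a workflow. Real preemptions are platform events; here
  they are seeded RNG draws.

Both choices trade realism of the *failure distribution* for a guaranteed
quiescent end state, which is what the multi-sample fault-tolerance run
asserts; they do not weaken the mechanisms under test (retry trigger, attempt
chains), which are exercised on every injected event.

## Synthetic data

`generate_delivery` writes paired gzipped FASTQ files per read group
(pseudo-random ACGT, fixed `I` qualities, 80 bp, default 4 read groups × 100
reads) plus a JSON manifest with the expected read-group count and per-file
checksums. Checksums are `zlib.crc32` stored under the property name the blob
schema uses (`crc32c`); algorithm parity with the cloud checksum is
irrelevant to the coordination logic and is not attempted. gzip mtimes are
pinned to zero so identical arguments yield byte-identical files. Mock tools
are pure functions of their input files and embed input checksums in their
outputs, making lineage verifiable from file content; biological realism
(sequence composition, quality profiles, variant plausibility) is explicitly
out of scope. Consequently, passing tests demonstrate the *coordination*
semantics — triggering, provenance, deduplication, retries — not the
scientific validity of any pipeline output.

## Numerical and design choices

- **Logical clocks everywhere**; no wall-clock dependence in any assertion.
- **Soft delete**: cleanup flags intermediate blobs (`deleted`) rather than
  removing nodes, so provenance survives object purging; default pattern
  matches skip flagged nodes, lineage traversal includes them.
- **Cleanup gate**: the query joins the genome node to all five essential
  types through their functional-domain relationships; with fewer than five
  present the join yields no rows and the (semaphore-guarded) purge/archive
  clauses never execute.
- **Duplicate sweep tie-break**: the kept job is the earliest by (logical
  start time, then job id); only *active* jobs (not failed, not already
  deactivated) compete for a key, since a retry legitimately reuses its
  failed predecessor's key. Cancelling an already-finished duplicate returns
  false from the ddel-style interface; its record is still labelled
  `Duplicate` and counted deactivated.
- **Trigger registry**: activation conditions are fully declarative (YAML
  round-trippable); query templates are referenced by name from a built-in
  pattern library rather than encoded in YAML — the trigger repertoire needs
  a small, audited set of query shapes, and free-form query serialization
  would add surface without coverage.
- **Query language**: a structured clause builder, not a Cypher parser; the
  expressive subset is exactly what the catalogue needs (fixed-length paths,
  label/property predicates, absence guards, count/collect aggregation with
  cross-node comparison, atomic write clauses). Pattern matching is verified
  against brute-force enumeration on random graphs.
- **Problem sizes** in tests and the acceptance script: single-sample runs
  use 2–4 read groups with 4–100 reads per file; the race study uses 50 seeds
  per mode with 4 read groups; the matcher oracle uses 200 graphs of ≤50
  nodes; the multi-sample run uses 50 samples at scatter width 2. These sizes
  fully exercise every code path (the coordination logic is insensitive to
  file size) while keeping a complete run on one CPU under a minute for the
  default suite.

## Known limitations

- Single-process, in-memory only: no crash recovery, no cross-process
  transactions, no persistent queue. Snapshots are explicit JSON-lines dumps.
- Under heavy *reordering*, a relationship-wiring trigger can observe a
  not-yet-registered endpoint and wire nothing; a later event or a `batch`
  re-evaluation (the CRON stand-in) repairs this, but the adversarial
  presets therefore only assert job-count invariants, not full wiring.
- The naive-mode race is a demonstration of a failure mode, not a calibrated
  model of production duplicate rates; the broker's duplicate/reorder knobs
  are test conditions, not estimates.
- `classify_blob` trusts the path grammar; content-based typing (e.g. peeking
  at file headers) is not attempted.
- Local cancellation is reliable by construction, so the sweep's
  "cancel failed, retry next sweep" branch exists but cannot be triggered by
  the local executor.
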