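# pergola

Event-driven orchestration of bioinformatics pipelines over a labelled
property graph — a desk-scale, fully deterministic re-creation of the
data/task-management architecture used by large cloud genomics platforms to
run variant calling across tens of thousands of genomes.

## The problem

Processing one 30× whole genome through a GATK-style pipeline produces on the
order of a thousand data objects and over a hundred jobs; at cohort scale the
bookkeeping — *which* objects exist, *what* produced them, *which* jobs still
need to run, *whether* two jobs were accidentally launched for the same
inputs — becomes the hard part. The production answer is an event-driven
design: every storage object becomes a node in a labelled property graph,
metadata-conditioned **database triggers** decide what to launch next, jobs
and their provenance are written back into the same graph, and services talk
over an **at-least-once** message broker.

That last property is the interesting one. At-least-once delivery plus the
lag between a trigger's read and its write produces real race conditions:
when a sample's fourth uBAM lands, several in-flight activations can each
observe "all read groups present, no job requested yet" and launch duplicate
variant-calling jobs. `pergola` implements both the failure mode and the fix:

- **naive mode** — the trigger query *guards* on the absence of a
  `JobRequest` node and then creates one in a separate step (the race-prone
  historical behaviour);
- **merge mode** (default) — the query atomically *merges* the `JobRequest`
  keyed by task + digest of the sorted inputs and carries a `created` flag;
  only the activation that actually created the node may launch.

Everything runs in one process: an embedded graph store with Cypher-like
pattern matching and merge semantics, a seeded adversarial broker (duplicate
deliveries, bounded reordering, interleaved handler phases), local stand-ins
for Dsub tasks and Cromwell scatter-gather workflows (with preemption and
attempt retries), a monitoring tier (lifecycle events, dstat-style status
checks, duplicate deactivation via the ddel-style cancel), and a synthetic
data generator, so the whole coordination model is testable and replayable
from a single seed.

## The graph model

Nodes carry labels (`Blob`, `Fastq`, `Ubam`, `Gvcf`, `Job`, `JobRequest`,
`Sample`, `Genome`, …) and key:value properties. Relationships come in three
vocabularies:

- **provenance** — `(:Blob)-[:WAS_USED_BY]->(:Job)-[:GENERATED]->(:Blob)`,
  tracing every object back to the sample of origin;
- **functional domain** — `HAS_BIOLOGICAL_OME`, `HAS_SEQUENCING_READS`,
  `HAS_VARIANT_CALLS`, `HAS_QC_DATA`, relating data to the genome concept for
  subset queries;
- **workflow internal** — `(:CromwellWorkflow)-[:LED_TO]->(:CromwellStep)
  -[:GENERATED_ATTEMPT]->(:CromwellAttempt)-[:AFTER]->(:CromwellAttempt)`,
  which keeps per-shard attempt bookkeeping (a 50-shard variant-call step has
  ≥50 attempts) out of provenance traversals.

A sample is *complete* when its genome node carries all five essential data
types (`Cram`, `Gvcf`, `FastQC`, `Flagstat`, `Vcfstats`); only then does the
cleanup trigger fire, soft-deleting intermediates and archiving FASTQs to
cold storage.

## Worked example

```python
from pergola import Engine, EngineConfig

engine = Engine(EngineConfig(watch_root="run/bucket", seed=1, scatter_width=4))
engine.deliver("S001", n_read_groups=2, reads_per_file=50)  # synthetic delivery
engine.run_until_quiescent()

print(engine.completeness("S001"))
path = engine.lineage("PLATE01/S001/variants/S001.g.vcf")[0]
print(" <- ".join(
    engine.store.node(nid).properties.get("path",
        "/".join(sorted(engine.store.node(nid).labels)))
    for nid in path.node_ids))
print(engine.monitor.summarize(engine.store).tail(6).to_string(index=False))
```

prints

```
{'Cram': True, 'Gvcf': True, 'FastQC': True, 'Flagstat': True, 'Vcfstats': True}
PLATE01/S001/variants/S001.g.vcf <- CromwellStep <- CromwellStep <- CromwellStep <- CromwellStep <- CromwellWorkflow/Job <- PLATE01/S001/ubam/S001_RG0.ubam.sam <- DsubJob/Job <- PLATE01/S001/fastq/S001_RG0_R1.fastq.gz <- Sample
              section      metric  value
relationships_by_type      LED_TO      5
relationships_by_type WAS_USED_BY      9
       jobs_by_status   succeeded      6
           duplicates    labelled      0
              samples    complete      1
              samples       total      1
```

Reading the output: all five essential data types were generated, so the
sample is complete; the first lineage path walks from the gathered gVCF back
through the workflow's step chain, the workflow job, one uBAM, the
FASTQ-to-uBAM job and its input FASTQ, terminating at the `Sample` node; the
summary shows six jobs (two FASTQ-to-uBAM, one workflow, three QC), all
succeeded, with zero duplicates.

The same operations are available from a shell via the `pergola` CLI
(`run`, `deliver`, `import`, `query lineage`, `query completeness`, `batch`,
`report`).

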