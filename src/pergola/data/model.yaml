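# Default graph data model: node label taxonomy, relationship vocabulary,
# and the blob-path classification grammar used by the watched-directory
# fixtures.  Node/relationship layout follows the Bento-style convention of
# separate node and relationship sections.

nodes:
  Blob:
    required: [bucket, path, size, crc32c]
    optional: [time_created, event_type, sample_id, plate_id, intermediate, archived]
  Fastq:
    required: [sample_id, plate_id, read_group, mate_pair]
  Ubam:
    required: [sample_id]
    optional: [read_group]
  Bam:
    required: [sample_id]
  Cram:
    required: [sample_id]
  Gvcf:
    required: [sample_id]
  FastQC:
    required: [sample_id]
  Flagstat:
    required: [sample_id]
  Vcfstats:
    required: [sample_id]
  Checksum:
    required: [sample_id]
    optional: [expected_read_groups, plate_id]
  Job:
    required: [task, job_id]
    optional: [input_digest, status, image, command, inputs, outputs, environment,
               start_ts, stop_ts, machine, network, error, retried, launch_topic, duplicate]
  JobRequest:
    required: [task, input_key]
    optional: [sample_id]
  DsubJob:
    required: []
  CromwellWorkflow:
    required: [workflow_id]
    optional: [sample_id, status]
  CromwellStep:
    required: [step_id, step_name]
    optional: [scatter_width]
  CromwellAttempt:
    required: [attempt_id, attempt_index, status]
    optional: [shard, start_ts, stop_ts, sandbox]
  Person:
    required: [person_id]
  Sample:
    required: [sample_id]
    optional: [plate_id]
  Genome:
    required: [sample_id]

relationships:
  GENERATED:
    category: provenance
    endpoints:
      - [Job, Blob]
      - [CromwellStep, Blob]
      - [Sample, Blob]
  WAS_USED_BY:
    category: provenance
    endpoints:
      - [Blob, Job]
  HAS_BIOLOGICAL_OME:
    category: functional-domain
    endpoints:
      - [Person, Genome]
      - [Sample, Genome]
  HAS_SEQUENCING_READS:
    category: functional-domain
    endpoints:
      - [Genome, Fastq]
      - [Genome, Cram]
  HAS_VARIANT_CALLS:
    category: functional-domain
    endpoints:
      - [Genome, Gvcf]
  HAS_QC_DATA:
    category: functional-domain
    endpoints:
      - [Genome, FastQC]
      - [Genome, Flagstat]
      - [Genome, Vcfstats]
  LED_TO:
    category: workflow-internal
    endpoints:
      - [CromwellWorkflow, CromwellStep]
      - [CromwellStep, CromwellStep]
  GENERATED_ATTEMPT:
    category: workflow-internal
    endpoints:
      - [CromwellStep, CromwellAttempt]
  AFTER:
    category: workflow-internal
    endpoints:
      - [CromwellAttempt, CromwellAttempt]

# Path grammar: <plate>/<sample>/<datatype-dir>/<name>.<ext>
# Each datatype directory maps to an extra label on top of Blob (null means
# bare Blob) and may attach fixed extra properties.  Files whose suffix
# carries finer typing (QC reports share one directory) use the suffix table.
classification:
  directories:
    fastq:        {label: Fastq}
    ubam:         {label: Ubam, properties: {intermediate: true}}
    aligned:      {label: Bam, properties: {intermediate: true}}
    cram:         {label: Cram}
    variants:     {label: Gvcf}
    manifest:     {label: Checksum}
    intermediate: {label: null, properties: {intermediate: true}}
    qc:           {label: null}
  suffixes:
    _fastqc.txt:   {label: FastQC}
    _flagstat.txt: {label: Flagstat}
    _vcfstats.txt: {label: Vcfstats}

# JobRequest carries no hard uniqueness constraint: deduplication of job
# requests is the semaphore *merge*'s job, and the naive (guard-only) mode
# must be able to materialise the duplicate request nodes it produces.
uniqueness:
  Blob: [bucket, path]
  Job: [task, input_digest, job_id]
  Sample: [sample_id]
  Genome: [sample_id]
  Person: [person_id]
  CromwellWorkflow: [workflow_id]
  CromwellStep: [step_id]
  CromwellAttempt: [attempt_id]
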