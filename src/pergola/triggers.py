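"""Metadata-conditioned database triggers and the built-in catalogue.

A trigger pairs a conjunction of declarative metadata predicates (checked
against a freshly created/updated node's properties and labels) with a graph
query rendered from that metadata.  The predicate decides whether the node's
*content* is right; the query decides whether its graph *context* is right —
e.g. "all unaligned BAMs for this sample exist and match the delivery
manifest's read-group count" — and, for job-launching triggers, performs the
semaphore step atomically.

Semaphore semantics (two modes):

* **merge** (default): the query merges a ``JobRequest`` node keyed by
  task + digest of the sorted input keys and carries a created flag; only a
  created=true merge may emit a launch message.  Concurrent activations
  collapse to a single launch no matter how messages are duplicated or
  reordered.
* **naive** (regression mode): the query only *guards* on the absence of a
  ``JobRequest`` and then creates one non-atomically; an engine running it
  splits the read and write phases, exposing the stale-read window in which
  two activations both pass the guard and launch duplicate jobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import yaml

from .datamodel import ESSENTIAL_TYPES
from .graphstore import Cmp, Const, Fn, N, Prop, Query, R, Ref

MERGE = "merge"
NAIVE = "naive"


class TriggerError(Exception):
    pass


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Predicate:
    """One activation predicate over node metadata.

    ``field`` names a metadata key; the special field ``labels`` is the node's
    label list.  Ops: eq ne lt le gt ge in contains intersects exists.
    A predicate referencing an absent property is false, never an error.
    """

    field: str
    op: str
    value: Any = None

    def holds(self, metadata: Mapping[str, Any]) -> bool:
        present = self.field in metadata
        if self.op == "exists":
            return present == bool(self.value)
        if not present:
            return False
        have = metadata[self.field]
        try:
            return {
                "eq": lambda: have == self.value,
                "ne": lambda: have != self.value,
                "lt": lambda: have < self.value,
                "le": lambda: have <= self.value,
                "gt": lambda: have > self.value,
                "ge": lambda: have >= self.value,
                "in": lambda: have in self.value,
                "contains": lambda: self.value in have,
                "intersects": lambda: bool(set(have) & set(self.value)),
            }[self.op]()
        except TypeError:
            return False
        except KeyError:
            raise TriggerError(f"unknown predicate op {self.op!r}") from None


@dataclass(frozen=True)
class Rendered:
    """A trigger activation ready for the query service."""

    trigger: str
    query: Query
    destination: str | None  # topic for result rows; None = write-only query
    two_phase: bool  # naive mode: read and write phases may be interleaved


@dataclass(frozen=True)
class TriggerContext:
    mode: str = MERGE
    retry_limit: int = 1
    workflow_task: str = "gatk-like"


Builder = Callable[[Mapping[str, Any], TriggerContext], Rendered]


@dataclass(frozen=True)
class TriggerSpec:
    """Declarative activation conditions plus a named query builder."""

    name: str
    conditions: tuple[Predicate, ...]
    builder_name: str
    destination: str | None = None
    semaphore_task: str | None = None  # set for job-launching triggers

    def check_conditions(self, metadata: Mapping[str, Any]) -> bool:
        """Pure conjunction of predicates; no graph access."""
        return all(p.holds(metadata) for p in self.conditions)

    def render(self, metadata: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
        """Build the parameterised query; requires check_conditions to hold."""
        try:
            builder = QUERY_BUILDERS[self.builder_name]
        except KeyError:
            raise TriggerError(f"unknown query builder {self.builder_name!r}") from None
        return builder(self, metadata, ctx)


# ---------------------------------------------------------------------------
# Semaphore helper
# ---------------------------------------------------------------------------


def _semaphore(q: Query, task: str, input_key_expr: Any, mode: str,
               extra: Mapping[str, Any] | None = None) -> None:
    """Append the job-request semaphore clauses to a launch query.

    merge mode: atomic merge + created-flag gate.  naive mode: an absence
    guard followed by a plain create — correct only if nothing interleaves
    between the read and the write.
    """
    props = dict(extra or {})
    if mode == MERGE:
        q.merge_node("req", {"JobRequest"},
                     key={"task": task, "input_key": input_key_expr},
                     on_create=props)
        q.filter_created("req")
    else:
        q.match(N("req", {"JobRequest"},
                  {"task": task, "input_key": input_key_expr}), absent=True)
        q.create_node("req", {"JobRequest"},
                      {"task": task, "input_key": input_key_expr, **props})


# ---------------------------------------------------------------------------
# Query builders (the catalogue's pattern library)
# ---------------------------------------------------------------------------


def _b_register_sample(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    sample, plate = md["sample_id"], md.get("plate_id", "")
    q = (Query(spec.name)
         .merge_node("s", {"Sample"}, key={"sample_id": sample}, on_create={"plate_id": plate})
         .merge_node("g", {"Genome"}, key={"sample_id": sample})
         .merge_node("p", {"Person"}, key={"person_id": f"P-{sample}"})
         .merge_rel("s", "HAS_BIOLOGICAL_OME", "g")
         .merge_rel("p", "HAS_BIOLOGICAL_OME", "g"))
    if "expected_read_groups" not in md:
        return Rendered(spec.name, q, None, False)
    # annotate the manifest/checksum node with delivery expectations
    q.match(N("m", {"Checksum"}, {"path": md["path"]}))
    q.set_props("m", {"expected_read_groups": md["expected_read_groups"]})
    return Rendered(spec.name, q, None, False)


def _b_relate_fastq(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    sample = md["sample_id"]
    q = (Query(spec.name)
         .match(N("f", {"Fastq"}, {"path": md["path"]}))
         .merge_node("s", {"Sample"}, key={"sample_id": sample},
                     on_create={"plate_id": md.get("plate_id", "")})
         .merge_node("g", {"Genome"}, key={"sample_id": sample})
         .merge_rel("s", "GENERATED", "f")
         .merge_rel("g", "HAS_SEQUENCING_READS", "f"))
    return Rendered(spec.name, q, None, False)


def _b_launch_fastq_to_ubam(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    sample, rg = md["sample_id"], md["read_group"]
    q = (Query(spec.name)
         .match(N("f", {"Fastq"}, {"sample_id": sample, "read_group": rg}))
         .aggregate(aggs={"paths": ("collect_distinct", Prop("f", "path")),
                          "mates": ("count_distinct", Prop("f", "mate_pair"))})
         .where(Cmp("eq", Ref("mates"), Const(2))))
    key = Fn("digest", (Ref("paths"),))
    _semaphore(q, "fastq-to-ubam", key, ctx.mode, {"sample_id": sample})
    q.returns(paths=Ref("paths"), sample_id=Const(sample),
              plate_id=Const(md.get("plate_id", "")), read_group=Const(rg),
              task=Const("fastq-to-ubam"))
    return Rendered(spec.name, q, spec.destination, ctx.mode == NAIVE)


def _b_launch_gatk(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    sample = md["sample_id"]
    q = (Query(spec.name)
         .match(N("u", {"Ubam"}, {"sample_id": sample}))
         .aggregate(aggs={"paths": ("collect_distinct", Prop("u", "path")),
                          "read_groups": ("count_distinct", Prop("u", "read_group"))})
         .match(N("m", {"Checksum"}, {"sample_id": sample}))
         .where(Cmp("eq", Ref("read_groups"), Prop("m", "expected_read_groups")))
         .where(Cmp("gt", Ref("read_groups"), Const(0))))
    key = Fn("digest", (Ref("paths"),))
    _semaphore(q, ctx.workflow_task, key, ctx.mode, {"sample_id": sample})
    q.returns(paths=Ref("paths"), sample_id=Const(sample),
              plate_id=Const(md.get("plate_id", "")), task=Const(ctx.workflow_task))
    return Rendered(spec.name, q, spec.destination, ctx.mode == NAIVE)


def _make_single_input_launch(task: str, label: str) -> Builder:
    def build(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
        q = (Query(spec.name)
             .match(N("b", {label}, {"path": md["path"]}))
             .aggregate(aggs={"paths": ("collect_distinct", Prop("b", "path"))}))
        key = Fn("digest", (Ref("paths"),))
        _semaphore(q, task, key, ctx.mode, {"sample_id": md.get("sample_id", "")})
        q.returns(paths=Ref("paths"), sample_id=Const(md.get("sample_id", "")),
                  plate_id=Const(md.get("plate_id", "")), task=Const(task))
        return Rendered(spec.name, q, spec.destination, ctx.mode == NAIVE)
    return build


def _b_relate_job_inputs(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    q = (Query(spec.name)
         .match(N("j", {"Job"}, {"job_id": md["job_id"]}))
         .match(N("b", {"Blob"}), optional=True)
         .where(Cmp("in", Prop("b", "path"), Prop("j", "inputs")))
         .merge_rel("b", "WAS_USED_BY", "j"))
    return Rendered(spec.name, q, None, False)


def _b_relate_job_outputs(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    q = (Query(spec.name)
         .match(N("b", {"Blob"}, {"path": md["path"]}))
         .match(N("j", {"Job"}, {"job_id": md["source_job_id"]}))
         .merge_rel("j", "GENERATED", "b"))
    return Rendered(spec.name, q, None, False)


def _b_relate_step_outputs(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    q = (Query(spec.name)
         .match(N("b", {"Blob"}, {"path": md["path"]}))
         .match(N("s", {"CromwellStep"}, {"step_id": md["source_step_id"]}))
         .merge_rel("s", "GENERATED", "b"))
    return Rendered(spec.name, q, None, False)


_DOMAIN_REL = {
    "Cram": "HAS_SEQUENCING_READS",
    "Gvcf": "HAS_VARIANT_CALLS",
    "FastQC": "HAS_QC_DATA",
    "Flagstat": "HAS_QC_DATA",
    "Vcfstats": "HAS_QC_DATA",
}


def _b_relate_functional_domain(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    label = next(l for l in md.get("labels", ()) if l in _DOMAIN_REL)
    q = (Query(spec.name)
         .match(N("b", {label}, {"path": md["path"]}))
         .merge_node("g", {"Genome"}, key={"sample_id": md["sample_id"]})
         .merge_rel("g", _DOMAIN_REL[label], "b"))
    return Rendered(spec.name, q, None, False)


def _b_postprocess_cleanup(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    sample = md["sample_id"]
    q = Query(spec.name).match(N("g", {"Genome"}, {"sample_id": sample}))
    # the gate: every essential genomic data type must already hang off the
    # genome node via its functional-domain relationship
    for label in ESSENTIAL_TYPES:
        q.match(N("g", {"Genome"}), R(_DOMAIN_REL[label]), N(f"e_{label}", {label}))
    q.aggregate(group={"g": Ref("g")})
    _semaphore(q, "postprocess-cleanup", Const(sample), ctx.mode, {"sample_id": sample})
    q.match(N("b", {"Blob"}, {"sample_id": sample, "intermediate": True}), optional=True)
    q.mark_deleted("b")
    q.aggregate(group={"g": Ref("g")}, aggs={"deleted": ("count", Ref("g"))})
    q.match(N("f", {"Fastq"}, {"sample_id": sample}))
    q.set_props("f", {"storage_class": "coldline", "archived": True})
    q.returns(path=Prop("f", "path"), sample_id=Const(sample))
    return Rendered(spec.name, q, spec.destination, ctx.mode == NAIVE)


def _b_retry_failed(spec: TriggerSpec, md: Mapping[str, Any], ctx: TriggerContext) -> Rendered:
    job_id = md["job_id"]
    q = (Query(spec.name)
         .match(N("j", {"Job"}, {"job_id": job_id, "status": "failed"}))
         .where(Cmp("lt", Prop("j", "retried"), Const(ctx.retry_limit))))
    _semaphore(q, "retry", Const(f"{job_id}:{md.get('retried', 0)}"), ctx.mode)
    q.set_props("j", {"retried": Fn("add", (Prop("j", "retried"), Const(1)))})
    q.returns(task=Prop("j", "task"), inputs=Prop("j", "inputs"),
              sample_id=Prop("j", "sample_id"), plate_id=Prop("j", "plate_id"),
              read_group=Prop("j", "read_group"), launch_topic=Prop("j", "launch_topic"))
    return Rendered(spec.name, q, spec.destination, ctx.mode == NAIVE)


QUERY_BUILDERS: dict[str, Builder] = {
    "register-sample": _b_register_sample,
    "relate-fastq-to-sample": _b_relate_fastq,
    "launch-fastq-to-ubam": _b_launch_fastq_to_ubam,
    "launch-gatk": _b_launch_gatk,
    "launch-fastqc": _make_single_input_launch("fastqc", "Bam"),
    "launch-flagstat": _make_single_input_launch("flagstat", "Bam"),
    "launch-vcfstats": _make_single_input_launch("vcfstats", "Gvcf"),
    "relate-job-inputs": _b_relate_job_inputs,
    "relate-job-outputs": _b_relate_job_outputs,
    "relate-step-outputs": _b_relate_step_outputs,
    "relate-functional-domain": _b_relate_functional_domain,
    "postprocess-cleanup": _b_postprocess_cleanup,
    "retry-failed": _b_retry_failed,
}


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


class TriggerRegistry:
    """Ordered trigger collection; evaluation order is registry order and
    triggers are independent of one another."""

    def __init__(self, specs: list[TriggerSpec] | None = None) -> None:
        self.specs: list[TriggerSpec] = list(specs or [])

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def get(self, name: str) -> TriggerSpec:
        for spec in self.specs:
            if spec.name == name:
                return spec
        raise TriggerError(f"no trigger named {name!r}")

    def activated(self, metadata: Mapping[str, Any]) -> list[TriggerSpec]:
        return [s for s in self.specs if s.check_conditions(metadata)]

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str) -> None:
        doc = [{
            "name": s.name,
            "conditions": [{"field": p.field, "op": p.op, "value": p.value}
                           for p in s.conditions],
            "query": s.builder_name,
            "destination": s.destination,
            "semaphore": {"task": s.semaphore_task} if s.semaphore_task else None,
        } for s in self.specs]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "TriggerRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        specs = []
        for entry in doc:
            if entry["query"] not in QUERY_BUILDERS:
                raise TriggerError(f"unknown query builder {entry['query']!r}")
            specs.append(TriggerSpec(
                name=entry["name"],
                conditions=tuple(Predicate(c["field"], c["op"], c.get("value"))
                                 for c in entry.get("conditions") or ()),
                builder_name=entry["query"],
                destination=entry.get("destination"),
                semaphore_task=(entry.get("semaphore") or {}).get("task"),
            ))
        return cls(specs)


def builtin_registry() -> TriggerRegistry:
    """The catalogue driving the default variant-calling + QC pipeline."""
    L = Predicate  # noqa: E741 — terse predicate constructor
    return TriggerRegistry([
        TriggerSpec("register-sample",
                    (L("labels", "contains", "Checksum"),),
                    "register-sample"),
        TriggerSpec("relate-fastq-to-sample",
                    (L("labels", "contains", "Fastq"),),
                    "relate-fastq-to-sample"),
        TriggerSpec("relate-job-inputs",
                    (L("labels", "contains", "Job"), L("inputs", "exists", True)),
                    "relate-job-inputs"),
        TriggerSpec("relate-job-outputs",
                    (L("labels", "contains", "Blob"), L("source_job_id", "exists", True)),
                    "relate-job-outputs"),
        TriggerSpec("relate-step-outputs",
                    (L("labels", "contains", "Blob"), L("source_step_id", "exists", True)),
                    "relate-step-outputs"),
        TriggerSpec("relate-functional-domain",
                    (L("labels", "intersects", list(ESSENTIAL_TYPES)),
                     L("sample_id", "exists", True)),
                    "relate-functional-domain"),
        TriggerSpec("launch-fastq-to-ubam",
                    (L("labels", "contains", "Fastq"), L("read_group", "exists", True)),
                    "launch-fastq-to-ubam",
                    destination="launch-fastq-to-ubam", semaphore_task="fastq-to-ubam"),
        TriggerSpec("launch-gatk",
                    (L("labels", "contains", "Ubam"),),
                    "launch-gatk",
                    destination="launch-gatk", semaphore_task="gatk-like"),
        TriggerSpec("launch-fastqc",
                    (L("labels", "contains", "Bam"),),
                    "launch-fastqc",
                    destination="launch-fastqc", semaphore_task="fastqc"),
        TriggerSpec("launch-flagstat",
                    (L("labels", "contains", "Bam"),),
                    "launch-flagstat",
                    destination="launch-flagstat", semaphore_task="flagstat"),
        TriggerSpec("launch-vcfstats",
                    (L("labels", "contains", "Gvcf"), L("intermediate", "exists", False)),
                    "launch-vcfstats",
                    destination="launch-vcfstats", semaphore_task="vcfstats"),
        TriggerSpec("postprocess-cleanup",
                    (L("labels", "intersects", list(ESSENTIAL_TYPES)),
                     L("sample_id", "exists", True)),
                    "postprocess-cleanup",
                    destination="object-management", semaphore_task="postprocess-cleanup"),
        TriggerSpec("retry-failed",
                    (L("labels", "contains", "Job"), L("status", "eq", "failed")),
                    "retry-failed",
                    destination="relaunch", semaphore_task="retry"),
    ])
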