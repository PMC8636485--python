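"""The operating cycle: services wired over the broker and graph store.

The standard cycle for one data object:

1. a file lands in the watched directory (the bucket stand-in) and an object
   event is published;
2. the blob service classifies it and publishes a merge query;
3. the query service (the only mutation path into the graph) applies the
   query and forwards the metadata of every node it created or changed to the
   trigger checker;
4. the trigger checker renders the queries of all activated triggers back to
   the query service;
5. launch-trigger results reach a task launcher, which submits the job to the
   local executor and registers a job node;
6. job outputs land back in the watched directory — the cycle continues until
   the broker is quiescent.

Two semaphore modes are supported: ``merge`` (atomic job-request merge with a
created flag gating the launch — the robust default) and ``naive`` (an absence
guard followed by a separate create; the query service then runs the read and
write phases as separate scheduler steps, exposing the stale-read window that
produces duplicate jobs under at-least-once delivery).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from . import fixtures
from .broker import Broker, DeliveryPolicy, EventMessage
from .datamodel import (BlobMetadata, ESSENTIAL_TYPES, ModelDescription,
                        classify_blob, load_model, validate_graph)
from .executor import (JobConfig, LocalExecutor, WorkflowResult,
                       gatk_like_workflow)
from .graphstore import (GraphError, GraphStore, N, Prop, Query, R)
from .monitoring import LifecycleEvent, Monitor
from .triggers import (MERGE, NAIVE, TriggerContext, TriggerRegistry,
                       builtin_registry)

logger = logging.getLogger(__name__)

TOPIC_OBJECT = "object-events"
TOPIC_DB_QUERY = "db-query"
TOPIC_TRIGGERS = "db-triggers"
TOPIC_CREATE_JOB = "create-job-node"
TOPIC_COMPLETE = "executor-complete"
TOPIC_LIFECYCLE = "job-lifecycle"
TOPIC_RELAUNCH = "relaunch"
TOPIC_OBJECT_MGMT = "object-management"
TOPIC_DEAD = "dead-letter"
TOPIC_REPORT = "report"

#: task name -> launcher topic
LAUNCH_TOPICS = {
    "fastq-to-ubam": "launch-fastq-to-ubam",
    "gatk-like": "launch-gatk",
    "fastqc": "launch-fastqc",
    "flagstat": "launch-flagstat",
    "vcfstats": "launch-vcfstats",
}

PROVENANCE_TYPES = ("GENERATED", "WAS_USED_BY", "LED_TO")


class EngineError(Exception):
    pass


@dataclass
class EngineConfig:
    """Run configuration (mirrors the YAML config file)."""

    watch_root: str
    archive_root: str | None = None
    mode: str = MERGE
    seed: int = 0
    scatter_width: int = 50
    retry_limit: int = 1
    failure_probability: float = 0.0
    preemption_probability: float = 0.0
    delivery: dict = field(default_factory=dict)
    registry_path: str | None = None
    model_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "EngineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def policy(self) -> DeliveryPolicy:
        kwargs = dict(self.delivery)
        kwargs.setdefault("seed", self.seed)
        return DeliveryPolicy(**kwargs)


class Engine:
    """One fully wired instance: store + broker + executor + monitor."""

    def __init__(self, config: EngineConfig) -> None:
        self.config = config
        self.watch_root = Path(config.watch_root)
        self.watch_root.mkdir(parents=True, exist_ok=True)
        self.archive_root = Path(config.archive_root or (self.watch_root.parent / "archive"))
        self.model: ModelDescription = load_model(config.model_path)
        self.store = GraphStore()
        self.model.register_constraints(self.store)
        self.registry: TriggerRegistry = (
            TriggerRegistry.from_yaml(config.registry_path) if config.registry_path
            else builtin_registry())
        self.ctx = TriggerContext(mode=config.mode, retry_limit=config.retry_limit)
        self.broker = Broker()
        self.executor = LocalExecutor(
            self.watch_root, seed=config.seed + 1,
            failure_probability=config.failure_probability,
            preemption_probability=config.preemption_probability,
            clock=lambda: self.broker.clock)
        self.executor.on_lifecycle.append(self._on_lifecycle)
        self.executor.on_output.append(self._on_output)
        self.monitor = Monitor()
        self.dead_letters: list[dict[str, Any]] = []
        self.reports: list[dict[str, Any]] = []
        self.log_records: list[dict[str, Any]] = []
        self._effect_done: set[str] = set()

        b = self.broker
        b.register_topic(TOPIC_OBJECT, self.on_object_event)
        b.register_topic(TOPIC_DB_QUERY, self.handle_query)
        b.register_topic(TOPIC_TRIGGERS, self.handle_trigger_check)
        b.register_topic(TOPIC_CREATE_JOB, self.handle_job_launched)
        b.register_topic(TOPIC_COMPLETE, self.handle_complete)
        b.register_topic(TOPIC_LIFECYCLE, self.handle_lifecycle)
        b.register_topic(TOPIC_RELAUNCH, self.handle_relaunch)
        b.register_topic(TOPIC_OBJECT_MGMT, self.handle_object_management)
        b.register_topic(TOPIC_DEAD, lambda m: self.dead_letters.append(dict(m.body)))
        b.register_topic(TOPIC_REPORT, lambda m: self.reports.append(dict(m.body)))
        for topic in LAUNCH_TOPICS.values():
            b.register_topic(topic, self.handle_launch)

    # ------------------------------------------------------------------
    # plumbing
    # ------------------------------------------------------------------
    def _log(self, service: str, msg: EventMessage | None, **info: Any) -> None:
        self.log_records.append({
            "clock": self.broker.clock, "service": service,
            "message_id": msg.message_id if msg else None, **info})

    def write_log(self, path: str) -> None:
        with open(path, "w") as fh:
            for rec in self.log_records:
                fh.write(json.dumps(rec) + "\n")

    def _dead_letter(self, msg: EventMessage | None, reason: str) -> None:
        body = {"reason": reason, "original_topic": msg.topic if msg else None,
                "original_message": msg.message_id if msg else None}
        self.broker.publish(TOPIC_DEAD, body, parent=msg, publisher="dead-letter")

    def _once(self, msg: EventMessage) -> bool:
        """Idempotent-consumer guard for side-effecting handlers: process each
        message id once no matter how many times the broker delivers it."""
        if msg.message_id in self._effect_done:
            return False
        self._effect_done.add(msg.message_id)
        return True

    def execute_query(self, query: Query) -> list[dict[str, Any]]:
        """Serialized direct query application (same apply point the query
        service uses); for monitoring sweeps and CLI reads."""
        self.store.begin_journal()
        try:
            return self.store.run(query)
        finally:
            self.store.take_journal()

    # ------------------------------------------------------------------
    # object events (create-blob-node service)
    # ------------------------------------------------------------------
    def publish_object_event(self, relpath: str, extra: Mapping[str, Any] | None = None,
                             event_type: str = "created") -> str:
        meta = fixtures.blob_metadata_for(self.watch_root, self.watch_root / relpath, event_type)
        body = dict(meta.__dict__)
        if extra:
            body["context"] = dict(extra)
        return self.broker.publish(TOPIC_OBJECT, body, publisher="storage-watcher")

    def on_object_event(self, msg: EventMessage) -> None:
        """Classify the blob and publish the node-merge query."""
        self._log("create-blob-node", msg, path=msg.body.get("path"))
        body = dict(msg.body)
        context = body.pop("context", {})
        meta = BlobMetadata(**body)
        labels, props = classify_blob(meta, self.model)
        props.update(context)
        if "Checksum" in labels:
            try:
                manifest = fixtures.load_manifest(self.watch_root, meta.path)
                props["expected_read_groups"] = manifest["expected_read_groups"]
                props.setdefault("sample_id", manifest["sample_id"])
                props.setdefault("plate_id", manifest["plate_id"])
            except (OSError, KeyError, json.JSONDecodeError):
                self._dead_letter(msg, f"unreadable manifest {meta.path}")
                return
        key = {"bucket": props["bucket"], "path": props["path"]}
        volatile = ("size", "crc32c", "time_created", "event_type")
        q = Query("merge-blob").merge_node(
            "b", labels, key,
            on_create={k: v for k, v in props.items() if k not in key},
            on_match={k: props[k] for k in volatile})
        self.broker.publish(TOPIC_DB_QUERY, {"query": q}, parent=msg,
                            publisher="create-blob-node")

    # ------------------------------------------------------------------
    # db-query service
    # ------------------------------------------------------------------
    def handle_query(self, msg: EventMessage):
        body = msg.body
        q = body.get("query")
        if not isinstance(q, Query):
            self._dead_letter(msg, "missing or malformed query")
            return None
        if body.get("two_phase") and q.has_writes:
            return self._two_phase(msg, q, body)
        self.store.begin_journal()
        try:
            rows = self.store.run(q)
        except GraphError as exc:
            self.store.take_journal()
            self._log("db-query", msg, query=q.name, error=str(exc))
            self._dead_letter(msg, f"{q.name}: {exc}")
            return None
        changes = self.store.take_journal()
        self._post_query(msg, body, rows, changes)
        return None

    def _two_phase(self, msg: EventMessage, q: Query, body: Mapping[str, Any]):
        """Naive-mode execution: read phase, a scheduling yield (the race
        window in which other queries may commit), then the write phase."""
        read, write = q.split_read_write()
        try:
            rows = self.store.run_clauses([{}], read)
        except GraphError as exc:
            self._dead_letter(msg, f"{q.name}: {exc}")
            return
        yield  # <-- other deliveries may interleave here
        self.store.begin_journal()
        try:
            rows = self.store.run_clauses(rows, write)
        except GraphError as exc:
            self.store.take_journal()
            self._dead_letter(msg, f"{q.name}: {exc}")
            return
        changes = self.store.take_journal()
        self._post_query(msg, body, rows, changes)

    def _post_query(self, msg: EventMessage, body: Mapping[str, Any],
                    rows: list[dict[str, Any]], changes: list[tuple[int, str]]) -> None:
        self._log("db-query", msg, query=body["query"].name,
                  rows=len(rows), changes=len(changes))
        job_created = False
        for nid, kind in changes:
            node = self.store.node(nid)
            if node.deleted:
                continue
            if "Job" in node.labels and kind == "created":
                job_created = True
            metadata = dict(node.properties)
            metadata["labels"] = sorted(node.labels)
            metadata["node_id"] = nid
            self.broker.publish(TOPIC_TRIGGERS, metadata, parent=msg, publisher="db-query")
        if job_created:
            for q in self.monitor.flush_parked(self.store):
                self.broker.publish(TOPIC_DB_QUERY, {"query": q}, parent=msg,
                                    publisher="job-monitor")
        destination = body.get("destination")
        if destination:
            for row in rows:
                self.broker.publish(destination,
                                    {"row": row, "trigger": body.get("trigger")},
                                    parent=msg, publisher="db-query")

    # ------------------------------------------------------------------
    # db-triggers service
    # ------------------------------------------------------------------
    def handle_trigger_check(self, msg: EventMessage) -> None:
        metadata = msg.body
        activated = []
        for spec in self.registry:
            if not spec.check_conditions(metadata):
                continue
            try:
                rendered = spec.render(metadata, self.ctx)
            except Exception as exc:  # a failing render is logged and skipped
                self._log("db-triggers", msg, trigger=spec.name, render_error=str(exc))
                continue
            activated.append(spec.name)
            self.broker.publish(TOPIC_DB_QUERY, {
                "query": rendered.query, "destination": rendered.destination,
                "trigger": rendered.trigger, "two_phase": rendered.two_phase,
            }, parent=msg, publisher="db-triggers")
        self._log("db-triggers", msg, activated=activated)

    # ------------------------------------------------------------------
    # job launchers
    # ------------------------------------------------------------------
    def handle_launch(self, msg: EventMessage) -> None:
        if not self._once(msg):
            return
        row = msg.body.get("row") or {}
        task = row.get("task")
        paths = row.get("paths") or row.get("inputs")
        if not task or not paths:
            self._dead_letter(msg, "launch message missing task or inputs")
            return
        env: dict[str, Any] = {"sample_id": row.get("sample_id", ""),
                               "plate_id": row.get("plate_id", "")}
        if row.get("read_group") is not None:
            env["read_group"] = row["read_group"]
        try:
            if task == self.ctx.workflow_task:
                env["scatter_width"] = self.config.scatter_width
                spec = gatk_like_workflow(self.config.scatter_width)
                job_id = self.executor.launch_workflow(spec, tuple(sorted(paths)), env)
                config = self.executor.jobs[job_id].config
                kind = "cromwell-workflow"
            else:
                config = JobConfig(task=task, image=f"mock/{task}:1",
                                   command_template=f"{task} {{inputs}} -o {{output_dir}}",
                                   inputs=tuple(sorted(paths)),
                                   output_dir=str(self.watch_root),
                                   environment=env, kind="dsub-task")
                job_id = self.executor.launch_task(config)
                kind = "dsub-task"
        except Exception as exc:
            self._dead_letter(msg, f"launch of {task} failed: {exc}")
            return
        self._log("job-launcher", msg, task=task, job_id=job_id)
        self.broker.publish(TOPIC_COMPLETE, {"job_id": job_id}, parent=msg,
                            publisher=f"launcher-{task}")
        self.broker.publish(TOPIC_CREATE_JOB, self._job_metadata(job_id, config, kind, msg.topic),
                            parent=msg, publisher=f"launcher-{task}")

    def _job_metadata(self, job_id: str, config: JobConfig, kind: str,
                      launch_topic: str) -> dict[str, Any]:
        md: dict[str, Any] = {
            "task": config.task, "job_id": job_id, "input_digest": config.input_digest,
            "inputs": sorted(config.inputs), "image": config.image,
            "command": config.render_command(),
            "environment": json.dumps(config.environment, sort_keys=True),
            "machine": config.machine, "kind": kind, "launch_topic": launch_topic,
            "sample_id": config.environment.get("sample_id", ""),
            "plate_id": config.environment.get("plate_id", ""),
            "status": "running", "retried": 0,
        }
        if "read_group" in config.environment:
            md["read_group"] = config.environment["read_group"]
        if kind == "cromwell-workflow":
            md["workflow_id"] = job_id
        return md

    # ------------------------------------------------------------------
    # create-job-node service
    # ------------------------------------------------------------------
    def handle_job_launched(self, msg: EventMessage) -> None:
        md = dict(msg.body)
        for required in ("image", "environment", "inputs", "command"):
            if required not in md:
                self._dead_letter(msg, f"job metadata missing replication field {required!r}")
                return
        labels = {"Job", "CromwellWorkflow" if md.get("kind") == "cromwell-workflow" else "DsubJob"}
        key = {"task": md["task"], "input_digest": md["input_digest"], "job_id": md["job_id"]}
        on_create = {k: v for k, v in md.items() if k not in key}
        q = Query("create-job-node").merge_node("j", labels, key, on_create=on_create)
        self.broker.publish(TOPIC_DB_QUERY, {"query": q}, parent=msg,
                            publisher="create-job-node")

    # ------------------------------------------------------------------
    # executor completion + lifecycle + relaunch
    # ------------------------------------------------------------------
    def _on_output(self, relpath: str, context: dict) -> None:
        self.publish_object_event(relpath, extra=context)

    def _on_lifecycle(self, event: dict) -> None:
        self.broker.publish(TOPIC_LIFECYCLE, event, publisher="log-insert-instance")

    def handle_complete(self, msg: EventMessage) -> None:
        if not self._once(msg):
            return
        job_id = msg.body["job_id"]
        job = self.executor.complete(job_id)
        self._log("executor", msg, job_id=job_id, status=job.status)
        labels = {"Job", "CromwellWorkflow" if job.config.kind == "cromwell-workflow" else "DsubJob"}
        key = {"task": job.config.task, "input_digest": job.config.input_digest,
               "job_id": job_id}
        status_md = self._job_metadata(job_id, job.config, job.config.kind,
                                       LAUNCH_TOPICS.get(job.config.task, ""))
        status_md.update({"status": job.status, "error": job.error or "",
                          "stop_ts": job.stop_ts, "outputs": sorted(job.outputs)})
        q = Query("job-status").merge_node(
            "j", labels, key,
            on_create={k: v for k, v in status_md.items() if k not in key},
            on_match={"status": job.status, "error": job.error or "",
                      "stop_ts": job.stop_ts, "outputs": sorted(job.outputs)})
        self.broker.publish(TOPIC_DB_QUERY, {"query": q}, parent=msg,
                            publisher="check-status")
        if job.workflow is not None:
            for wq in self._workflow_graph_queries(job.workflow, job.config):
                self.broker.publish(TOPIC_DB_QUERY, {"query": wq}, parent=msg,
                                    publisher="create-workflow-nodes")

    def _workflow_graph_queries(self, wf: WorkflowResult, config: JobConfig) -> list[Query]:
        """One self-contained query per step: workflow node, LED_TO chain link,
        attempt nodes chained by AFTER within each shard."""
        queries: list[Query] = []
        wf_key = {"workflow_id": wf.workflow_id, "job_id": wf.workflow_id,
                  "task": config.task, "input_digest": config.input_digest}
        for i, step in enumerate(wf.steps):
            q = Query(f"workflow-step-{step.name}")
            q.merge_node("w", {"Job", "CromwellWorkflow"}, wf_key,
                         on_create={"status": wf.status, "sample_id":
                                    config.environment.get("sample_id", "")})
            if i > 0:
                prev = wf.steps[i - 1]
                q.merge_node("prev", {"CromwellStep"}, {"step_id": prev.step_id},
                             on_create={"step_name": prev.name, "scatter_width": prev.scatter_width})
                q.merge_node("s", {"CromwellStep"}, {"step_id": step.step_id},
                             on_create={"step_name": step.name, "scatter_width": step.scatter_width})
                q.merge_rel("prev", "LED_TO", "s")
            else:
                q.merge_node("s", {"CromwellStep"}, {"step_id": step.step_id},
                             on_create={"step_name": step.name, "scatter_width": step.scatter_width})
                q.merge_rel("w", "LED_TO", "s")
            by_shard: dict[int, list] = {}
            for att in step.attempts:
                by_shard.setdefault(att.shard, []).append(att)
            k = 0
            for shard, attempts in sorted(by_shard.items()):
                attempts.sort(key=lambda a: a.attempt_index)
                prev_var: str | None = None
                for att in attempts:
                    var = f"a{k}"
                    k += 1
                    q.merge_node(var, {"CromwellAttempt"}, {"attempt_id": att.sandbox},
                                 on_create={"attempt_index": att.attempt_index,
                                            "status": att.status, "shard": att.shard,
                                            "start_ts": att.start_ts, "stop_ts": att.stop_ts,
                                            "sandbox": att.sandbox})
                    q.merge_rel("s", "GENERATED_ATTEMPT", var)
                    if prev_var is not None:
                        q.merge_rel(var, "AFTER", prev_var)
                    prev_var = var
            queries.append(q)
        return queries

    def handle_lifecycle(self, msg: EventMessage) -> None:
        if not self._once(msg):
            return
        body = msg.body
        event = LifecycleEvent(body["job_id"], body["kind"], body["timestamp"],
                               {k: v for k, v in body.items()
                                if k not in ("job_id", "kind", "timestamp")})
        q = self.monitor.on_lifecycle_event(event, self.store)
        if q is not None:
            self.broker.publish(TOPIC_DB_QUERY, {"query": q}, parent=msg,
                                publisher="log-instance-monitor")

    def handle_relaunch(self, msg: EventMessage) -> None:
        if not self._once(msg):
            return
        row = msg.body.get("row") or {}
        topic = row.get("launch_topic")
        if not topic or not row.get("inputs"):
            self._dead_letter(msg, "relaunch row missing launch topic or inputs")
            return
        self._log("retry-relaunch", msg, task=row.get("task"))
        self.broker.publish(topic, {"row": {
            "paths": row["inputs"], "task": row["task"],
            "sample_id": row.get("sample_id", ""), "plate_id": row.get("plate_id", ""),
            "read_group": row.get("read_group"),
        }}, parent=msg, publisher="retry-relaunch")

    def handle_object_management(self, msg: EventMessage) -> None:
        if not self._once(msg):
            return
        row = msg.body.get("row") or {}
        rel = row.get("path")
        if not rel:
            return
        src = self.watch_root / rel
        dst = self.archive_root / rel
        if src.exists():
            dst.parent.mkdir(parents=True, exist_ok=True)
            src.rename(dst)
            self._log("object-management", msg, archived=rel)

    # ------------------------------------------------------------------
    # public operations
    # ------------------------------------------------------------------
    def deliver(self, sample_id: str, n_read_groups: int = fixtures.DEFAULT_READ_GROUPS,
                reads_per_file: int = fixtures.DEFAULT_READS_PER_FILE,
                seed: int | None = None, plate_id: str = fixtures.DEFAULT_PLATE) -> list[str]:
        """Generate a synthetic delivery under the watched root and publish its
        object events (fastqs first, manifest last, as a sequencer would)."""
        created = fixtures.generate_delivery(
            self.watch_root, sample_id, n_read_groups, reads_per_file,
            seed if seed is not None else self.config.seed, plate_id)
        rels = [p.relative_to(self.watch_root).as_posix() for p in created]
        for rel in rels:
            self.publish_object_event(rel)
        return rels

    def import_dir(self, subdir: str | None = None) -> int:
        """Data-import path: publish events for files already present."""
        base = self.watch_root / subdir if subdir else self.watch_root
        count = 0
        for p in sorted(base.rglob("*")):
            if p.is_file():
                self.publish_object_event(p.relative_to(self.watch_root).as_posix())
                count += 1
        return count

    def batch(self, trigger_name: str) -> int:
        """CRON stand-in: re-evaluate one trigger against every live node
        (semaphores make re-evaluation of already-handled work a no-op)."""
        spec = self.registry.get(trigger_name)
        published = 0
        for node in list(self.store.nodes(include_deleted=False)):
            metadata = dict(node.properties)
            metadata["labels"] = sorted(node.labels)
            if not spec.check_conditions(metadata):
                continue
            rendered = spec.render(metadata, self.ctx)
            self.broker.publish(TOPIC_DB_QUERY, {
                "query": rendered.query, "destination": rendered.destination,
                "trigger": rendered.trigger, "two_phase": rendered.two_phase,
            }, publisher="cron-batch")
            published += 1
        return published

    def run_until_quiescent(self, policy: DeliveryPolicy | None = None):
        return self.broker.run_until_quiescent(policy or self.config.policy())

    def watch(self, poll_interval: float = 0.5, max_cycles: int | None = None) -> None:
        """Polling directory watcher: publish events for new files, then run
        the broker to quiescence; repeat."""
        seen: set[str] = set()
        cycles = 0
        while max_cycles is None or cycles < max_cycles:
            cycles += 1
            new = 0
            for p in sorted(self.watch_root.rglob("*")):
                rel = p.relative_to(self.watch_root).as_posix()
                if p.is_file() and rel not in seen:
                    seen.add(rel)
                    self.publish_object_event(rel)
                    new += 1
            if new:
                self.run_until_quiescent()
            else:
                time.sleep(poll_interval)

    # -- queries -----------------------------------------------------------
    def blob_node(self, relpath: str):
        rows = self.store.match(N("b", {"Blob"}, {"path": relpath}), include_deleted=True)
        if not rows:
            raise EngineError(f"no blob node for {relpath!r}")
        return self.store.node(rows[0]["b"])

    def lineage(self, relpath: str, direction: str = "upstream"):
        """Provenance lineage of a data object (attempt nodes never appear:
        they hang off steps via workflow-internal relationships only)."""
        node = self.blob_node(relpath)
        return self.store.traverse_lineage(node.id, PROVENANCE_TYPES, direction)

    def completeness(self, sample_id: str) -> dict[str, bool]:
        from .triggers import _DOMAIN_REL
        out = {}
        for label in ESSENTIAL_TYPES:
            hit = self.store.match(N("g", {"Genome"}, {"sample_id": sample_id}),
                                   R(_DOMAIN_REL[label]), N("e", {label}))
            out[label] = bool(hit)
        return out

    def schema_violations(self) -> list[str]:
        return validate_graph(self.store, self.model)
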