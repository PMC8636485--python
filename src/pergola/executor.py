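"""Local task and workflow execution: stand-ins for Dsub and Cromwell.

Two execution kinds are supported:

* **single tasks** (Dsub analog) — one mock tool invocation in a sandbox,
  with lifecycle events (instance insert/delete), transient-failure
  injection, status checks (dstat analog) and cancellation (ddel analog);
* **packaged workflows** (Cromwell analog) — an ordered multi-step pipeline
  where steps may scatter per input file or into a fixed shard width, each
  shard attempt may be preempted (retried up to an attempt cap), and the full
  step/attempt structure is reported for graph registration:
  workflow -LED_TO-> step -LED_TO-> step, step -GENERATED_ATTEMPT-> attempt
  -AFTER-> attempt, step outputs attached to the *step*, never to attempts.

Execution is *deferred*: launching registers the job as running and emits its
start event; the actual tool run happens when :meth:`LocalExecutor.complete`
is called (the engine routes completion through the broker, so jobs have a
real running window in logical time during which duplicates can be observed
and cancelled).  All stochastic behaviour (failure and preemption injection)
is seeded and replayable.  Injected failures are transient — they strike at
most the first attempt of a given (task, input-set), mimicking the platform
hiccups that a single retry resolves — so a retry limit of one suffices to
recover every injected fault.
"""

from __future__ import annotations

import itertools
import random
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable

from .fixtures import TASKS, file_crc32
from .graphstore import input_digest


class ExecutorError(Exception):
    pass


_FORMAT_FIELD = re.compile(r"\{(\w+)")


@dataclass(frozen=True)
class JobConfig:
    """Everything needed to replicate a job: image, command, inputs, env."""

    task: str
    image: str
    command_template: str
    inputs: tuple[str, ...]
    output_dir: str
    environment: dict[str, Any] = field(default_factory=dict)
    machine: str = "n1-standard-1"
    kind: str = "dsub-task"

    def __post_init__(self) -> None:
        allowed = {"inputs", "output_dir", "task"} | set(self.environment)
        for m in _FORMAT_FIELD.finditer(self.command_template):
            if m.group(1) not in allowed:
                raise ExecutorError(
                    f"command template slot {m.group(1)!r} is not a declared input/output")

    @property
    def input_digest(self) -> str:
        return input_digest(self.inputs)

    def render_command(self) -> str:
        return self.command_template.format(
            inputs=" ".join(self.inputs), output_dir=self.output_dir,
            task=self.task, **self.environment)


@dataclass(frozen=True)
class WorkflowStep:
    name: str
    task: str
    scatter: int | str = 1  # 1 = no scatter; int width; "per-input"
    preemptible: bool = False
    inputs_from: str | None = None  # previous step by default; "workflow" = workflow inputs

    def __post_init__(self) -> None:
        if isinstance(self.scatter, int) and self.scatter < 1:
            raise ExecutorError("scatter width must be >= 1")


@dataclass(frozen=True)
class WorkflowSpec:
    name: str
    steps: tuple[WorkflowStep, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.steps]
        if len(set(names)) != len(names):
            raise ExecutorError("step names must be unique")
        for step in self.steps:
            if step.task not in TASKS:
                raise ExecutorError(f"unknown task {step.task!r}")


@dataclass
class AttemptRecord:
    step_name: str
    attempt_index: int  # 1-based; chained by AFTER in index order
    status: str  # succeeded | failed | preempted
    start_ts: int
    stop_ts: int
    sandbox: str
    shard: int = 0


@dataclass
class StepResult:
    step_id: str
    name: str
    scatter_width: int
    outputs: list[str]
    attempts: list[AttemptRecord]


@dataclass
class WorkflowResult:
    workflow_id: str
    name: str
    status: str
    inputs: tuple[str, ...]
    steps: list[StepResult]


@dataclass
class JobRecord:
    job_id: str
    config: JobConfig
    status: str  # running | succeeded | failed | deactivated
    start_ts: int
    stop_ts: int | None = None
    error: str | None = None
    outputs: list[str] = field(default_factory=list)
    workflow: WorkflowResult | None = None
    spec: WorkflowSpec | None = None


def gatk_like_workflow(scatter_width: int = 50) -> WorkflowSpec:
    """The packaged fixture workflow: align per read group, merge, scatter the
    variant caller into genomic shards, gather the gVCF, compress to CRAM."""
    return WorkflowSpec("gatk-like", (
        WorkflowStep("align-per-readgroup", "align-per-readgroup", "per-input", preemptible=True,
                     inputs_from="workflow"),
        WorkflowStep("merge", "merge"),
        WorkflowStep("scatter-variant-call", "scatter-variant-call", scatter_width,
                     preemptible=True),
        WorkflowStep("gather-gvcf", "gather-gvcf"),
        WorkflowStep("cram", "cram", inputs_from="merge"),
    ))


_RG_RE = re.compile(r"_RG(\d+)")


class LocalExecutor:
    """Runs mock tools against a watched directory; seeded fault injection.

    Callbacks:
      on_lifecycle(dict)  -- instance-insert / instance-delete events
      on_output(relpath, context)  -- each produced file, with its source job
                                      or workflow step identifiers
    """

    def __init__(self, root: str | Path, seed: int = 0,
                 failure_probability: float = 0.0,
                 preemption_probability: float = 0.0,
                 attempt_cap: int = 3,
                 clock: Callable[[], int] | None = None) -> None:
        self.root = Path(root)
        self.failure_probability = failure_probability
        self.preemption_probability = preemption_probability
        self.attempt_cap = attempt_cap
        self._rng = random.Random(seed)
        self._counter = itertools.count(1)
        self._wall = itertools.count(1)
        self.clock = clock or (lambda: next(self._wall))
        self.jobs: dict[str, JobRecord] = {}
        self._failed_once: set[tuple[str, str]] = set()
        self.on_lifecycle: list[Callable[[dict], None]] = []
        self.on_output: list[Callable[[str, dict], None]] = []

    # -- events ------------------------------------------------------------
    def _emit_lifecycle(self, job: JobRecord, kind: str) -> None:
        event = {
            "job_id": job.job_id, "kind": kind, "timestamp": self.clock(),
            "machine": job.config.machine,
            "network": "vpc-internal",
            "task": job.config.task,
        }
        for cb in self.on_lifecycle:
            cb(event)

    def _emit_output(self, relpath: str, context: dict) -> None:
        for cb in self.on_output:
            cb(relpath, context)

    # -- single tasks ------------------------------------------------------
    def launch_task(self, config: JobConfig) -> str:
        for rel in config.inputs:
            if not (self.root / rel).exists():
                raise ExecutorError(f"missing input {rel!r}")
        job_id = f"job-{next(self._counter):05d}"
        job = JobRecord(job_id, config, "running", self.clock())
        self.jobs[job_id] = job
        self._emit_lifecycle(job, "instance-insert")
        return job_id

    def launch_workflow(self, spec: WorkflowSpec, inputs: Iterable[str],
                        environment: dict[str, Any] | None = None) -> str:
        inputs = tuple(inputs)
        for rel in inputs:
            if not (self.root / rel).exists():
                raise ExecutorError(f"missing input {rel!r}")
        config = JobConfig(
            task=spec.name, image=f"mock/{spec.name}:1",
            command_template="cromwell run {task} {inputs}",
            inputs=inputs, output_dir=str(self.root),
            environment=dict(environment or {}), kind="cromwell-workflow")
        job_id = f"wf-{next(self._counter):05d}"
        job = JobRecord(job_id, config, "running", self.clock(), spec=spec)
        self.jobs[job_id] = job
        self._emit_lifecycle(job, "instance-insert")
        return job_id

    def complete(self, job_id: str) -> JobRecord:
        """Run the deferred job to its terminal state (no-op if cancelled)."""
        job = self._get(job_id)
        if job.status != "running":
            return job
        if job.spec is not None:
            self._run_workflow(job)
        else:
            self._run_task(job)
        self._emit_lifecycle(job, "instance-delete")
        return job

    def _inject_failure(self, config: JobConfig) -> bool:
        key = (config.task, config.input_digest)
        if key in self._failed_once:
            return False
        if self._rng.random() < self.failure_probability:
            self._failed_once.add(key)
            return True
        return False

    def _run_task(self, job: JobRecord) -> None:
        config = job.config
        if self._inject_failure(config):
            job.status = "failed"
            job.error = f"transient executor fault running {config.task}"
            job.stop_ts = self.clock()
            return
        try:
            tool = TASKS[config.task]
        except KeyError:
            job.status = "failed"
            job.error = f"unknown task {config.task!r}"
            job.stop_ts = self.clock()
            return
        try:
            outputs = tool(list(config.inputs), self.root, dict(config.environment))
        except Exception as exc:
            job.status = "failed"
            job.error = str(exc)
            job.stop_ts = self.clock()
            return
        job.outputs = [p.relative_to(self.root).as_posix() for p in outputs]
        job.status = "succeeded"
        job.stop_ts = self.clock()
        for rel in job.outputs:
            self._emit_output(rel, {"source_job_id": job.job_id, "task": config.task})

    # -- workflows ---------------------------------------------------------
    def _run_workflow(self, job: JobRecord) -> None:
        spec = job.spec
        assert spec is not None
        env = dict(job.config.environment)
        result = WorkflowResult(job.job_id, spec.name, "succeeded", job.config.inputs, [])
        produced: dict[str, list[str]] = {"workflow": list(job.config.inputs)}
        prev_step: str | None = None
        for step in spec.steps:
            source = step.inputs_from or prev_step or "workflow"
            step_inputs = produced[source]
            step_id = f"{job.job_id}/{step.name}"
            shards = self._shard_inputs(step, step_inputs)
            sres = StepResult(step_id, step.name, len(shards), [], [])
            failed = False
            for shard_idx, shard_inputs in enumerate(shards):
                params = dict(env)
                params["shard"] = shard_idx
                params["scatter_width"] = len(shards)
                if step.scatter == "per-input":
                    m = _RG_RE.search(shard_inputs[0])
                    params["read_group"] = int(m.group(1)) if m else shard_idx
                outputs, attempts = self._run_shard(step, step_id, shard_idx, shard_inputs, params)
                sres.attempts.extend(attempts)
                if outputs is None:
                    failed = True
                else:
                    sres.outputs.extend(outputs)
            result.steps.append(sres)
            if failed:
                result.status = "failed"
                break
            produced[step.name] = sres.outputs
            prev_step = step.name
        job.workflow = result
        job.status = result.status
        job.stop_ts = self.clock()
        if result.status == "failed":
            job.error = f"workflow step {result.steps[-1].name} exceeded attempt cap"
            return
        job.outputs = result.steps[-1].outputs if result.steps else []
        for sres in result.steps:
            for rel in sres.outputs:
                self._emit_output(rel, {
                    "source_step_id": sres.step_id, "source_workflow_id": job.job_id,
                    "task": sres.name})

    def _shard_inputs(self, step: WorkflowStep, inputs: list[str]) -> list[list[str]]:
        if step.scatter == "per-input":
            return [[rel] for rel in sorted(inputs)]
        if step.scatter == 1:
            return [sorted(inputs)]
        return [sorted(inputs) for _ in range(int(step.scatter))]

    def _run_shard(self, step: WorkflowStep, step_id: str, shard: int,
                   inputs: list[str], params: dict) -> tuple[list[str] | None, list[AttemptRecord]]:
        attempts: list[AttemptRecord] = []
        # preemption draws are capped below the attempt limit, so an injected
        # preemption storm never turns into a hard workflow failure
        n_preempt = 0
        if step.preemptible:
            while (n_preempt < self.attempt_cap - 1
                   and self._rng.random() < self.preemption_probability):
                n_preempt += 1
        for i in range(1, n_preempt + 1):
            start = self.clock()
            attempts.append(AttemptRecord(step.name, i, "preempted", start, self.clock(),
                                          f"{step_id}/shard{shard}/attempt{i}", shard))
        if n_preempt >= self.attempt_cap:
            return None, attempts
        start = self.clock()
        tool = TASKS[step.task]
        outputs = tool(list(inputs), self.root, params)
        rels = [p.relative_to(self.root).as_posix() for p in outputs]
        attempts.append(AttemptRecord(step.name, n_preempt + 1, "succeeded", start, self.clock(),
                                      f"{step_id}/shard{shard}/attempt{n_preempt + 1}", shard))
        return rels, attempts

    # -- control plane (dstat / ddel analogs) ------------------------------
    def _get(self, job_id: str) -> JobRecord:
        try:
            return self.jobs[job_id]
        except KeyError:
            raise ExecutorError(f"unknown job {job_id!r}") from None

    def check_status(self, job_id: str) -> tuple[str, str | None]:
        job = self._get(job_id)
        return job.status, job.error

    def cancel(self, job_id: str) -> bool:
        """Deactivate a running job; completed jobs cannot be cancelled."""
        job = self._get(job_id)
        if job.status == "running":
            job.status = "deactivated"
            job.stop_ts = self.clock()
            self._emit_lifecycle(job, "instance-delete")
            return True
        return False

    def pending_jobs(self) -> list[str]:
        return [jid for jid, job in self.jobs.items() if job.status == "running"]
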