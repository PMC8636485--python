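"""Job lifecycle bookkeeping, duplicate deactivation, and summary metrics.

Mirrors the monitoring tier of the production design: virtual-machine
lifecycle events (instance insert/delete) annotate job nodes with runtime
metadata; a dstat-style status check writes the terminal status (and error
text) onto the job node, which re-enters the trigger cycle so failure
triggers can react; a sweep detects jobs that duplicate the same
(task, input-set) key, cancels all but the earliest via the executor's
ddel-style interface and labels the rest ``Duplicate``; and a summary table
counts nodes, relationships, job statuses and completed samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import pandas as pd

from .datamodel import ESSENTIAL_TYPES
from .executor import ExecutorError, LocalExecutor
from .graphstore import GraphStore, N, Prop, Query, R

logger = logging.getLogger(__name__)


class MonitoringError(Exception):
    pass


@dataclass(frozen=True)
class LifecycleEvent:
    """VM lifecycle notification for a job."""

    job_id: str
    kind: str  # "instance-insert" | "instance-delete"
    timestamp: int
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("instance-insert", "instance-delete"):
            raise MonitoringError(f"unknown lifecycle kind {self.kind!r}")


def _lifecycle_query(event: LifecycleEvent) -> Query:
    props: dict[str, Any] = {k: event.metadata[k] for k in ("machine", "network")
                             if k in event.metadata}
    if event.kind == "instance-insert":
        props["start_ts"] = event.timestamp
    else:
        props["stop_ts"] = event.timestamp
    return (Query("lifecycle-update")
            .match(N("j", {"Job"}, {"job_id": event.job_id}))
            .set_props("j", props))


class Monitor:
    """Stateful monitoring service: parks early events, sweeps duplicates."""

    def __init__(self) -> None:
        self._parked: list[LifecycleEvent] = []
        self._seen_insert: set[str] = set()
        self.last_duplicate_report: list[dict[str, Any]] = []

    # -- lifecycle ---------------------------------------------------------
    def on_lifecycle_event(self, event: LifecycleEvent, store: GraphStore) -> Query | None:
        """Return the node-update query, or park the event until it can apply
        (job node not yet registered, or delete seen before insert)."""
        node_exists = bool(store.match(N("j", {"Job"}, {"job_id": event.job_id})))
        ordered = event.kind == "instance-insert" or event.job_id in self._seen_insert
        if not node_exists or not ordered:
            logger.warning("parking lifecycle event %s for %s", event.kind, event.job_id)
            self._parked.append(event)
            return None
        if event.kind == "instance-insert":
            self._seen_insert.add(event.job_id)
        return _lifecycle_query(event)

    def flush_parked(self, store: GraphStore) -> list[Query]:
        """Re-attempt parked events; call after job nodes are created."""
        still_parked: list[LifecycleEvent] = []
        queries: list[Query] = []
        # inserts first so delete-before-insert pairs resolve in one flush
        for event in sorted(self._parked, key=lambda e: (e.kind != "instance-insert", e.timestamp)):
            if store.match(N("j", {"Job"}, {"job_id": event.job_id})):
                if event.kind == "instance-insert":
                    self._seen_insert.add(event.job_id)
                    queries.append(_lifecycle_query(event))
                elif event.job_id in self._seen_insert:
                    queries.append(_lifecycle_query(event))
                else:
                    still_parked.append(event)
            else:
                still_parked.append(event)
        self._parked = still_parked
        return queries

    @property
    def parked_count(self) -> int:
        return len(self._parked)

    # -- status (dstat analog) ---------------------------------------------
    def check_status(self, job_id: str, executor: LocalExecutor) -> tuple[str, Query | None]:
        """Ask the executor for the job's status; if terminal, return the
        annotation query for the job node (running jobs are not annotated)."""
        status, error = executor.check_status(job_id)
        if status == "running":
            return status, None
        q = (Query("status-annotate")
             .match(N("j", {"Job"}, {"job_id": job_id}))
             .set_props("j", {"status": status, "error": error or ""}))
        return status, q

    # -- duplicate sweep ----------------------------------------------------
    def detect_and_deactivate_duplicates(
            self, store: GraphStore, executor: LocalExecutor,
            apply: Callable[[Query], Any] | None = None) -> list[dict[str, Any]]:
        """Group active jobs by (task, input-set digest); keep the earliest of
        each group (logical start time, then job id) and deactivate the rest.

        Idempotent: already-labelled duplicates are excluded from grouping.
        Returns the report rows; also retained on ``last_duplicate_report``.
        """
        apply = apply or store.run
        groups: dict[tuple[str, str], list[dict[str, Any]]] = {}
        for node in store.nodes():
            if "Job" not in node.labels or node.properties.get("duplicate"):
                continue
            # only *active* jobs compete for a key: a failed or deactivated job
            # holds no resources, and a retry legitimately reuses its key
            if node.properties.get("status") in ("deactivated", "failed"):
                continue
            p = node.properties
            key = (p.get("task", ""), p.get("input_digest", ""))
            groups.setdefault(key, []).append(p)
        report: list[dict[str, Any]] = []
        for (task, digest), jobs in sorted(groups.items()):
            if len(jobs) < 2:
                continue
            jobs.sort(key=lambda p: (p.get("start_ts", 0), p["job_id"]))
            kept, extras = jobs[0], jobs[1:]
            deactivated, failures = [], []
            for extra in extras:
                jid = extra["job_id"]
                try:
                    cancelled = executor.cancel(jid)
                except ExecutorError:
                    cancelled = False  # not tracked by this executor: nothing runs
                except Exception as exc:  # genuine cancel failure: retried next sweep
                    failures.append(jid)
                    logger.warning("cancel of %s failed: %s", jid, exc)
                    continue
                q = (Query("deactivate-duplicate")
                     .match(N("j", {"Job"}, {"job_id": jid}))
                     .add_label("j", "Duplicate")
                     .set_props("j", {"duplicate": True, "status": "deactivated"}))
                apply(q)
                deactivated.append(jid)
                if not cancelled:
                    logger.info("job %s already finished; record deactivated", jid)
            report.append({"task": task, "input_digest": digest,
                           "kept": kept["job_id"], "deactivated": deactivated,
                           "cancel_failures": failures})
        self.last_duplicate_report = report
        return report

    def write_duplicate_report(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("task\tinput_digest\tkept\tdeactivated\tcancel_failures\n")
            for row in self.last_duplicate_report:
                fh.write(f"{row['task']}\t{row['input_digest']}\t{row['kept']}\t"
                         f"{','.join(row['deactivated'])}\t{','.join(row['cancel_failures'])}\n")

    # -- summary -----------------------------------------------------------
    def summarize(self, store: GraphStore) -> pd.DataFrame:
        """Daily-style metrics table: deterministic given the graph state."""
        rows: list[tuple[str, str, int]] = []
        label_counts: dict[str, int] = {}
        status_counts: dict[str, int] = {}
        duplicates = 0
        for node in store.nodes():
            for label in node.labels:
                label_counts[label] = label_counts.get(label, 0) + 1
            if "Job" in node.labels:
                status_counts[node.properties.get("status", "unknown")] = \
                    status_counts.get(node.properties.get("status", "unknown"), 0) + 1
                if node.properties.get("duplicate"):
                    duplicates += 1
        rel_counts: dict[str, int] = {}
        for rel in store.relationships():
            rel_counts[rel.type] = rel_counts.get(rel.type, 0) + 1
        for label, count in sorted(label_counts.items()):
            rows.append(("nodes_by_label", label, count))
        for rtype, count in sorted(rel_counts.items()):
            rows.append(("relationships_by_type", rtype, count))
        for status, count in sorted(status_counts.items()):
            rows.append(("jobs_by_status", status, count))
        rows.append(("duplicates", "labelled", duplicates))
        rows.append(("samples", "complete", count_complete_samples(store)))
        rows.append(("samples", "total", label_counts.get("Sample", 0)))
        return pd.DataFrame(rows, columns=["section", "metric", "value"])

    def write_metrics(self, store: GraphStore, path: str) -> None:
        self.summarize(store).to_csv(path, index=False)


def count_complete_samples(store: GraphStore) -> int:
    """Samples whose genome carries every essential data type."""
    from .triggers import _DOMAIN_REL  # local import to avoid cycle at import time
    complete = 0
    for node in store.nodes():
        if "Genome" not in node.labels:
            continue
        ok = True
        for label in ESSENTIAL_TYPES:
            hit = store.match(N("g", {"Genome"}, {"sample_id": node.properties["sample_id"]}),
                              R(_DOMAIN_REL[label]), N("e", {label}))
            if not hit:
                ok = False
                break
        complete += ok
    return complete
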