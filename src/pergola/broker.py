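"""In-process topic broker with seeded at-least-once delivery semantics.

Cloud pub/sub brokers guarantee *at least* one delivery per message: handlers
must tolerate duplicates and reordering.  This broker reproduces exactly that
contract, deterministically, so the race conditions that produce duplicate
jobs in production can be replayed under a seed:

* every message is delivered >= 1 time;
* a :class:`DeliveryPolicy` injects bounded duplicate deliveries and bounded
  reordering from a seeded RNG;
* time is logical (a delivery-step counter), so interleavings are replayable;
* handlers may be generator functions that ``yield`` between their read-graph
  and write-graph phases; the scheduler interleaves other deliveries into that
  window — the exact mechanism by which a trigger query can act on stale state.

With ``duplicate_probability=0`` and ``reorder_window=0`` delivery order equals
publish order and every message is delivered exactly once.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Any, Callable, Iterator

Handler = Callable[["EventMessage"], Any]


class BrokerError(Exception):
    pass


class UnknownTopicError(BrokerError):
    pass


class DeliveryLimitExceeded(BrokerError):
    """Non-termination guard tripped."""


@dataclass(frozen=True)
class EventMessage:
    """Unit of communication between services."""

    message_id: str
    topic: str
    publish_time: int
    attempt: int
    body: dict[str, Any]
    trace: tuple[tuple[str, str], ...]  # (publisher service, message_id) ancestry


@dataclass(frozen=True)
class DeliveryPolicy:
    """Adversarial delivery knobs; the schedule is a pure function of
    (policy, publish sequence, handler behaviour)."""

    duplicate_probability: float = 0.0
    max_extra_deliveries: int = 0
    reorder_window: int = 0
    max_concurrent_handlers: int = 20
    seed: int = 0
    max_deliveries: int = 200_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.duplicate_probability <= 1.0:
            raise BrokerError("duplicate_probability must be in [0, 1]")
        if self.max_extra_deliveries < 0 or self.reorder_window < 0:
            raise BrokerError("negative policy bound")


@dataclass(frozen=True)
class DeliveryRecord:
    step: int
    message_id: str
    topic: str
    attempt: int
    outcome: str  # "handled" | "started" | "resumed" | "finished" | "error:<...>"


class DeliveryLog:
    def __init__(self) -> None:
        self.records: list[DeliveryRecord] = []

    def append(self, rec: DeliveryRecord) -> None:
        self.records.append(rec)

    def delivery_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            if rec.outcome in ("handled", "started"):
                counts[rec.message_id] = counts.get(rec.message_id, 0) + 1
        return counts

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.__dict__) + "\n")

    def dumps(self) -> str:
        return "\n".join(json.dumps(rec.__dict__) for rec in self.records)


@dataclass
class _Pending:
    message: EventMessage
    seq: int  # global ordering of scheduled deliveries


@dataclass
class _InFlight:
    message: EventMessage
    gen: Iterator[Any]


class Broker:
    """Topic registry, publish queue and the deterministic delivery loop."""

    def __init__(self) -> None:
        self._handlers: dict[str, Handler] = {}
        self._pending: list[_Pending] = []
        self._published: dict[str, EventMessage] = {}
        self._delivered: dict[str, int] = {}
        self._publish_counter = 0
        self._seq = 0
        self._clock = 0
        self.log = DeliveryLog()

    # -- registration ------------------------------------------------------
    def register_topic(self, topic: str, handler: Handler | None = None) -> None:
        self._handlers[topic] = handler or (lambda msg: None)

    @property
    def topics(self) -> list[str]:
        return sorted(self._handlers)

    @property
    def clock(self) -> int:
        """Logical time: delivery steps elapsed."""
        return self._clock

    def queue_length(self, topic: str | None = None) -> int:
        return sum(1 for p in self._pending if topic is None or p.message.topic == topic)

    def delivered(self, message_id: str) -> int:
        return self._delivered.get(message_id, 0)

    # -- publishing --------------------------------------------------------
    def publish(self, topic: str, body: dict[str, Any],
                parent: EventMessage | None = None, publisher: str = "anonymous") -> str:
        if topic not in self._handlers:
            raise UnknownTopicError(f"topic {topic!r} is not registered")
        self._publish_counter += 1
        mid = f"m{self._publish_counter:06d}"
        trace = (parent.trace if parent else ()) + ((publisher, mid),)
        msg = EventMessage(mid, topic, self._clock, 1, dict(body), trace)
        self._published[mid] = msg
        self._pending.append(_Pending(msg, self._next_seq()))
        return mid

    def _next_seq(self) -> int:
        self._seq += 1
        return self._seq

    def _schedule_duplicates(self, rng: random.Random, policy: DeliveryPolicy,
                             msg: EventMessage) -> None:
        extras = sum(rng.random() < policy.duplicate_probability
                     for _ in range(policy.max_extra_deliveries))
        for i in range(extras):
            dup = EventMessage(msg.message_id, msg.topic, msg.publish_time,
                               msg.attempt + 1 + i, msg.body, msg.trace)
            self._pending.append(_Pending(dup, self._next_seq()))

    # -- the loop ----------------------------------------------------------
    def run_until_quiescent(self, policy: DeliveryPolicy | None = None) -> DeliveryLog:
        """Deliver until no message is pending and no handler is mid-flight.

        Returns the delivery log.  Raises :class:`DeliveryLimitExceeded` if the
        configured maximum delivery count is hit (a cycle of handlers endlessly
        republishing would otherwise never quiesce).
        """
        policy = policy or DeliveryPolicy()
        rng = random.Random(policy.seed)
        in_flight: list[_InFlight] = []
        per_topic: dict[str, int] = {}
        steps = 0

        while self._pending or in_flight:
            steps += 1
            if steps > policy.max_deliveries:
                raise DeliveryLimitExceeded(f"exceeded {policy.max_deliveries} delivery steps")
            self._clock += 1

            # candidate actions: resume an in-flight handler, or start a
            # delivery from the head reorder window (respecting topic caps)
            startable: list[int] = []
            self._pending.sort(key=lambda p: p.seq)
            for idx, p in enumerate(self._pending[: policy.reorder_window + 1]):
                if per_topic.get(p.message.topic, 0) < policy.max_concurrent_handlers:
                    startable.append(idx)
            actions: list[tuple[str, int]] = [("resume", i) for i in range(len(in_flight))]
            actions += [("start", i) for i in startable]
            if not actions:
                raise BrokerError("deadlock: pending messages but topic concurrency exhausted")
            kind, idx = actions[rng.randrange(len(actions))] if len(actions) > 1 else actions[0]

            if kind == "start":
                pend = self._pending.pop(idx)
                msg = pend.message
                self._delivered[msg.message_id] = self._delivered.get(msg.message_id, 0) + 1
                if msg.attempt == 1:
                    self._schedule_duplicates(rng, policy, msg)
                handler = self._handlers[msg.topic]
                try:
                    result = handler(msg)
                except Exception as exc:  # handler errors are recorded, not fatal
                    self.log.append(DeliveryRecord(self._clock, msg.message_id, msg.topic,
                                                   msg.attempt, f"error:{type(exc).__name__}"))
                    continue
                if hasattr(result, "__next__"):
                    gen: Iterator[Any] = result
                    try:
                        next(gen)
                    except StopIteration:
                        self.log.append(DeliveryRecord(self._clock, msg.message_id, msg.topic,
                                                       msg.attempt, "handled"))
                        continue
                    per_topic[msg.topic] = per_topic.get(msg.topic, 0) + 1
                    in_flight.append(_InFlight(msg, gen))
                    self.log.append(DeliveryRecord(self._clock, msg.message_id, msg.topic,
                                                   msg.attempt, "started"))
                else:
                    self.log.append(DeliveryRecord(self._clock, msg.message_id, msg.topic,
                                                   msg.attempt, "handled"))
            else:
                flight = in_flight[idx]
                try:
                    next(flight.gen)
                    self.log.append(DeliveryRecord(self._clock, flight.message.message_id,
                                                   flight.message.topic, flight.message.attempt,
                                                   "resumed"))
                except StopIteration:
                    in_flight.pop(idx)
                    per_topic[flight.message.topic] -= 1
                    self.log.append(DeliveryRecord(self._clock, flight.message.message_id,
                                                   flight.message.topic, flight.message.attempt,
                                                   "finished"))
                except Exception as exc:
                    in_flight.pop(idx)
                    per_topic[flight.message.topic] -= 1
                    self.log.append(DeliveryRecord(self._clock, flight.message.message_id,
                                                   flight.message.topic, flight.message.attempt,
                                                   f"error:{type(exc).__name__}"))
        return self.log

    # -- audit -------------------------------------------------------------
    def undelivered(self) -> list[str]:
        return [mid for mid, msg in self._published.items() if self.delivered(mid) == 0]

    def trace_chain(self, message_id: str) -> list[str]:
        """Ancestry of a message: publisher message ids from root to leaf."""
        msg = self._published.get(message_id)
        if msg is None:
            raise BrokerError(f"unknown message {message_id!r}")
        return [mid for _, mid in msg.trace]
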