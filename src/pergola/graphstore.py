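"""Embedded labelled property graph with merge semantics and pattern matching.

This is the stateful hub of the orchestration engine: every data object, job
and biological entity is a node, every provenance or functional-domain link a
directed relationship, and all workflow coordination is expressed as queries
against this store.  The model is the labelled property graph popularised by
Neo4j: nodes carry a non-empty set of string labels plus key:value properties
(scalars or lists of scalars); relationships carry an UPPER_SNAKE type and
properties.

The query surface is deliberately small.  Instead of a Cypher parser there is
a structured clause pipeline (:class:`Query`) covering the repertoire that
metadata-conditioned triggers actually need: fixed-length path matching with
label and property predicates, absence guards, grouping/aggregation
(count/collect), and write clauses (merge node with a created flag, merge
relationship, set, add-label, soft delete) that execute atomically with the
match.  Soft deletion hides nodes from trigger-driving matches while keeping
them reachable for provenance traversals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import Any, Iterable, Iterator, Mapping, Sequence

import networkx as nx

Scalar = str | int | float | bool | None
PropertyMap = dict[str, Any]


class GraphError(Exception):
    """Base class for graph store errors."""


class ConstraintViolation(GraphError):
    """A registered uniqueness key would be duplicated."""


class UnknownNodeError(GraphError):
    """Referenced node id does not exist."""


class AmbiguousMergeError(GraphError):
    """More than one pre-existing node matches a merge key."""


class PatternError(GraphError):
    """Malformed pattern or query."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeRecord:
    id: int
    labels: frozenset[str]
    properties: PropertyMap
    deleted: bool = False


@dataclass(frozen=True)
class RelationshipRecord:
    id: int
    type: str
    start_id: int
    end_id: int
    properties: PropertyMap


@dataclass(frozen=True)
class MergeResult:
    """Outcome of a merge: the node id plus whether the call created it.

    The ``created`` flag is the binary property that makes merge-based
    semaphores work: only the caller that actually created the node may
    proceed to launch a job.
    """

    node_id: int
    created: bool


@dataclass(frozen=True)
class LineagePath:
    """Alternating node/relationship path returned by lineage traversal."""

    node_ids: tuple[int, ...]
    relationship_ids: tuple[int, ...]

    def __len__(self) -> int:  # number of hops
        return len(self.relationship_ids)


# ---------------------------------------------------------------------------
# Expressions (used in predicates, merge keys and return items)
# ---------------------------------------------------------------------------


class Expr:
    """Marker base class for query expressions."""


@dataclass(frozen=True)
class Const(Expr):
    value: Any


@dataclass(frozen=True)
class Ref(Expr):
    """A binding from the current row (a matched var or aggregate name)."""

    name: str


@dataclass(frozen=True)
class Prop(Expr):
    """Property lookup on a bound node variable."""

    var: str
    key: str


@dataclass(frozen=True)
class Fn(Expr):
    """Built-in function application: len, sorted, digest, labels."""

    name: str
    args: tuple[Expr, ...]


def _as_expr(value: Any) -> Expr:
    return value if isinstance(value, Expr) else Const(value)


def input_digest(items: Iterable[Any]) -> str:
    """Stable digest of a collection of input keys (order-insensitive)."""
    blob = json.dumps(sorted(str(x) for x in items))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Cmp(Expr):
    """Binary comparison; ops: eq ne lt le gt ge in contains."""

    op: str
    left: Expr
    right: Expr


@dataclass(frozen=True)
class BoolOp(Expr):
    op: str  # "and" | "or" | "not"
    args: tuple[Expr, ...]


# ---------------------------------------------------------------------------
# Pattern elements
# ---------------------------------------------------------------------------

_MISSING = object()


@dataclass(frozen=True)
class N:
    """Node constraint: variable name, required labels, property predicates.

    ``where`` values are either plain scalars (equality) or ``(op, value)``
    tuples with op in {eq, ne, lt, le, gt, ge, in, contains, exists}.
    """

    var: str
    labels: frozenset[str] = frozenset()
    where: tuple[tuple[str, Any], ...] = ()

    def __init__(self, var: str, labels: Iterable[str] = (), where: Mapping[str, Any] | None = None):
        object.__setattr__(self, "var", var)
        object.__setattr__(self, "labels", frozenset(labels))
        object.__setattr__(self, "where", tuple(sorted((where or {}).items())))


@dataclass(frozen=True)
class R:
    """Relationship constraint: type(s) and direction relative to reading order.

    direction "out" means the edge points from the preceding node constraint to
    the following one; "in" the reverse; "any" matches either.
    """

    types: frozenset[str]
    direction: str = "out"
    var: str | None = None

    def __init__(self, types: str | Iterable[str], direction: str = "out", var: str | None = None):
        if isinstance(types, str):
            types = (types,)
        if direction not in ("out", "in", "any"):
            raise PatternError(f"bad direction {direction!r}")
        object.__setattr__(self, "types", frozenset(types))
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "var", var)


GraphPattern = Sequence[N | R]


def _check_alternation(elements: GraphPattern) -> None:
    if not elements or not isinstance(elements[0], N):
        raise PatternError("pattern must start with a node constraint")
    expect_node = False
    for el in elements[1:]:
        if expect_node and not isinstance(el, N):
            raise PatternError("pattern must alternate node and relationship constraints")
        if not expect_node and not isinstance(el, R):
            raise PatternError("pattern must alternate node and relationship constraints")
        expect_node = not expect_node
    if not isinstance(elements[-1], N):
        raise PatternError("pattern must end with a node constraint")


# ---------------------------------------------------------------------------
# Query clauses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchClause:
    elements: tuple[N | R, ...]
    absent: bool = False  # keep rows where the pattern has NO match (guard)
    optional: bool = False
    include_deleted: bool = False


@dataclass(frozen=True)
class WhereClause:
    cond: Expr


@dataclass(frozen=True)
class AggregateClause:
    """Group rows and bind aggregate values.

    ``group`` maps output names to expressions; ``aggs`` maps output names to
    (kind, expr) with kind in {count, count_distinct, collect, collect_distinct}.
    With no group keys and zero input rows a single all-empty row is produced
    (count = 0), matching the usual aggregate-query convention.
    """

    group: tuple[tuple[str, Expr], ...]
    aggs: tuple[tuple[str, tuple[str, Expr]], ...]


@dataclass(frozen=True)
class MergeNodeClause:
    var: str
    labels: frozenset[str]
    key: tuple[tuple[str, Expr], ...]
    on_create: tuple[tuple[str, Expr], ...] = ()
    on_match: tuple[tuple[str, Expr], ...] = ()


@dataclass(frozen=True)
class CreateNodeClause:
    """Unconditional node creation (no merge); used by the naive, race-prone
    semaphore mode that reproduces pre-fix behaviour."""

    var: str
    labels: frozenset[str]
    props: tuple[tuple[str, Expr], ...]


@dataclass(frozen=True)
class MergeRelClause:
    start_var: str
    rtype: str
    end_var: str
    props: tuple[tuple[str, Expr], ...] = ()


@dataclass(frozen=True)
class SetClause:
    var: str
    props: tuple[tuple[str, Expr], ...]


@dataclass(frozen=True)
class AddLabelClause:
    var: str
    label: str


@dataclass(frozen=True)
class MarkDeletedClause:
    var: str


@dataclass(frozen=True)
class FilterCreatedClause:
    """Keep only rows whose preceding merge actually created the node —
    the merge-semaphore gate."""

    var: str


@dataclass(frozen=True)
class ReturnClause:
    items: tuple[tuple[str, Expr], ...]


_WRITE_CLAUSES = (
    MergeNodeClause,
    CreateNodeClause,
    MergeRelClause,
    SetClause,
    AddLabelClause,
    MarkDeletedClause,
)


class Query:
    """A clause pipeline executed against the store.

    Built fluently::

        q = (Query("launch-check")
             .match(N("u", {"Ubam"}, {"sample_id": "S001"}))
             .aggregate(aggs={"paths": ("collect", Prop("u", "path"))})
             .merge_node("req", {"JobRequest"},
                         key={"task": "gatk", "input_key": Fn("digest", (Ref("paths"),))})
             .filter_created("req")
             .returns(paths=Ref("paths")))

    The read prefix (match/where/aggregate before the first write clause) can
    be executed separately from the write suffix; an engine running in naive
    mode exploits this to reproduce the read-then-write race window, while the
    default mode runs the whole pipeline atomically.
    """

    def __init__(self, name: str = "query"):
        self.name = name
        self.clauses: list[Any] = []

    # -- builders ----------------------------------------------------------
    def match(self, *elements: N | R, absent: bool = False, optional: bool = False,
              include_deleted: bool = False) -> "Query":
        _check_alternation(elements)
        self.clauses.append(MatchClause(tuple(elements), absent, optional, include_deleted))
        return self

    def where(self, cond: Expr) -> "Query":
        self.clauses.append(WhereClause(cond))
        return self

    def aggregate(self, group: Mapping[str, Expr] | None = None,
                  aggs: Mapping[str, tuple[str, Expr]] | None = None) -> "Query":
        self.clauses.append(AggregateClause(
            tuple((k, _as_expr(v)) for k, v in (group or {}).items()),
            tuple((k, (kind, _as_expr(e))) for k, (kind, e) in (aggs or {}).items()),
        ))
        return self

    def merge_node(self, var: str, labels: Iterable[str], key: Mapping[str, Any],
                   on_create: Mapping[str, Any] | None = None,
                   on_match: Mapping[str, Any] | None = None) -> "Query":
        self.clauses.append(MergeNodeClause(
            var, frozenset(labels),
            tuple((k, _as_expr(v)) for k, v in key.items()),
            tuple((k, _as_expr(v)) for k, v in (on_create or {}).items()),
            tuple((k, _as_expr(v)) for k, v in (on_match or {}).items()),
        ))
        return self

    def create_node(self, var: str, labels: Iterable[str], props: Mapping[str, Any]) -> "Query":
        self.clauses.append(CreateNodeClause(
            var, frozenset(labels), tuple((k, _as_expr(v)) for k, v in props.items())))
        return self

    def merge_rel(self, start_var: str, rtype: str, end_var: str,
                  props: Mapping[str, Any] | None = None) -> "Query":
        self.clauses.append(MergeRelClause(
            start_var, rtype, end_var, tuple((k, _as_expr(v)) for k, v in (props or {}).items())))
        return self

    def set_props(self, var: str, props: Mapping[str, Any]) -> "Query":
        self.clauses.append(SetClause(var, tuple((k, _as_expr(v)) for k, v in props.items())))
        return self

    def add_label(self, var: str, label: str) -> "Query":
        self.clauses.append(AddLabelClause(var, label))
        return self

    def mark_deleted(self, var: str) -> "Query":
        self.clauses.append(MarkDeletedClause(var))
        return self

    def filter_created(self, var: str) -> "Query":
        self.clauses.append(FilterCreatedClause(var))
        return self

    def returns(self, **items: Any) -> "Query":
        self.clauses.append(ReturnClause(tuple((k, _as_expr(v)) for k, v in items.items())))
        return self

    # -- introspection -----------------------------------------------------
    @property
    def has_writes(self) -> bool:
        return any(isinstance(c, _WRITE_CLAUSES) for c in self.clauses)

    def split_read_write(self) -> tuple[list[Any], list[Any]]:
        """Split at the first write clause (for the naive two-phase mode)."""
        for i, c in enumerate(self.clauses):
            if isinstance(c, _WRITE_CLAUSES):
                return self.clauses[:i], self.clauses[i:]
        return list(self.clauses), []


# ---------------------------------------------------------------------------
# The store
# ---------------------------------------------------------------------------


class GraphStore:
    """In-memory labelled property graph with per-label uniqueness keys."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._next_node = 1
        self._next_rel = 1
        self._unique: dict[str, tuple[str, ...]] = {}
        self._journal: list[tuple[int, str]] | None = None

    # -- change journal ----------------------------------------------------
    def begin_journal(self) -> None:
        """Start recording created/updated node ids (used by the query
        service to forward metadata of touched nodes to the trigger checker).
        Updates are recorded only when a property value actually changes, so
        idempotent re-runs of a merge produce an empty journal."""
        self._journal = []

    def take_journal(self) -> list[tuple[int, str]]:
        journal, self._journal = self._journal or [], None
        seen: set[int] = set()
        out = []
        for nid, kind in journal:
            if nid not in seen:
                seen.add(nid)
                out.append((nid, kind))
        return out

    def _record(self, nid: int, kind: str) -> None:
        if self._journal is not None:
            self._journal.append((nid, kind))

    # -- constraints -------------------------------------------------------
    def register_unique(self, label: str, properties: Sequence[str]) -> None:
        """Register a uniqueness key: at most one node with `label` may carry
        any given value combination of `properties`."""
        self._unique[label] = tuple(properties)

    def _key_of(self, label: str, labels: Iterable[str], props: Mapping[str, Any]):
        keyprops = self._unique.get(label)
        if keyprops is None or label not in labels:
            return None
        if any(p not in props for p in keyprops):
            return None
        return tuple(_hashable(props[p]) for p in keyprops)

    def _find_unique_conflicts(self, labels: Iterable[str], props: Mapping[str, Any],
                               exclude: int | None = None) -> list[int]:
        hits: list[int] = []
        for label in labels:
            key = self._key_of(label, labels, props)
            if key is None:
                continue
            for nid, data in self._g.nodes(data=True):
                if nid == exclude or label not in data["labels"]:
                    continue
                other = self._key_of(label, data["labels"], data["props"])
                if other == key:
                    hits.append(nid)
        return hits

    # -- node / relationship primitives ------------------------------------
    def create_node(self, labels: Iterable[str], properties: Mapping[str, Any] | None = None) -> NodeRecord:
        labels = frozenset(labels)
        if not labels:
            raise GraphError("node must carry at least one label")
        props = dict(properties or {})
        conflicts = self._find_unique_conflicts(labels, props)
        if conflicts:
            raise ConstraintViolation(
                f"uniqueness violation on labels {sorted(labels)} against node(s) {conflicts}")
        nid = self._next_node
        self._next_node += 1
        self._g.add_node(nid, labels=set(labels), props=props, deleted=False)
        self._record(nid, "created")
        return self.node(nid)

    def merge_node(self, key_labels: Iterable[str], key_properties: Mapping[str, Any],
                   on_create: Mapping[str, Any] | None = None,
                   on_match: Mapping[str, Any] | None = None) -> MergeResult:
        key_labels = frozenset(key_labels)
        if not key_labels:
            raise GraphError("merge requires at least one key label")
        if not key_properties:
            raise GraphError("merge requires non-empty key properties")
        matches = [
            nid for nid, data in self._g.nodes(data=True)
            if key_labels <= data["labels"]
            and all(data["props"].get(k, _MISSING) == v for k, v in key_properties.items())
        ]
        if len(matches) > 1:
            raise AmbiguousMergeError(
                f"merge key {dict(key_properties)} on {sorted(key_labels)} matches {len(matches)} nodes")
        if matches:
            nid = matches[0]
            if on_match:
                self.set_properties(nid, on_match)
            return MergeResult(nid, created=False)
        props = dict(key_properties)
        if on_create:
            props.update(on_create)
        rec = self.create_node(key_labels, props)
        return MergeResult(rec.id, created=True)

    def merge_relationship(self, start_id: int, rtype: str, end_id: int,
                           properties: Mapping[str, Any] | None = None) -> RelationshipRecord:
        for nid in (start_id, end_id):
            if nid not in self._g:
                raise UnknownNodeError(f"node {nid} does not exist")
        for _, _, key, data in self._g.out_edges(start_id, keys=True, data=True):
            if key[0] == rtype and key[1] == end_id:
                if properties:
                    data["props"].update(properties)
                return RelationshipRecord(data["rid"], rtype, start_id, end_id, dict(data["props"]))
        rid = self._next_rel
        self._next_rel += 1
        self._g.add_edge(start_id, end_id, key=(rtype, end_id, rid),
                         rid=rid, rtype=rtype, props=dict(properties or {}))
        return RelationshipRecord(rid, rtype, start_id, end_id, dict(properties or {}))

    def node(self, nid: int) -> NodeRecord:
        if nid not in self._g:
            raise UnknownNodeError(f"node {nid} does not exist")
        d = self._g.nodes[nid]
        return NodeRecord(nid, frozenset(d["labels"]), dict(d["props"]), d["deleted"])

    def nodes(self, include_deleted: bool = True) -> Iterator[NodeRecord]:
        for nid in sorted(self._g.nodes):
            rec = self.node(nid)
            if include_deleted or not rec.deleted:
                yield rec

    def relationships(self) -> Iterator[RelationshipRecord]:
        recs = [
            RelationshipRecord(d["rid"], d["rtype"], u, v, dict(d["props"]))
            for u, v, d in self._g.edges(data=True)
        ]
        return iter(sorted(recs, key=lambda r: r.id))

    def set_properties(self, nid: int, props: Mapping[str, Any]) -> None:
        if nid not in self._g:
            raise UnknownNodeError(f"node {nid} does not exist")
        current = self._g.nodes[nid]["props"]
        if any(current.get(k, _MISSING) != v for k, v in props.items()):
            self._record(nid, "updated")
        current.update(props)

    def add_label(self, nid: int, label: str) -> None:
        if nid not in self._g:
            raise UnknownNodeError(f"node {nid} does not exist")
        if label not in self._g.nodes[nid]["labels"]:
            self._record(nid, "updated")
        self._g.nodes[nid]["labels"].add(label)

    def mark_deleted(self, node_ids: Iterable[int]) -> int:
        """Soft-delete: flag nodes so default matches skip them.  Relationships
        are untouched and lineage traversal still reaches flagged nodes.
        Returns the number of newly flagged nodes."""
        count = 0
        for nid in node_ids:
            if nid not in self._g:
                raise UnknownNodeError(f"node {nid} does not exist")
            if not self._g.nodes[nid]["deleted"]:
                self._g.nodes[nid]["deleted"] = True
                count += 1
        return count

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def relationship_count(self) -> int:
        return self._g.number_of_edges()

    # -- matching ----------------------------------------------------------
    def match(self, *elements: N | R, include_deleted: bool = False) -> list[dict[str, Any]]:
        """Enumerate all bindings of a single pattern (read-only)."""
        _check_alternation(elements)
        return self._expand_pattern({}, tuple(elements), include_deleted)

    def run(self, query: Query) -> list[dict[str, Any]]:
        """Execute a full clause pipeline atomically; returns result rows."""
        rows = self._run_clauses([{}], query.clauses)
        return rows

    def run_clauses(self, rows: list[dict[str, Any]], clauses: Sequence[Any]) -> list[dict[str, Any]]:
        """Execute a clause sub-sequence starting from pre-bound rows.

        Exposed so an engine can split a query into a read phase and a write
        phase with other work interleaved between them (the naive mode that
        reproduces duplicate-job races)."""
        return self._run_clauses(rows, clauses)

    def _run_clauses(self, rows: list[dict[str, Any]], clauses: Sequence[Any]) -> list[dict[str, Any]]:
        for clause in clauses:
            rows = self._apply_clause(rows, clause)
        return rows

    def _apply_clause(self, rows: list[dict[str, Any]], clause: Any) -> list[dict[str, Any]]:
        if isinstance(clause, MatchClause):
            out: list[dict[str, Any]] = []
            for row in rows:
                found = self._expand_pattern(row, clause.elements, clause.include_deleted)
                if clause.absent:
                    if not found:
                        out.append(row)
                elif clause.optional and not found:
                    out.append(row)
                else:
                    out.extend(found)
            return out
        if isinstance(clause, WhereClause):
            out = []
            for r in rows:
                try:
                    keep = self._eval(clause.cond, r)
                except PatternError:  # unbound optional binding: null predicate
                    keep = False
                if keep:
                    out.append(r)
            return out
        if isinstance(clause, AggregateClause):
            return self._aggregate(rows, clause)
        if isinstance(clause, MergeNodeClause):
            for row in rows:
                key = {k: self._eval(e, row) for k, e in clause.key}
                oc = {k: self._eval(e, row) for k, e in clause.on_create}
                om = {k: self._eval(e, row) for k, e in clause.on_match}
                res = self.merge_node(clause.labels, key, oc, om)
                row[clause.var] = res.node_id
                row[f"{clause.var}__created"] = res.created
            return rows
        if isinstance(clause, CreateNodeClause):
            for row in rows:
                props = {k: self._eval(e, row) for k, e in clause.props}
                rec = self.create_node(clause.labels, props)
                row[clause.var] = rec.id
                row[f"{clause.var}__created"] = True
            return rows
        if isinstance(clause, MergeRelClause):
            for row in rows:
                if clause.start_var not in row or clause.end_var not in row:
                    continue  # optional-match semantics
                props = {k: self._eval(e, row) for k, e in clause.props}
                self.merge_relationship(row[clause.start_var], clause.rtype, row[clause.end_var], props)
            return rows
        if isinstance(clause, SetClause):
            for row in rows:
                if clause.var not in row:
                    continue
                self.set_properties(row[clause.var], {k: self._eval(e, row) for k, e in clause.props})
            return rows
        if isinstance(clause, AddLabelClause):
            for row in rows:
                if clause.var not in row:
                    continue
                self.add_label(row[clause.var], clause.label)
            return rows
        if isinstance(clause, MarkDeletedClause):
            for row in rows:
                if clause.var not in row:
                    continue
                self.mark_deleted([row[clause.var]])
            return rows
        if isinstance(clause, FilterCreatedClause):
            return [r for r in rows if r.get(f"{clause.var}__created")]
        if isinstance(clause, ReturnClause):
            return [{k: self._eval(e, r) for k, e in clause.items} for r in rows]
        raise PatternError(f"unknown clause {clause!r}")

    def _node_ok(self, nid: int, nc: N, include_deleted: bool,
                 row: Mapping[str, Any] | None = None) -> bool:
        data = self._g.nodes[nid]
        if data["deleted"] and not include_deleted:
            return False
        if not nc.labels <= data["labels"]:
            return False
        props = data["props"]
        for key, pred in nc.where:
            op, value = pred if isinstance(pred, tuple) else ("eq", pred)
            if isinstance(value, Expr):
                value = self._eval(value, row or {})
            have = props.get(key, _MISSING)
            if op == "exists":
                if (have is not _MISSING) != bool(value):
                    return False
                continue
            if have is _MISSING:
                return False
            if not _compare(op, have, value):
                return False
        return True

    def _expand_pattern(self, row: dict[str, Any], elements: tuple[N | R, ...],
                        include_deleted: bool) -> list[dict[str, Any]]:
        nc0 = elements[0]
        assert isinstance(nc0, N)
        if nc0.var in row:
            starts = [row[nc0.var]] if self._node_ok(row[nc0.var], nc0, True, row) else []
        else:
            starts = [nid for nid in sorted(self._g.nodes)
                      if self._node_ok(nid, nc0, include_deleted, row)]
        results: list[dict[str, Any]] = []

        def step(current: int, idx: int, binding: dict[str, Any]) -> None:
            if idx >= len(elements):
                results.append(binding)
                return
            rc, nc = elements[idx], elements[idx + 1]
            assert isinstance(rc, R) and isinstance(nc, N)
            for rid, other in self._adjacent(current, rc):
                if nc.var in binding:
                    if binding[nc.var] != other or not self._node_ok(other, nc, True, binding):
                        continue
                    nb = dict(binding)
                elif not self._node_ok(other, nc, include_deleted, binding):
                    continue
                else:
                    nb = dict(binding)
                    nb[nc.var] = other
                if rc.var:
                    nb[rc.var] = rid
                step(other, idx + 2, nb)

        for s in starts:
            b = dict(row)
            b[nc0.var] = s
            step(s, 1, b)
        return results

    def _adjacent(self, nid: int, rc: R) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        if rc.direction in ("out", "any"):
            for _, v, d in self._g.out_edges(nid, data=True):
                if d["rtype"] in rc.types:
                    out.append((d["rid"], v))
        if rc.direction in ("in", "any"):
            for u, _, d in self._g.in_edges(nid, data=True):
                if d["rtype"] in rc.types:
                    out.append((d["rid"], u))
        return sorted(out)

    # -- expression evaluation ---------------------------------------------
    def _eval(self, expr: Expr, row: Mapping[str, Any]) -> Any:
        if isinstance(expr, Const):
            return expr.value
        if isinstance(expr, Ref):
            if expr.name not in row:
                raise PatternError(f"unbound reference {expr.name!r}")
            return row[expr.name]
        if isinstance(expr, Prop):
            if expr.var not in row:
                raise PatternError(f"unbound variable {expr.var!r}")
            return self._g.nodes[row[expr.var]]["props"].get(expr.key)
        if isinstance(expr, Fn):
            args = [self._eval(a, row) for a in expr.args]
            if expr.name == "len":
                return len(args[0])
            if expr.name == "sorted":
                return sorted(args[0])
            if expr.name == "digest":
                return input_digest(args[0])
            if expr.name == "add":
                return sum(a or 0 for a in args)
            if expr.name == "labels":
                return sorted(self._g.nodes[args[0]]["labels"])
            raise PatternError(f"unknown function {expr.name!r}")
        if isinstance(expr, Cmp):
            return _compare(expr.op, self._eval(expr.left, row), self._eval(expr.right, row))
        if isinstance(expr, BoolOp):
            vals = (self._eval(a, row) for a in expr.args)
            if expr.op == "and":
                return all(vals)
            if expr.op == "or":
                return any(vals)
            if expr.op == "not":
                return not next(vals)
        raise PatternError(f"cannot evaluate {expr!r}")

    def _aggregate(self, rows: list[dict[str, Any]], clause: AggregateClause) -> list[dict[str, Any]]:
        groups: dict[tuple, list[dict[str, Any]]] = {}
        for row in rows:
            key = tuple(_hashable(self._eval(e, row)) for _, e in clause.group)
            groups.setdefault(key, []).append(row)
        if not groups and not clause.group:
            groups[()] = []
        out = []
        for key, members in sorted(groups.items(), key=lambda kv: repr(kv[0])):
            newrow: dict[str, Any] = {name: value for (name, _), value in zip(clause.group, key)}
            for name, (kind, e) in clause.aggs:
                values = [self._eval(e, m) for m in members]
                if kind == "count":
                    newrow[name] = len(values)
                elif kind == "count_distinct":
                    newrow[name] = len({_hashable(v) for v in values})
                elif kind == "collect":
                    newrow[name] = sorted(values, key=repr)
                elif kind == "collect_distinct":
                    newrow[name] = sorted({_hashable(v) for v in values}, key=repr)
                else:
                    raise PatternError(f"unknown aggregate {kind!r}")
            out.append(newrow)
        return out

    # -- lineage -----------------------------------------------------------
    def traverse_lineage(self, node_id: int, relationship_types: Iterable[str],
                         direction: str = "upstream",
                         include_deleted: bool = True) -> list[LineagePath]:
        """All maximal paths from ``node_id`` along the given relationship
        types.  ``upstream`` walks edges against their direction (towards
        origins: a blob's generating job, that job's inputs, ... back to the
        sample); ``downstream`` walks with them.  Terminal nodes have no
        further edge of the requested types in the travel direction."""
        if node_id not in self._g:
            raise UnknownNodeError(f"node {node_id} does not exist")
        if direction not in ("upstream", "downstream"):
            raise GraphError(f"bad direction {direction!r}")
        rtypes = frozenset(relationship_types)
        rc = R(rtypes, "in" if direction == "upstream" else "out")
        paths: list[LineagePath] = []

        def walk(current: int, nodes: tuple[int, ...], rels: tuple[int, ...]) -> None:
            nxt = [
                (rid, other) for rid, other in self._adjacent(current, rc)
                if other not in nodes  # cycle guard
                and (include_deleted or not self._g.nodes[other]["deleted"])
            ]
            if not nxt:
                paths.append(LineagePath(nodes, rels))
                return
            for rid, other in nxt:
                walk(other, nodes + (other,), rels + (rid,))

        walk(node_id, (node_id,), ())
        return paths

    # -- serialization ------------------------------------------------------
    def to_jsonl(self, path: str | FsPath) -> None:
        with open(path, "w") as fh:
            for label, props in sorted(self._unique.items()):
                fh.write(json.dumps({"kind": "unique", "label": label, "properties": list(props)}) + "\n")
            for rec in self.nodes():
                fh.write(json.dumps({
                    "kind": "node", "id": rec.id, "labels": sorted(rec.labels),
                    "properties": rec.properties, "deleted": rec.deleted}) + "\n")
            for rel in self.relationships():
                fh.write(json.dumps({
                    "kind": "rel", "id": rel.id, "type": rel.type,
                    "start": rel.start_id, "end": rel.end_id, "properties": rel.properties}) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | FsPath) -> "GraphStore":
        store = cls()
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                if rec["kind"] == "unique":
                    store.register_unique(rec["label"], rec["properties"])
                elif rec["kind"] == "node":
                    store._g.add_node(rec["id"], labels=set(rec["labels"]),
                                      props=dict(rec["properties"]), deleted=rec["deleted"])
                    store._next_node = max(store._next_node, rec["id"] + 1)
                else:
                    store._g.add_edge(rec["start"], rec["end"],
                                      key=(rec["type"], rec["end"], rec["id"]),
                                      rid=rec["id"], rtype=rec["type"],
                                      props=dict(rec["properties"]))
                    store._next_rel = max(store._next_rel, rec["id"] + 1)
        return store

    def fingerprint(self) -> str:
        """Canonical digest of graph content, ignoring internal ids — two
        stores with the same nodes (labels+properties) and relationships are
        fingerprint-equal.  Used by replay-idempotency checks."""
        def nodesig(rec: NodeRecord) -> str:
            return json.dumps([sorted(rec.labels),
                               sorted((k, repr(v)) for k, v in rec.properties.items()),
                               rec.deleted])
        sigs = {rec.id: nodesig(rec) for rec in self.nodes()}
        nodes = sorted(sigs.values())
        rels = sorted(json.dumps([r.type, sigs[r.start_id], sigs[r.end_id],
                                  sorted((k, repr(v)) for k, v in r.properties.items())])
                      for r in self.relationships())
        return hashlib.sha256(json.dumps([nodes, rels]).encode()).hexdigest()


def _compare(op: str, left: Any, right: Any) -> bool:
    try:
        if op == "eq":
            return left == right
        if op == "ne":
            return left != right
        if op == "lt":
            return left < right
        if op == "le":
            return left <= right
        if op == "gt":
            return left > right
        if op == "ge":
            return left >= right
        if op == "in":
            return left in right
        if op == "contains":
            return right in left
    except TypeError:
        return False
    raise PatternError(f"unknown comparison {op!r}")


def _hashable(v: Any) -> Any:
    return tuple(v) if isinstance(v, list) else v
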