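"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import random
from collections import Counter

import pytest

from pergola.engine import Engine, EngineConfig
from pergola.graphstore import GraphStore, N, R

# ---------------------------------------------------------------------------
# Brute-force pattern-matching oracle (independent of GraphStore internals:
# uses only the public nodes()/relationships() iteration)
# ---------------------------------------------------------------------------

ORACLE_LABELS = ["Blob", "Fastq", "Ubam", "Job", "Sample"]
ORACLE_RTYPES = ["GENERATED", "WAS_USED_BY", "LED_TO"]


_PRED_OPS = {
    "eq": lambda a, b: a == b, "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b, "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b, "ge": lambda a, b: a >= b,
    "in": lambda a, b: a in b, "contains": lambda a, b: b in a,
}


def _pred_holds(op: str, have, want) -> bool:
    try:
        return _PRED_OPS[op](have, want)
    except TypeError:
        return False


def node_matches(nc: N, node) -> bool:
    if not set(nc.labels) <= set(node.labels):
        return False
    for key, pred in nc.where:
        op, want = pred if isinstance(pred, tuple) else ("eq", pred)
        if op == "exists":
            if (key in node.properties) != bool(want):
                return False
            continue
        if key not in node.properties:
            return False
        if not _pred_holds(op, node.properties[key], want):
            return False
    return True


def brute_force_match(store: GraphStore, elements, include_deleted: bool = False) -> Counter:
    """Exhaustive enumeration over node tuples; returns a multiset of
    variable-binding tuples (multiplicity = number of distinct relationship
    choices realising the binding)."""
    nodes = [n for n in store.nodes() if include_deleted or not n.deleted]
    rels = list(store.relationships())
    ncs = list(elements[0::2])
    rcs = list(elements[1::2])
    result: Counter = Counter()
    for combo in itertools.product(nodes, repeat=len(ncs)):
        binding: dict[str, int] = {}
        ok = True
        for nc, node in zip(ncs, combo):
            if nc.var in binding:
                if binding[nc.var] != node.id:
                    ok = False
                    break
            else:
                binding[nc.var] = node.id
            if not node_matches(nc, node):
                ok = False
                break
        if not ok:
            continue
        multiplicity = 1
        for i, rc in enumerate(rcs):
            a, b = combo[i].id, combo[i + 1].id
            count = 0
            if rc.direction in ("out", "any"):
                count += sum(1 for r in rels
                             if r.start_id == a and r.end_id == b and r.type in rc.types)
            if rc.direction in ("in", "any"):
                count += sum(1 for r in rels
                             if r.start_id == b and r.end_id == a and r.type in rc.types)
            multiplicity *= count
            if multiplicity == 0:
                break
        if multiplicity:
            result[tuple(sorted(binding.items()))] += multiplicity
    return result


def rows_to_multiset(rows, node_vars) -> Counter:
    return Counter(tuple(sorted((v, row[v]) for v in node_vars)) for row in rows)


def random_store(seed: int, n_nodes: int = 30, n_edges: int = 60) -> GraphStore:
    rng = random.Random(seed)
    store = GraphStore()
    ids = []
    for _ in range(n_nodes):
        labels = set(rng.sample(ORACLE_LABELS, rng.randint(1, 2)))
        props = {f"p{k}": rng.randint(0, 3) for k in range(rng.randint(0, 3))}
        ids.append(store.create_node(labels, props).id)
    for _ in range(n_edges):
        store.merge_relationship(rng.choice(ids), rng.choice(ORACLE_RTYPES), rng.choice(ids))
    return store


def random_pattern(rng: random.Random):
    length = rng.randint(1, 3)
    elements = []
    for i in range(length):
        labels = set(rng.sample(ORACLE_LABELS, rng.randint(0, 1)))
        where = {}
        if rng.random() < 0.5:
            where[f"p{rng.randint(0, 2)}"] = (
                rng.choice(["eq", "ge", "le"]), rng.randint(0, 3))
        elements.append(N(f"n{i}", labels, where))
        if i < length - 1:
            types = set(rng.sample(ORACLE_RTYPES, rng.randint(1, 2)))
            elements.append(R(types, rng.choice(["out", "in", "any"])))
    return elements


# ---------------------------------------------------------------------------
# Engine factory
# ---------------------------------------------------------------------------


@pytest.fixture
def engine_factory(tmp_path):
    """Build independent engines (fresh watched directory each)."""
    counter = itertools.count()

    def make(**kwargs) -> Engine:
        i = next(counter)
        kwargs.setdefault("seed", 1)
        kwargs.setdefault("scatter_width", 2)
        cfg = EngineConfig(watch_root=str(tmp_path / f"run{i}" / "bucket"), **kwargs)
        return Engine(cfg)

    return make
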