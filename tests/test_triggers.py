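"""Trigger contract: pure condition checks, query rendering, semaphore gates."""

import itertools
import random

import pytest

from pergola.datamodel import ESSENTIAL_TYPES, load_model
from pergola.graphstore import GraphStore
from pergola.triggers import (MERGE, NAIVE, Predicate, TriggerContext,
                              TriggerRegistry, builtin_registry)

CTX = TriggerContext()


@pytest.fixture
def registry():
    return builtin_registry()


@pytest.fixture
def store():
    s = GraphStore()
    load_model().register_constraints(s)
    return s


def ubam_metadata(sample="S001", rg=0):
    return {"labels": ["Blob", "Ubam"], "bucket": "b", "sample_id": sample,
            "plate_id": "PLATE01", "read_group": rg,
            "path": f"PLATE01/{sample}/ubam/{sample}_RG{rg}.ubam.sam"}


def fastq_metadata(sample="S001", rg=0, mate=1):
    return {"labels": ["Blob", "Fastq"], "bucket": "b", "sample_id": sample,
            "plate_id": "PLATE01", "read_group": rg, "mate_pair": mate,
            "path": f"PLATE01/{sample}/fastq/{sample}_RG{rg}_R{mate}.fastq.gz"}


class TestConditions:
    def test_ubam_activates_gatk_launch(self, registry):
        assert registry.get("launch-gatk").check_conditions(ubam_metadata())

    def test_fastq_does_not_activate_gatk_launch(self, registry):
        assert not registry.get("launch-gatk").check_conditions(fastq_metadata())

    def test_absent_property_is_false_not_error(self):
        pred = Predicate("read_group", "ge", 0)
        assert pred.holds({"labels": ["Fastq"]}) is False

    def test_exists_false_matches_absent(self):
        pred = Predicate("intermediate", "exists", False)
        assert pred.holds({"labels": ["Gvcf"]})
        assert not pred.holds({"labels": ["Gvcf"], "intermediate": True})

    @pytest.mark.parametrize("seed", range(5))
    def test_activation_set_matches_truth_table_oracle(self, registry, seed):
        """Registry activation equals independent per-predicate evaluation."""
        rng = random.Random(seed)
        label_pool = ["Blob", "Fastq", "Ubam", "Bam", "Gvcf", "Cram", "Job",
                      "Checksum", "FastQC"]
        def oracle_pred(p, md):
            if p.op == "exists":
                return (p.field in md) == bool(p.value)
            if p.field not in md:
                return False
            have = md[p.field]
            try:
                if p.op == "eq":
                    return have == p.value
                if p.op == "contains":
                    return p.value in have
                if p.op == "intersects":
                    return len(set(have) & set(p.value)) > 0
                if p.op == "lt":
                    return have < p.value
            except TypeError:
                return False
            raise AssertionError(f"oracle missing op {p.op}")
        for _ in range(40):
            md = {"labels": rng.sample(label_pool, rng.randint(1, 3))}
            for key in ("sample_id", "read_group", "status", "source_job_id",
                        "source_step_id", "inputs", "job_id", "intermediate"):
                if rng.random() < 0.5:
                    md[key] = rng.choice(["S001", 0, "failed", "x", ["a"], True])
            got = {s.name for s in registry.activated(md)}
            want = {s.name for s in registry
                    if all(oracle_pred(p, md) for p in s.conditions)}
            assert got == want


class TestPairTrigger:
    def _load_fastqs(self, store, mates=(1, 2)):
        for mate in mates:
            md = fastq_metadata(mate=mate)
            props = {k: v for k, v in md.items() if k != "labels"}
            store.create_node(set(md["labels"]), props)

    def test_fires_only_when_both_mates_present(self, registry, store):
        self._load_fastqs(store, mates=(1,))
        spec = registry.get("launch-fastq-to-ubam")
        rendered = spec.render(fastq_metadata(), CTX)
        assert store.run(rendered.query) == []
        self._load_fastqs(store, mates=(2,))
        rows = store.run(spec.render(fastq_metadata(), CTX).query)
        assert len(rows) == 1
        assert len(rows[0]["paths"]) == 2
        assert rows[0]["task"] == "fastq-to-ubam"


class TestGatkTrigger:
    def _load(self, store, n_ubams, expected):
        for rg in range(n_ubams):
            md = ubam_metadata(rg=rg)
            store.create_node(set(md["labels"]),
                              {k: v for k, v in md.items() if k != "labels"})
        store.create_node({"Blob", "Checksum"},
                          {"bucket": "b", "path": "PLATE01/S001/manifest/m.json",
                           "sample_id": "S001", "expected_read_groups": expected})

    def test_complete_read_groups_return_all_inputs(self, registry, store):
        self._load(store, 4, expected=4)
        rows = store.run(registry.get("launch-gatk").render(ubam_metadata(), CTX).query)
        assert len(rows) == 1
        assert sorted(rows[0]["paths"]) == [ubam_metadata(rg=r)["path"] for r in range(4)]

    def test_incomplete_read_groups_launch_nothing(self, registry, store):
        self._load(store, 3, expected=4)
        assert store.run(registry.get("launch-gatk").render(ubam_metadata(), CTX).query) == []

    def test_merge_semaphore_collapses_racing_activations(self, registry, store):
        self._load(store, 4, expected=4)
        spec = registry.get("launch-gatk")
        first = store.run(spec.render(ubam_metadata(rg=3), CTX).query)
        second = store.run(spec.render(ubam_metadata(rg=2), CTX).query)
        assert len(first) == 1 and second == []
        reqs = [n for n in store.nodes() if "JobRequest" in n.labels]
        assert len(reqs) == 1

    def test_naive_interleaved_phases_produce_duplicate_requests(self, registry, store):
        """The regression the merge fix addresses: two activations read the
        guard before either writes, and both launch."""
        self._load(store, 4, expected=4)
        ctx = TriggerContext(mode=NAIVE)
        spec = registry.get("launch-gatk")
        qa = spec.render(ubam_metadata(rg=3), ctx).query
        qb = spec.render(ubam_metadata(rg=2), ctx).query
        ra, wa = qa.split_read_write()
        rb, wb = qb.split_read_write()
        rows_a = store.run_clauses([{}], ra)
        rows_b = store.run_clauses([{}], rb)  # stale read: no JobRequest yet
        out_a = store.run_clauses(rows_a, wa)
        out_b = store.run_clauses(rows_b, wb)
        assert len(out_a) == 1 and len(out_b) == 1  # both launch
        reqs = [n for n in store.nodes() if "JobRequest" in n.labels]
        assert len(reqs) == 2


class TestCleanupGate:
    @pytest.mark.parametrize("present", [
        tuple(c) for r in range(len(ESSENTIAL_TYPES) + 1)
        for c in itertools.combinations(ESSENTIAL_TYPES, r)
    ])
    def test_fires_iff_all_essential_types_present(self, registry, store, present):
        """All 31 proper subsets stay silent; only the full set fires."""
        from pergola.triggers import _DOMAIN_REL
        g = store.create_node({"Genome"}, {"sample_id": "S001"}).id
        for label in present:
            b = store.create_node({"Blob", label},
                                  {"bucket": "b", "path": f"p/{label}",
                                   "sample_id": "S001"}).id
            store.merge_relationship(g, _DOMAIN_REL[label], b)
        md = {"labels": ["Blob", present[-1] if present else "Gvcf"],
              "sample_id": "S001", "path": "p/x"}
        spec = registry.get("postprocess-cleanup")
        fired = bool(store.run(spec.render(md, CTX).query)) or any(
            "JobRequest" in n.labels for n in store.nodes())
        assert fired == (set(present) == set(ESSENTIAL_TYPES))


class TestRegistryFile:
    def test_yaml_round_trip(self, registry, tmp_path):
        path = tmp_path / "registry.yaml"
        registry.to_yaml(path)
        again = TriggerRegistry.from_yaml(path)
        assert [s.name for s in again] == [s.name for s in registry]
        assert [s.conditions for s in again] == [s.conditions for s in registry]
        assert [s.destination for s in again] == [s.destination for s in registry]

    def test_unknown_builder_rejected(self, tmp_path):
        path = tmp_path / "registry.yaml"
        path.write_text("- name: x\n  query: bogus\n  conditions: []\n")
        with pytest.raises(Exception):
            TriggerRegistry.from_yaml(path)
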