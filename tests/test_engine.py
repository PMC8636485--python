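"""Engine integration: the closed operating cycle over broker + store."""

import json

import pytest

from pergola.engine import TOPIC_DB_QUERY
from pergola.graphstore import N, Query, R, Ref


def jobs_by_key(engine):
    groups = {}
    for node in engine.store.nodes():
        if "Job" in node.labels:
            key = (node.properties["task"], node.properties["input_digest"])
            groups.setdefault(key, []).append(node.properties["job_id"])
    return groups


class TestHappyPath:
    @pytest.fixture
    def engine(self, engine_factory):
        eng = engine_factory(seed=3, scatter_width=2)
        eng.deliver("S001", 2, 8)
        eng.run_until_quiescent()
        return eng

    def test_single_workflow_job_and_complete_sample(self, engine):
        assert all(len(v) == 1 for v in jobs_by_key(engine).values())
        assert all(engine.completeness("S001").values())
        assert engine.dead_letters == []

    def test_every_file_has_a_blob_node(self, engine):
        tracked = {n.properties["path"] for n in engine.store.nodes()
                   if "Blob" in n.labels}
        on_disk = {p.relative_to(engine.watch_root).as_posix()
                   for p in engine.watch_root.rglob("*") if p.is_file()}
        archived = {p.relative_to(engine.archive_root).as_posix()
                    for p in engine.archive_root.rglob("*") if p.is_file()}
        assert on_disk | archived <= tracked

    def test_zero_schema_violations(self, engine):
        assert engine.schema_violations() == []

    def test_lineage_reaches_fastqs_and_sample(self, engine):
        paths = engine.lineage("PLATE01/S001/variants/S001.g.vcf")
        fastqs, terminals = set(), set()
        for p in paths:
            terminals.add(frozenset(engine.store.node(p.node_ids[-1]).labels))
            for nid in p.node_ids:
                node = engine.store.node(nid)
                assert "CromwellAttempt" not in node.labels
                if "Fastq" in node.labels:
                    fastqs.add(node.properties["path"])
        assert len(fastqs) == 4
        assert terminals == {frozenset({"Sample"})}

    def test_cleanup_flags_exactly_the_intermediates(self, engine):
        flagged = {n.properties["path"] for n in engine.store.nodes() if n.deleted}
        intermediates = {n.properties["path"] for n in engine.store.nodes()
                         if "Blob" in n.labels and n.properties.get("intermediate")}
        assert flagged == intermediates and flagged

    def test_fastqs_archived_to_cold_storage(self, engine):
        assert not list(engine.watch_root.rglob("*.fastq.gz"))
        assert len(list(engine.archive_root.rglob("*.fastq.gz"))) == 4
        for node in engine.store.nodes():
            if "Fastq" in node.labels:
                assert node.properties["storage_class"] == "coldline"

    def test_workflow_graph_shape(self, engine):
        rows = engine.store.match(N("w", {"CromwellWorkflow"}), include_deleted=True)
        assert len(rows) == 1
        first = engine.store.match(N("w", {"CromwellWorkflow"}), R("LED_TO"),
                                   N("s", {"CromwellStep"}))
        assert len(first) == 1  # workflow node links only the first step
        steps = engine.store.match(N("s", {"CromwellStep"}))
        assert len(steps) == 5
        attempts = engine.store.match(N("a", {"CromwellAttempt"}))
        assert len(attempts) >= 5  # at least one per step shard

    def test_jobs_have_lifecycle_metadata(self, engine):
        for node in engine.store.nodes():
            if "Job" in node.labels:
                props = node.properties
                assert props["status"] == "succeeded"
                assert props["stop_ts"] >= props["start_ts"] >= 0
                assert props["machine"]
        assert engine.monitor.parked_count == 0


class TestReplayIdempotency:
    def test_reimporting_every_object_changes_nothing(self, engine_factory):
        eng = engine_factory(seed=5, scatter_width=2)
        eng.deliver("S001", 2, 6)
        eng.run_until_quiescent()
        before = (eng.store.fingerprint(), len(eng.store), eng.store.relationship_count)
        eng.import_dir()  # re-announce every surviving object
        eng.run_until_quiescent()
        after = (eng.store.fingerprint(), len(eng.store), eng.store.relationship_count)
        assert before == after

    def test_updated_object_keeps_node_identity(self, engine_factory):
        eng = engine_factory(seed=5)
        rels = eng.deliver("S001", 1, 4)
        eng.run_until_quiescent()
        node = eng.blob_node(rels[-1])
        eng.publish_object_event(rels[-1], event_type="updated")
        eng.run_until_quiescent()
        again = eng.blob_node(rels[-1])
        assert again.id == node.id
        assert again.properties["event_type"] == "updated"


class TestFaultTolerance:
    def test_every_task_failing_once_is_recovered_by_retry(self, engine_factory):
        eng = engine_factory(seed=7, scatter_width=2, failure_probability=1.0,
                             retry_limit=1)
        eng.deliver("S001", 2, 6)
        eng.run_until_quiescent()
        assert all(eng.completeness("S001").values())
        statuses = [n.properties["status"] for n in eng.store.nodes()
                    if "Job" in n.labels]
        assert "failed" in statuses  # failures really happened
        for node in eng.store.nodes():
            if "Job" in node.labels and node.properties["status"] == "failed":
                assert node.properties["retried"] == 1

    def test_malformed_query_goes_to_dead_letter_engine_continues(self, engine_factory):
        eng = engine_factory()
        eng.broker.publish(TOPIC_DB_QUERY, {"query": "not a query"})
        eng.broker.publish(TOPIC_DB_QUERY, {"query": Query("bad").returns(x=Ref("missing"))})
        eng.deliver("S001", 1, 4)
        eng.run_until_quiescent()
        assert len(eng.dead_letters) == 2
        assert all(eng.completeness("S001").values())


class TestRaceModes:
    POLICY = {"duplicate_probability": 0.6, "max_extra_deliveries": 1, "reorder_window": 4}

    def test_naive_mode_races_and_sweep_cleans_up(self, engine_factory):
        saw_duplicate = False
        for seed in range(10):
            eng = engine_factory(seed=seed, mode="naive", delivery=self.POLICY)
            eng.deliver("S001", 4, 4)
            eng.run_until_quiescent()
            groups = jobs_by_key(eng)
            if any(len(v) > 1 for v in groups.values()):
                saw_duplicate = True
                report = eng.monitor.detect_and_deactivate_duplicates(
                    eng.store, eng.executor, eng.execute_query)
                assert report
                assert jobs_active_by_key(eng) == {k: 1 for k in groups}
                break
        assert saw_duplicate

    def test_merge_mode_never_duplicates(self, engine_factory):
        for seed in range(6):
            eng = engine_factory(seed=seed, mode="merge", delivery=self.POLICY)
            eng.deliver("S001", 4, 4)
            eng.run_until_quiescent()
            assert all(len(v) == 1 for v in jobs_by_key(eng).values()), seed


def jobs_active_by_key(engine):
    groups = {}
    for node in engine.store.nodes():
        if "Job" in node.labels and not node.properties.get("duplicate"):
            key = (node.properties["task"], node.properties["input_digest"])
            groups.setdefault(key, 0)
            groups[key] += 1
    return groups


class TestBatchAndImport:
    def test_import_registers_preexisting_files(self, engine_factory):
        from pergola.fixtures import generate_delivery
        eng = engine_factory(seed=2, scatter_width=2)
        generate_delivery(eng.watch_root, "S009", 2, 4, seed=1)
        n = eng.import_dir()
        eng.run_until_quiescent()
        assert n == 5
        assert all(eng.completeness("S009").values())

    def test_batch_reevaluation_is_a_noop_after_completion(self, engine_factory):
        eng = engine_factory(seed=2, scatter_width=2)
        eng.deliver("S001", 2, 4)
        eng.run_until_quiescent()
        before = eng.store.fingerprint()
        published = eng.batch("postprocess-cleanup")
        eng.run_until_quiescent()
        assert published >= 1  # essential blobs re-rendered the trigger
        assert eng.store.fingerprint() == before  # semaphore made it a no-op

    def test_structured_log_export(self, engine_factory, tmp_path):
        eng = engine_factory()
        eng.deliver("S001", 1, 4)
        eng.run_until_quiescent()
        out = tmp_path / "log.jsonl"
        eng.write_log(out)
        records = [json.loads(l) for l in out.read_text().splitlines()]
        services = {r["service"] for r in records}
        assert {"create-blob-node", "db-query", "db-triggers", "job-launcher",
                "executor"} <= services


class TestCli:
    def test_deliver_and_report_commands(self, tmp_path):
        from click.testing import CliRunner
        from pergola.cli import main
        runner = CliRunner()
        root = str(tmp_path / "bucket")
        res = runner.invoke(main, ["deliver", "S001", "--root", root,
                                   "--read-groups", "1", "--reads", "4"])
        assert res.exit_code == 0, res.output
        assert "Cram=yes" in res.output
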