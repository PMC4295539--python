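"""Scheduler: done-flags, invalidation, backends, remote connection, gc."""

import json

import networkx as nx
import numpy as np
import pytest

import pipecraft as pc
from pipecraft.engine import InstanceMap
from pipecraft.interfaces import ModuleInvocation, Tasklist
from pipecraft.toys import DEFAULT_REGISTRY, load_series, save_volume

from conftest import build_toy_analysis


def preproc_tasklist():
    return Tasklist(
        main=[
            ModuleInvocation("epi_import"),
            ModuleInvocation("discard_dummies"),
            ModuleInvocation("realign"),
        ]
    )


def preproc_analysis(root, cfg=None, seed=13):
    cfg = cfg or pc.SyntheticStudyConfig(seed=seed, n_scans=8, shape=(10, 10, 8))
    study = pc.generate_synthetic_study(cfg, root)
    interfaces = pc.builtin_interfaces()
    tasklist = preproc_tasklist()
    params = pc.merge_parameters(
        pc.builtin_parameters(), tasklist, interfaces,
        {"tasksettings": {"discard_dummies": {"numdummies": cfg.numdummies}}},
    )
    pipeline = pc.expand_tasklist(tasklist, interfaces)
    return cfg, study, pipeline, params


class TestDoneFlags:
    def test_fresh_analysis_nothing_done(self, tmp_path):
        _, study, pipeline, _ = preproc_analysis(tmp_path)
        imap = InstanceMap(pipeline, study)
        assert all(not imap.is_done(i) for i in imap.graph.nodes)

    def test_flag_file_name_embeds_stage_and_index(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        pc.run_pipeline(pipeline, study, params)
        imap = InstanceMap(pipeline, study)
        inst = next(i for i in imap.graph.nodes if i.stage_name == "realign")
        flag = imap.flag_path(inst)
        assert flag.name == "done_realign_00001"
        assert flag.exists()

    def test_rerun_with_flags_and_unchanged_inputs_executes_nothing(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        first = pc.run_pipeline(pipeline, study, params)
        assert len(first.executed) == 6  # 3 stages x 2 subjects x 1 session
        second = pc.run_pipeline(pipeline, study, params)
        assert second.executed == []

    def test_adding_a_subject_invalidates_study_level_instance(self, tmp_path):
        cfg = pc.SyntheticStudyConfig(seed=4, n_subjects=2, noise_sd=0.5)
        toy = build_toy_analysis(tmp_path, cfg=cfg)
        toy.run()
        # grow the study: a third subject arrives
        cfg3 = pc.SyntheticStudyConfig(seed=4, n_subjects=3, noise_sd=0.5)
        toy3 = build_toy_analysis(tmp_path, cfg=cfg3)
        record = toy3.run()
        second_level = [e for e in record.executed if "secondlevel" in e]
        assert second_level  # study-level t-test re-ran
        # existing subjects' session work was not repeated
        assert not any(
            e.startswith("realign") and "S01" in e for e in record.executed
        )

    def test_mutating_an_upstream_payload_reruns_dependents(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        pc.run_pipeline(pipeline, study, params)
        target = (
            study.analysis_root / "analysis" / "discard_dummies_00001"
            / "S01" / "movie" / "epi.nii"
        )
        data, zooms = load_series(target)
        save_volume(data + 1.0, zooms, target)
        record = pc.run_pipeline(pipeline, study, params)
        assert sorted(record.executed) == ["realign_00001:S01/movie"]


class TestInvalidation:
    def test_terminal_instance_set_of_size_one(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        pc.run_pipeline(pipeline, study, params)
        closed = pc.invalidate(pipeline, study, "realign", ("S01", "movie"))
        assert {i.stage_name for i in closed} == {"realign"}
        assert len(closed) == 1

    def test_invalidation_set_equals_graph_reachability(self, tmp_path):
        toy = build_toy_analysis(tmp_path)
        toy.run()
        imap = InstanceMap(toy.pipeline, toy.study)
        inst = next(
            i
            for i in imap.graph.nodes
            if i.stage_name == "realign"
            and tuple(x for _, x in i.coordinate) == ("S01", "movie")
        )
        closed = imap.invalidate(inst)
        assert closed == {inst} | set(nx.descendants(imap.graph, inst))
        record = toy.run()
        assert {e for e in record.executed} == {
            f"{i.stage_dir_name}:{'/'.join(x for _, x in i.coordinate)}"
            for i in closed
        }

    def test_invalidate_without_flags_is_idempotent(self, tmp_path):
        _, study, pipeline, _ = preproc_analysis(tmp_path)
        first = pc.invalidate(pipeline, study, "epi_import")
        second = pc.invalidate(pipeline, study, "epi_import")
        assert first == second
        assert len(first) == 6


class TestFailureHandling:
    def failing_registry(self):
        registry = dict(DEFAULT_REGISTRY)

        def boom(ctx):
            raise RuntimeError("synthetic failure")

        registry["realign"] = boom
        return registry

    def test_failure_blocks_dependents_but_not_independent_subtrees(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        record = pc.run_pipeline(
            pipeline, study, params, registry=self.failing_registry()
        )
        assert len(record.failed) == 2  # realign per session
        assert all("realign" in f for f in record.failed)
        # import/trim completed for both subjects despite downstream failure
        assert sum("discard" in e for e in record.executed) == 2

    def test_crash_resume_skips_completed_stages(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        pc.run_pipeline(pipeline, study, params, registry=self.failing_registry())
        record = pc.run_pipeline(pipeline, study, params)  # fixed code
        assert sorted(record.executed) == [
            "realign_00001:S01/movie",
            "realign_00001:S02/movie",
        ]

    def test_fail_fast_stops_dispatching(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        record = pc.run_pipeline(
            pipeline, study, params, registry=self.failing_registry(),
            fail_fast=True,
        )
        assert len(record.failed) == 1


class TestBackendEquivalence:
    def test_parallel_and_serial_runs_produce_identical_digest_trees(self, tmp_path):
        cfg = pc.SyntheticStudyConfig(seed=17)
        serial = build_toy_analysis(tmp_path / "serial", cfg=cfg)
        serial.run(backend="localsingle")
        parallel = build_toy_analysis(tmp_path / "parallel", cfg=cfg)
        record = parallel.run(backend="localparallel", n_workers=3)
        assert not record.failed
        assert serial.digests() == parallel.digests()
        assert len(serial.digests()) > 0

    def test_deterministic_modules_reproduce_digests_after_invalidate(self, tmp_path):
        toy = build_toy_analysis(tmp_path)
        toy.run()
        before = toy.digests()
        pc.invalidate(toy.pipeline, toy.study, "realign")
        toy.run()
        assert toy.digests() == before


class TestBranchEconomy:
    def test_trunk_runs_once_and_divergence_is_downstream_only(self, tmp_path):
        toy = build_toy_analysis(tmp_path, tasklist_name="toy_fmri_branched")
        record = toy.run()
        assert not record.failed
        from collections import Counter

        counts = Counter(e.split(":")[0] for e in record.executed)
        for trunk in ("epi_import_00001", "discard_dummies_00001",
                      "realign_00001", "tsdiffana_00001"):
            assert counts[trunk] == 2  # one per subject-session, once each
        assert counts["smooth_00001"] == counts["smooth_00002"] == 2
        # trunk data live in the unsuffixed analysis directory, shared
        root = toy.study.analysis_root
        assert (root / "analysis" / "realign_00001").is_dir()
        assert (root / "analysis_s08" / "smooth_00001").is_dir()
        assert (root / "analysis_s12" / "smooth_00002").is_dir()
        assert not (root / "analysis_s08" / "realign_00001").exists()
        # the two branches differ only by the smoothing kernel
        t8, _ = load_series(
            root / "analysis_s08" / "secondlevel_ttest_00001" / "group_t_001.nii"
        )
        t12, _ = load_series(
            root / "analysis_s12" / "secondlevel_ttest_00002" / "group_t_001.nii"
        )
        assert not np.array_equal(t8, t12)

    def test_rerun_of_branched_tasklist_executes_nothing(self, tmp_path):
        toy = build_toy_analysis(tmp_path, tasklist_name="toy_fmri_branched")
        toy.run()
        assert toy.run().executed == []


class TestRemoteConnection:
    def _server(self, root, seed=5):
        cfg, study, pipeline, params = preproc_analysis(root, seed=seed)
        pc.run_pipeline(pipeline, study, params)
        return cfg, study, pipeline, params

    def _local(self, root, subjects):
        study = pc.StudyDescription(
            analysis_root=root / "analysis", analysis_id="local",
            subjects=subjects,
            sessions_per_subject={s: ["movie"] for s in subjects},
        )
        interfaces = pc.builtin_interfaces()
        tasklist = Tasklist(main=[ModuleInvocation("smooth")])
        params = pc.merge_parameters(
            pc.builtin_parameters(), tasklist, interfaces, {}
        )
        return study, pc.expand_tasklist(tasklist, interfaces), params

    def test_subset_of_remote_subjects_binds_only_those_records(self, tmp_path):
        _, rstudy, *_ = self._server(tmp_path / "server")
        study, pipeline, params = self._local(tmp_path / "local", ["S01"])
        remote = pc.connect_remote(pipeline, rstudy.analysis_root)
        coords = {
            "/".join(i for _, i in c) for c in remote.streams["epi"].records
        }
        assert coords == {"S01/movie", "S02/movie"}  # offered
        record = pc.run_pipeline(pipeline, study, params, remote=remote)
        assert record.executed == ["smooth_00001:S01/movie"]  # only used

    def test_default_binding_is_terminal_producer(self, tmp_path):
        _, rstudy, *_ = self._server(tmp_path / "server")
        _, pipeline, _ = self._local(tmp_path / "local", ["S01"])
        remote = pc.connect_remote(pipeline, rstudy.analysis_root)
        producer = next(iter(remote.streams["epi"].records.values())).producer
        assert producer.stage_name == "realign"

    def test_explicit_binding_selects_earlier_stage(self, tmp_path):
        _, rstudy, *_ = self._server(tmp_path / "server")
        _, pipeline, _ = self._local(tmp_path / "local", ["S01"])
        remote = pc.connect_remote(
            pipeline, rstudy.analysis_root, bindings={"epi": "discard_dummies"}
        )
        producer = next(iter(remote.streams["epi"].records.values())).producer
        assert producer.stage_name == "discard_dummies"

    def test_remote_mutation_reruns_exactly_dependents(self, tmp_path):
        _, rstudy, *_ = self._server(tmp_path / "server")
        study, pipeline, params = self._local(tmp_path / "local", ["S01", "S02"])
        connect = lambda: pc.connect_remote(pipeline, rstudy.analysis_root)
        pc.run_pipeline(pipeline, study, params, remote=connect())
        assert (
            pc.run_pipeline(pipeline, study, params, remote=connect()).executed
            == []
        )
        target = (
            rstudy.analysis_root / "analysis" / "realign_00001" / "S01" / "movie"
            / "epi.nii"
        )
        data, zooms = load_series(target)
        save_volume(data * 1.01, zooms, target)
        record = pc.run_pipeline(pipeline, study, params, remote=connect())
        assert record.executed == ["smooth_00001:S01/movie"]

    def test_unreadable_remote_and_absent_stream_error(self, tmp_path):
        _, pipeline, _ = self._local(tmp_path / "local", ["S01"])
        with pytest.raises(pc.RemoteConnectionError):
            pc.connect_remote(pipeline, tmp_path / "nowhere")
        _, rstudy, *_ = self._server(tmp_path / "server")
        with pytest.raises(pc.UnconnectedStreamError):
            pc.connect_remote(
                pipeline, rstudy.analysis_root, bindings={"epi": "nosuchmodule"}
            )


class TestGarbageCollection:
    def test_threshold_zero_deletes_nothing(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        pc.run_pipeline(pipeline, study, params)
        with pytest.warns(UserWarning):
            deleted = pc.garbage_collect(
                study.analysis_root, pc.GarbagePolicy(keep_threshold=0)
            )
        assert deleted == []

    def test_only_low_rank_payloads_deleted_flags_kept(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        pc.run_pipeline(pipeline, study, params)
        deleted = pc.garbage_collect(
            study.analysis_root, pc.GarbagePolicy(keep_threshold=2)
        )
        # epi_import (rank 1) and discard_dummies (rank 1) payloads only
        assert deleted and all(
            p.split("/")[1].startswith(("epi_import", "discard_dummies"))
            for p in deleted
        )
        imap = InstanceMap(pipeline, study)
        assert all(imap.flag_path(i).exists() for i in imap.graph.nodes)
        # completed terminal results remain done: nothing re-runs by itself
        assert pc.run_pipeline(pipeline, study, params).executed == []

    def test_dry_run_lists_without_deleting(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        pc.run_pipeline(pipeline, study, params)
        listed = pc.garbage_collect(
            study.analysis_root, pc.GarbagePolicy(keep_threshold=2, dry_run=True)
        )
        assert listed
        for rel in listed:
            assert (study.analysis_root / rel).exists()

    def test_pending_work_regenerates_exactly_deleted_producers(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        pc.run_pipeline(pipeline, study, params)
        before = pc.output_tree_digests(pipeline, study)
        pc.garbage_collect(study.analysis_root, pc.GarbagePolicy(keep_threshold=2))
        pc.invalidate(pipeline, study, "realign", ("S01", "movie"))
        record = pc.run_pipeline(pipeline, study, params)
        # the invalidated instance plus the gc'd producers it needs, S01 only
        assert sorted(record.executed) == [
            "discard_dummies_00001:S01/movie",
            "epi_import_00001:S01/movie",
            "realign_00001:S01/movie",
        ]
        assert pc.output_tree_digests(pipeline, study) == before


class TestProvenance:
    def test_record_is_reloadable_and_reconstructs_pipeline(self, tmp_path):
        toy = build_toy_analysis(tmp_path)
        toy.run()
        prov = pc.load_provenance(toy.study.analysis_root)
        rebuilt = pc.pipeline_from_provenance(prov)
        assert [s.key for s in rebuilt.stages] == [
            s.key for s in toy.pipeline.stages
        ]
        assert [s.interface.domain for s in rebuilt.stages] == [
            s.interface.domain for s in toy.pipeline.stages
        ]
        study = pc.StudyDescription.from_dict(prov["study"])
        assert study.subjects == toy.study.subjects

    def test_instance_statuses_and_parameters_recorded(self, tmp_path):
        toy = build_toy_analysis(tmp_path)
        record = toy.run()
        prov = pc.load_provenance(toy.study.analysis_root)
        statuses = {e["status"] for e in prov["instances"]}
        assert statuses == {"completed"}
        assert prov["parameters"]["tasksettings"]["smooth"]["FWHM"] == 10
        assert record.engine_version == prov["engine_version"]

    def test_dot_export_contains_all_edges(self, tmp_path):
        _, study, pipeline, _ = preproc_analysis(tmp_path)
        imap = InstanceMap(pipeline, study)
        dot = pc.dependency_graph_dot(imap)
        assert dot.startswith("digraph")
        assert dot.count("->") == imap.graph.number_of_edges()


class TestWriteContainment:
    def test_sideways_write_surfaces_as_instance_failure(self, tmp_path):
        _, study, pipeline, params = preproc_analysis(tmp_path)
        registry = dict(DEFAULT_REGISTRY)

        def rogue(ctx):
            sibling = ctx.directory.parent / "other_session"
            sibling.mkdir(parents=True, exist_ok=True)
            out = sibling / "epi.nii"
            out.write_text("stolen")
            return {"epi": [out]}

        registry["trim_series"] = rogue
        record = pc.run_pipeline(pipeline, study, params, registry=registry)
        assert len(record.failed) == 2
        assert all("discard" in f for f in record.failed)

    def test_toy_modules_write_only_inside_their_instance_directory(self, tmp_path):
        toy = build_toy_analysis(tmp_path)
        before = {p for p in (tmp_path / "raw").rglob("*")}
        toy.run()
        # raw inputs untouched; all outputs under the analysis root
        assert {p for p in (tmp_path / "raw").rglob("*")} == before
        imap = InstanceMap(toy.pipeline, toy.study)
        for inst in imap.graph.nodes:
            directory = imap.directory(inst)
            stage = imap.stage_of(inst)
            for stream in stage.interface.output_streams:
                from pipecraft.streams import read_stream_record

                record = read_stream_record(directory, stream)
                for f in record.files:
                    assert (directory / f.path).resolve().is_relative_to(
                        directory.resolve()
                    )
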