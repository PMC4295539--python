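"""Stream wiring: producer resolution, dependency maps, placement contract."""

from pathlib import Path

import numpy as np
import pytest

import pipecraft as pc
from pipecraft.domains import DEFAULT_TREE
from pipecraft.interfaces import ModuleInvocation, Tasklist
from pipecraft.streams import (
    IncomingStream,
    digest_file,
    read_stream_record,
)

from conftest import oracle_dependency_map, random_pipeline_and_study


def iface(name, domain, inputs=(), outputs=()):
    return pc.ModuleInterface(
        name=name, domain=domain,
        input_streams=list(inputs), output_streams=list(outputs),
    )


def chain_pipeline(*specs, qualified=None):
    """specs: (name, domain, inputs, outputs)."""
    interfaces = {s[0]: iface(*s) for s in specs}
    invs = []
    for s in specs:
        q = (qualified or {}).get(s[0], {})
        invs.append(ModuleInvocation(s[0], qualified_inputs=q))
    return pc.expand_tasklist(Tasklist(main=invs), interfaces)


def study_2x2(root="/tmp/s"):
    return pc.StudyDescription(
        analysis_root=Path(root), analysis_id="a",
        subjects=["S1", "S2"],
        sessions_per_subject={"S1": ["m", "r"], "S2": ["m", "r"]},
    )


class TestResolveSource:
    def test_last_producer_skips_non_producers(self):
        # qc module between realign and the consumer outputs no epi
        pipe = chain_pipeline(
            ("realign", "session", ["epi"], ["epi", "realignment_parameter"]),
            ("tsdiffana", "session", ["epi"], ["qc"]),
            ("slicetiming", "session", ["epi"], ["epi"]),
        )
        # realign itself has no producer for epi; drop its input for the test
        pipe.stages[0].interface.input_streams = []
        source, stream = pc.resolve_stream_source(pipe, pipe.stages[2], "epi")
        assert source.name == "realign"
        assert stream == "epi"

    def test_qualified_reference_overrides_last_producer(self):
        pipe = chain_pipeline(
            ("importer", "session", [], ["epi"]),
            ("norm", "session", ["epi"], ["epi"]),
            ("consumer", "session", ["epi"], []),
            qualified={"consumer": {"epi": "importer.epi"}},
        )
        source, _ = pc.resolve_stream_source(pipe, pipe.stages[2], "epi")
        assert source.name == "importer"

    def test_unconnected_stream_errors_at_build(self):
        pipe = chain_pipeline(("consumer", "session", ["epi"], []))
        with pytest.raises(pc.UnconnectedStreamError, match="epi"):
            pc.build_dependency_map(pipe, study_2x2())

    def test_branch_resolution_never_crosses_sibling(self):
        interfaces = {
            "importer": iface("importer", "session", [], ["epi"]),
            "smooth": iface("smooth", "session", ["epi"], ["epi"]),
            "model": iface("model", "session", ["epi"], ["beta"]),
        }
        tl = Tasklist(
            main=[
                ModuleInvocation("importer"),
                pc.Branch(
                    [
                        ("_a", [ModuleInvocation("smooth"), ModuleInvocation("model")]),
                        ("_b", [ModuleInvocation("model")]),
                    ]
                ),
            ]
        )
        pipe = pc.expand_tasklist(tl, interfaces)
        # model in branch _a reads from its own smooth; model in _b must
        # fall through to the trunk importer, not branch _a's smooth
        src_a, _ = pc.resolve_stream_source(pipe, pipe.stages[2], "epi")
        src_b, _ = pc.resolve_stream_source(pipe, pipe.stages[3], "epi")
        assert src_a.name == "smooth"
        assert src_b.name == "importer"


class TestDependencyMap:
    def test_equal_domain_matches_coordinates_only(self):
        pipe = chain_pipeline(
            ("norm_write", "session", [], ["epi"]),
            ("smooth", "session", ["epi"], ["epi"]),
        )
        study = pc.StudyDescription(
            analysis_root=Path("/tmp/s"), analysis_id="a",
            subjects=[f"S{i}" for i in range(1, 5)],
            sessions_per_subject={f"S{i}": ["1", "2"] for i in range(1, 5)},
        )
        edges = pc.build_dependency_map(pipe, study)
        targets_s4s2 = [
            e for e in edges
            if tuple(i for _, i in e.target.coordinate) == ("S4", "2")
        ]
        # the smooth instance for subject 4 session 2 depends on exactly the
        # norm_write instance that processed subject 4 session 2
        assert len(targets_s4s2) == 1
        assert tuple(i for _, i in targets_s4s2[0].source.coordinate) == ("S4", "2")

    def test_fan_in_sessions_to_study(self):
        pipe = chain_pipeline(
            ("contrasts", "session", [], ["con"]),
            ("secondlevel", "study", ["con"], ["tmap"]),
        )
        edges = pc.build_dependency_map(pipe, study_2x2())
        incoming = [e for e in edges if e.target.stage_name == "secondlevel"]
        assert len(incoming) == 4
        assert len({e.target for e in incoming}) == 1

    def test_ancestor_subject_source_feeds_each_session(self):
        pipe = chain_pipeline(
            ("structural", "subject", [], ["structural"]),
            ("coreg", "session", ["structural"], ["epi"]),
        )
        study = pc.StudyDescription(
            analysis_root=Path("/tmp/s"), analysis_id="a",
            subjects=["S1"], sessions_per_subject={"S1": ["m", "r"]},
        )
        edges = pc.build_dependency_map(pipe, study)
        assert len(edges) == 2
        assert {tuple(i for _, i in e.source.coordinate) for e in edges} == {("S1",)}

    def test_sideways_domains_are_illegal_reads(self):
        tree = DEFAULT_TREE.with_session_domain("diffusion_session")
        interfaces = {
            "dwi": pc.ModuleInterface(
                name="dwi", domain="diffusion_session", output_streams=["dwi"]
            ),
            "consumer": pc.ModuleInterface(
                name="consumer", domain="session", input_streams=["dwi"]
            ),
        }
        pipe = pc.expand_tasklist(
            Tasklist(main=[ModuleInvocation("dwi"), ModuleInvocation("consumer")]),
            interfaces,
        )
        study = pc.StudyDescription(
            analysis_root=Path("/tmp/s"), analysis_id="a",
            subjects=["S1"], sessions_per_subject={"S1": ["m"]},
            extra_units={"diffusion_session": {"S1": ["d"]}},
        )
        with pytest.raises(pc.IllegalReadError):
            pc.build_dependency_map(pipe, study, tree)

    def test_engine_map_equals_brute_force_on_random_pipelines(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            pipeline, study = random_pipeline_and_study(rng)
            assert pc.build_dependency_map(pipeline, study) == oracle_dependency_map(
                pipeline, study
            )

    def test_no_edge_connects_disjoint_coordinates(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pipeline, study = random_pipeline_and_study(rng)
            for e in pc.build_dependency_map(pipeline, study):
                assert (
                    pc.coordinate_relation(e.source.coordinate, e.target.coordinate)
                    != "disjoint"
                )


def _make_record(tmp_path, name, files, coord=(("subject", "S1"), ("session", "m"))):
    src_dir = tmp_path / name
    src_dir.mkdir(parents=True, exist_ok=True)
    produced = {}
    for stream, fnames in files.items():
        for f in fnames:
            (src_dir / f).write_text(f"payload of {f}")
        produced[stream] = fnames
    instance = pc.InstanceKey(name, 1, coord)
    records = pc.register_outputs(instance, src_dir, list(files), produced)
    return instance, src_dir, {r.stream: r for r in records}


class TestPlacementContract:
    def test_only_requested_streams_are_present(self, tmp_path):
        src, _, records = _make_record(
            tmp_path, "producer", {"epi": ["epi.nii"], "structural": ["t1.nii"]}
        )
        target = pc.InstanceKey("consumer", 1, (("subject", "S1"), ("session", "m")))
        target_dir = tmp_path / "consumer"
        placed = pc.place_inputs(
            target, target_dir, [IncomingStream("epi", src, records["epi"])]
        )
        assert list(placed) == ["epi"]
        placed_files = [p.name for p in target_dir.rglob("*") if p.is_file()]
        assert "t1.nii" not in placed_files  # unrequested data cannot be used
        assert (target_dir / "input_epi.json").exists()

    def test_zero_input_instance_gets_empty_manifest(self, tmp_path):
        target = pc.InstanceKey("importer", 1, ())
        target_dir = tmp_path / "importer"
        assert pc.place_inputs(target, target_dir, []) == {}
        assert target_dir.is_dir()

    def test_fan_in_placed_in_per_source_subfolders(self, tmp_path):
        study_target = pc.InstanceKey("secondlevel", 1, ())
        items = []
        for subject in ["S1", "S2"]:
            for session in ["m", "r"]:
                src, _, records = _make_record(
                    tmp_path, f"con_{subject}_{session}",
                    {"con": ["con.nii"]},
                    coord=(("subject", subject), ("session", session)),
                )
                items.append(IncomingStream("con", src, records["con"]))
        target_dir = tmp_path / "secondlevel"
        placed = pc.place_inputs(study_target, target_dir, items)
        assert sorted(placed["con"]) == [
            "inputs/con/S1/m/con.nii",
            "inputs/con/S1/r/con.nii",
            "inputs/con/S2/m/con.nii",
            "inputs/con/S2/r/con.nii",
        ]
        import json

        manifest = json.loads((target_dir / "input_con.json").read_text())
        assert len(manifest["sources"]) == 4

    def test_placement_preserves_digests_end_to_end(self, tmp_path):
        src, _, records = _make_record(tmp_path, "producer", {"epi": ["epi.nii"]})
        target = pc.InstanceKey("consumer", 1, (("subject", "S1"), ("session", "m")))
        target_dir = tmp_path / "consumer"
        placed = pc.place_inputs(
            target, target_dir, [IncomingStream("epi", src, records["epi"])]
        )
        for rel in placed["epi"]:
            assert digest_file(target_dir / rel) == records["epi"].files[0].digest

    def test_missing_source_record_is_not_ready(self, tmp_path):
        target = pc.InstanceKey("consumer", 1, ())
        src = pc.InstanceKey("producer", 1, ())
        with pytest.raises(pc.DependencyNotReadyError):
            pc.place_inputs(
                target, tmp_path / "c", [IncomingStream("epi", src, None)]
            )


class TestRegisterOutputs:
    def test_declared_streams_yield_records(self, tmp_path):
        _, src_dir, records = _make_record(
            tmp_path, "realign",
            {"realignment_parameter": ["rp.txt"], "meanepi": ["mean.nii"],
             "epi": ["epi.nii"]},
        )
        assert set(records) == {"realignment_parameter", "meanepi", "epi"}
        for stream in records:
            assert read_stream_record(src_dir, stream) is not None

    def test_undeclared_scratch_file_not_registered(self, tmp_path):
        d = tmp_path / "mod"
        d.mkdir()
        (d / "out.nii").write_text("x")
        (d / "scratch.tmp").write_text("y")
        inst = pc.InstanceKey("mod", 1, ())
        records = pc.register_outputs(
            inst, d, ["epi"], {"epi": ["out.nii"], "scratch": ["scratch.tmp"]}
        )
        assert [r.stream for r in records] == ["epi"]
        assert read_stream_record(d, "scratch") is None

    def test_declared_stream_without_files_is_missing_output(self, tmp_path):
        d = tmp_path / "mod"
        d.mkdir()
        inst = pc.InstanceKey("mod", 1, ())
        with pytest.raises(pc.MissingOutputError):
            pc.register_outputs(inst, d, ["epi"], {})

    def test_write_outside_instance_directory_is_illegal(self, tmp_path):
        d = tmp_path / "mod"
        sibling = tmp_path / "other"
        d.mkdir(); sibling.mkdir()
        (sibling / "stolen.nii").write_text("x")
        inst = pc.InstanceKey("mod", 1, (("subject", "S1"), ("session", "m")))
        with pytest.raises(pc.IllegalWriteError):
            pc.register_outputs(
                inst, d, ["epi"], {"epi": [sibling / "stolen.nii"]}
            )
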