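"""Incremental, parallel pipeline execution.

The engine builds a map of every instance of every stage and the
instance-level data dependencies between them, then runs only what needs
to be run. Completion is tracked with a ``done_<stage>_<index>`` flag file
in each instance's directory; the flag stores a snapshot of the input
digests, so an instance is *done* only while its flag exists **and** its
upstream digests still equal the snapshot (adding a subject, editing an
upstream file, or connecting changed remote data all invalidate it).
Flags downstream of a stale instance are deleted eagerly at map-build
time. Flag writes are atomic (write-temp-then-rename), so a crash cannot
fake completion.

Two backends share all of this logic: ``localsingle`` steps through the
eligible instances one at a time in topological order, while
``localparallel`` dispatches each instance to an in-process worker pool
the moment its own dependencies complete. Cluster submission is an
extension point honouring the interfaces' resource estimates, not a
bundled backend.
"""

from __future__ import annotations

import json
import os
import time
import traceback
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import networkx as nx

from .domains import (
    DEFAULT_TREE,
    Coordinate,
    DomainTree,
    InstanceKey,
    StudyDescription,
    coord_ids,
    coord_key,
    enumerate_coordinates,
    enumerate_instances,
    instance_directory,
)
from .errors import (
    PipelineError,
    RemoteConnectionError,
    UnconnectedStreamError,
)
from .interfaces import ExpandedPipeline, ParameterSet, Stage
from .streams import (
    FileDigest,
    IncomingStream,
    StreamRecord,
    current_digest_multiset,
    digest_file,
    instance_sources,
    place_inputs,
    read_stream_record,
    register_outputs,
    resolve_stream_source,
)

ENGINE_VERSION = "0.1.0"
PROVENANCE_NAME = "provenance.json"


@dataclass
class ModuleContext:
    """What an implementation sees when it runs: its own directory, bound
    settings, placed inputs, and the study description."""

    instance: InstanceKey
    directory: Path
    settings: Mapping
    inputs: Mapping[str, list[Path]]
    study: StudyDescription
    _log_path: Path | None = None

    def log(self, message: str) -> None:
        line = f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {message}\n"
        if self._log_path is not None:
            with open(self._log_path, "a") as fh:
                fh.write(line)


# ---------------------------------------------------------------------------
# remote pipelines


@dataclass
class RemoteStream:
    stream: str
    domain: str
    records: dict[Coordinate, StreamRecord]


@dataclass
class RemoteConnection:
    root: Path
    streams: dict[str, RemoteStream]
    explicit: set[str] = field(default_factory=set)


def connect_remote(
    pipeline: ExpandedPipeline,
    remote_root: Path,
    bindings: Mapping[str, str] | None = None,
    tree: DomainTree = DEFAULT_TREE,
) -> RemoteConnection:
    """Bind the local pipeline's unconnected input streams to a remote
    analysis tree.

    By default each stream attaches to the terminal producer in the remote
    pipeline; ``bindings`` maps a stream name to a remote module name to
    select an earlier stage instead. Remote payload files are re-hashed on
    every connection, so data changed out-of-band invalidate exactly the
    dependent local instances. No remote data are duplicated here — copies
    happen only when placed as input.
    """
    remote_root = Path(remote_root)
    prov_path = remote_root / PROVENANCE_NAME
    if not prov_path.exists():
        raise RemoteConnectionError(
            f"remote analysis at {remote_root} is unreadable (no {PROVENANCE_NAME})"
        )
    prov = json.loads(prov_path.read_text())
    remote_stages = prov["stages"]
    analysis_id = prov["study"]["analysis_id"]
    bindings = dict(bindings or {})

    needed: set[str] = set(bindings)
    for stage in pipeline.stages:
        if stage.interface is None:
            continue
        for stream in stage.interface.input_streams:
            try:
                resolve_stream_source(pipeline, stage, stream)
            except UnconnectedStreamError:
                needed.add(stream)

    streams: dict[str, RemoteStream] = {}
    for stream in needed:
        candidates = [s for s in remote_stages if stream in s["output_streams"]]
        if stream in bindings:
            candidates = [s for s in candidates if s["name"] == bindings[stream]]
        if not candidates:
            raise UnconnectedStreamError(
                f"stream {stream!r} is not produced by the remote pipeline"
                + (f" stage {bindings[stream]!r}" if stream in bindings else "")
            )
        chosen = candidates[-1]  # terminal end of the remote pipeline
        records: dict[Coordinate, StreamRecord] = {}
        for inst in prov["instances"]:
            if inst["stage_key"] != chosen["key"]:
                continue
            coordinate: Coordinate = tuple(
                (node, ident) for node, ident in inst["coordinate"]
            )
            directory = remote_root / (analysis_id + chosen.get("branch_suffix", ""))
            directory = directory / chosen["key"]
            for ident in coord_ids(coordinate):
                directory = directory / ident
            record = read_stream_record(directory, stream)
            if record is None:
                continue
            fresh = [
                FileDigest(
                    path=f.path,
                    digest=(
                        digest_file(directory / f.path)
                        if (directory / f.path).exists()
                        else f.digest
                    ),
                    size=f.size,
                )
                for f in record.files
            ]
            record.files = fresh
            records[coordinate] = record
        streams[stream] = RemoteStream(
            stream=stream, domain=chosen["domain"], records=records
        )
    return RemoteConnection(
        root=remote_root, streams=streams, explicit=set(bindings)
    )


# ---------------------------------------------------------------------------
# the instance map


class InstanceMap:
    """All instances of all stages, their dependency edges, directories,
    and completion state."""

    def __init__(
        self,
        pipeline: ExpandedPipeline,
        study: StudyDescription,
        tree: DomainTree = DEFAULT_TREE,
        remote: RemoteConnection | None = None,
    ):
        self.pipeline = pipeline
        self.study = study
        self.tree = tree
        self.remote = remote
        self.stage_by_key: dict[str, Stage] = {s.key: s for s in pipeline.stages}
        self.stage_pos = {s.key: i for i, s in enumerate(pipeline.stages)}
        self.graph = nx.DiGraph()
        self.incoming: dict[InstanceKey, list[tuple[InstanceKey, str]]] = {}
        self.remote_incoming: dict[InstanceKey, list[IncomingStream]] = {}
        self._build()

    # -- construction ------------------------------------------------------

    def _route(self, stage: Stage, stream: str) -> tuple[str, object]:
        """('local', source stage) or ('remote', RemoteStream)."""
        conn = self.remote
        if conn and stream in conn.explicit and stream not in stage.qualified_inputs:
            return "remote", conn.streams[stream]
        try:
            source_stage, _ = resolve_stream_source(self.pipeline, stage, stream)
            return "local", source_stage
        except UnconnectedStreamError:
            if conn and stream in conn.streams:
                return "remote", conn.streams[stream]
            raise

    def _build(self) -> None:
        for stage in self.pipeline.stages:
            for instance in enumerate_instances(stage, self.study, self.tree):
                self.graph.add_node(instance)
                self.incoming.setdefault(instance, [])
                self.remote_incoming.setdefault(instance, [])
        for stage in self.pipeline.stages:
            if stage.interface is None:
                continue
            for stream in stage.interface.input_streams:
                kind, source = self._route(stage, stream)
                for target in enumerate_instances(stage, self.study, self.tree):
                    if kind == "local":
                        for src in instance_sources(
                            source, target.coordinate, self.study, self.tree
                        ):
                            self.graph.add_edge(src, target, stream=stream)
                            self.incoming[target].append((src, stream))
                    else:
                        for item in self._remote_sources(source, target):
                            self.remote_incoming[target].append(item)

    def _remote_sources(
        self, remote_stream: RemoteStream, target: InstanceKey
    ) -> list[IncomingStream]:
        source_path = self.tree.path_below_root(remote_stream.domain)
        target_path = tuple(node for node, _ in target.coordinate)
        if source_path == target_path:
            coords = [target.coordinate]
        elif source_path == target_path[: len(source_path)]:
            coords = [target.coordinate[: len(source_path)]]
        elif target_path == source_path[: len(target_path)]:
            coords = [
                c
                for c in enumerate_coordinates(
                    remote_stream.domain, self.study, self.tree
                )
                if c[: len(target.coordinate)] == target.coordinate
            ]
        else:
            raise UnconnectedStreamError(
                f"remote stream {remote_stream.stream!r} crosses domains sideways"
            )
        items = []
        for coord in coords:
            if coord not in remote_stream.records:
                raise UnconnectedStreamError(
                    f"remote pipeline has no {remote_stream.stream!r} record for "
                    f"coordinate {coord_key(coord) or '<study>'}"
                )
            record = remote_stream.records[coord]
            items.append(
                IncomingStream(
                    stream=remote_stream.stream,
                    source=record.producer,
                    record=record,
                )
            )
        return items

    # -- locations and records --------------------------------------------

    def stage_of(self, instance: InstanceKey) -> Stage:
        return self.stage_by_key[instance.stage_dir_name]

    def directory(self, instance: InstanceKey) -> Path:
        return instance_directory(
            instance, self.study, self.stage_of(instance).branch_suffix
        )

    def flag_path(self, instance: InstanceKey) -> Path:
        return self.directory(instance) / instance.flag_name

    def record_for(self, source: InstanceKey, stream: str) -> StreamRecord | None:
        return read_stream_record(self.directory(source), stream)

    def incoming_streams(self, instance: InstanceKey) -> list[IncomingStream]:
        items = [
            IncomingStream(stream=stream, source=src, record=self.record_for(src, stream))
            for src, stream in self.incoming[instance]
        ]
        return items + list(self.remote_incoming[instance])

    # -- completion state --------------------------------------------------

    def current_input_snapshot(self, instance: InstanceKey) -> dict | None:
        """Digest snapshot of the instance's inputs as they are now, or
        None if some upstream record does not exist yet."""
        snapshot: dict[str, list] = {}
        for src, stream in self.incoming[instance]:
            record = self.record_for(src, stream)
            if record is None:
                return None
            key = f"{stream}@{src.stage_dir_name}:{coord_key(src.coordinate)}"
            snapshot[key] = [list(p) for p in current_digest_multiset(record)]
        for item in self.remote_incoming[instance]:
            key = f"{item.stream}@remote:{coord_key(item.record.producer.coordinate)}"
            snapshot[key] = [list(p) for p in item.record.digest_multiset()]
        return snapshot

    def snapshot_from_records(self, instance: InstanceKey, items) -> dict:
        snapshot: dict[str, list] = {}
        for item in items:
            where = (
                "remote"
                if item in self.remote_incoming[instance]
                else item.source.stage_dir_name
            )
            key = f"{item.stream}@{where}:{coord_key(item.source.coordinate)}"
            snapshot[key] = [list(p) for p in item.record.digest_multiset()]
        return snapshot

    def is_done(self, instance: InstanceKey) -> bool:
        """True iff the flag exists and current upstream digests equal the
        snapshot taken when the instance completed."""
        flag = self.flag_path(instance)
        if not flag.exists():
            return False
        try:
            stored = json.loads(flag.read_text()).get("inputs", {})
        except (json.JSONDecodeError, OSError):
            return False
        current = self.current_input_snapshot(instance)
        return current is not None and current == stored

    def write_flag(self, instance: InstanceKey, snapshot: dict) -> None:
        flag = self.flag_path(instance)
        tmp = flag.with_name(flag.name + ".tmp")
        tmp.write_text(
            json.dumps({"inputs": snapshot, "completed_at": time.time()}, indent=1)
        )
        os.replace(tmp, flag)  # atomic: a crash mid-write cannot fake completion

    def delete_flag(self, instance: InstanceKey) -> bool:
        flag = self.flag_path(instance)
        if flag.exists():
            flag.unlink()
            return True
        return False

    def downstream(self, instance: InstanceKey) -> set[InstanceKey]:
        return set(nx.descendants(self.graph, instance))

    def invalidate(self, instance: InstanceKey) -> set[InstanceKey]:
        """Delete the instance's flag and, transitively, every
        downstream-dependent flag; returns the closed set (idempotent)."""
        closed = {instance} | self.downstream(instance)
        for inst in closed:
            self.delete_flag(inst)
        return closed

    def sort_key(self, instance: InstanceKey):
        return (
            self.stage_pos[instance.stage_dir_name],
            coord_ids(instance.coordinate),
        )

    def topological_order(self) -> list[InstanceKey]:
        return list(
            nx.lexicographical_topological_sort(self.graph, key=self.sort_key)
        )


def invalidate(
    pipeline: ExpandedPipeline,
    study: StudyDescription,
    stage_name: str,
    coordinate_ids: tuple[str, ...] | None = None,
    stage_index: int | None = None,
    tree: DomainTree = DEFAULT_TREE,
) -> set[InstanceKey]:
    """Invalidate matching instances (and everything downstream of them)."""
    imap = InstanceMap(pipeline, study, tree)
    selected = [
        inst
        for inst in imap.graph.nodes
        if inst.stage_name == stage_name
        and (stage_index is None or inst.stage_index == stage_index)
        and (coordinate_ids is None or coord_ids(inst.coordinate) == tuple(coordinate_ids))
    ]
    closed: set[InstanceKey] = set()
    for inst in selected:
        closed |= imap.invalidate(inst)
    return closed


# ---------------------------------------------------------------------------
# provenance


@dataclass
class ProvenanceRecord:
    """Self-contained record of a run: merged parameters, expanded
    pipeline, study description, and per-instance status/timings.
    Serializable and reloadable to recreate the analysis."""

    engine_version: str
    backend: str
    parameters: dict
    stages: list[dict]
    study: dict
    instances: list[dict]
    executed: list[str] = field(default_factory=list)
    failed: list[str] = field(default_factory=list)
    blocked: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "engine_version": self.engine_version,
            "backend": self.backend,
            "parameters": self.parameters,
            "stages": self.stages,
            "study": self.study,
            "instances": self.instances,
            "executed": self.executed,
            "failed": self.failed,
            "blocked": self.blocked,
        }

    def save(self, analysis_root: Path) -> Path:
        path = Path(analysis_root) / PROVENANCE_NAME
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(self.to_dict(), indent=1, default=str))
        os.replace(tmp, path)
        return path


def load_provenance(analysis_root: Path) -> dict:
    return json.loads((Path(analysis_root) / PROVENANCE_NAME).read_text())


def _stage_summary(stage: Stage) -> dict:
    iface = stage.interface
    return {
        "name": stage.name,
        "index": stage.index,
        "key": stage.key,
        "settings_key": stage.settings_key,
        "domain": iface.domain if iface else None,
        "origin": stage.origin,
        "branch_suffix": stage.branch_suffix,
        "branch_path": list(stage.branch_path),
        "permanence_of_output": iface.permanence_of_output if iface else 0,
        "input_streams": list(iface.input_streams) if iface else [],
        "output_streams": list(iface.output_streams) if iface else [],
    }


def _instance_label(instance: InstanceKey) -> str:
    return f"{instance.stage_dir_name}:{coord_key(instance.coordinate)}"


# ---------------------------------------------------------------------------
# execution


def run_instance(
    imap: InstanceMap,
    instance: InstanceKey,
    settings: Mapping,
    registry: Mapping[str, Callable],
    placement_mode: str = "link",
) -> list[StreamRecord]:
    """Place inputs, invoke the implementation (resolved via the
    interface's implementation alias when present), register declared
    outputs, and write the completion flag."""
    stage = imap.stage_of(instance)
    directory = imap.directory(instance)
    directory.mkdir(parents=True, exist_ok=True)
    items = imap.incoming_streams(instance)
    placed = place_inputs(instance, directory, items, mode=placement_mode)
    ctx = ModuleContext(
        instance=instance,
        directory=directory,
        settings=settings,
        inputs={
            stream: [directory / rel for rel in rels]
            for stream, rels in placed.items()
        },
        study=imap.study,
        _log_path=directory / f"log_{stage.key}.txt",
    )
    impl_name = stage.interface.impl_name
    if impl_name not in registry:
        raise PipelineError(
            f"no implementation registered for {impl_name!r} "
            f"(stage {stage.key})"
        )
    ctx.log(f"running {impl_name} for {_instance_label(instance)}")
    produced = registry[impl_name](ctx) or {}
    records = register_outputs(
        instance, directory, stage.interface.output_streams, produced
    )
    imap.write_flag(instance, imap.snapshot_from_records(instance, items))
    ctx.log("completed")
    return records


def _run_initialisation(
    pipeline: ExpandedPipeline,
    study: StudyDescription,
    parameters: ParameterSet,
    registry: Mapping[str, Callable],
    tree: DomainTree,
) -> list[dict]:
    """Initialisation stages run unconditionally, every invocation."""
    results = []
    for stage in pipeline.init_stages:
        settings = parameters.tasksettings.get(
            stage.settings_key, dict(stage.interface.settings if stage.interface else {})
        )
        for coord in enumerate_coordinates(stage.interface.domain, study, tree):
            instance = InstanceKey(stage.name, stage.index, coord)
            directory = instance_directory(instance, study, stage.branch_suffix)
            directory.mkdir(parents=True, exist_ok=True)
            ctx = ModuleContext(
                instance=instance,
                directory=directory,
                settings=settings,
                inputs={},
                study=study,
                _log_path=directory / f"log_{stage.key}.txt",
            )
            registry[stage.interface.impl_name](ctx)
            results.append(
                {"stage_key": stage.key,
                 "coordinate": [list(p) for p in coord],
                 "status": "completed"}
            )
    return results


def _default_registry() -> Mapping[str, Callable]:
    from .toys import DEFAULT_REGISTRY

    return DEFAULT_REGISTRY


def run_pipeline(
    pipeline: ExpandedPipeline,
    study: StudyDescription,
    parameters: ParameterSet,
    *,
    registry: Mapping[str, Callable] | None = None,
    backend: str = "localsingle",
    n_workers: int = 2,
    tree: DomainTree = DEFAULT_TREE,
    remote: RemoteConnection | None = None,
    fail_fast: bool = False,
    placement_mode: str = "link",
) -> ProvenanceRecord:
    """Execute the pipeline incrementally and return the provenance record.

    Each main instance runs at most once per call, and only after the
    sources of all its dependency edges are done; with the parallel
    backend an instance becomes eligible the moment its own dependencies
    complete, independent of unrelated instances. On failure, dependent
    instances are blocked while independent subtrees continue (set
    ``fail_fast`` to stop dispatching instead).
    """
    if registry is None:
        registry = _default_registry()
    if backend not in ("localsingle", "localparallel"):
        raise PipelineError(f"unknown backend {backend!r}")

    init_results = _run_initialisation(pipeline, study, parameters, registry, tree)
    imap = InstanceMap(pipeline, study, tree, remote)

    # eagerly drop flags downstream of anything stale or never-run
    stale = {inst for inst in imap.graph.nodes if not imap.is_done(inst)}
    eager = set(stale)
    for inst in stale:
        eager |= imap.downstream(inst)
    for inst in eager:
        imap.delete_flag(inst)
    to_run = set(eager)

    # demand-driven regeneration: a needed upstream payload that has been
    # garbage-collected (or lost) pulls its producer back into the run set,
    # without touching flags of that producer's other consumers
    changed = True
    while changed:
        changed = False
        for inst in list(to_run):
            for src, stream in imap.incoming[inst]:
                if src in to_run:
                    continue
                record = imap.record_for(src, stream)
                if record is None or not record.available():
                    to_run.add(src)
                    imap.delete_flag(src)
                    changed = True

    order = [i for i in imap.topological_order() if i in to_run]
    statuses: dict[InstanceKey, str] = {
        inst: "skipped" for inst in imap.graph.nodes if inst not in to_run
    }
    timings: dict[InstanceKey, tuple[float, float]] = {}
    failures: dict[InstanceKey, str] = {}

    def settings_for(inst: InstanceKey) -> Mapping:
        stage = imap.stage_of(inst)
        return parameters.tasksettings.get(
            stage.settings_key, dict(stage.interface.settings)
        )

    def execute(inst: InstanceKey) -> None:
        start = time.time()
        run_instance(imap, inst, settings_for(inst), registry, placement_mode)
        timings[inst] = (start, time.time())

    blocked: set[InstanceKey] = set()
    stop = False
    if backend == "localsingle":
        for inst in order:
            if stop:
                break
            if inst in blocked:
                statuses[inst] = "blocked"
                continue
            try:
                execute(inst)
                statuses[inst] = "completed"
            except Exception as exc:
                statuses[inst] = "failed"
                failures[inst] = f"{exc}\n{traceback.format_exc()}"
                blocked |= imap.downstream(inst) & to_run
                if fail_fast:
                    stop = True
        for inst in order:
            if inst in blocked and statuses.get(inst) not in ("failed", "completed"):
                statuses[inst] = "blocked"
    else:
        pending = set(order)
        waiting_on = {
            inst: {
                src
                for src, _ in imap.incoming[inst]
                if src in pending or src in to_run
            } & set(order)
            for inst in order
        }
        running: dict = {}
        with ThreadPoolExecutor(max_workers=max(1, n_workers)) as pool:
            def ready() -> list[InstanceKey]:
                return sorted(
                    (
                        i
                        for i in pending
                        if not waiting_on[i] and i not in blocked
                    ),
                    key=imap.sort_key,
                )

            while pending or running:
                if not stop:
                    for inst in ready():
                        pending.discard(inst)
                        running[pool.submit(execute, inst)] = inst
                if not running:
                    break
                done, _ = wait(running, return_when=FIRST_COMPLETED)
                for future in done:
                    inst = running.pop(future)
                    error = future.exception()
                    if error is None:
                        statuses[inst] = "completed"
                        for other in waiting_on.values():
                            other.discard(inst)
                    else:
                        statuses[inst] = "failed"
                        failures[inst] = str(error)
                        blocked |= imap.downstream(inst) & (pending | to_run)
                        if fail_fast:
                            stop = True
            for inst in pending | blocked:
                if statuses.get(inst) not in ("failed", "completed"):
                    statuses[inst] = "blocked"

    instances = list(init_results)
    for inst in imap.topological_order():
        start, end = timings.get(inst, (None, None))
        entry = {
            "stage_key": inst.stage_dir_name,
            "coordinate": [list(p) for p in inst.coordinate],
            "status": statuses.get(inst, "blocked"),
            "started": start,
            "finished": end,
        }
        if inst in failures:
            entry["error"] = failures[inst].splitlines()[0]
        instances.append(entry)

    record = ProvenanceRecord(
        engine_version=ENGINE_VERSION,
        backend=backend,
        parameters={
            "global": parameters.global_settings,
            "tasksettings": parameters.tasksettings,
        },
        stages=[_stage_summary(s) for s in pipeline.all_stages],
        study=study.to_dict(),
        instances=instances,
        executed=[
            _instance_label(i) for i in order if statuses.get(i) == "completed"
        ],
        failed=[_instance_label(i) for i, s in statuses.items() if s == "failed"],
        blocked=[_instance_label(i) for i, s in statuses.items() if s == "blocked"],
    )
    record.save(study.analysis_root)
    return record


def output_tree_digests(
    pipeline: ExpandedPipeline,
    study: StudyDescription,
    tree: DomainTree = DEFAULT_TREE,
) -> dict[str, str]:
    """Map of every registered stream payload file (relative to the
    analysis root) to its content digest — the run's deterministic
    fingerprint, used to compare backends."""
    imap = InstanceMap(pipeline, study, tree)
    digests: dict[str, str] = {}
    for inst in imap.graph.nodes:
        stage = imap.stage_of(inst)
        directory = imap.directory(inst)
        for stream in stage.interface.output_streams:
            record = read_stream_record(directory, stream)
            if record is None:
                continue
            for f in record.files:
                rel = (directory / f.path).relative_to(study.analysis_root)
                digests[str(rel)] = f.digest
    return digests


def pipeline_from_provenance(prov: dict) -> ExpandedPipeline:
    """Reconstruct an expanded pipeline (interfaces included) from a
    persisted provenance record, e.g. to invalidate or inspect an existing
    analysis tree without the original declarative documents."""
    from .interfaces import ModuleInterface

    init_stages, stages = [], []
    for s in prov["stages"]:
        iface = ModuleInterface(
            name=s["name"],
            domain=s["domain"],
            input_streams=list(s["input_streams"]),
            output_streams=list(s["output_streams"]),
            permanence_of_output=s["permanence_of_output"],
        )
        stage = Stage(
            name=s["name"],
            index=s["index"],
            interface=iface,
            branch_suffix=s.get("branch_suffix", ""),
            branch_path=tuple(s.get("branch_path", ())),
            origin=s.get("origin", "main"),
        )
        (init_stages if stage.origin == "initialisation" else stages).append(stage)
    return ExpandedPipeline(init_stages=init_stages, stages=stages)


def dependency_graph_dot(imap: InstanceMap) -> str:
    """Dependency map in DOT format."""
    lines = ["digraph pipeline {"]
    for inst in imap.topological_order():
        lines.append(f'  "{_instance_label(inst)}";')
    for src, dst, data in imap.graph.edges(data=True):
        lines.append(
            f'  "{_instance_label(src)}" -> "{_instance_label(dst)}"'
            f' [label="{data.get("stream", "")}"];'
        )
    lines.append("}")
    return "\n".join(lines)
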