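"""Stream wiring: producer resolution, instance-level dependency edges,
input placement and output registration.

A *stream* is a named category of data (``epi``, ``structural``,
``realignment_parameter`` ...) passed between module instances by the
engine. Stream identity is the bare name; the processing state of the
payload is deliberately unspecified. Each completed instance registers one
:class:`StreamRecord` per declared output stream — a manifest of files and
content digests written alongside the data — and the engine materializes
exactly the requested records in a consumer's directory before it runs.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .domains import (
    Coordinate,
    InstanceKey,
    StudyDescription,
    DomainTree,
    DEFAULT_TREE,
    coord_ids,
    coordinate_relation,
    enumerate_coordinates,
)
from .errors import (
    DependencyNotReadyError,
    IllegalReadError,
    IllegalWriteError,
    MissingOutputError,
    UnconnectedStreamError,
)
from .interfaces import ExpandedPipeline, Stage, can_read_from


@dataclass(frozen=True)
class DependencyEdge:
    """One instance-level data dependency: target consumes ``stream``
    produced by source."""

    source: InstanceKey
    target: InstanceKey
    stream: str


@dataclass
class FileDigest:
    path: str  # relative to the producing instance's directory
    digest: str
    size: int

    def to_dict(self) -> dict:
        return {"path": self.path, "digest": self.digest, "size": self.size}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FileDigest":
        return cls(path=d["path"], digest=d["digest"], size=int(d["size"]))


@dataclass
class StreamRecord:
    """Registered output data of one instance for one stream."""

    stream: str
    producer: InstanceKey
    files: list[FileDigest]
    created_at: float = field(default_factory=time.time)
    stale: bool = False  # payload garbage-collected; digests still recorded
    directory: Path | None = None  # where the payload lives (not serialized)

    def digest_multiset(self) -> tuple[tuple[str, str], ...]:
        """Sorted (path, digest) pairs; stream change = any difference."""
        return tuple(sorted((f.path, f.digest) for f in self.files))

    def available(self) -> bool:
        if self.stale or self.directory is None:
            return False
        return all((self.directory / f.path).exists() for f in self.files)


def digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# manifest persistence


def manifest_path(directory: Path, stream: str) -> Path:
    return Path(directory) / f"stream_{stream}.json"


def write_stream_record(record: StreamRecord, directory: Path) -> Path:
    payload = {
        "stream": record.stream,
        "producer": {
            "stage_name": record.producer.stage_name,
            "stage_index": record.producer.stage_index,
            "coordinate": [list(pair) for pair in record.producer.coordinate],
        },
        "files": [f.to_dict() for f in record.files],
        "created_at": record.created_at,
        "stale": record.stale,
    }
    path = manifest_path(directory, record.stream)
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(payload, indent=1))
    os.replace(tmp, path)
    return path


def read_stream_record(directory: Path, stream: str) -> StreamRecord | None:
    path = manifest_path(directory, stream)
    if not path.exists():
        return None
    payload = json.loads(path.read_text())
    producer = InstanceKey(
        stage_name=payload["producer"]["stage_name"],
        stage_index=int(payload["producer"]["stage_index"]),
        coordinate=tuple(
            (node, ident) for node, ident in payload["producer"]["coordinate"]
        ),
    )
    return StreamRecord(
        stream=payload["stream"],
        producer=producer,
        files=[FileDigest.from_dict(f) for f in payload["files"]],
        created_at=payload.get("created_at", 0.0),
        stale=bool(payload.get("stale", False)),
        directory=Path(directory),
    )


def current_digest_multiset(record: StreamRecord, rehash: bool = True):
    """Digest multiset reflecting the payload *now*.

    Stale (garbage-collected) records keep their recorded digests — the
    data are regenerable, not changed. Live records are re-hashed so that
    out-of-band mutation is detected.
    """
    if record.stale or not rehash or record.directory is None:
        return record.digest_multiset()
    pairs = []
    for f in record.files:
        p = record.directory / f.path
        digest = digest_file(p) if p.exists() else f.digest
        pairs.append((f.path, digest))
    return tuple(sorted(pairs))


# ---------------------------------------------------------------------------
# producer resolution


def resolve_stream_source(
    pipeline: ExpandedPipeline,
    target_stage: Stage,
    stream: str,
) -> tuple[Stage, str]:
    """Which stage supplies ``stream`` to ``target_stage``.

    Returns ``(source stage, source stream name)``. A fully qualified
    reference ``module-name.stream-name`` on the invocation selects the
    named module's most recent prior occurrence; otherwise the nearest
    preceding stage whose outputs include the stream wins (stages that do
    not produce it are skipped). The backward search covers the target's
    own branch and the shared trunk, never a sibling branch.
    """
    stages = pipeline.stages
    target_pos = stages.index(target_stage)
    qualified = target_stage.qualified_inputs.get(stream)
    if qualified:
        module_name, source_stream = qualified.split(".", 1)
        for pos in range(target_pos - 1, -1, -1):
            candidate = stages[pos]
            if candidate.name != module_name:
                continue
            if not can_read_from(candidate, target_stage, pos, target_pos):
                continue
            if source_stream in (candidate.interface.output_streams if candidate.interface else []):
                return candidate, source_stream
        raise UnconnectedStreamError(
            f"stage {target_stage.key!r}: qualified reference {qualified!r} "
            f"matches no prior producer"
        )
    for pos in range(target_pos - 1, -1, -1):
        candidate = stages[pos]
        if not can_read_from(candidate, target_stage, pos, target_pos):
            continue
        outputs = candidate.interface.output_streams if candidate.interface else []
        if stream in outputs:
            return candidate, stream
    raise UnconnectedStreamError(
        f"stage {target_stage.key!r} consumes stream {stream!r} but no "
        f"earlier stage produces it"
    )


# ---------------------------------------------------------------------------
# instance-level dependency map


def _domain_relation(source_path: tuple, target_path: tuple) -> str:
    if source_path == target_path:
        return "equal"
    if source_path == target_path[: len(source_path)]:
        return "ancestor"
    if target_path == source_path[: len(target_path)]:
        return "descendant"
    return "disjoint"


def instance_sources(
    source_stage: Stage,
    target_coord: Coordinate,
    study: StudyDescription,
    tree: DomainTree = DEFAULT_TREE,
) -> list[InstanceKey]:
    """Source instances feeding one target coordinate, per the domain rules:
    equal domains match coordinates one-to-one; an ancestor-domain source
    contributes its unique prefix instance; a descendant-domain source fans
    in every instance beneath the target's coordinate. Sideways (disjoint)
    domains are illegal reads."""
    source_path = tree.path_below_root(source_stage.interface.domain)
    target_path = tuple(node for node, _ in target_coord)
    relation = _domain_relation(source_path, target_path)
    if relation == "disjoint":
        raise IllegalReadError(
            f"stream from domain {source_stage.interface.domain!r} to a "
            f"{'/'.join(target_path) or 'study'}-level instance crosses "
            f"domains sideways"
        )
    if relation == "equal":
        coords = [target_coord]
    elif relation == "ancestor":
        coords = [target_coord[: len(source_path)]]
    else:  # descendant: fan-in
        coords = [
            c
            for c in enumerate_coordinates(source_stage.interface.domain, study, tree)
            if c[: len(target_coord)] == target_coord
        ]
    return [
        InstanceKey(source_stage.name, source_stage.index, c) for c in coords
    ]


def build_dependency_map(
    pipeline: ExpandedPipeline,
    study: StudyDescription,
    tree: DomainTree = DEFAULT_TREE,
    remote_streams: Iterable[str] = (),
) -> set[DependencyEdge]:
    """Instance-level dependency edges for the whole pipeline.

    Raised errors (unconnected streams, sideways reads) surface here, at
    pipeline build time, before anything executes. Streams listed in
    ``remote_streams`` are satisfied by a connected remote pipeline and get
    no local edge.
    """
    remote = set(remote_streams)
    edges: set[DependencyEdge] = set()
    for target_stage in pipeline.stages:
        if target_stage.interface is None:
            continue
        for stream in target_stage.interface.input_streams:
            if stream in remote and stream not in target_stage.qualified_inputs:
                try:
                    resolve_stream_source(pipeline, target_stage, stream)
                except UnconnectedStreamError:
                    continue  # remote-bound
            source_stage, _src_stream = resolve_stream_source(
                pipeline, target_stage, stream
            )
            for target in _stage_instances(target_stage, study, tree):
                for source in instance_sources(
                    source_stage, target.coordinate, study, tree
                ):
                    rel = coordinate_relation(source.coordinate, target.coordinate)
                    assert rel != "disjoint"
                    edges.add(DependencyEdge(source, target, stream))
    return edges


def _stage_instances(stage: Stage, study, tree) -> list[InstanceKey]:
    from .domains import enumerate_instances

    return enumerate_instances(stage, study, tree)


# ---------------------------------------------------------------------------
# the data-placement contract


@dataclass
class IncomingStream:
    """One resolved input of an instance: the record to materialize and
    where its payload currently lives."""

    stream: str
    source: InstanceKey
    record: StreamRecord


def _fan_in_subdir(source: InstanceKey, target: InstanceKey) -> str:
    """Sub-folder key for fan-in placement (descendant sources land in
    per-source folders named by the coordinate below the target)."""
    rel = coordinate_relation(source.coordinate, target.coordinate)
    if rel == "descendant":
        below = source.coordinate[len(target.coordinate):]
        return "/".join(coord_ids(below))
    return ""


def place_inputs(
    instance: InstanceKey,
    directory: Path,
    incoming: Sequence[IncomingStream],
    mode: str = "link",
) -> dict[str, list[str]]:
    """Materialize exactly the requested streams under ``directory``.

    Each stream lands under ``inputs/<stream>/`` inside the instance
    directory (so placed data can never collide with the instance's own
    outputs), hard-linked when possible and copied otherwise. Fan-in
    sources are placed in per-source subfolders keyed by the source
    coordinate. A per-stream input manifest listing provenance digests is
    written alongside. Streams that are not requested are simply absent.
    Returns the placed manifest ``{stream: [relative paths]}``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    placed: dict[str, list[str]] = {}
    provenance: dict[str, list[dict]] = {}
    for item in incoming:
        record = item.record
        if record is None or not record.available():
            raise DependencyNotReadyError(
                f"instance {instance} needs stream {item.stream!r} from "
                f"{item.source}, which is not ready"
            )
        subdir = _fan_in_subdir(item.source, instance)
        rel_paths = []
        for f in record.files:
            rel = str(Path("inputs") / item.stream / subdir / f.path)
            dest = directory / rel
            dest.parent.mkdir(parents=True, exist_ok=True)
            src = record.directory / f.path
            if dest.exists():
                dest.unlink()
            if mode == "link":
                try:
                    os.link(src, dest)
                except OSError:
                    shutil.copy2(src, dest)
            else:
                shutil.copy2(src, dest)
            rel_paths.append(rel)
        placed.setdefault(item.stream, []).extend(rel_paths)
        provenance.setdefault(item.stream, []).append(
            {
                "source": {
                    "stage": item.source.stage_dir_name,
                    "coordinate": list(coord_ids(item.source.coordinate)),
                },
                "files": [f.to_dict() for f in record.files],
                "placed": rel_paths,
            }
        )
    for stream, sources in provenance.items():
        (directory / f"input_{stream}.json").write_text(
            json.dumps({"stream": stream, "sources": sources}, indent=1)
        )
    return placed


def register_outputs(
    instance: InstanceKey,
    directory: Path,
    declared_streams: Sequence[str],
    produced: Mapping[str, Sequence[str | Path]],
) -> list[StreamRecord]:
    """Register the declared output streams of a completed instance.

    ``produced`` maps stream name to the files the implementation wrote
    (relative to, or inside, the instance directory). Undeclared entries
    are ignored — if a module does not declare an output it is not passed.
    A declared stream with no files is an error, as is any file outside
    the instance's own directory (a sideways or upward write).
    """
    directory = Path(directory).resolve()
    records = []
    for stream in declared_streams:
        files = list(produced.get(stream, []))
        if not files:
            raise MissingOutputError(
                f"instance {instance} declared output stream {stream!r} "
                f"but produced no files for it"
            )
        digests = []
        for item in files:
            p = Path(item)
            abspath = (p if p.is_absolute() else directory / p).resolve()
            try:
                rel = abspath.relative_to(directory)
            except ValueError:
                raise IllegalWriteError(
                    f"instance {instance} wrote {abspath} outside its own "
                    f"directory {directory} (modules must never write "
                    f"outside their domain)"
                )
            if not abspath.exists():
                raise MissingOutputError(
                    f"instance {instance}: declared output file {abspath} "
                    f"does not exist"
                )
            digests.append(
                FileDigest(
                    path=str(rel),
                    digest=digest_file(abspath),
                    size=abspath.stat().st_size,
                )
            )
        record = StreamRecord(
            stream=stream, producer=instance, files=digests, directory=directory
        )
        write_stream_record(record, directory)
        records.append(record)
    return records
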