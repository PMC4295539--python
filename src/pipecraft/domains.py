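"""Domain hierarchy, study description, and instance enumeration.

A *domain* is the granularity at which a processing module instantiates:
``study`` modules run once, ``subject`` modules once per subject, and
``session`` modules once per (subject, session). Domains form a tree rooted
at ``study``; additional session-like leaves (e.g. ``diffusion_session``)
may be registered as siblings of ``session``.

A :class:`DomainCoordinate` pins an instance to one point of that tree as
the ordered path of (node, identifier) pairs below the root: the study
level is the empty path, ``(("subject", "S1"),)`` is subject S1, and
``(("subject", "S1"), ("session", "movie"))`` is that subject's movie
session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import DomainError, SchemaError

# A coordinate is an ordered path of (domain-node, identifier) pairs below
# the tree root. The study level is the empty tuple.
Coordinate = tuple[tuple[str, str], ...]


def coord_ids(coord: Coordinate) -> tuple[str, ...]:
    """Identifiers along a coordinate path, e.g. ('S1', 'movie')."""
    return tuple(ident for _, ident in coord)


def coord_key(coord: Coordinate) -> str:
    """Filesystem-style key for a coordinate ('' at study level)."""
    return "/".join(coord_ids(coord))


@dataclass(frozen=True)
class DomainTree:
    """Tree of domain nodes rooted at ``study``.

    ``children`` maps each node to its child nodes. The default tree is the
    study → subject → session chain; new leaves can be grafted with
    :meth:`with_session_domain`.
    """

    children: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "study": ("subject",),
            "subject": ("session",),
            "session": (),
        }
    )
    root: str = "study"

    def nodes(self) -> set[str]:
        found = set(self.children)
        for kids in self.children.values():
            found.update(kids)
        return found

    def has_node(self, node: str) -> bool:
        return node in self.nodes()

    def path_below_root(self, node: str) -> tuple[str, ...]:
        """Path of nodes from (but excluding) the root down to ``node``."""
        if node == self.root:
            return ()

        def search(current: str, trail: tuple[str, ...]) -> tuple[str, ...] | None:
            for child in self.children.get(current, ()):
                if child == node:
                    return trail + (child,)
                deeper = search(child, trail + (child,))
                if deeper is not None:
                    return deeper
            return None

        path = search(self.root, ())
        if path is None:
            raise DomainError(f"domain {node!r} is not a node of the domain tree")
        return path

    def with_session_domain(self, name: str) -> "DomainTree":
        """Return a tree with an extra session-like leaf under subject."""
        children = {k: tuple(v) for k, v in self.children.items()}
        children["subject"] = children.get("subject", ()) + (name,)
        children[name] = ()
        return DomainTree(children=children, root=self.root)


DEFAULT_TREE = DomainTree()


def coordinate_relation(a: Coordinate, b: Coordinate) -> str:
    """Relation of two coordinates on the same tree.

    ``ancestor`` means ``a``'s path is a proper prefix of ``b``'s (``a`` is
    nearer the trunk); ``disjoint`` covers sideways coordinates (neither is
    a prefix of the other), from which reads are never permitted.
    """
    if a == b:
        return "equal"
    if len(a) < len(b) and b[: len(a)] == a:
        return "ancestor"
    if len(b) < len(a) and a[: len(b)] == b:
        return "descendant"
    return "disjoint"


@dataclass
class StudyDescription:
    """What data the analysis operates on, and where results go.

    ``input_locations`` maps identifier tuples to raw NIfTI paths: a
    ``(subject, session)`` key locates a 4D EPI series, a ``(subject,)``
    key a structural volume. ``numdummies`` initial volumes of each EPI
    series are discarded before modelling (steady-state magnetisation).
    """

    analysis_root: Path
    analysis_id: str
    subjects: list[str]
    sessions_per_subject: dict[str, list[str]]
    input_locations: dict[tuple[str, ...], Path] = field(default_factory=dict)
    numdummies: int = 0
    extra_units: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self):
        self.analysis_root = Path(self.analysis_root)
        if not self.analysis_id:
            raise SchemaError("analysis_id must be nonempty")
        if self.numdummies < 0:
            raise SchemaError("numdummies must be >= 0")
        for subject in self.sessions_per_subject:
            if subject not in self.subjects:
                raise SchemaError(
                    f"sessions listed for unknown subject {subject!r}"
                )
        self.input_locations = {
            tuple(k): Path(v) for k, v in self.input_locations.items()
        }

    def sessions(self, subject: str) -> list[str]:
        return self.sessions_per_subject.get(subject, [])

    def units(self, node: str, subject: str) -> list[str]:
        """Per-subject unit names for a session-like domain node."""
        if node == "session":
            return self.sessions(subject)
        return self.extra_units.get(node, {}).get(subject, [])

    def to_dict(self) -> dict:
        return {
            "analysis_root": str(self.analysis_root),
            "analysis_id": self.analysis_id,
            "subjects": list(self.subjects),
            "sessions_per_subject": {
                k: list(v) for k, v in self.sessions_per_subject.items()
            },
            "input_locations": {
                "/".join(k): str(v) for k, v in self.input_locations.items()
            },
            "numdummies": self.numdummies,
            "extra_units": self.extra_units,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDescription":
        locations = {
            tuple(key.split("/")): Path(value)
            for key, value in (d.get("input_locations") or {}).items()
        }
        return cls(
            analysis_root=Path(d["analysis_root"]),
            analysis_id=d["analysis_id"],
            subjects=list(d["subjects"]),
            sessions_per_subject={
                k: list(v) for k, v in (d.get("sessions_per_subject") or {}).items()
            },
            input_locations=locations,
            numdummies=int(d.get("numdummies", 0)),
            extra_units=dict(d.get("extra_units") or {}),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "StudyDescription":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class InstanceKey:
    """One executable unit: a pipeline stage bound to a domain coordinate."""

    stage_name: str
    stage_index: int
    coordinate: Coordinate

    @property
    def stage_dir_name(self) -> str:
        return f"{self.stage_name}_{self.stage_index:05d}"

    @property
    def flag_name(self) -> str:
        return f"done_{self.stage_name}_{self.stage_index:05d}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = coord_key(self.coordinate) or "<study>"
        return f"{self.stage_dir_name}[{where}]"


def enumerate_coordinates(
    domain: str, study: StudyDescription, tree: DomainTree = DEFAULT_TREE
) -> list[Coordinate]:
    """All coordinates at ``domain`` for a study, in deterministic order
    (subject order, then session order within each subject)."""
    path = tree.path_below_root(domain)
    if len(path) == 0:
        return [()]
    if path == ("subject",):
        return [(("subject", s),) for s in study.subjects]
    if len(path) == 2 and path[0] == "subject":
        leaf = path[1]
        coords: list[Coordinate] = []
        for subject in study.subjects:
            for unit in study.units(leaf, subject):
                coords.append((("subject", subject), (leaf, unit)))
        return coords
    raise DomainError(f"unsupported domain path {path!r}")


def enumerate_instances(
    stage, study: StudyDescription, tree: DomainTree = DEFAULT_TREE
) -> list[InstanceKey]:
    """One :class:`InstanceKey` per coordinate of the stage's domain."""
    domain = stage.interface.domain
    return [
        InstanceKey(stage.name, stage.index, coord)
        for coord in enumerate_coordinates(domain, study, tree)
    ]


def instance_directory(
    instance: InstanceKey,
    study: StudyDescription,
    branch_suffix: str = "",
) -> Path:
    """Directory in which an instance executes.

    Layout: ``analysis_root / (analysis_id + branch_suffix) /
    <stage>_<index> / <subject> / <session>``, truncated at the stage's
    domain level; study-domain instances live in the stage directory
    itself. Subject and session directory names are the user-supplied
    identifiers verbatim.
    """
    base = (
        study.analysis_root
        / (study.analysis_id + branch_suffix)
        / instance.stage_dir_name
    )
    for ident in coord_ids(instance.coordinate):
        base = base / ident
    return base


def iter_all_instances(stages: Iterable, study, tree=DEFAULT_TREE):
    for stage in stages:
        yield from enumerate_instances(stage, study, tree)
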