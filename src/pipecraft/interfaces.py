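"""Declarative pipeline description: module interfaces, tasklists, parameters.

Every processing stage is described by an XML *interface* document giving
its domain, default settings, resource estimates, and the named data
streams it consumes and produces::

    <interface name="smooth">
      <currenttask domain="session" desc="Smooth EPI" modality="MRI">
        <qsub><memoryBase>0.5</memoryBase><timeBase>1</timeBase></qsub>
        <permanenceofoutput>1</permanenceofoutput>
        <settings><FWHM>10</FWHM></settings>
        <inputstreams><stream>epi</stream></inputstreams>
        <outputstreams><stream>epi</stream></outputstreams>
      </currenttask>
    </interface>

A *tasklist* orders module invocations (an ``initialisation`` list that is
run every time, and a ``main`` list that is run incrementally), possibly
with branches. A YAML dialect with identical information content is
accepted alongside XML; XML remains canonical.
"""

from __future__ import annotations

import copy
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import yaml

from .domains import DEFAULT_TREE, DomainTree
from .errors import (
    DomainError,
    InclusionError,
    SchemaError,
    UnknownSettingError,
)

XINCLUDE_NS = "http://www.w3.org/2001/XInclude"
XINCLUDE_TAG = f"{{{XINCLUDE_NS}}}include"


# ---------------------------------------------------------------------------
# value coercion: XML carries text only


def _number(text: str):
    try:
        return int(text)
    except ValueError:
        return float(text)


def coerce_value(text: str | None):
    """Turn XML text into a number, boolean, numeric vector, or string."""
    if text is None:
        return ""
    s = text.strip()
    if s == "":
        return ""
    if s.lower() in ("true", "false"):
        return s.lower() == "true"
    try:
        return _number(s)
    except ValueError:
        pass
    parts = s.split()
    if len(parts) > 1:
        try:
            return [_number(p) for p in parts]
        except ValueError:
            pass
    return s


def _value_to_text(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (list, tuple)):
        return " ".join(str(v) for v in value)
    return str(value)


def _parse_settings(element: ET.Element | None) -> dict:
    """Nested settings map; leaves coerced, children recursed."""
    if element is None:
        return {}
    settings: dict = {}
    for child in element:
        if len(child):
            settings[child.tag] = _parse_settings(child)
        else:
            settings[child.tag] = coerce_value(child.text)
    return settings


def _settings_to_xml(parent: ET.Element, settings: Mapping) -> None:
    for key, value in settings.items():
        sub = ET.SubElement(parent, key)
        if isinstance(value, Mapping):
            _settings_to_xml(sub, value)
        else:
            sub.text = _value_to_text(value)


# ---------------------------------------------------------------------------
# module interfaces


@dataclass
class ModuleInterface:
    """Declarative description of one processing stage."""

    name: str
    domain: str
    description: str = ""
    modality: str = ""
    settings: dict = field(default_factory=dict)
    input_streams: list[str] = field(default_factory=list)
    output_streams: list[str] = field(default_factory=list)
    resource_estimates: dict = field(default_factory=dict)
    permanence_of_output: int = 0
    impl_alias: str | None = None
    extra_elements: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not self.name:
            raise SchemaError("module interface name must be nonempty")
        for streams, label in (
            (self.input_streams, "input"),
            (self.output_streams, "output"),
        ):
            if len(streams) != len(set(streams)):
                raise SchemaError(
                    f"duplicate {label} stream names in interface {self.name!r}"
                )
        if self.permanence_of_output < 0:
            raise SchemaError(
                f"permanenceofoutput must be >= 0 in interface {self.name!r}"
            )

    @property
    def impl_name(self) -> str:
        """Implementation to invoke: the alias when declared, else the name."""
        return self.impl_alias or self.name


_KNOWN_TASK_CHILDREN = {
    "qsub",
    "permanenceofoutput",
    "settings",
    "inputstreams",
    "outputstreams",
}


def parse_module_interface(
    document: str,
    *,
    name: str | None = None,
    tree: DomainTree = DEFAULT_TREE,
) -> ModuleInterface:
    """Parse one XML interface document.

    The stage name comes from the root's ``name`` attribute (or the
    ``name`` keyword, e.g. derived from the filename). Missing optional
    blocks yield empty collections; unknown extra elements are preserved
    but ignored.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise SchemaError(f"malformed interface document: {exc}") from exc
    task = root if root.tag == "currenttask" else root.find(".//currenttask")
    if task is None:
        raise SchemaError(
            f"interface document {name or root.tag!r} lacks a <currenttask> element"
        )
    iface_name = root.get("name") or task.get("name") or name
    if not iface_name:
        raise SchemaError("interface document does not declare a module name")
    domain = task.get("domain")
    if domain is None:
        raise SchemaError(
            f"interface document {iface_name!r} is missing the domain attribute"
        )
    if not tree.has_node(domain):
        raise DomainError(
            f"interface {iface_name!r} declares unknown domain {domain!r}"
        )

    qsub = task.find("qsub")
    permanence = task.find("permanenceofoutput")
    settings = _parse_settings(task.find("settings"))
    input_streams = [
        (s.text or "").strip() for s in task.findall("inputstreams/stream")
    ]
    output_streams = [
        (s.text or "").strip() for s in task.findall("outputstreams/stream")
    ]
    extras = [
        ET.tostring(child, encoding="unicode")
        for child in task
        if child.tag not in _KNOWN_TASK_CHILDREN
    ]
    return ModuleInterface(
        name=iface_name,
        domain=domain,
        description=task.get("desc", ""),
        modality=task.get("modality", ""),
        settings=settings,
        input_streams=input_streams,
        output_streams=output_streams,
        resource_estimates=_parse_settings(qsub),
        permanence_of_output=(
            int(permanence.text.strip()) if permanence is not None else 0
        ),
        impl_alias=task.get("impl_alias") or root.get("impl_alias"),
        extra_elements=extras,
    )


def serialize_module_interface(iface: ModuleInterface) -> str:
    """Inverse of :func:`parse_module_interface` (semantically lossless)."""
    root = ET.Element("interface", {"name": iface.name})
    attrs = {"domain": iface.domain}
    if iface.description:
        attrs["desc"] = iface.description
    if iface.modality:
        attrs["modality"] = iface.modality
    if iface.impl_alias:
        attrs["impl_alias"] = iface.impl_alias
    task = ET.SubElement(root, "currenttask", attrs)
    if iface.resource_estimates:
        _settings_to_xml(ET.SubElement(task, "qsub"), iface.resource_estimates)
    perm = ET.SubElement(task, "permanenceofoutput")
    perm.text = str(iface.permanence_of_output)
    if iface.settings:
        _settings_to_xml(ET.SubElement(task, "settings"), iface.settings)
    instreams = ET.SubElement(task, "inputstreams")
    for s in iface.input_streams:
        ET.SubElement(instreams, "stream").text = s
    outstreams = ET.SubElement(task, "outputstreams")
    for s in iface.output_streams:
        ET.SubElement(outstreams, "stream").text = s
    return ET.tostring(root, encoding="unicode")


def module_interface_from_dict(d: Mapping, *, tree: DomainTree = DEFAULT_TREE) -> ModuleInterface:
    iface = ModuleInterface(
        name=d["name"],
        domain=d["domain"],
        description=d.get("description", ""),
        modality=d.get("modality", ""),
        settings=dict(d.get("settings") or {}),
        input_streams=list(d.get("inputstreams") or []),
        output_streams=list(d.get("outputstreams") or []),
        resource_estimates=dict(d.get("qsub") or {}),
        permanence_of_output=int(d.get("permanenceofoutput", 0)),
        impl_alias=d.get("impl_alias"),
    )
    if not tree.has_node(iface.domain):
        raise DomainError(
            f"interface {iface.name!r} declares unknown domain {iface.domain!r}"
        )
    return iface


def load_module_interface(
    text: str, *, name: str | None = None, tree: DomainTree = DEFAULT_TREE
) -> ModuleInterface:
    """Load an interface from XML (canonical) or the YAML dialect."""
    if text.lstrip().startswith("<"):
        return parse_module_interface(text, name=name, tree=tree)
    d = yaml.safe_load(text)
    if name and "name" not in d:
        d["name"] = name
    return module_interface_from_dict(d, tree=tree)


# ---------------------------------------------------------------------------
# tasklists


@dataclass
class ModuleInvocation:
    """One occurrence of a module in a tasklist."""

    module_name: str
    local_settings: dict = field(default_factory=dict)
    # consumed-stream -> fully qualified "module-name.stream-name" source
    qualified_inputs: dict[str, str] = field(default_factory=dict)


@dataclass
class Branch:
    """A fork: alternatives share the upstream trunk and diverge below."""

    alternatives: list[tuple[str, list[ModuleInvocation]]]

    def __post_init__(self):
        if len(self.alternatives) < 2:
            raise SchemaError("a branch must contain at least 2 alternatives")
        suffixes = [s for s, _ in self.alternatives]
        if len(suffixes) != len(set(suffixes)):
            raise SchemaError("branch alternative suffixes must be distinct")


@dataclass
class Tasklist:
    initialisation: list[ModuleInvocation] = field(default_factory=list)
    main: list = field(default_factory=list)  # ModuleInvocation | Branch


def _parse_invocation(el: ET.Element) -> ModuleInvocation:
    name_el = el.find("name")
    if name_el is None or not (name_el.text or "").strip():
        raise SchemaError("tasklist <module> entry lacks a <name>")
    qualified = {}
    for inp in el.findall("input"):
        stream = inp.get("stream")
        source = inp.get("from")
        if not stream or not source or "." not in source:
            raise SchemaError(
                "qualified input needs stream=... and from='module.stream'"
            )
        if stream in qualified:
            raise SchemaError(
                f"duplicate qualified input for stream {stream!r}"
            )
        qualified[stream] = source
    return ModuleInvocation(
        module_name=name_el.text.strip(),
        local_settings=_parse_settings(el.find("settings")),
        qualified_inputs=qualified,
    )


def parse_tasklist(document: str) -> Tasklist:
    """Parse an XML tasklist (initialisation + main, branches allowed)."""
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise SchemaError(f"malformed tasklist document: {exc}") from exc
    init = [
        _parse_invocation(m) for m in root.findall("initialisation/module")
    ]
    main: list = []
    main_el = root.find("main")
    if main_el is not None:
        for entry in main_el:
            if entry.tag == "module":
                main.append(_parse_invocation(entry))
            elif entry.tag == "branch":
                alternatives = []
                for alt in entry.findall("alternative"):
                    suffix = alt.get("analysisid_suffix", "")
                    mods = [_parse_invocation(m) for m in alt.findall("module")]
                    alternatives.append((suffix, mods))
                main.append(Branch(alternatives))
            else:
                raise SchemaError(
                    f"unexpected tasklist entry <{entry.tag}>"
                )
    return Tasklist(initialisation=init, main=main)


def _invocation_from_dict(d) -> ModuleInvocation:
    if isinstance(d, str):
        return ModuleInvocation(module_name=d)
    return ModuleInvocation(
        module_name=d["module"],
        local_settings=dict(d.get("settings") or {}),
        qualified_inputs=dict(d.get("inputs") or {}),
    )


def load_tasklist(text: str) -> Tasklist:
    """Load a tasklist from XML (canonical) or the YAML dialect."""
    if text.lstrip().startswith("<"):
        return parse_tasklist(text)
    d = yaml.safe_load(text)
    main: list = []
    for entry in d.get("main") or []:
        if isinstance(entry, Mapping) and "branch" in entry:
            alternatives = [
                (
                    alt.get("suffix", ""),
                    [_invocation_from_dict(m) for m in alt.get("modules") or []],
                )
                for alt in entry["branch"]
            ]
            main.append(Branch(alternatives))
        else:
            main.append(_invocation_from_dict(entry))
    init = [_invocation_from_dict(m) for m in d.get("initialisation") or []]
    return Tasklist(initialisation=init, main=main)


# ---------------------------------------------------------------------------
# XML inclusion with local overrides


def _merge_override(target: ET.Element, override: ET.Element) -> None:
    """Replace same-named elements of ``target`` with ``override``'s content,
    recursing where both sides have children."""
    match = target.find(override.tag)
    if match is None:
        target.append(copy.deepcopy(override))
        return
    if len(override) and len(match):
        for child in override:
            _merge_override(match, child)
    else:
        idx = list(target).index(match)
        target.remove(match)
        target.insert(idx, copy.deepcopy(override))


def _resolve_element(
    el: ET.Element, resolver: Callable[[str], str], stack: tuple[str, ...]
) -> None:
    # splice includes, depth first, in document order
    position = 0
    while position < len(el):
        child = el[position]
        if child.tag == XINCLUDE_TAG:
            href = child.get("href", "")
            if href in stack:
                chain = " -> ".join(stack + (href,))
                raise InclusionError(f"inclusion cycle: {chain}")
            try:
                text = resolver(href)
            except Exception as exc:
                raise InclusionError(
                    f"cannot resolve inclusion target {href!r}: {exc}"
                ) from exc
            if text is None:
                raise InclusionError(f"cannot resolve inclusion target {href!r}")
            included = ET.fromstring(text)
            _resolve_element(included, resolver, stack + (href,))
            el.remove(child)
            if included.tag == el.tag:
                # same root tag: splice children flat so <local> overrides
                # can address the included content
                for offset, grandchild in enumerate(list(included)):
                    el.insert(position + offset, grandchild)
                position += len(included)
            else:
                el.insert(position, included)
                position += 1
        else:
            _resolve_element(child, resolver, stack)
            position += 1
    # then apply <local> override sections
    for local in [c for c in el if c.tag == "local"]:
        el.remove(local)
        for override in local:
            _merge_override(el, override)


def resolve_inclusion(document: str, resolver: Callable[[str], str]) -> str:
    """Expand XInclude references and apply ``<local>`` override sections.

    ``resolver`` maps an href to document text. Included content is spliced
    in document order; elements inside a ``<local>`` section then replace
    same-named elements from the included content. A document with no
    includes and no local section is returned semantically unchanged.
    """
    root = ET.fromstring(document)
    _resolve_element(root, resolver, stack=())
    return ET.tostring(root, encoding="unicode")


# ---------------------------------------------------------------------------
# parameter documents and the three-source merge


@dataclass
class ParameterSet:
    """Fully merged analysis parameters.

    ``global_settings`` holds engine-wide namespaces (``acq_details``,
    ``directory_conventions``, ``options``, ...); ``tasksettings`` holds
    one fully-merged settings map per pipeline stage, keyed by the stage
    name (index 1) or ``name_0000k`` (k > 1).
    """

    global_settings: dict = field(default_factory=dict)
    tasksettings: dict[str, dict] = field(default_factory=dict)


def parse_parameters(document: str) -> ParameterSet:
    """Parse a parameter-defaults document (any root tag; nested values)."""
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise SchemaError(f"malformed parameter document: {exc}") from exc
    global_settings = {}
    tasksettings = {}
    for child in root:
        if child.tag == "tasksettings":
            tasksettings = _parse_settings(child)
        elif len(child):
            global_settings[child.tag] = _parse_settings(child)
        else:
            global_settings[child.tag] = coerce_value(child.text)
    return ParameterSet(global_settings=global_settings, tasksettings=tasksettings)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if (
            key in out
            and isinstance(out[key], dict)
            and isinstance(value, Mapping)
        ):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value) if isinstance(value, dict) else value
    return out


def settings_key(name: str, index: int) -> str:
    """Addressing key for per-stage settings: bare name for the first
    occurrence, ``name_0000k`` for repeats."""
    return name if index == 1 else f"{name}_{index:05d}"


def merge_parameters(
    defaults: ParameterSet,
    tasklist: Tasklist,
    interfaces: Mapping[str, ModuleInterface] | Sequence[ModuleInterface],
    user_overrides: Mapping | None = None,
) -> ParameterSet:
    """Merge the three parameter sources into a self-contained set.

    Precedence, lowest to highest: interface defaults, tasklist
    per-invocation settings, parameter-document ``tasksettings``, then
    user overrides (``{"tasksettings": {stage: {...}}, "options": {...}}``).
    Overrides addressing a nonexistent stage or setting raise
    :class:`UnknownSettingError`. Merging an already-merged set with empty
    overrides is the identity.
    """
    if not isinstance(interfaces, Mapping):
        interfaces = {i.name: i for i in interfaces}
    user_overrides = dict(user_overrides or {})
    user_task = user_overrides.pop("tasksettings", {})

    pipeline = expand_tasklist(tasklist, interfaces=interfaces)
    merged_global = _deep_merge(defaults.global_settings, user_overrides)

    merged_tasks: dict[str, dict] = {}
    for stage in pipeline.all_stages:
        iface = interfaces[stage.name]
        merged = copy.deepcopy(iface.settings)
        for source in (
            stage.invocation_settings,
            defaults.tasksettings.get(stage.settings_key, {}),
        ):
            for key in source:
                if key not in iface.settings:
                    raise UnknownSettingError(
                        f"setting {key!r} does not exist in interface "
                        f"{stage.name!r}"
                    )
            merged = _deep_merge(merged, source)
        merged_tasks[stage.settings_key] = merged

    for stage_key, overrides in user_task.items():
        if stage_key not in merged_tasks:
            raise UnknownSettingError(
                f"override addresses unknown stage {stage_key!r}"
            )
        stage_name = stage_key if stage_key in interfaces else stage_key.rsplit("_", 1)[0]
        iface = interfaces[stage_name]
        for key in overrides:
            if key not in iface.settings:
                raise UnknownSettingError(
                    f"override addresses unknown setting {key!r} of stage "
                    f"{stage_key!r}"
                )
        merged_tasks[stage_key] = _deep_merge(merged_tasks[stage_key], overrides)

    return ParameterSet(global_settings=merged_global, tasksettings=merged_tasks)


# ---------------------------------------------------------------------------
# tasklist expansion


@dataclass
class Stage:
    """One stage of the expanded pipeline."""

    name: str
    index: int
    interface: ModuleInterface | None = None
    invocation_settings: dict = field(default_factory=dict)
    branch_suffix: str = ""
    qualified_inputs: dict[str, str] = field(default_factory=dict)
    branch_path: tuple = ()
    origin: str = "main"  # "initialisation" | "main"

    @property
    def key(self) -> str:
        """Directory-name key, e.g. ``smooth_00001``."""
        return f"{self.name}_{self.index:05d}"

    @property
    def settings_key(self) -> str:
        return settings_key(self.name, self.index)


@dataclass
class ExpandedPipeline:
    """Linear, indexed serialization of a tasklist."""

    init_stages: list[Stage] = field(default_factory=list)
    stages: list[Stage] = field(default_factory=list)

    @property
    def all_stages(self) -> list[Stage]:
        return self.init_stages + self.stages

    def stage(self, key: str) -> Stage:
        for s in self.all_stages:
            if s.key == key or (s.index == 1 and s.name == key):
                return s
        raise KeyError(key)


def can_read_from(source: Stage, target: Stage, source_pos: int, target_pos: int) -> bool:
    """Whether ``target`` may take input from ``source``: the source must
    precede the target and lie on the target's own branch path or the
    shared trunk — never on a sibling branch."""
    if source_pos >= target_pos:
        return False
    return source.branch_path == target.branch_path[: len(source.branch_path)]


def expand_tasklist(
    tasklist: Tasklist,
    interfaces: Mapping[str, ModuleInterface] | Sequence[ModuleInterface] | None = None,
) -> ExpandedPipeline:
    """Flatten a tasklist (branches alternative-by-alternative, in
    declaration order) and assign each stage an occurrence index: 1 + the
    number of earlier occurrences of the same module name."""
    if interfaces is not None and not isinstance(interfaces, Mapping):
        interfaces = {i.name: i for i in interfaces}
    counts: dict[str, int] = {}

    def make_stage(inv: ModuleInvocation, suffix: str, path: tuple, origin: str) -> Stage:
        counts[inv.module_name] = counts.get(inv.module_name, 0) + 1
        iface = None
        if interfaces is not None:
            if inv.module_name not in interfaces:
                raise SchemaError(
                    f"no interface document for module {inv.module_name!r}"
                )
            iface = interfaces[inv.module_name]
            for key in inv.local_settings:
                if key not in iface.settings:
                    raise UnknownSettingError(
                        f"tasklist sets unknown setting {key!r} on module "
                        f"{inv.module_name!r}"
                    )
        return Stage(
            name=inv.module_name,
            index=counts[inv.module_name],
            interface=iface,
            invocation_settings=copy.deepcopy(inv.local_settings),
            branch_suffix=suffix,
            qualified_inputs=dict(inv.qualified_inputs),
            branch_path=path,
            origin=origin,
        )

    init_stages = [
        make_stage(inv, "", (), "initialisation") for inv in tasklist.initialisation
    ]
    stages: list[Stage] = []
    branch_seq = 0
    for entry in tasklist.main:
        if isinstance(entry, Branch):
            for alt_index, (suffix, invs) in enumerate(entry.alternatives):
                for inv in invs:
                    stages.append(
                        make_stage(inv, suffix, (branch_seq, alt_index), "main")
                    )
            branch_seq += 1
        else:
            stages.append(make_stage(entry, "", (), "main"))
    return ExpandedPipeline(init_stages=init_stages, stages=stages)
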