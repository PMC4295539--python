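"""Bundled interface documents, tasklists, and parameter defaults."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .interfaces import (
    ModuleInterface,
    ParameterSet,
    Tasklist,
    load_module_interface,
    load_tasklist,
    parse_parameters,
)


def _data_dir():
    return resources.files("pipecraft") / "data"


def builtin_interfaces() -> dict[str, ModuleInterface]:
    """All bundled module interfaces, keyed by name (from the filename)."""
    out = {}
    for entry in sorted((_data_dir() / "modules").iterdir(), key=lambda e: e.name):
        if entry.name.endswith((".xml", ".yaml")):
            iface = load_module_interface(
                entry.read_text(), name=entry.name.rsplit(".", 1)[0]
            )
            out[iface.name] = iface
    return out


def load_interfaces_dir(path: Path) -> dict[str, ModuleInterface]:
    out = {}
    for entry in sorted(Path(path).iterdir()):
        if entry.suffix in (".xml", ".yaml"):
            iface = load_module_interface(entry.read_text(), name=entry.stem)
            out[iface.name] = iface
    return out


def builtin_tasklist(name: str = "toy_fmri") -> Tasklist:
    text = (_data_dir() / "tasklists" / f"{name}.xml").read_text()
    return load_tasklist(text)


def builtin_parameters() -> ParameterSet:
    return parse_parameters((_data_dir() / "parameters_defaults.xml").read_text())
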