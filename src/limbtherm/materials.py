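"""Library of bench-measured prosthetic materials and stack combinations.

The shipped defaults cover five liners, one stump sock and three socket
lay-ups, each with its individually measured thermal time constant, plus
six liner+socket combinations with the (slower) time constant measured
at the liner-socket interface.  A custom library can be loaded from any
YAML file with the same layout.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .exceptions import ValidationError
from .thermal import LayerKind, Material, StackSpec

__all__ = ["MaterialLibrary", "material_library", "load_library"]


@dataclass(frozen=True)
class MaterialLibrary:
    materials: tuple[Material, ...]
    stacks: tuple[StackSpec, ...]

    def material(self, name: str) -> Material:
        """Look up a single material by (case-insensitive) name."""
        key = name.strip().lower()
        for m in self.materials:
            if m.name.lower() == key:
                return m
        raise ValidationError(
            f"unknown material {name!r}; known: {[m.name for m in self.materials]}"
        )

    def stack(self, liner: str, socket: str) -> StackSpec:
        """Look up a liner+socket combination by the two material names."""
        lk, sk = liner.strip().lower(), socket.strip().lower()
        for s in self.stacks:
            if s.liner.name.lower() == lk and s.socket.name.lower() == sk:
                return s
        raise ValidationError(
            f"no combination {liner!r} + {socket!r}; known: "
            f"{[s.name for s in self.stacks]}"
        )

    @property
    def liners(self) -> tuple[Material, ...]:
        return tuple(m for m in self.materials if m.kind is LayerKind.LINER)

    @property
    def sockets(self) -> tuple[Material, ...]:
        return tuple(m for m in self.materials if m.kind is LayerKind.SOCKET)


def _parse(doc: dict) -> MaterialLibrary:
    try:
        mats = tuple(
            Material(
                name=str(e["name"]),
                kind=LayerKind(e["kind"]),
                thickness_mm=float(e["thickness_mm"]),
                tau_min=float(e["tau_min"]),
            )
            for e in doc["materials"]
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed material entry: {exc}") from exc
    by_name = {m.name: m for m in mats}
    stacks = []
    for e in doc.get("combinations", []):
        try:
            liner = by_name[e["liner"]]
            socket = by_name[e["socket"]]
            stacks.append(
                StackSpec(liner=liner, socket=socket, combo_tau_min=float(e["combo_tau_min"]))
            )
        except KeyError as exc:
            raise ValidationError(f"combination references unknown material: {exc}") from exc
    return MaterialLibrary(materials=mats, stacks=tuple(stacks))


def load_library(path: str | Path) -> MaterialLibrary:
    """Load a material library from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "materials" not in doc:
        raise ValidationError(f"{path}: not a material-library file")
    return _parse(doc)


def material_library() -> MaterialLibrary:
    """Return the shipped default library (all measured materials and stacks)."""
    text = resources.files("limbtherm").joinpath("data/materials.yaml").read_text("utf-8")
    return _parse(yaml.safe_load(text))
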