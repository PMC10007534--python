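"""Marker sets and edge lists for the skeleton graph.

The body model is Vicon's 39-marker full-body Plug-in Gait placement; the
racket is a seven-marker rigid cluster.  Both ship as plain-text presets
(one label per line, ``#`` comments) so users can substitute their own.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "MarkerSet",
    "EdgeList",
    "load_marker_set",
    "load_edge_list",
    "PRESET_MARKER_SETS",
    "PRESET_EDGE_LISTS",
]

PRESET_MARKER_SETS = {
    "plug_in_gait_39": "plug_in_gait_39.txt",
    "racket_7": "racket_7.txt",
}
PRESET_EDGE_LISTS = {
    "body_edges_39": "body_edges_39.txt",
    "racket_attachment_right": "racket_attachment_right.txt",
    "racket_attachment_left": "racket_attachment_left.txt",
}


def _preset_text(filename: str) -> str:
    return (importlib.resources.files("strokegcn.data") / filename).read_text()


def _parse_lines(text: str) -> list[list[str]]:
    rows = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            rows.append(line.split())
    return rows


@dataclass(frozen=True)
class MarkerSet:
    """Ordered set of marker labels; the order defines node indexing."""

    names: tuple[str, ...]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate marker labels: {dupes}")
        if not self.names:
            raise ValueError("marker set is empty")

    @property
    def count(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        return self.names.index(label)

    def __contains__(self, label: str) -> bool:
        return label in self.names

    def __add__(self, other: "MarkerSet") -> "MarkerSet":
        overlap = set(self.names) & set(other.names)
        if overlap:
            raise ValueError(f"marker label collision: {sorted(overlap)}")
        return MarkerSet(self.names + other.names, {**self.groups, **other.groups})


@dataclass(frozen=True)
class EdgeList:
    """Set of unordered label pairs; no self-edges."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs) -> "EdgeList":
        norm = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            norm.add((min(a, b), max(a, b)))
        return cls(frozenset(norm))

    def __len__(self):
        return len(self.edges)

    def __iter__(self):
        return iter(sorted(self.edges))

    def validate(self, markers: MarkerSet) -> None:
        for a, b in self.edges:
            for lbl in (a, b):
                if lbl not in markers:
                    raise ValueError(f"edge references unknown marker {lbl!r}")


def load_marker_set(preset_or_path: str | Path) -> MarkerSet:
    """Load a marker set by preset name (``plug_in_gait_39``, ``racket_7``)
    or from a label file (``label [group]`` per line)."""
    key = str(preset_or_path)
    if key in PRESET_MARKER_SETS:
        text = _preset_text(PRESET_MARKER_SETS[key])
    elif Path(preset_or_path).is_file():
        text = Path(preset_or_path).read_text()
    else:
        raise ValueError(
            f"unknown marker-set preset or missing file: {preset_or_path!r}; "
            f"presets are {sorted(PRESET_MARKER_SETS)}"
        )
    names, groups = [], {}
    for row in _parse_lines(text):
        names.append(row[0])
        if len(row) > 1:
            groups[row[0]] = row[1]
    return MarkerSet(tuple(names), groups)


def load_edge_list(preset_or_path: str | Path) -> EdgeList:
    """Load an edge table by preset name or from a two-column pair file."""
    key = str(preset_or_path)
    if key in PRESET_EDGE_LISTS:
        text = _preset_text(PRESET_EDGE_LISTS[key])
    elif Path(preset_or_path).is_file():
        text = Path(preset_or_path).read_text()
    else:
        raise ValueError(
            f"unknown edge-list preset or missing file: {preset_or_path!r}; "
            f"presets are {sorted(PRESET_EDGE_LISTS)}"
        )
    pairs = []
    for row in _parse_lines(text):
        if len(row) != 2:
            raise ValueError(f"edge line needs exactly two labels, got {row}")
        pairs.append((row[0], row[1]))
    return EdgeList.from_pairs(pairs)
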