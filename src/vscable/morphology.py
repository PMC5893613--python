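"""Reconstructed dendritic trees: SWC I/O, branchlet enumeration, morphometrics.

A morphology is a rooted tree of 3-D points with radii (SWC semantics). The
dendritic arbor is partitioned into *branchlets* — maximal unbranched sections
running from a branch point (or the root) to the next branch point or to a
terminal tip. Branchlets are the unit at which receptive fields are measured
and at which current is injected in the cable model.

Units: coordinates and radii in micrometres throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRUCT_SOMA",
    "STRUCT_AXON",
    "STRUCT_DENDRITE",
    "Morphology",
    "Branchlet",
    "Morphometrics",
    "SWCParseError",
    "read_swc",
    "write_swc",
    "enumerate_sections",
    "enumerate_branchlets",
    "morphometrics",
    "map_point_to_branchlet",
    "branchlet_table",
]

# Canonical SWC structure codes. Codes 3 (basal) and 4 (apical) both count as
# dendrite; anything above 4 is "other" and excluded from dendritic metrics.
STRUCT_UNDEFINED = 0
STRUCT_SOMA = 1
STRUCT_AXON = 2
STRUCT_DENDRITE = 3
STRUCT_APICAL = 4

_DENDRITE_CODES = (STRUCT_DENDRITE, STRUCT_APICAL)


class SWCParseError(ValueError):
    """Raised for malformed SWC content; message names the offending line."""


@dataclass
class Morphology:
    """A validated rooted tree of 3-D points with radii.

    Parameters
    ----------
    ids : integer node identifiers (as given in the SWC file).
    struct : SWC structure code per node (1 soma, 2 axon, 3/4 dendrite).
    xyz : (n, 3) coordinates in μm.
    radius : per-node radius in μm (diameter = 2 * radius).
    parent : parent node id per node, -1 for the root.
    name : free-text label for the cell.
    """

    ids: np.ndarray
    struct: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    name: str = ""

    # id -> row index, filled in __post_init__
    _row: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.struct = np.asarray(self.struct, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        n = len(self.ids)
        if n == 0:
            raise ValueError("empty morphology")
        if len(set(self.ids.tolist())) != n:
            raise ValueError("duplicate node ids")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radius <= 0) or not np.all(np.isfinite(self.radius)):
            raise ValueError("all radii must be positive and finite")
        self._row = {int(i): k for k, i in enumerate(self.ids)}
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        # every parent must exist and precede its child (tree, no cycles)
        for k in range(n):
            p = int(self.parent[k])
            if p < 0:
                continue
            if p not in self._row:
                raise ValueError(f"node {self.ids[k]} references missing parent {p}")
            if self._row[p] >= k:
                raise ValueError(
                    f"node {self.ids[k]} appears before its parent {p}"
                )

    # -- basic topology helpers -------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_id(self) -> int:
        return int(self.ids[np.flatnonzero(self.parent < 0)[0]])

    def row(self, node_id: int) -> int:
        return self._row[int(node_id)]

    def children_map(self) -> dict[int, list[int]]:
        """Map node id -> list of child ids, in file order."""
        ch: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for k in range(self.n_nodes):
            p = int(self.parent[k])
            if p >= 0:
                ch[p].append(int(self.ids[k]))
        return ch

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "struct": self.struct,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "radius": self.radius,
                "parent": self.parent,
            }
        )


@dataclass(frozen=True)
class Branchlet:
    """A maximal unbranched section of the tree.

    ``node_path`` runs from the proximal attachment node (a branch point or
    the root, which geometrically belongs to the parent section) to the distal
    end. ``length`` and ``mean_diameter`` are computed over the path segments;
    the mean diameter is length-weighted.
    """

    id: int
    node_path: tuple[int, ...]
    is_terminal: bool
    length: float
    mean_diameter: float
    struct: int = STRUCT_DENDRITE


@dataclass(frozen=True)
class Morphometrics:
    total_dendritic_length: float  # μm
    total_membrane_area: float  # μm²
    average_diameter: float  # μm, length-weighted
    average_terminal_diameter: float  # μm
    n_branchlets: int
    n_terminals: int


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> Morphology:
    """Read a canonical 7-column SWC file.

    Columns: id, structure code, x, y, z, radius, parent id (-1 for root);
    '#' starts a comment. Malformed lines raise :class:`SWCParseError`
    naming the line number.
    """
    path = Path(path)
    ids, struct, xyz, radius, parent = [], [], [], [], []
    seen: set[int] = set()
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"{path.name}:{ln}: expected 7 columns, got {len(fields)}"
                )
            try:
                i = int(fields[0])
                t = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                p = int(fields[6])
            except ValueError as exc:
                raise SWCParseError(f"{path.name}:{ln}: {exc}") from None
            if i in seen:
                raise SWCParseError(f"{path.name}:{ln}: duplicate node id {i}")
            if r <= 0:
                raise SWCParseError(
                    f"{path.name}:{ln}: non-positive radius {r} for node {i}"
                )
            if p >= 0 and p not in seen:
                raise SWCParseError(
                    f"{path.name}:{ln}: parent {p} of node {i} not defined yet"
                )
            seen.add(i)
            ids.append(i)
            struct.append(t)
            xyz.append((x, y, z))
            radius.append(r)
            parent.append(p)
    if not ids:
        raise SWCParseError(f"{path.name}: no nodes found")
    try:
        return Morphology(
            np.array(ids), np.array(struct), np.array(xyz), np.array(radius),
            np.array(parent), name=path.stem,
        )
    except ValueError as exc:
        raise SWCParseError(f"{path.name}: {exc}") from None


def write_swc(m: Morphology, path: str | Path) -> None:
    """Write canonical SWC; round-trips with :func:`read_swc`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# SWC export of '{m.name}' (id type x y z radius parent)\n")
        for k in range(m.n_nodes):
            x, y, z = m.xyz[k]
            fh.write(
                f"{m.ids[k]} {m.struct[k]} {x:.6g} {y:.6g} {z:.6g} "
                f"{m.radius[k]:.6g} {m.parent[k]}\n"
            )


# ---------------------------------------------------------------------------
# Sections / branchlets
# ---------------------------------------------------------------------------

def _segment_lengths(m: Morphology, node_path: Sequence[int]) -> np.ndarray:
    rows = [m.row(i) for i in node_path]
    pts = m.xyz[rows]
    return np.linalg.norm(np.diff(pts, axis=0), axis=1)


def _segment_mean_diameters(m: Morphology, node_path: Sequence[int]) -> np.ndarray:
    rows = [m.row(i) for i in node_path]
    r = m.radius[rows]
    return r[:-1] + r[1:]  # mean diameter = (d1+d2)/2 = r1+r2


def enumerate_sections(m: Morphology) -> list[Branchlet]:
    """Partition the whole tree into maximal unbranched sections.

    A new section starts at every child of the root, of a branch point
    (>= 2 children) or of a structure-code transition, and runs until the next
    branch point or terminal. Section ids are assigned in depth-first file
    order, starting at 1. Every non-root node belongs to exactly one section.
    """
    ch = m.children_map()
    sections: list[Branchlet] = []

    # depth-first over section start edges, preserving file order
    stack: list[int] = list(reversed(ch[m.root_id]))
    start_parent = {c: m.root_id for c in ch[m.root_id]}
    while stack:
        first = stack.pop()
        path = [start_parent[first], first]
        node = first
        while len(ch[node]) == 1 and m.struct[m.row(ch[node][0])] == m.struct[m.row(node)]:
            node = ch[node][0]
            path.append(node)
        seg_len = _segment_lengths(m, path)
        seg_d = _segment_mean_diameters(m, path)
        total = float(seg_len.sum())
        mean_d = float((seg_d * seg_len).sum() / total) if total > 0 else float(seg_d.mean())
        sections.append(
            Branchlet(
                id=len(sections) + 1,
                node_path=tuple(int(i) for i in path),
                is_terminal=len(ch[node]) == 0,
                length=total,
                mean_diameter=mean_d,
                struct=int(m.struct[m.row(node)]),
            )
        )
        for c in reversed(ch[node]):
            start_parent[c] = node
            stack.append(c)
    return sections


def enumerate_branchlets(m: Morphology) -> list[Branchlet]:
    """Dendritic branchlets: the sections whose nodes are dendrite-labelled.

    Section ids are shared with :func:`enumerate_sections` so that cable loci
    and branchlet ids refer to the same numbering.
    """
    sections = [s for s in enumerate_sections(m) if s.struct in _DENDRITE_CODES]
    if not sections:
        raise ValueError("morphology has no dendritic nodes (empty arbor)")
    return sections


def _node_to_section(m: Morphology, sections: Iterable[Branchlet]) -> dict[int, int]:
    """Each non-root node belongs to the section of its (parent -> node) edge."""
    owner: dict[int, int] = {}
    for s in sections:
        for node in s.node_path[1:]:
            owner[node] = s.id
    return owner


def morphometrics(m: Morphology) -> Morphometrics:
    """Summary measurements of the dendritic arbor.

    Segment geometry is a truncated cone (frustum) between consecutive nodes:
    length = 3-D inter-node distance, lateral area = π (r1 + r2) ℓ. For a
    constant-diameter tree this reduces exactly to π d L. The average diameter
    is length-weighted; the average terminal diameter is the unweighted mean
    of terminal branchlets' mean diameters.
    """
    branchlets = enumerate_branchlets(m)
    total_len = 0.0
    total_area = 0.0
    diam_weighted = 0.0
    for b in branchlets:
        seg_len = _segment_lengths(m, b.node_path)
        rows = [m.row(i) for i in b.node_path]
        r = m.radius[rows]
        total_len += float(seg_len.sum())
        total_area += float((np.pi * (r[:-1] + r[1:]) * seg_len).sum())
        diam_weighted += b.mean_diameter * b.length
    terminals = [b for b in branchlets if b.is_terminal]
    return Morphometrics(
        total_dendritic_length=total_len,
        total_membrane_area=total_area,
        average_diameter=diam_weighted / total_len,
        average_terminal_diameter=float(np.mean([b.mean_diameter for b in terminals])),
        n_branchlets=len(branchlets),
        n_terminals=len(terminals),
    )


def map_point_to_branchlet(
    m: Morphology, point: Sequence[float]
) -> tuple[int, float]:
    """Assign a 3-D point (an imaged ROI centre) to the nearest branchlet.

    Returns ``(branchlet_id, distance_um)`` for the dendritic node nearest to
    ``point`` in Euclidean 3-space; ties break to the smallest node id.
    """
    branchlets = enumerate_branchlets(m)
    owner = _node_to_section(m, branchlets)
    cand = sorted(owner)  # ascending node id gives the declared tie-break
    rows = [m.row(i) for i in cand]
    d = np.linalg.norm(m.xyz[rows] - np.asarray(point, dtype=float), axis=1)
    k = int(np.argmin(d))  # argmin returns the first (smallest-id) minimum
    return owner[cand[k]], float(d[k])


def branchlet_table(m: Morphology, cell: str | None = None) -> pd.DataFrame:
    """Branchlet summary as a tidy table (CSV-ready)."""
    rows = [
        {
            "cell": cell if cell is not None else m.name,
            "branchlet_id": b.id,
            "is_terminal": b.is_terminal,
            "length_um": b.length,
            "mean_diameter_um": b.mean_diameter,
        }
        for b in enumerate_branchlets(m)
    ]
    return pd.DataFrame(rows)
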