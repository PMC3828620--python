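"""Branched 1D cell morphologies.

A neuron (or any branched cell) is represented as a forest of *sections*:
unbranched cables of constant diameter, each discretized into ``nseg`` equal
finite-volume *segments*.  Sections connect end-to-end: a child attaches its
x=0 end to either end (``parent_x`` in {0, 1}) of its parent, and the
connectivity must remain a forest (no cycles, at most one parent each).

Positions along a section are normalized to x in [0, 1]; segment ``i`` owns
the half-open interval [i/nseg, (i+1)/nseg) and its center sits at
(i + 0.5)/nseg.

Morphologies are built programmatically or read from SWC files (the standard
one-point-per-line morphology exchange format).  SWC import groups points
into one section per unbranched path; type codes are ignored (everything is
treated as cable), and diameters are averaged per path.
"""

from __future__ import annotations

import math
from typing import IO, Iterable, Optional

import numpy as np

__all__ = [
    "MorphologyError",
    "SWCParseError",
    "Section",
    "Morphology",
    "read_swc",
    "write_swc",
]


class MorphologyError(ValueError):
    """Invalid morphology construction (bad dimensions, cycles, re-parenting)."""


class SWCParseError(MorphologyError):
    """Malformed SWC input; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class Section:
    """An unbranched cable of length ``L`` (µm) and constant diameter ``diam``
    (µm), discretized into ``nseg`` equal segments.

    Created through :meth:`Morphology.create_section`; connected through
    :meth:`Morphology.connect`.
    """

    def __init__(self, name: str, L: float, diam: float, nseg: int = 1):
        if not (L > 0):
            raise MorphologyError(f"section {name!r}: L must be > 0, got {L}")
        if not (diam > 0):
            raise MorphologyError(f"section {name!r}: diam must be > 0, got {diam}")
        if int(nseg) != nseg or nseg < 1:
            raise MorphologyError(
                f"section {name!r}: nseg must be a positive integer, got {nseg}"
            )
        self.name = str(name)
        self.L = float(L)
        self.diam = float(diam)
        self.nseg = int(nseg)
        self.parent: Optional[Section] = None
        self.parent_x: Optional[int] = None
        self.children: list[Section] = []

    @property
    def dx(self) -> float:
        """Segment length L/nseg (µm)."""
        return self.L / self.nseg

    def segment_centers(self) -> np.ndarray:
        """Normalized segment-center positions (i + 0.5)/nseg."""
        return (np.arange(self.nseg) + 0.5) / self.nseg

    def arc_centers(self) -> np.ndarray:
        """Segment-center positions in µm along the section."""
        return self.segment_centers() * self.L

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Section({self.name!r}, L={self.L}, diam={self.diam}, "
            f"nseg={self.nseg})"
        )


class Morphology:
    """A forest of connected sections with unique names."""

    def __init__(self):
        self.sections: list[Section] = []
        self._by_name: dict[str, Section] = {}

    def create_section(self, name: str, L: float, diam: float, nseg: int = 1) -> Section:
        if name in self._by_name:
            raise MorphologyError(f"duplicate section name {name!r}")
        sec = Section(name, L, diam, nseg)
        self.sections.append(sec)
        self._by_name[sec.name] = sec
        return sec

    def __getitem__(self, name: str) -> Section:
        return self._by_name[name]

    def __contains__(self, sec: Section) -> bool:
        return sec in self.sections

    @property
    def roots(self) -> list[Section]:
        return [s for s in self.sections if s.parent is None]

    def connect(self, child: Section, parent: Section, parent_x: int = 1) -> "Morphology":
        """Attach ``child`` (its x=0 end) to the ``parent_x`` end of ``parent``."""
        if child not in self.sections or parent not in self.sections:
            raise MorphologyError("both sections must belong to this morphology")
        if parent_x not in (0, 1):
            raise MorphologyError(f"parent_x must be 0 or 1, got {parent_x}")
        if child.parent is not None:
            raise MorphologyError(f"section {child.name!r} already has a parent")
        if child is parent:
            raise MorphologyError("cannot connect a section to itself")
        # Walk up from the parent; reaching `child` would close a cycle.
        anc = parent
        while anc is not None:
            if anc is child:
                raise MorphologyError(
                    f"connecting {child.name!r} to {parent.name!r} would create a cycle"
                )
            anc = anc.parent
        child.parent = parent
        child.parent_x = int(parent_x)
        parent.children.append(child)
        return self

    def validate(self) -> None:
        """Check the forest invariant (each section reachable from one root)."""
        seen: set[int] = set()
        for root in self.roots:
            stack = [root]
            while stack:
                sec = stack.pop()
                if id(sec) in seen:
                    raise MorphologyError(f"section {sec.name!r} reachable twice")
                seen.add(id(sec))
                stack.extend(sec.children)
        if len(seen) != len(self.sections):
            raise MorphologyError("not every section is reachable from a root")

    # -- endpoint bookkeeping used by the diffusion assembler --------------

    def end_vertices(self) -> dict[tuple[int, int], int]:
        """Partition section ends into shared junction vertices.

        Returns a map (section index, end in {0,1}) -> vertex id, where a
        child's 0-end shares a vertex with the parent end it attaches to.
        """
        index = {id(s): i for i, s in enumerate(self.sections)}
        parent_uf: dict[tuple[int, int], tuple[int, int]] = {}

        def find(k):
            while parent_uf.get(k, k) != k:
                parent_uf[k] = parent_uf.get(parent_uf[k], parent_uf[k])
                k = parent_uf[k]
            return k

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent_uf[ra] = rb

        for sec in self.sections:
            if sec.parent is not None:
                union((index[id(sec)], 0), (index[id(sec.parent)], sec.parent_x))
        vertex_of: dict[tuple[int, int], int] = {}
        next_id = 0
        for i, sec in enumerate(self.sections):
            for end in (0, 1):
                r = find((i, end))
                if r not in vertex_of:
                    vertex_of[r] = next_id
                    next_id += 1
        return {
            (i, end): vertex_of[find((i, end))]
            for i in range(len(self.sections))
            for end in (0, 1)
        }


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------


def _dist(p, q) -> float:
    return math.dist(p[1:4], q[1:4])


def read_swc(stream: IO[str] | Iterable[str]) -> Morphology:
    """Read an SWC morphology into sections.

    Each line is ``id type x y z radius parent`` with ``#`` comments.  One
    section is created per unbranched path between root/branch/leaf points;
    type codes carry no meaning except that a type change along an unbranched
    chain also starts a new section (all types are treated as plain cable).
    A section's length is the summed 3D distance along its path; its diameter
    is the mean of 2·radius over the path's own points (a shared branch point
    contributes distance to the child path but its radius stays with the
    parent).  Parent ids must be defined before use.
    """
    points: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCParseError(f"expected 7 fields, got {len(fields)}", lineno)
        try:
            pid = int(fields[0])
            ptype = int(fields[1])
            x, y, z, r = (float(v) for v in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise SWCParseError(f"non-numeric field ({exc})", lineno) from None
        if pid in points:
            raise SWCParseError(f"duplicate point id {pid}", lineno)
        if parent != -1 and parent not in points:
            raise SWCParseError(
                f"point {pid} references undefined parent {parent}", lineno
            )
        points[pid] = (ptype, x, y, z, r, parent)
        order.append(pid)

    children: dict[int, list[int]] = {pid: [] for pid in points}
    roots: list[int] = []
    for pid in order:
        parent = points[pid][5]
        if parent == -1:
            roots.append(pid)
        else:
            children[parent].append(pid)

    morph = Morphology()
    # section attached to a point: either the section whose path *ends* at it
    # (children attach at parent_x=1), or a sibling section whose path
    # *starts* at it (parent_x=0) when the start point itself begins no chain.
    attach_at: dict[int, tuple[Section, int]] = {}  # point id -> (section, end)

    def walk(start: int, via: Optional[int]) -> None:
        """Emit one section: from `start` through `via` (a specific child,
        used below branch points) along the unbranched chain; then recurse
        into the children of the chain's last point."""
        path = [start]
        cur = start
        if via is not None:
            path.append(via)
            cur = via
        sec_type = points[cur][0]
        while (
            len(children[cur]) == 1
            and points[children[cur][0]][0] == sec_type
        ):
            cur = children[cur][0]
            path.append(cur)
        if len(path) >= 2:
            # a shared start point (branch point / shared root) contributes
            # its distance but not its radius
            own = path if via is None else path[1:]
            L = sum(
                _dist(points[a], points[b]) for a, b in zip(path[:-1], path[1:])
            )
            diam = float(np.mean([2.0 * points[p][4] for p in own]))
            if L <= 0:
                raise SWCParseError(f"zero-length path ending at point {path[-1]}")
            sec = morph.create_section(f"swc_{len(morph.sections)}", L, diam, nseg=1)
            if path[0] in attach_at:
                parent_sec, end = attach_at[path[0]]
                morph.connect(sec, parent_sec, parent_x=end)
            else:
                # First section touching this start point: later siblings
                # sharing the point attach to this section's 0-end.
                attach_at[path[0]] = (sec, 0)
            attach_at[path[-1]] = (sec, 1)
        for child in children[path[-1]]:
            walk(path[-1], child)

    for root in roots:
        if len(children[root]) == 1 or not children[root]:
            walk(root, None)
        else:  # root that branches immediately: one section per child chain
            for child in children[root]:
                walk(root, child)

    if not morph.sections:
        raise SWCParseError("no sections could be built from the SWC input")
    morph.validate()
    return morph


def write_swc(morph: Morphology, stream: IO[str]) -> None:
    """Write a morphology as SWC (mirror of :func:`read_swc` for round trips).

    Sections are emitted as single straight edges in synthetic 3D coordinates
    (directions chosen only to be distinct); lengths, diameters, topology and
    section count survive a read/write/read round trip, per-section ``nseg``
    does not (SWC has no discretization concept).  Type codes alternate with
    tree depth so that consecutive chained sections remain separate sections
    on re-import.
    """
    stream.write("# SWC export\n")
    next_id = 1
    end_point_id: dict[int, int] = {}  # id(section) -> SWC id of its far end
    end_point_xyz: dict[int, tuple[float, float, float]] = {}
    counter = 0

    def emit(sec: Section, root_index: int, depth: int) -> None:
        nonlocal next_id, counter
        r = sec.diam / 2.0
        ptype = 3 + depth % 2
        if sec.parent is None:
            sx, sy, sz = (0.0, 1000.0 * root_index, 0.0)
            stream.write(f"{next_id} {ptype} {sx} {sy} {sz} {r} -1\n")
            start_id = next_id
            next_id += 1
        else:
            if sec.parent_x == 1:
                start_id = end_point_id[id(sec.parent)]
                sx, sy, sz = end_point_xyz[id(sec.parent)]
            else:
                # attaching at the parent's 0-end: reuse the parent's start
                start_id = _start_id[id(sec.parent)]
                sx, sy, sz = _start_xyz[id(sec.parent)]
        _start_id[id(sec)] = start_id
        _start_xyz[id(sec)] = (sx, sy, sz)
        theta = 2.399963229728653 * counter  # golden angle: distinct directions
        counter += 1
        ex = sx + sec.L * math.cos(theta)
        ey = sy + sec.L * math.sin(theta)
        stream.write(f"{next_id} {ptype} {ex} {ey} {sz} {r} {start_id}\n")
        end_point_id[id(sec)] = next_id
        end_point_xyz[id(sec)] = (ex, ey, sz)
        next_id += 1
        for child in sec.children:
            emit(child, root_index, depth + 1)

    _start_id: dict[int, int] = {}
    _start_xyz: dict[int, tuple[float, float, float]] = {}
    for k, root in enumerate(morph.roots):
        emit(root, k, 0)
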