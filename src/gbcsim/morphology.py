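"""Tagged cell morphologies: parsing, measurement, inflation, editing.

A morphology is a tree of *sections*; each section is a polyline of 3-D
points with radii and carries exactly one morphological tag.  Consecutive
points define conical frustums, which is the geometric primitive used for
all surface-area accounting.  The extended SWC dialect used here is the
standard 7-column whitespace format, with a configurable integer->tag map
so that non-standard structures (hubs, swellings, axon subdivisions) can
be round-tripped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Tag",
    "DEFAULT_TAG_MAP",
    "Section",
    "Morphology",
    "InflationResult",
    "AxonBranch",
    "MorphologyError",
    "parse_swc",
    "write_swc",
    "surface_area",
    "inflate",
    "prune",
    "substitute_standard_axon",
    "branch_delay",
]


class MorphologyError(ValueError):
    """Structural or tagging problem in a morphology."""


class Tag(str, Enum):
    """Morphological feature tags for globular bushy cells."""

    SOMA = "soma"
    AXON_HILLOCK = "axon_hillock"
    AIS = "AIS"
    MYELINATED_AXON = "myelinated_axon"
    PROXIMAL_DENDRITE = "proximal_dendrite"
    HUB = "hub"
    DISTAL_DENDRITE = "distal_dendrite"
    SWELLING = "swelling"


#: Dendritic tags pooled together for inflation and decoration.
DENDRITE_TAGS = frozenset(
    {Tag.PROXIMAL_DENDRITE, Tag.HUB, Tag.DISTAL_DENDRITE, Tag.SWELLING}
)
AXON_TAGS = frozenset({Tag.AXON_HILLOCK, Tag.AIS, Tag.MYELINATED_AXON})

#: Default integer->tag map for the extended SWC dialect.  1=soma follows
#: the SWC convention; the remaining codes are this package's documented
#: assignment for the extra bushy-cell structures.
DEFAULT_TAG_MAP: Mapping[int, Tag] = {
    1: Tag.SOMA,
    2: Tag.MYELINATED_AXON,
    3: Tag.DISTAL_DENDRITE,
    4: Tag.PROXIMAL_DENDRITE,
    5: Tag.HUB,
    6: Tag.SWELLING,
    7: Tag.AXON_HILLOCK,
    8: Tag.AIS,
}


@dataclass
class Section:
    """One unbranched run of frustums with a single tag.

    points is an (n, 4) float array of x, y, z, r in micrometres; n >= 2.
    """

    id: int
    parent_id: int | None
    tag: Tag
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 4:
            raise MorphologyError("section points must be (n, 4)")
        if len(self.points) < 2:
            raise MorphologyError(f"section {self.id} has < 2 points")
        if np.any(self.points[:, 3] <= 0):
            raise MorphologyError(f"section {self.id} has non-positive radius")

    @property
    def length(self) -> float:
        """Axial (polyline) length in micrometres."""
        d = np.diff(self.points[:, :3], axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    @property
    def mean_diameter(self) -> float:
        """Frustum-length-weighted mean diameter, micrometres."""
        seg_len = np.sqrt((np.diff(self.points[:, :3], axis=0) ** 2).sum(axis=1))
        mean_r = 0.5 * (self.points[:-1, 3] + self.points[1:, 3])
        total = seg_len.sum()
        if total == 0:
            return float(2 * self.points[:, 3].mean())
        return float(2 * (mean_r * seg_len).sum() / total)

    def frustum_areas(self) -> np.ndarray:
        """Lateral surface area of each frustum: pi*(r1+r2)*slant."""
        d = np.diff(self.points[:, :3], axis=0)
        axial = np.sqrt((d**2).sum(axis=1))
        r1 = self.points[:-1, 3]
        r2 = self.points[1:, 3]
        slant = np.sqrt(axial**2 + (r2 - r1) ** 2)
        return np.pi * (r1 + r2) * slant

    @property
    def area(self) -> float:
        return float(self.frustum_areas().sum())


@dataclass
class Morphology:
    """A tagged cell morphology: a tree of sections."""

    sections: list[Section]
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise MorphologyError("duplicate section ids")
        idset = set(ids)
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        for s in self.sections:
            if s.parent_id is not None and s.parent_id not in idset:
                raise MorphologyError(f"section {s.id} has unknown parent {s.parent_id}")
        # cycle check by walking to root from every node
        parent = {s.id: s.parent_id for s in self.sections}
        for sid in ids:
            seen = set()
            cur: int | None = sid
            while cur is not None:
                if cur in seen:
                    raise MorphologyError("cycle in section parent links")
                seen.add(cur)
                cur = parent[cur]

    # -- convenience accessors -------------------------------------------------
    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent_id is None)

    def section(self, sid: int) -> Section:
        for s in self.sections:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def children(self, sid: int) -> list[Section]:
        return [s for s in self.sections if s.parent_id == sid]

    def subtree_ids(self, sid: int) -> set[int]:
        out = {sid}
        stack = [sid]
        while stack:
            cur = stack.pop()
            for c in self.children(cur):
                out.add(c.id)
                stack.append(c.id)
        return out

    def copy(self) -> "Morphology":
        return Morphology(
            [replace(s, points=s.points.copy()) for s in self.sections],
            cell_id=self.cell_id,
        )

    def total_length(self, tags: Iterable[Tag] | None = None) -> float:
        tagset = set(tags) if tags is not None else None
        return sum(
            s.length for s in self.sections if tagset is None or s.tag in tagset
        )


@dataclass
class InflationResult:
    """Outcome of matching frustum areas to mesh-derived target areas."""

    soma_factor: float
    dendrite_factor: float
    achieved_soma_area: float
    achieved_dendrite_area: float
    iterations: int


@dataclass
class AxonBranch:
    """A myelinated branch from a parent fibre to an endbulb terminal.

    fiber_diameter = axon diameter / g_ratio (myelin included).
    """

    length: float  # um
    axon_diameter: float  # um
    g_ratio: float = 0.76

    def __post_init__(self) -> None:
        if not 0 < self.g_ratio < 1:
            raise ValueError("g_ratio must lie in (0, 1)")

    @property
    def fiber_diameter(self) -> float:
        return self.axon_diameter / self.g_ratio


# -----------------------------------------------------------------------------
# SWC I/O
# -----------------------------------------------------------------------------

def parse_swc(
    path: str | Path,
    tag_map: Mapping[int, Tag] = DEFAULT_TAG_MAP,
    cell_id: str = "",
) -> Morphology:
    """Parse a whitespace-delimited extended SWC file into a Morphology.

    Columns: id, type, x, y, z, r, parent (parent -1 for the root point).
    '#' comments and blank lines are ignored.  Runs of points sharing a tag
    are grouped into sections; a section starts at the root, at every tag
    change, and at every branch point.  Zero-length frustums (consecutive
    duplicate points) are merged silently.
    """
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"malformed SWC line: {raw!r}")
        pid, code = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        if code not in tag_map:
            raise MorphologyError(f"unknown SWC type code {code}")
        rows[pid] = (code, x, y, z, r, parent)
        order.append(pid)

    if not rows:
        raise MorphologyError("empty SWC file")

    children: dict[int, list[int]] = {}
    roots = []
    for pid in order:
        parent = rows[pid][5]
        if parent == -1:
            roots.append(pid)
        else:
            if parent not in rows:
                raise MorphologyError(f"point {pid} references missing parent {parent}")
            children.setdefault(parent, []).append(pid)
    if len(roots) != 1:
        raise MorphologyError(f"expected one SWC root point, found {len(roots)}")

    sections: list[Section] = []
    sec_of_point: dict[int, int] = {}
    next_sid = 0

    def point_xyzr(pid: int) -> tuple[float, float, float, float]:
        code, x, y, z, r, _ = rows[pid]
        return (x, y, z, r)

    # walk the point tree: a section continues through the unique same-tag
    # child; every other child starts a new section attached here
    stack: list[tuple[int, int | None]] = [(roots[0], None)]
    while stack:
        start, parent_sec = stack.pop()
        raw_pts: list[tuple[float, float, float, float]] = []
        tag = tag_map[rows[start][0]]
        sid = next_sid
        next_sid += 1
        if parent_sec is not None:
            # prepend the attachment point for geometric continuity
            attach = rows[start][5]
            raw_pts.append(point_xyzr(attach))
        cur = start
        while True:
            raw_pts.append(point_xyzr(cur))
            sec_of_point[cur] = sid
            kids = children.get(cur, [])
            same = [k for k in kids if tag_map[rows[k][0]] is tag]
            if len(same) == 1 and len(kids) >= 1:
                for k in kids:
                    if k != same[0]:
                        stack.append((k, sid))
                cur = same[0]
            else:
                for k in kids:
                    stack.append((k, sid))
                break
        pts = np.array(raw_pts, dtype=float)
        # if the prepended attachment coincides with the first real point,
        # the real point (with its own radius) wins
        if len(pts) > 1 and np.allclose(pts[0, :3], pts[1, :3]):
            pts = pts[1:]
        # drop zero-length duplicates
        if len(pts) > 1:
            keep = np.ones(len(pts), dtype=bool)
            d = np.sqrt((np.diff(pts[:, :3], axis=0) ** 2).sum(axis=1))
            keep[1:] = d > 0
            pts = pts[keep]
        if len(pts) < 2:
            # single-point section (e.g. spherical soma point): make a
            # zero-taper cylinder of length 2r so frustum math is defined
            x, y, z, r = pts[0]
            pts = np.array([[x - r, y, z, r], [x + r, y, z, r]])
        sections.append(Section(id=sid, parent_id=parent_sec, tag=tag, points=pts))

    sections.sort(key=lambda s: s.id)
    return Morphology(sections, cell_id=cell_id)


def write_swc(
    m: Morphology,
    path: str | Path,
    tag_map: Mapping[int, Tag] = DEFAULT_TAG_MAP,
) -> None:
    """Write a Morphology back to the extended SWC dialect."""
    code_of = {tag: code for code, tag in tag_map.items()}
    lines = ["# extended SWC written by gbcsim"]
    next_pid = 1
    pids_of_sec: dict[int, list[int]] = {}  # point ids written per section
    # topological order: parents before children
    ordered: list[Section] = []
    queue = [m.root]
    while queue:
        sec = queue.pop(0)
        ordered.append(sec)
        queue.extend(sorted(m.children(sec.id), key=lambda s: s.id))
    for s in ordered:
        pts = s.points
        if s.parent_id is None:
            parent_pid = -1
        else:
            # attach to the geometrically nearest point of the parent section
            parent = m.section(s.parent_id)
            d2 = ((parent.points[:, :3] - pts[0, :3]) ** 2).sum(axis=1)
            parent_pid = pids_of_sec[s.parent_id][int(np.argmin(d2))]
        own: list[int] = []
        for x, y, z, r in pts:
            lines.append(
                f"{next_pid} {code_of[s.tag]} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {parent_pid}"
            )
            own.append(next_pid)
            parent_pid = next_pid
            next_pid += 1
        pids_of_sec[s.id] = own
    Path(path).write_text("\n".join(lines) + "\n")


# -----------------------------------------------------------------------------
# Measurement and editing
# -----------------------------------------------------------------------------

def surface_area(m: Morphology, tags: Iterable[Tag] | None = None) -> float:
    """Frustum lateral surface area in um^2, optionally restricted to tags.

    An empty tag selection returns 0.
    """
    tagset = set(tags) if tags is not None else None
    if tagset is not None and not tagset:
        import warnings

        warnings.warn("empty tag selection; surface area is 0", stacklevel=2)
        return 0.0
    return float(
        sum(s.area for s in m.sections if tagset is None or s.tag in tagset)
    )


def _scale_radii(m: Morphology, tags: frozenset[Tag] | set[Tag], factor: float) -> None:
    for s in m.sections:
        if s.tag in tags:
            s.points[:, 3] *= factor


def inflate(
    m: Morphology,
    target_soma_area: float,
    target_dendrite_area: float,
    rel_tol: float = 1e-3,
    max_iter: int = 50,
) -> tuple[Morphology, InflationResult]:
    """Scale soma and dendrite radii so frustum areas match mesh targets.

    Mesh surface areas exceed frustum-cone areas because meshes resolve
    membrane crenelations; compensation multiplies all point radii in each
    group (soma; pooled dendritic tags) by one factor, leaving lengths
    unchanged.  Because frustum lateral area is linear in radius at fixed
    length the iteration converges essentially in one step; the loop guards
    the general case.
    """
    if target_soma_area <= 0 or target_dendrite_area <= 0:
        raise ValueError("target areas must be positive")
    out = m.copy()
    groups = [
        (frozenset({Tag.SOMA}), target_soma_area),
        (DENDRITE_TAGS, target_dendrite_area),
    ]
    factors = [1.0, 1.0]
    iterations = 0
    for gi, (tags, target) in enumerate(groups):
        current = surface_area(out, tags)
        if current == 0:
            raise MorphologyError("tag group for inflation is empty")
        for _ in range(max_iter):
            iterations += 1
            ratio = target / surface_area(out, tags)
            if abs(ratio - 1.0) <= rel_tol:
                break
            _scale_radii(out, tags, ratio)
            factors[gi] *= ratio
        else:
            raise MorphologyError("inflation failed to converge in 50 iterations")
    result = InflationResult(
        soma_factor=factors[0],
        dendrite_factor=factors[1],
        achieved_soma_area=surface_area(out, {Tag.SOMA}),
        achieved_dendrite_area=surface_area(out, DENDRITE_TAGS),
        iterations=iterations,
    )
    return out, result


def prune(m: Morphology, section_ids: Iterable[int]) -> Morphology:
    """Remove whole subtrees rooted at the given section ids."""
    ids = set(section_ids)
    if not ids:
        return m.copy()
    known = {s.id for s in m.sections}
    missing = ids - known
    if missing:
        raise KeyError(f"unknown section ids: {sorted(missing)}")
    doomed: set[int] = set()
    for sid in ids:
        sec = m.section(sid)
        if sec.parent_id is None or sec.tag is Tag.SOMA:
            raise MorphologyError("refusing to prune the root/soma")
        doomed |= m.subtree_ids(sid)
    kept = [replace(s, points=s.points.copy()) for s in m.sections if s.id not in doomed]
    return Morphology(kept, cell_id=m.cell_id)


def substitute_standard_axon(m: Morphology, standard: Morphology) -> Morphology:
    """Replace hillock + AIS + myelinated axon with a standard axon fragment.

    The fragment must itself be a valid morphology whose root section is the
    hillock; it is grafted at the original hillock's somatic attachment,
    translated so the graft point coincides.
    """
    frag_tags = {s.tag for s in standard.sections}
    if not AXON_TAGS <= frag_tags:
        raise MorphologyError("standard axon must contain hillock, AIS, myelinated axon")
    old_axon = [s for s in m.sections if s.tag in AXON_TAGS]
    hillocks = [
        s
        for s in old_axon
        if s.tag is Tag.AXON_HILLOCK
        and (s.parent_id is None or m.section(s.parent_id).tag not in AXON_TAGS)
    ]
    if not hillocks:
        raise MorphologyError("no somatic axon attachment found")
    attach_parent = hillocks[0].parent_id
    if attach_parent is None or m.section(attach_parent).tag is not Tag.SOMA:
        raise MorphologyError("axon hillock does not attach to the soma")
    attach_xyz = hillocks[0].points[0, :3].copy()

    doomed: set[int] = set()
    for s in hillocks:
        doomed |= m.subtree_ids(s.id)
    kept = [replace(s, points=s.points.copy()) for s in m.sections if s.id not in doomed]
    next_id = max(s.id for s in kept) + 1

    id_map: dict[int, int] = {}
    frag_root = standard.root
    shift = attach_xyz - frag_root.points[0, :3]
    grafted: list[Section] = []
    for s in standard.sections:
        new = replace(s, points=s.points.copy())
        new.points[:, :3] += shift
        id_map[s.id] = next_id
        new.id = next_id
        next_id += 1
        grafted.append(new)
    for s in grafted:
        orig_parent = standard.section(
            [k for k, v in id_map.items() if v == s.id][0]
        ).parent_id
        s.parent_id = attach_parent if orig_parent is None else id_map[orig_parent]
    return Morphology(kept + grafted, cell_id=m.cell_id)


# -----------------------------------------------------------------------------
# Axon-branch conduction delay
# -----------------------------------------------------------------------------

def branch_delay(b: AxonBranch, ld_slowing_k: float = 1.0) -> float:
    """Conduction delay (us) along a myelinated branch to its terminal.

    Velocity follows the linear fibre-diameter rule CV = 4.6 * fiber_diameter
    (m/s with diameters in um).  Short internodal branches conduct slower
    than the infinite-cable rule predicts; this is modelled as a
    multiplicative slowing factor 1 + k*(d/L), which grows as the branch
    shortens relative to its diameter and vanishes for long branches.  A
    zero-length (en passant) branch has zero delay.
    """
    if b.length == 0:
        return 0.0
    cv = 4.6 * b.fiber_diameter  # m/s == um/us
    base = b.length / cv  # us
    slowing = 1.0 + ld_slowing_k * (b.axon_diameter / b.length)
    return base * slowing
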