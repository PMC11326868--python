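"""Neuron morphology: cylinder-section trees, the canonical MOC fixture, and SWC I/O.

A morphology is a tree of unbranched cylindrical sections, each carrying a
length, a diameter, a parent pointer and a segment (spatial discretization)
count.  The canonical fixture reproduces the published MOC neuron geometry:
a soma (33.6 x 6.1 um), a 180 um axon, and three primary dendrites (lateral,
dorsal, medial) that branch into short daughter dendrites, discretized into
exactly 86 segments in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "moc_fixture",
    "read_swc",
    "write_swc",
]


@dataclass
class Section:
    """One unbranched cylinder in the section tree."""

    name: str
    length_um: float
    diam_um: float
    parent: str | None = None
    nseg: int = 1
    swc_type: int = 3  # SWC structure id (1 soma, 2 axon, 3 dendrite)

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError(f"section {self.name!r}: length must be > 0")
        if self.diam_um <= 0:
            raise ValueError(f"section {self.name!r}: diameter must be > 0")
        if self.nseg < 1:
            raise ValueError(f"section {self.name!r}: nseg must be >= 1")

    @property
    def lateral_area_um2(self) -> float:
        return math.pi * self.diam_um * self.length_um


@dataclass
class Morphology:
    """A validated tree of sections with a single root."""

    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sections]
        if len(set(names)) != len(names):
            raise ValueError("duplicate section names")
        by_name = {s.name: s for s in self.sections}
        roots = [s for s in self.sections if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"morphology must have exactly one root, got {len(roots)}")
        for s in self.sections:
            if s.parent is not None and s.parent not in by_name:
                raise ValueError(f"section {s.name!r} is disconnected: "
                                 f"unknown parent {s.parent!r}")

    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent is None)

    def section(self, name: str) -> Section:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def total_nseg(self) -> int:
        return sum(s.nseg for s in self.sections)

    @property
    def total_area_um2(self) -> float:
        return sum(s.lateral_area_um2 for s in self.sections)


# Daughter counts per primary dendrite for the fixture.  The published
# reconstruction reports 8-46 daughters per primary with lengths 1.5-31.4 um
# and diameters 1-2 um; the exact topology is not recoverable, so the fixture
# spreads daughters deterministically over the stated ranges while keeping
# the total segment count at exactly 86 (soma 1 + axon 8 + 3 primaries +
# 74 daughters, one segment each).
_FIXTURE_DAUGHTERS = {"dend_lateral": 46, "dend_dorsal": 20, "dend_medial": 8}
_FIXTURE_PRIMARIES = {"dend_lateral": 12.8, "dend_dorsal": 10.1, "dend_medial": 7.3}


def moc_fixture() -> Morphology:
    """The canonical 86-segment MOC neuron morphology."""
    sections = [
        Section("soma", 33.6, 6.1, parent=None, nseg=1, swc_type=1),
        Section("axon", 180.0, 1.0, parent="soma", nseg=8, swc_type=2),
    ]
    for name, length in _FIXTURE_PRIMARIES.items():
        sections.append(Section(name, length, 1.0, parent="soma", nseg=1))
    for primary, n_daughters in _FIXTURE_DAUGHTERS.items():
        lengths = np.linspace(1.5, 31.4, n_daughters)
        diams = np.linspace(1.0, 2.0, n_daughters)
        for i, (length, diam) in enumerate(zip(lengths, diams)):
            sections.append(
                Section(f"{primary}_d{i}", float(length), float(diam), parent=primary)
            )
    return Morphology(sections)


_SOMA_TYPE = 1


def write_swc(morph: Morphology, path) -> None:
    """Write the section tree as a plain-text SWC file.

    Sections are laid out along abstract coordinates (x = path distance from
    the root along each branch, y staggered by section index); SWC here
    records connectivity and cylinder dimensions, not true 3-D shape.
    Each section is two SWC points (proximal, distal) except the root soma,
    which is a single point of half-length radius so that a round-trip
    preserves the stated soma dimensions via the conventional one-point-soma
    encoding (length = diameter = 2r is *not* assumed; length is stored in
    the radius field's companion comment).
    """
    lines = ["# SWC export; columns: id type x y z radius parent"]
    next_id = 1
    # distal point id of each section, for children to attach to
    distal: dict[str, int] = {}
    # record soma explicitly with two points so length survives a round trip
    for i, sec in enumerate(morph.sections):
        y = float(i)
        if sec.parent is None:
            pid = -1
            x0 = 0.0
        else:
            pid = distal[sec.parent]
            x0 = 0.0
        r = sec.diam_um / 2.0
        lines.append(f"{next_id} {sec.swc_type} {x0:.4f} {y:.4f} 0.0 {r:.4f} {pid}")
        prox_id = next_id
        next_id += 1
        lines.append(
            f"{next_id} {sec.swc_type} {x0 + sec.length_um:.4f} {y:.4f} 0.0 {r:.4f} {prox_id}"
        )
        distal[sec.name] = next_id
        next_id += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(path, nseg_by_type: dict[int, int] | None = None) -> Morphology:
    """Read an SWC file written by :func:`write_swc` back into a Morphology.

    Consecutive point pairs become sections.  ``nseg_by_type`` optionally
    maps SWC structure types to segment counts (default 1 per section).
    """
    pts: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            idx = int(fields[0])
            pts[idx] = (
                int(fields[1]),
                float(fields[2]),
                float(fields[3]),
                float(fields[4]),
                float(fields[5]),
                int(fields[6]),
            )
    nseg_by_type = nseg_by_type or {}
    sections: list[Section] = []
    # a section = (proximal point whose parent is -1 or another section's
    # distal point) + its single child point on the same branch
    owner: dict[int, str] = {}  # distal point id -> section name
    counter: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    for idx, (_, _, _, _, _, par) in pts.items():
        children.setdefault(par, []).append(idx)
    for prox_id in sorted(pts):
        typ, x0, y0, z0, r, par = pts[prox_id]
        if par != -1 and par not in owner:
            continue  # this is a distal point, handled with its proximal mate
        kids = children.get(prox_id, [])
        if len(kids) != 1:
            raise ValueError("read_swc expects two-point sections from write_swc")
        dist_id = kids[0]
        _, x1, y1, z1, r1, _ = pts[dist_id]
        length = math.dist((x0, y0, z0), (x1, y1, z1))
        counter[typ] = counter.get(typ, 0) + 1
        name = {1: "soma", 2: "axon"}.get(typ, "dend") + (
            "" if typ in (1, 2) and counter[typ] == 1 else f"_{counter[typ]}"
        )
        parent_name = owner[par] if par != -1 else None
        sections.append(
            Section(
                name,
                length,
                2.0 * r,
                parent=parent_name,
                nseg=nseg_by_type.get(typ, 1),
                swc_type=typ,
            )
        )
        owner[dist_id] = name
    return Morphology(sections)
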