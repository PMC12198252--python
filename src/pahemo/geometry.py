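"""Pulmonary-artery tree geometry.

A :class:`PATree` is a bifurcating network of straight, constant-radius
vessel segments: one root segment (the main pulmonary artery, MPA), two
principal children (right and left pulmonary arteries, RPA/LPA), and a
set of distal branches terminating in outlets on each side.  Centerline
arclength is tracked so that index-measurement cross-sections can be
placed at a prescribed distance from the MPA bifurcation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "VesselSegment",
    "PATree",
    "MeasurementSite",
    "measurement_site",
    "tree_to_json",
    "tree_from_json",
]

TREE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class VesselSegment:
    """A straight vessel segment with circular cross-section.

    Parameters
    ----------
    segment_id : str
        Unique identifier within the tree.
    parent_id : str or None
        Identifier of the upstream segment; ``None`` for the root.
    radius : float
        Lumen radius in cm.
    length : float
        Centerline length in cm.
    """

    segment_id: str
    parent_id: str | None
    radius: float
    length: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"segment {self.segment_id!r}: radius must be > 0, got {self.radius}")
        if self.length <= 0:
            raise ValueError(f"segment {self.segment_id!r}: length must be > 0, got {self.length}")

    @property
    def area(self) -> float:
        """Cross-sectional area pi r^2 in cm^2."""
        return math.pi * self.radius**2

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class PATree:
    """Bifurcating pulmonary-artery tree.

    ``root_id`` names the MPA segment; its two children are the principal
    RPA and LPA segments (``rpa_id`` / ``lpa_id``).  All leaves distal to
    a principal segment are that side's outlets.
    """

    segments: list[VesselSegment]
    root_id: str = "MPA"
    rpa_id: str = "RPA"
    lpa_id: str = "LPA"
    _by_id: dict[str, VesselSegment] = field(init=False, repr=False)
    _children: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._reindex()
        self.validate()

    def _reindex(self) -> None:
        self._by_id = {s.segment_id: s for s in self.segments}
        if len(self._by_id) != len(self.segments):
            raise ValueError("duplicate segment ids")
        self._children = {s.segment_id: [] for s in self.segments}
        for s in self.segments:
            if s.parent_id is not None:
                if s.parent_id not in self._by_id:
                    raise ValueError(f"segment {s.segment_id!r} references unknown parent {s.parent_id!r}")
                self._children[s.parent_id].append(s.segment_id)

    def validate(self) -> None:
        roots = [s for s in self.segments if s.parent_id is None]
        if len(roots) != 1 or roots[0].segment_id != self.root_id:
            raise ValueError("tree must have exactly one root, the MPA segment")
        principal = self._children[self.root_id]
        if sorted(principal) != sorted([self.rpa_id, self.lpa_id]):
            raise ValueError("root must have exactly the RPA and LPA principal segments as children")
        root = self._by_id[self.root_id]
        for pid in (self.rpa_id, self.lpa_id):
            if self._by_id[pid].radius > root.radius:
                raise ValueError(f"principal segment {pid!r} radius exceeds MPA radius")

    # -- accessors ---------------------------------------------------------

    def segment(self, segment_id: str) -> VesselSegment:
        try:
            return self._by_id[segment_id]
        except KeyError:
            raise KeyError(f"no segment {segment_id!r} in tree") from None

    def children(self, segment_id: str) -> list[VesselSegment]:
        return [self._by_id[c] for c in self._children[segment_id]]

    def is_outlet(self, segment_id: str) -> bool:
        return not self._children[segment_id]

    @property
    def outlet_ids(self) -> list[str]:
        return [s.segment_id for s in self.segments if self.is_outlet(s.segment_id)]

    def side_of(self, segment_id: str) -> str:
        """Return 'RPA', 'LPA' or 'MPA' for the side a segment belongs to."""
        sid = segment_id
        while True:
            if sid == self.rpa_id:
                return "RPA"
            if sid == self.lpa_id:
                return "LPA"
            parent = self._by_id[sid].parent_id
            if parent is None:
                return "MPA"
            sid = parent

    def side_outlets(self, side: str) -> list[str]:
        if side not in ("RPA", "LPA"):
            raise ValueError(f"side must be 'RPA' or 'LPA', got {side!r}")
        return [oid for oid in self.outlet_ids if self.side_of(oid) == side]

    def arclength_from_bifurcation(self, segment_id: str) -> float:
        """Centerline distance from the MPA bifurcation to a segment's proximal end.

        The bifurcation is the distal end of the MPA segment; the MPA
        itself reports the (negative) distance of its own proximal end.
        """
        if segment_id == self.root_id:
            return -self._by_id[self.root_id].length
        total = 0.0
        sid = segment_id
        while True:
            parent = self._by_id[sid].parent_id
            if parent == self.root_id:
                return total
            total += self._by_id[parent].length
            sid = parent


@dataclass(frozen=True)
class MeasurementSite:
    """A cross-section where indices are evaluated."""

    branch: str  # "MPA" | "RPA" | "LPA"
    segment_id: str
    arclength_in_segment: float  # cm from the segment's proximal end
    radius: float  # cm
    area: float  # cm^2


def measurement_site(tree: PATree, branch: str) -> MeasurementSite:
    """Locate the index-measurement cross-section for one artery.

    For the RPA and LPA the site lies at a centerline distance equal to
    the MPA radius distal to the bifurcation, walking through child
    segments if the principal segment is shorter (ties broken toward the
    largest-radius child).  For the MPA the site is the mid-length
    cross-section of the root segment.
    """
    if branch == "MPA":
        root = tree.segment(tree.root_id)
        return MeasurementSite("MPA", root.segment_id, root.length / 2.0, root.radius, root.area)
    if branch not in ("RPA", "LPA"):
        raise ValueError(f"branch must be 'MPA', 'RPA' or 'LPA', got {branch!r}")

    target = tree.segment(tree.root_id).radius
    seg = tree.segment(tree.rpa_id if branch == "RPA" else tree.lpa_id)
    remaining = target
    while remaining > seg.length:
        remaining -= seg.length
        kids = tree.children(seg.segment_id)
        if not kids:
            raise ValueError(
                f"{branch} centerline ({target - remaining:.3g} cm) is shorter than the "
                f"MPA radius ({target:.3g} cm); cannot place measurement site"
            )
        seg = max(kids, key=lambda s: (s.radius, s.segment_id))
    return MeasurementSite(branch, seg.segment_id, remaining, seg.radius, seg.area)


# -- serialization ---------------------------------------------------------


def tree_to_json(tree: PATree) -> str:
    payload = {
        "schema_version": TREE_SCHEMA_VERSION,
        "root_id": tree.root_id,
        "rpa_id": tree.rpa_id,
        "lpa_id": tree.lpa_id,
        "segments": [
            {
                "id": s.segment_id,
                "parent": s.parent_id,
                "radius_cm": s.radius,
                "length_cm": s.length,
            }
            for s in tree.segments
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def tree_from_json(text: str) -> PATree:
    payload = json.loads(text)
    version = payload.get("schema_version")
    if version != TREE_SCHEMA_VERSION:
        raise ValueError(f"unsupported tree schema version {version!r}")
    segments = [
        VesselSegment(d["id"], d["parent"], d["radius_cm"], d["length_cm"])
        for d in payload["segments"]
    ]
    return PATree(
        segments,
        root_id=payload["root_id"],
        rpa_id=payload["rpa_id"],
        lpa_id=payload["lpa_id"],
    )
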