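"""SWC neuron morphologies: reading, validation and morphometry.

A morphology is a rooted tree of 3D sample points with radii and SWC
structure labels (1 = soma, 3 = basal dendrite, 4 = apical dendrite).
Consecutive points define cylindrical segments whose diameter is the mean
of the two endpoint diameters; the soma is treated as a single isopotential
sphere, so steps between soma points contribute nothing to path distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SOMA, BASAL, APICAL = 1, 3, 4
_KNOWN_STRUCTURES = {SOMA, BASAL, APICAL}


class MorphologyError(ValueError):
    """Invalid morphology (structure or validation failure)."""


class SWCParseError(MorphologyError):
    """Malformed SWC content."""


@dataclass(frozen=True)
class MorphPoint:
    """One SWC sample point.

    ``structure`` is the raw SWC type code; codes other than 1/3/4 are kept
    but treated as "other" and excluded from arbor-specific analyses.
    """

    id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def structure_label(self) -> str:
        return {SOMA: "soma", BASAL: "basal", APICAL: "apical"}.get(
            self.structure, "other"
        )


@dataclass
class Morphology:
    """A validated single-tree neuron morphology.

    Parameters
    ----------
    points
        Sample points, ids contiguous from 1, every parent preceding its
        children (the root has ``parent_id == -1``).
    soma_area_override
        If given, :func:`soma_surface` returns this value (μm²) instead of
        the sphere area of the mean soma radius.  The study assigned each
        reconstructed neuron its measured soma area this way.
    """

    points: list[MorphPoint]
    soma_area_override: float | None = None
    name: str = ""
    _dist_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not self.points:
            raise MorphologyError("morphology has no points")
        ids = [p.id for p in self.points]
        if ids != list(range(1, len(ids) + 1)):
            raise MorphologyError("point ids must be contiguous from 1")
        roots = [p for p in self.points if p.parent_id == -1]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        seen: set[int] = set()
        for p in self.points:
            if p.radius <= 0:
                raise MorphologyError(f"point {p.id}: nonpositive radius {p.radius}")
            if p.parent_id != -1 and p.parent_id not in seen:
                raise MorphologyError(
                    f"point {p.id}: parent {p.parent_id} does not precede it"
                )
            seen.add(p.id)
        if not any(p.structure != SOMA for p in self.points):
            raise MorphologyError("morphology has no dendritic points")
        unknown = sorted(
            {p.structure for p in self.points} - _KNOWN_STRUCTURES
        )
        if unknown:
            log.warning(
                "morphology %s: structure codes %s treated as 'other' and "
                "excluded from arbor analyses",
                self.name or "<unnamed>",
                unknown,
            )

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.points)

    def point(self, point_id: int) -> MorphPoint:
        if not 1 <= point_id <= len(self.points):
            raise KeyError(f"no point with id {point_id}")
        return self.points[point_id - 1]

    @property
    def root(self) -> MorphPoint:
        return next(p for p in self.points if p.parent_id == -1)

    def children(self, point_id: int) -> list[MorphPoint]:
        return [p for p in self.points if p.parent_id == point_id]

    # -- geometry -----------------------------------------------------------

    def _distances(self) -> np.ndarray:
        """Path distance from the soma root for every point (μm), cached."""
        if self._dist_cache is None:
            d = np.zeros(len(self.points))
            for p in self.points:
                if p.parent_id == -1:
                    continue
                parent = self.points[p.parent_id - 1]
                step = 0.0 if p.structure == SOMA else math.dist(
                    (p.x, p.y, p.z), (parent.x, parent.y, parent.z)
                )
                d[p.id - 1] = d[p.parent_id - 1] + step
            object.__setattr__(self, "_dist_cache", d)
        return self._dist_cache

    def segments(self) -> pd.DataFrame:
        """Dendritic cylinder segments, one row per (parent, child) pair.

        Columns: child_id, parent_id, length, diameter, area, arbor,
        mid_distance.  Soma–soma steps are excluded (the soma is a sphere);
        a segment whose proximal end is a soma point takes the child's
        diameter (the cable starts at the soma surface).
        """
        rows = []
        dist = self._distances()
        alias: dict[int, int] = {}  # zero-length children attach via their parent
        for p in self.points:
            if p.parent_id == -1 or p.structure == SOMA:
                continue
            parent = self.points[p.parent_id - 1]
            length = math.dist((p.x, p.y, p.z), (parent.x, parent.y, parent.z))
            eff_parent_id = alias.get(parent.id, parent.id)
            if length == 0.0:
                alias[p.id] = eff_parent_id
                continue
            eff_parent = self.points[eff_parent_id - 1]
            if eff_parent.structure == SOMA:
                diam = 2.0 * p.radius
            else:
                diam = p.radius + eff_parent.radius  # mean of the two diameters
            rows.append(
                {
                    "child_id": p.id,
                    "parent_id": eff_parent_id,
                    "length": length,
                    "diameter": diam,
                    "area": math.pi * diam * length,
                    "arbor": p.structure_label,
                    "mid_distance": 0.5 * (dist[p.id - 1] + dist[p.parent_id - 1]),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "child_id",
                "parent_id",
                "length",
                "diameter",
                "area",
                "arbor",
                "mid_distance",
            ],
        )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------


def read_swc(path: str | Path, soma_area_override: float | None = None) -> Morphology:
    """Parse a whitespace-delimited 7-column SWC file into a :class:`Morphology`.

    Ids are re-indexed contiguously from 1 (preserving parent links);
    ``#`` comment lines and blank lines are ignored.
    """
    path = Path(path)
    raw: list[tuple[int, int, float, float, float, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            cols = body.split()
            if len(cols) != 7:
                raise SWCParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(cols)}"
                )
            try:
                raw.append(
                    (
                        int(cols[0]),
                        int(cols[1]),
                        float(cols[2]),
                        float(cols[3]),
                        float(cols[4]),
                        float(cols[5]),
                        int(cols[6]),
                    )
                )
            except ValueError as exc:
                raise SWCParseError(f"{path.name}:{lineno}: {exc}") from None
    if not raw:
        raise SWCParseError(f"{path.name}: no data lines")
    id_map = {old_id: new_id for new_id, (old_id, *_) in enumerate(raw, start=1)}
    if len(id_map) != len(raw):
        raise MorphologyError(f"{path.name}: duplicate point ids")
    points = []
    for old_id, struct, x, y, z, radius, parent in raw:
        if parent == -1:
            new_parent = -1
        elif parent in id_map:
            new_parent = id_map[parent]
        else:
            raise MorphologyError(
                f"{path.name}: point {old_id} references unknown parent {parent}"
            )
        points.append(
            MorphPoint(id_map[old_id], struct, x, y, z, radius, new_parent)
        )
    return Morphology(points, soma_area_override=soma_area_override, name=path.stem)


def write_swc(m: Morphology, path: str | Path) -> None:
    """Write a morphology as standard 7-column SWC (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for p in m.points:
            fh.write(
                f"{p.id} {p.structure} {p.x!r} {p.y!r} {p.z!r} {p.radius!r} "
                f"{p.parent_id}\n"
            )


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------


def path_distance(m: Morphology, point_id: int) -> float:
    """Path distance (μm) from the soma root to a sample point.

    Sum of Euclidean inter-point steps along the unique path to the root;
    steps between soma points contribute zero (the soma is isopotential).
    """
    m.point(point_id)  # raises KeyError for unknown ids
    return float(m._distances()[point_id - 1])


def segment_surface_area(d: float, l: float) -> float:
    """Lateral (open-cylinder) surface area π·d·l, μm²."""
    if d <= 0 or l <= 0:
        raise ValueError("segment_surface_area requires positive d and l")
    return math.pi * d * l


def soma_surface(m: Morphology) -> float:
    """Soma surface area, μm².

    The override wins when set (reconstructed areas were assigned per
    neuron); otherwise the sphere area 4π·r̄² of the mean soma-point radius.
    """
    if m.soma_area_override is not None:
        return float(m.soma_area_override)
    radii = [p.radius for p in m.points if p.structure == SOMA]
    if not radii:
        raise MorphologyError("no soma points and no soma_area_override")
    r = float(np.mean(radii))
    return 4.0 * math.pi * r * r


def distribution_by_distance(
    m: Morphology,
    quantity: Literal["length", "area"],
    bin_width: float,
    arbor: Literal["apical", "basal"],
) -> pd.DataFrame:
    """Fraction of arbor length or lateral surface area per path-distance bin.

    Each dendritic segment is assigned to the bin containing its midpoint
    path distance; fractions sum to 1.  This is the length/surface-area
    distribution whose identity (for near-constant diameters) justifies
    using surface area as a proxy for synapse counts.
    """
    if quantity not in ("length", "area"):
        raise ValueError(f"unknown quantity {quantity!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    seg = m.segments()
    seg = seg[seg["arbor"] == arbor]
    if seg.empty:
        raise MorphologyError(f"morphology has no {arbor} segments")
    w = seg[quantity].to_numpy()
    mid = seg["mid_distance"].to_numpy()
    n_bins = int(np.floor(mid.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(mid, bins=edges, weights=w)
    frac = hist / w.sum()
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "fraction": frac}
    )


def total_by_arbor(m: Morphology) -> pd.DataFrame:
    """Per-arbor totals: length, lateral area, segment count (one row each)."""
    seg = m.segments()
    out = (
        seg.groupby("arbor", sort=True)
        .agg(total_length=("length", "sum"), total_area=("area", "sum"),
             n_segments=("length", "size"))
        .reset_index()
    )
    out.insert(0, "neuron", m.name)
    return out


def morphometry_summary(morphologies: Iterable[Morphology]) -> pd.DataFrame:
    """One row per neuron: totals per arbor plus soma area (tidy CSV-ready)."""
    frames = []
    for m in morphologies:
        t = total_by_arbor(m)
        wide = t.pivot(index="neuron", columns="arbor")
        wide.columns = [f"{q}_{a}" for q, a in wide.columns]
        wide["soma_area"] = soma_surface(m)
        frames.append(wide.reset_index())
    return pd.concat(frames, ignore_index=True).fillna(0.0)
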