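"""Membrane curvature from three points, and region classification around Par-islands.

The equatorial membrane contour is partitioned relative to Par-islands
(contiguous membrane compartments co-localizing with Par3 signal, longer than
1 µm along the contour):

* island regions — the island spans themselves;
* neighboring regions — membrane within 5 µm (geodesic arc distance on the
  closed contour) of any island edge; classified but not measured;
* non-neighboring regions — compartments of at most 5 µm lying entirely
  beyond the 5 µm exclusion zone;
* cells without islands contribute compartments of at most 5 µm over the
  whole contour (``non_island_cell`` class).

Each measured region yields a curvature radius: the circumradius of the
circle through the region's two endpoints and its arc-length midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

COLLINEAR_AREA_TOL = 1e-9  # µm^2; flatter triangles are treated as straight


class CollinearPointsError(ValueError):
    """Raised when three points are (numerically) collinear: infinite radius,
    i.e. a locally straight membrane."""


def circumradius(p1, p2, p3) -> float:
    """Radius of the unique circle through three non-collinear points.

    R = |a||b||c| / (4·area) with a, b, c the triangle side lengths.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    if min(a, b, c) == 0.0:
        raise ValueError("duplicate points: circumscribed circle is undefined")
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    area = 0.5 * abs(cross)
    if area < COLLINEAR_AREA_TOL:
        raise CollinearPointsError(
            "collinear points: infinite radius / straight membrane"
        )
    return float(a * b * c / (4.0 * area))


@dataclass
class MembraneTrace:
    """Ordered equatorial membrane coordinates (µm) with Par-island spans.

    ``island_spans`` are (start_um, end_um) arc intervals along the closed
    contour where Par signal co-localizes with the membrane.
    """

    coords: np.ndarray
    island_spans: Sequence[tuple[float, float]] = ()
    cell_id: str = ""
    closed: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if self.coords.shape[0] < 3:
            raise ValueError("membrane trace needs at least 3 points")
        L = self.total_length_um
        spans = sorted((float(a), float(b)) for a, b in self.island_spans)
        for a, b in spans:
            if not 0 <= a < b <= L:
                raise ValueError(
                    f"island span ({a}, {b}) exceeds the contour length {L:.3f} um"
                )
        for (_, b0), (a1, _) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError("island spans overlap")
        self.island_spans = spans

    @property
    def has_islands(self) -> bool:
        return len(self.island_spans) > 0

    @property
    def _arc(self) -> np.ndarray:
        pts = self.coords
        ring = np.vstack([pts, pts[0]]) if self.closed else pts
        seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
        return np.concatenate(([0.0], np.cumsum(seg)))

    @property
    def total_length_um(self) -> float:
        return float(self._arc[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Coordinates at arc position ``s`` (wrapping the closed contour)."""
        arc = self._arc
        L = arc[-1]
        s = float(s) % L if self.closed else min(max(s, 0.0), L)
        pts = self.coords
        ring = np.vstack([pts, pts[0]]) if self.closed else pts
        x = np.interp(s, arc, ring[:, 0])
        y = np.interp(s, arc, ring[:, 1])
        return np.array([x, y])


@dataclass
class RegionMeasurement:
    region_class: str  # island | neighboring | non_neighboring | non_island_cell
    start_um: float
    end_um: float
    cell_id: str = ""
    endpoints: Optional[np.ndarray] = field(default=None, repr=False)
    midpoint: Optional[np.ndarray] = field(default=None, repr=False)
    radius_um: Optional[float] = None
    excluded: bool = False
    note: str = ""

    @property
    def arc_length_um(self) -> float:
        return self.end_um - self.start_um


def _split_into_compartments(start: float, end: float, max_len: float):
    """Cut [start, end] into consecutive pieces of at most ``max_len``,
    starting from ``start``; the final remainder may be shorter."""
    out = []
    s = start
    while end - s > 1e-12:
        e = min(s + max_len, end)
        out.append((s, e))
        s = e
    return out


def partition_regions(
    trace: MembraneTrace,
    min_island_um: float = 1.0,
    exclusion_um: float = 5.0,
    max_region_um: float = 5.0,
) -> list[RegionMeasurement]:
    """Classify the closed contour into island / neighboring / non-neighboring
    regions (or non_island_cell compartments when no islands are present).

    Arc distances to island edges are geodesic on the closed contour.  The
    stretch of each inter-island gap beyond the exclusion distance is split
    into consecutive compartments of at most ``max_region_um`` starting at the
    exclusion boundary.
    """
    L = trace.total_length_um
    cid = trace.cell_id
    regions: list[RegionMeasurement] = []

    islands = [
        (a, b) for a, b in trace.island_spans if (b - a) > min_island_um
    ]
    if not trace.has_islands:
        for s, e in _split_into_compartments(0.0, L, max_region_um):
            regions.append(RegionMeasurement("non_island_cell", s, e, cid))
        return regions

    for a, b in islands:
        regions.append(RegionMeasurement("island", a, b, cid))

    if not islands:
        # only sub-threshold spans: nothing is an island region, but the cell
        # still *has* islands, so no non_island_cell class either; the whole
        # contour outside the spans is left unclassified for measurement.
        return regions

    # gaps between consecutive islands, circularly
    for i, (_, b0) in enumerate(islands):
        a1 = islands[(i + 1) % len(islands)][0]
        gap_start, gap_end = b0, a1 if a1 > b0 else a1 + L
        gap = gap_end - gap_start
        near = min(exclusion_um, gap / 2)
        if gap <= 2 * exclusion_um:
            regions.append(
                RegionMeasurement("neighboring", gap_start % L, gap_end, cid)
            )
            continue
        regions.append(
            RegionMeasurement("neighboring", gap_start, gap_start + near, cid)
        )
        regions.append(RegionMeasurement("neighboring", gap_end - near, gap_end, cid))
        for s, e in _split_into_compartments(
            gap_start + near, gap_end - near, max_region_um
        ):
            regions.append(RegionMeasurement("non_neighboring", s, e, cid))
    return regions


MEASURED_CLASSES = ("island", "non_neighboring", "non_island_cell")


def region_radius(trace: MembraneTrace, region: RegionMeasurement) -> RegionMeasurement:
    """Curvature radius of a region: circumradius of its two endpoints and the
    trace point at half the region's arc length.

    Collinear triples mark the region as excluded with an explanatory note
    rather than raising, so cohort summaries can simply drop them.
    """
    s, e = region.start_um, region.end_um
    p_start = trace.point_at(s)
    p_end = trace.point_at(e)
    p_mid = trace.point_at((s + e) / 2.0)
    region.endpoints = np.vstack([p_start, p_end])
    region.midpoint = p_mid
    try:
        region.radius_um = circumradius(p_start, p_mid, p_end)
    except CollinearPointsError as err:
        region.excluded = True
        region.note = str(err)
    return region


def measure_regions(
    trace: MembraneTrace,
    min_island_um: float = 1.0,
    exclusion_um: float = 5.0,
    max_region_um: float = 5.0,
) -> list[RegionMeasurement]:
    """Partition a trace and measure curvature radii for the measured classes."""
    regions = partition_regions(trace, min_island_um, exclusion_um, max_region_um)
    for r in regions:
        if r.region_class in MEASURED_CLASSES:
            region_radius(trace, r)
    return regions


@dataclass
class GroupComparison:
    medians: dict
    counts: dict
    ks_tests: dict  # (group_a, group_b) -> (statistic, p_value)


def curvature_compare(
    groups: dict[str, Sequence[float]],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> GroupComparison:
    """Per-group median radii and pairwise two-sample Kolmogorov–Smirnov tests."""
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, vals in clean.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
    if pairs is None:
        names = list(clean)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    ks = {}
    for a, b in pairs:
        if clean[a].size < 2 or clean[b].size < 2:
            raise ValueError("KS test needs at least 2 values per group")
        res = stats.ks_2samp(clean[a], clean[b])
        ks[(a, b)] = (float(res.statistic), float(res.pvalue))
    return GroupComparison(
        medians={k: float(np.median(v)) for k, v in clean.items()},
        counts={k: int(v.size) for k, v in clean.items()},
        ks_tests=ks,
    )
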