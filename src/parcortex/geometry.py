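"""Aggregate morphometrics, centrosome–crescent fan geometry, and cohort statistics.

Covers: ROI polygon areas for Par-aggregate size, the fan test (is the
centrosome direction from the cell center inside the angular sector spanned
by the cortical crescent?), per-cell expression ratios from western-blot
intensities normalised by transfection efficiency, and Fisher's exact test
with Bonferroni correction for comparing polarized-cell fractions.

Angles follow the image convention: coordinates have y increasing downward,
angles are measured in degrees, clockwise-positive as displayed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# ROI areas


def _is_simple_polygon(vertices: np.ndarray) -> bool:
    """Check a polygon for self-intersection by brute-force segment pairs."""
    n = vertices.shape[0]
    segs = [(vertices[i], vertices[(i + 1) % n]) for i in range(n)]

    def intersects(p, q, r, s):
        def orient(a, b, c):
            v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

        o1, o2 = orient(p, q, r), orient(p, q, s)
        o3, o4 = orient(r, s, p), orient(r, s, q)
        return o1 != o2 and o3 != o4

    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if intersects(*segs[i], *segs[j]):
                return False
    return True


def roi_area(vertices: np.ndarray) -> float:
    """Area (µm²) of a simple polygon by the shoelace formula, orientation-free."""
    v = np.asarray(vertices, dtype=float)
    if np.allclose(v[0], v[-1]) and v.shape[0] > 3:
        v = v[:-1]
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("ROI polygon needs at least 3 distinct vertices")
    if not _is_simple_polygon(v):
        raise ValueError("ROI polygon is self-intersecting")
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0:
        raise ValueError("ROI polygon has zero area")
    return float(area)


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int


def aggregate_size_summary(
    groups: dict[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
):
    """Per-group (mean, sd, n) of aggregate areas plus pairwise two-sample
    Kolmogorov–Smirnov tests."""
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, vals in clean.items():
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
    if pairs is None:
        names = list(clean)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    summaries = {
        k: GroupSummary(
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
            n=int(v.size),
        )
        for k, v in clean.items()
    }
    ks = {}
    for a, b in pairs:
        res = stats.ks_2samp(clean[a], clean[b])
        ks[(a, b)] = (float(res.statistic), float(res.pvalue))
    return summaries, ks


# ---------------------------------------------------------------------------
# fan geometry


@dataclass
class FanGeometry:
    """Angular geometry of a cortical crescent and the centrosome.

    theta1_deg is the crescent's angular extent seen from the cell center
    (clockwise from edge a to edge b); theta2_deg the clockwise angle from
    edge a to the centrosome direction.  The centrosome lies within the fan
    iff 0 <= theta2 <= theta1 (edges inclusive).
    """

    theta1_deg: float
    theta2_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta1_deg < 360.0:
            raise ValueError("crescent extent theta1 must lie in (0, 360) degrees")

    @property
    def within_fan(self) -> bool:
        return 0.0 <= self.theta2_deg <= self.theta1_deg


def _direction_angle_deg(center: np.ndarray, point: np.ndarray) -> float:
    v = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    if np.linalg.norm(v) == 0:
        raise ValueError("point coincides with the cell center: no direction")
    # image coordinates (y down): atan2 measures clockwise as displayed
    return float(np.degrees(np.arctan2(v[1], v[0])))


def crescent_fan(center, edge_a, edge_b, centrosome) -> FanGeometry:
    """Fan geometry from the cell center, the two crescent edge points
    (ordered so the crescent runs clockwise from edge_a to edge_b), and the
    centrosome position."""
    a = _direction_angle_deg(center, edge_a)
    b = _direction_angle_deg(center, edge_b)
    c = _direction_angle_deg(center, centrosome)
    theta1 = (b - a) % 360.0
    if theta1 == 0.0:
        raise ValueError("crescent edges are collinear with the center")
    theta2 = (c - a) % 360.0
    return FanGeometry(theta1_deg=theta1, theta2_deg=theta2)


def fraction_within_fan(cohort: Sequence[FanGeometry]) -> tuple[int, int, float]:
    """(count inside, n, fraction) over a cohort of fan geometries."""
    n = len(cohort)
    if n == 0:
        raise ValueError("fan cohort is empty")
    inside = sum(1 for g in cohort if g.within_fan)
    return inside, n, inside / n


# ---------------------------------------------------------------------------
# expression ratios and count-table tests


def expression_ratio(
    intensity_a: float,
    transfection_eff_a: float,
    intensity_b: float,
    transfection_eff_b: float,
) -> float:
    """Fold ratio of per-cell expression levels.

    Western-blot staining intensities are divided by transfection efficiencies
    to obtain per-cell levels before taking the ratio a/b.
    """
    for eff in (transfection_eff_a, transfection_eff_b):
        if not 0.0 < eff <= 1.0:
            raise ValueError("transfection efficiency must lie in (0, 1]")
    if intensity_a < 0 or intensity_b < 0:
        raise ValueError("intensities must be non-negative")
    if intensity_b == 0:
        raise ValueError("reference intensity is zero: ratio undefined")
    return (intensity_a / transfection_eff_a) / (intensity_b / transfection_eff_b)


def polarized_fraction_test(
    tables: Sequence[tuple[tuple[int, int], tuple[int, int]]],
) -> list[dict]:
    """Fisher's exact test (two-sided) per 2×2 table of
    (polarized, non-polarized) counts for condition vs reference, with
    Bonferroni adjustment over the number of comparisons (capped at 1)."""
    m = len(tables)
    if m == 0:
        raise ValueError("no count tables given")
    results = []
    for tab in tables:
        arr = np.asarray(tab, dtype=int)
        if arr.shape != (2, 2) or np.any(arr < 0):
            raise ValueError("each table must be a 2x2 array of non-negative counts")
        _, p = stats.fisher_exact(arr, alternative="two-sided")
        results.append(
            {"p_raw": float(p), "p_adjusted": float(min(1.0, p * m)), "table": arr}
        )
    return results
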