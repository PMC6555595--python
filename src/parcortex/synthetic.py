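"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one of the measurement modalities the pipeline
consumes — perimeter intensity profiles with a contiguous crescent, circle
arcs of known radius for curvature, contour-length samples from a Gaussian
comb, raster images of a polygonal meshwork, Gaussian cross-sections of known
FWHM, and crescent/centrosome angular configurations — and returns the data
together with a ground-truth record, so zero-noise outputs round-trip exactly
through the corresponding analysis.

All randomness flows through ``numpy.random.default_rng(seed)``: a fixed seed
gives identical output on every run and platform.  Lengths are in µm; default
pixel sizes are 0.108 µm (confocal, ASI context) and 0.053 µm
(super-resolution context).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .asymmetry import DEFAULT_SPACING_UM, PerimeterProfile
from .geometry import FanGeometry
from .meshwork import FWHM_PER_SIGMA

SRRF_PIXEL_UM = 0.053


@dataclass
class GroundTruth:
    """Truth record emitted alongside every synthetic dataset (units µm)."""

    kind: str
    params: dict = field(default_factory=dict)


def make_perimeter_profile(
    n_samples: int,
    crescent_fraction: float,
    crescent_level: float,
    background_level: float,
    noise_sd: float,
    seed: int,
    spacing_um: float = DEFAULT_SPACING_UM,
) -> tuple[PerimeterProfile, GroundTruth]:
    """Perimeter profile with one contiguous crescent arc.

    ``round(n·fraction)`` consecutive samples (start drawn uniformly; the ASI
    is rotation invariant, so placement is immaterial) sit at
    ``crescent_level``, the rest at ``background_level``; additive Gaussian
    noise is truncated at zero since fluorescence is non-negative.
    """
    if n_samples < 8 or n_samples % 2:
        raise ValueError(
            f"n_samples must be even and >= 8 (half-perimeter windows), got {n_samples}"
        )
    if not 0.0 < crescent_fraction <= 1.0:
        raise ValueError("crescent_fraction must lie in (0, 1]")
    if crescent_level < 0 or background_level < 0 or noise_sd < 0:
        raise ValueError("levels and noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    width = int(round(n_samples * crescent_fraction))
    start = int(rng.integers(0, n_samples))
    y = np.full(n_samples, float(background_level))
    idx = (start + np.arange(width)) % n_samples
    y[idx] = crescent_level
    if noise_sd > 0:
        y = np.maximum(y + rng.normal(0.0, noise_sd, n_samples), 0.0)
    profile = PerimeterProfile(intensities=y, spacing_um=spacing_um)
    truth = GroundTruth(
        "perimeter_profile",
        {
            "crescent_fraction": crescent_fraction,
            "crescent_start_index": start,
            "crescent_n_samples": width,
            "crescent_level": crescent_level,
            "background_level": background_level,
            "true_asi": _noiseless_asi(n_samples, width, crescent_level, background_level),
        },
    )
    return profile, truth


def _noiseless_asi(n: int, width: int, hi: float, lo: float) -> float:
    """Closed-form ASI of a two-level crescent profile (no noise).

    The best half-window covers min(width, n/2) crescent samples; with window
    sum S and total T the ASI is |2S - T|/T.
    """
    half = n // 2
    covered = min(width, half)
    total = width * hi + (n - width) * lo
    if total == 0:
        return 0.0
    s = covered * hi + (half - covered) * lo
    return abs(2 * s - total) / total


def make_arc_points(
    radius_um: float,
    center: Sequence[float],
    theta_start_deg: float,
    theta_mid_deg: float,
    theta_end_deg: float,
    jitter_sd: float,
    seed: int,
) -> tuple[np.ndarray, GroundTruth]:
    """Three points on (or jittered off) a circle of known radius."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    angles = np.radians([theta_start_deg, theta_mid_deg, theta_end_deg])
    if len({round(a % (2 * np.pi), 12) for a in angles}) < 3:
        raise ValueError("the three angles must be distinct")
    rng = np.random.default_rng(seed)
    c = np.asarray(center, dtype=float)
    pts = c + radius_um * np.column_stack([np.cos(angles), np.sin(angles)])
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
    truth = GroundTruth("arc_points", {"radius_um": radius_um, "center": tuple(c)})
    return pts, truth


def make_comb_lengths(
    n: int,
    spacing_um: float,
    component_sds,
    weights=None,
    k: int = 7,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Contour-length sample from a k-component Gaussian comb.

    Component j (j = 1..k) has mean j·spacing; draws that fall at or below
    zero are re-drawn (not clipped) so each component stays Gaussian.
    """
    if k < 2:
        raise ValueError("comb needs k >= 2 components")
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    sds = np.broadcast_to(np.asarray(component_sds, dtype=float), (k,)).copy()
    if np.any(sds < 0):
        raise ValueError("component sds must be non-negative")
    if weights is None:
        w = np.full(k, 1.0 / k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != k or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must have length k and sum to 1")
    rng = np.random.default_rng(seed)
    comps = rng.choice(k, size=n, p=w)
    means = (np.arange(1, k + 1)) * spacing_um
    lengths = rng.normal(means[comps], sds[comps])
    bad = lengths <= 0
    while np.any(bad):
        lengths[bad] = rng.normal(means[comps[bad]], sds[comps[bad]])
        bad = lengths <= 0
    truth = GroundTruth(
        "comb_lengths",
        {
            "spacing_um": spacing_um,
            "k": k,
            "means_um": means.tolist(),
            "sds_um": sds.tolist(),
            "weights": w.tolist(),
        },
    )
    return lengths, truth


def make_meshwork_image(
    grid_pitch_um: float,
    pixel_um: float = SRRF_PIXEL_UM,
    line_width_um: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_cells: int = 3,
) -> tuple[np.ndarray, list[np.ndarray], GroundTruth]:
    """Raster of a square lattice meshwork plus its ground-truth polylines.

    The lattice has ``n_cells`` × ``n_cells`` unit cells of edge
    ``grid_pitch_um``; lines are ``line_width_um`` wide.  Polylines (one per
    lattice edge, µm coordinates) are emitted alongside, each of arc length
    exactly the pitch.
    """
    if pixel_um > line_width_um:
        raise ValueError("pixel size must not exceed the line width")
    if grid_pitch_um <= 2 * line_width_um:
        raise ValueError("pitch must exceed twice the line width")
    if n_cells < 1:
        raise ValueError("image must contain at least one lattice cell")
    margin = grid_pitch_um / 2
    extent = n_cells * grid_pitch_um + 2 * margin
    n_px = int(np.ceil(extent / pixel_um))
    coords = (np.arange(n_px) + 0.5) * pixel_um
    # distance of each coordinate to the nearest lattice line position
    lines = margin + np.arange(n_cells + 1) * grid_pitch_um
    dist = np.min(np.abs(coords[:, None] - lines[None, :]), axis=1)
    on_line = dist <= line_width_um / 2
    img = (on_line[:, None] | on_line[None, :]).astype(float)
    # restrict to the lattice bounding box (no dangling half-lines)
    inside = (coords >= margin - line_width_um / 2) & (
        coords <= extent - margin + line_width_um / 2
    )
    img *= inside[:, None] & inside[None, :]
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = np.maximum(img + rng.normal(0.0, noise_sd, img.shape), 0.0)

    polylines = []
    for i, u in enumerate(lines):
        for j, v in enumerate(lines[:-1]):
            # vertical edge (x = u) and horizontal edge (y = u) of length pitch
            polylines.append(np.array([[u, v], [u, v + grid_pitch_um]]))
            polylines.append(np.array([[v, u], [v + grid_pitch_um, u]]))
    truth = GroundTruth(
        "meshwork_image",
        {
            "grid_pitch_um": grid_pitch_um,
            "pixel_um": pixel_um,
            "line_width_um": line_width_um,
            "n_edges": len(polylines),
        },
    )
    return img, polylines, truth


def make_cross_profile(
    fwhm_um: float,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    pixel_um: float = 0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
    half_extent_um: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Sampled Gaussian cross-section of known FWHM (positions, intensities)."""
    if fwhm_um <= 0:
        raise ValueError("FWHM must be positive")
    if fwhm_um <= 2 * pixel_um:
        raise ValueError("FWHM must exceed two pixels to be resolvable")
    sigma = fwhm_um / FWHM_PER_SIGMA
    if half_extent_um is None:
        half_extent_um = 4 * sigma
    x = np.arange(-half_extent_um, half_extent_um + pixel_um / 2, pixel_um)
    y = amplitude * np.exp(-0.5 * (x / sigma) ** 2) + baseline
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd * amplitude, y.shape)
    truth = GroundTruth(
        "cross_profile",
        {"fwhm_um": fwhm_um, "sigma_um": sigma, "amplitude": amplitude,
         "baseline": baseline},
    )
    return x, y, truth


def make_fan_cohort(
    n_cells: int,
    theta1_range_deg: tuple[float, float] = (60.0, 120.0),
    inside_fraction: float = 0.8,
    seed: int = 0,
    cell_radius_um: float = 4.5,
    centrosome_radius_um: float = 2.0,
):
    """Cohort of crescent/centrosome configurations with an exact inside count.

    Exactly ``round(n·inside_fraction)`` cells place the centrosome direction
    inside the crescent fan.  Returns per-cell coordinate records
    (center, edge_a, edge_b, centrosome) plus the truth.
    Coordinates use the image convention (y down, clockwise-positive angles).
    """
    if n_cells < 1:
        raise ValueError("cohort needs at least one cell")
    if not 0.0 <= inside_fraction <= 1.0:
        raise ValueError("inside_fraction must lie in [0, 1]")
    lo, hi = theta1_range_deg
    if not 0 < lo <= hi < 360:
        raise ValueError("theta1 range must lie in (0, 360)")
    rng = np.random.default_rng(seed)
    n_inside = int(round(n_cells * inside_fraction))
    inside_flags = np.zeros(n_cells, dtype=bool)
    inside_flags[rng.permutation(n_cells)[:n_inside]] = True

    def cw_rotate(angle_deg):
        # clockwise as displayed == mathematically positive with y down
        a = np.radians(angle_deg)
        return np.array([np.cos(a), np.sin(a)])

    cells = []
    for flag in inside_flags:
        center = rng.uniform(5.0, 15.0, 2)
        theta1 = rng.uniform(lo, hi)
        phi = rng.uniform(0.0, 360.0)  # orientation of edge a
        if flag:
            theta2 = rng.uniform(0.0, theta1)
        else:
            theta2 = rng.uniform(theta1 + 1.0, 359.0)
        edge_a = center + cell_radius_um * cw_rotate(phi)
        edge_b = center + cell_radius_um * cw_rotate(phi + theta1)
        centrosome = center + centrosome_radius_um * cw_rotate(phi + theta2)
        cells.append(
            {
                "center": center,
                "edge_a": edge_a,
                "edge_b": edge_b,
                "centrosome": centrosome,
                "true_theta1_deg": theta1,
                "true_theta2_deg": theta2,
                "true_within_fan": bool(flag),
            }
        )
    truth = GroundTruth(
        "fan_cohort",
        {"n_cells": n_cells, "n_inside": n_inside,
         "inside_fraction": n_inside / n_cells},
    )
    return cells, truth


def make_circular_trace(
    radius_um: float,
    n_points: int = 400,
    center: Sequence[float] = (0.0, 0.0),
    jitter_sd: float = 0.0,
    seed: int = 0,
    island_spans: Sequence[tuple[float, float]] = (),
):
    """Closed circular membrane trace of known radius (optionally jittered),
    with optional island spans in arc-length µm — the curvature fixture."""
    from .curvature import MembraneTrace

    if radius_um <= 0 or n_points < 3:
        raise ValueError("need positive radius and >= 3 points")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    pts = np.asarray(center, dtype=float) + radius_um * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
    trace = MembraneTrace(coords=pts, island_spans=island_spans)
    truth = GroundTruth("circular_trace", {"radius_um": radius_um})
    return trace, truth


def make_crescent_cell_image(
    radius_um: float = 4.5,
    crescent_fraction: float = 0.3,
    crescent_level: float = 5.0,
    background_level: float = 1.0,
    pixel_um: float = DEFAULT_SPACING_UM,
    ring_width_um: float = 0.4,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Raster of a cell with a bright cortical crescent, plus its contour.

    Returns (image, contour polyline in µm, truth).  The cortex is a ring of
    ``ring_width_um``; a contiguous angular arc of ``crescent_fraction`` of
    the circumference is at ``crescent_level``, the rest at
    ``background_level``.  Fixture for perimeter-profile extraction.
    """
    if not 0 < crescent_fraction <= 1:
        raise ValueError("crescent_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    extent = 2 * (radius_um + 5 * ring_width_um)
    n_px = int(np.ceil(extent / pixel_um))
    c = extent / 2
    ii, jj = np.mgrid[0:n_px, 0:n_px]
    x = (jj + 0.5) * pixel_um - c
    y = (ii + 0.5) * pixel_um - c
    r = np.hypot(x, y)
    ring = np.abs(r - radius_um) <= ring_width_um / 2
    ang = np.mod(np.arctan2(y, x), 2 * np.pi)
    start = rng.uniform(0.0, 2 * np.pi)
    width = 2 * np.pi * crescent_fraction
    in_arc = np.mod(ang - start, 2 * np.pi) <= width
    img = np.zeros((n_px, n_px))
    img[ring] = background_level
    img[ring & in_arc] = crescent_level
    if noise_sd > 0:
        img = np.maximum(img + rng.normal(0.0, noise_sd, img.shape), 0.0)
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    contour = np.column_stack(
        [c + radius_um * np.cos(theta), c + radius_um * np.sin(theta)]
    )
    contour = np.vstack([contour, contour[0]])
    truth = GroundTruth(
        "crescent_cell_image",
        {
            "radius_um": radius_um,
            "crescent_fraction": crescent_fraction,
            "crescent_start_rad": start,
            "crescent_level": crescent_level,
            "background_level": background_level,
        },
    )
    return img, contour, truth
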