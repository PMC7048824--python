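"""Core geometric types for bilateral airway ducts.

A :class:`DuctGeometry` is a triangulated surface of a bilateral nasal-
cavity-like airway: two lateral ducts (left ``x < 0``, right ``x > 0``)
joined by a short shared pharynx tube, each duct discretised as a stack of
cross-sectional vertex rings along a centerline.  Station-wise profiles
(cross-sectional area, perimeter, ellipse semi-axes, centerline arc length)
are always *recomputed from the vertices*, so they stay consistent under
deformation, averaging and mirroring.

Coordinates are millimetres.  The mid-sagittal plane is ``x = 0``; the main
flow axis is ``y`` (nostril at low ``y``, choana/pharynx at high ``y``).
Cross-sections are measured in planes perpendicular to ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

SIDE_LEFT = -1
SIDE_RIGHT = 1
SIDE_SHARED = 0

SIDE_NAMES: Dict[str, int] = {"left": SIDE_LEFT, "right": SIDE_RIGHT, "shared": SIDE_SHARED}


class DegenerateRingError(ValueError):
    """A cross-sectional ring collapsed or self-intersected after deformation."""

    def __init__(self, side: str, station: int, reason: str):
        self.side = side
        self.station = station
        super().__init__(
            f"degenerate ring on side '{side}' at station {station}: {reason}"
        )


@dataclass
class SideProfile:
    """Station-wise cross-sectional profile of one duct.

    All lengths in mm, areas in mm².  ``s`` is the normalized
    nostril-to-choana distance in [0, 1]; ``arclength_mm`` is the physical
    cumulative centerline arc length (0 at the first station).
    """

    s: np.ndarray
    area_mm2: np.ndarray
    perimeter_mm: np.ndarray
    semi_axis_a_mm: np.ndarray
    semi_axis_b_mm: np.ndarray
    arclength_mm: np.ndarray
    centroids_mm: np.ndarray  # (n_stations, 3), for diagnostics

    @property
    def n_stations(self) -> int:
        return int(self.s.size)

    @property
    def length_mm(self) -> float:
        return float(self.arclength_mm[-1])

    def volume_mm3(self) -> float:
        """Duct volume by trapezoidal integration of A over arc length."""
        return float(np.trapezoid(self.area_mm2, self.arclength_mm))


@dataclass
class DuctGeometry:
    """One subject's bilateral airway surface plus per-side station profiles.

    ``side_of_vertex`` holds -1 (left), +1 (right) or 0 (shared pharynx
    tube); ``station_of_vertex`` and ``ring_index_of_vertex`` locate every
    vertex within its ring stack.  All members of a corpus share
    ``triangles``, ``patch_labels`` and these index arrays byte-for-byte;
    ``mirror_map`` is the left-right vertex symmetry permutation of the
    template (an involution).
    """

    vertices: np.ndarray  # (V, 3) float64, mm
    triangles: np.ndarray  # (T, 3) int
    patch_labels: Optional[np.ndarray] = None  # (T,) int in 1..24
    side_of_vertex: Optional[np.ndarray] = None  # (V,) int8
    station_of_vertex: Optional[np.ndarray] = None  # (V,) int
    ring_index_of_vertex: Optional[np.ndarray] = None  # (V,) int
    s_values: Optional[np.ndarray] = None  # (n_stations,) in [0, 1]
    mirror_map: Optional[np.ndarray] = None  # (V,) int involution
    profiles: Dict[str, SideProfile] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])

    @property
    def has_structure(self) -> bool:
        """True when ring/station metadata is available (flow proxy usable)."""
        return (
            self.side_of_vertex is not None
            and self.station_of_vertex is not None
            and self.ring_index_of_vertex is not None
            and self.s_values is not None
        )

    def with_vertices(self, vertices: np.ndarray, recompute: bool = True) -> "DuctGeometry":
        """Copy of this geometry with new vertex positions (shared topology)."""
        g = replace(self, vertices=np.asarray(vertices, dtype=float).copy(), profiles={})
        if recompute and g.has_structure:
            g.profiles = compute_profiles(g)
        return g

    def side_volume_mm3(self, side: str) -> float:
        return self.profiles[side].volume_mm3()

    def triangle_areas_mm2(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        e1 = v[t[:, 1]] - v[t[:, 0]]
        e2 = v[t[:, 2]] - v[t[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def ring_vertex_indices(g: DuctGeometry, side: str, station: int) -> np.ndarray:
    """Vertex indices of one ring, in angular order."""
    code = SIDE_NAMES[side]
    mask = (g.side_of_vertex == code) & (g.station_of_vertex == station)
    idx = np.nonzero(mask)[0]
    order = np.argsort(g.ring_index_of_vertex[idx])
    return idx[order]


def _fit_ring_ellipse(points: np.ndarray, side: str, station: int):
    """Semi-axes of the best-fit ellipse of one ring via second moments.

    For a ring sampled uniformly in the ellipse parameter the second-moment
    estimate is exact: with x = a·cosθ over a uniform grid, mean(x²) = a²/2.
    The ring is projected onto the plane perpendicular to the main flow
    axis (y); a 2x2 eigendecomposition handles arbitrary in-plane rotation.
    Raises :class:`DegenerateRingError` for collapsed or self-intersecting
    (non-star-shaped, multiply wound) rings.
    """
    xz = points[:, [0, 2]]
    centroid = xz.mean(axis=0)
    d = xz - centroid
    # Winding check: angles about the centroid must be strictly monotone
    # (mod 2π) with every step below π — detects flipped/self-crossing rings.
    ang = np.arctan2(d[:, 1], d[:, 0])
    steps = np.diff(np.concatenate([ang, ang[:1]]))
    steps = np.mod(steps + np.pi, 2 * np.pi) - np.pi  # wrap to (-π, π]
    if np.any(steps == 0.0):
        raise DegenerateRingError(side, station, "coincident ring vertices")
    if not (np.all(steps > 0) or np.all(steps < 0)):
        raise DegenerateRingError(side, station, "ring is not star-shaped (self-intersection)")
    if abs(float(np.sum(steps))) < np.pi:  # winding number must be ±1
        raise DegenerateRingError(side, station, "ring does not wind once around its centroid")
    cov = d.T @ d / d.shape[0]
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 0:
        raise DegenerateRingError(side, station, "non-positive cross-sectional area")
    b_ax = float(np.sqrt(2.0 * evals[0]))
    a_ax = float(np.sqrt(2.0 * evals[1]))
    return a_ax, b_ax, np.array([centroid[0], points[:, 1].mean(), centroid[1]])


def ellipse_perimeter(a: float, b: float) -> float:
    """Ellipse perimeter by Ramanujan's second approximation.

    Exact for circles; relative error < 0.05% for aspect ratios up to ~4.
    """
    h = ((a - b) / (a + b)) ** 2 if (a + b) > 0 else 0.0
    return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


def semi_axes_from_area_perimeter(area: float, perimeter: float):
    """Invert (A, P) -> ellipse semi-axes (a, b), a ≥ b.

    Used when profiles come from a CSV file rather than from rings.  Solves
    for the aspect ratio with a bracketed root find on Ramanujan's formula;
    P is clipped up to the circular lower bound P ≥ 2·sqrt(πA).
    """
    from scipy.optimize import brentq

    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    p_min = 2.0 * np.sqrt(np.pi * area)
    if perimeter <= p_min * (1.0 + 1e-12):
        r = float(np.sqrt(area / np.pi))
        return r, r

    def resid(t: float) -> float:
        a = np.sqrt(area / (np.pi * t))
        return ellipse_perimeter(a, a * t) - perimeter

    t = brentq(resid, 1e-6, 1.0, xtol=1e-15, rtol=1e-14)
    a = float(np.sqrt(area / (np.pi * t)))
    return a, a * t


def compute_profiles(g: DuctGeometry) -> Dict[str, SideProfile]:
    """Recompute per-side (and shared-pharynx) profiles from the vertices."""
    if not g.has_structure:
        raise ValueError(
            "geometry lacks ring/station structure; supply profiles explicitly "
            "(e.g. read_profiles) to use the flow proxy"
        )
    out: Dict[str, SideProfile] = {}
    for side in ("left", "right", "shared"):
        code = SIDE_NAMES[side]
        stations = np.unique(g.station_of_vertex[g.side_of_vertex == code])
        if stations.size == 0:
            continue
        n = stations.size
        a_ax = np.empty(n)
        b_ax = np.empty(n)
        cents = np.empty((n, 3))
        for k, st in enumerate(np.sort(stations)):
            idx = ring_vertex_indices(g, side, int(st))
            a_ax[k], b_ax[k], cents[k] = _fit_ring_ellipse(g.vertices[idx], side, int(st))
        area = np.pi * a_ax * b_ax
        perim = np.array([ellipse_perimeter(a, b) for a, b in zip(a_ax, b_ax)])
        arclen = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(cents, axis=0), axis=1))]
        )
        if side == "shared":
            s = np.linspace(0.0, 1.0, n)
        else:
            s = np.asarray(g.s_values, dtype=float)
        out[side] = SideProfile(
            s=s,
            area_mm2=area,
            perimeter_mm=perim,
            semi_axis_a_mm=a_ax,
            semi_axis_b_mm=b_ax,
            arclength_mm=arclen,
            centroids_mm=cents,
        )
    return out


def verify_isoperimetric(g: DuctGeometry, rtol: float = 1e-9) -> None:
    """Check P² ≥ 4πA at every station of every side (raises on violation)."""
    for side, prof in g.profiles.items():
        lhs = prof.perimeter_mm**2
        rhs = 4.0 * np.pi * prof.area_mm2
        bad = np.nonzero(lhs < rhs * (1.0 - rtol))[0]
        if bad.size:
            raise ValueError(
                f"isoperimetric inequality violated on side '{side}' at station {bad[0]}"
            )


def same_topology(a: DuctGeometry, b: DuctGeometry) -> bool:
    if a.triangles.shape != b.triangles.shape or np.any(a.triangles != b.triangles):
        return False
    if (a.patch_labels is None) != (b.patch_labels is None):
        return False
    if a.patch_labels is not None and np.any(a.patch_labels != b.patch_labels):
        return False
    return True
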