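"""Mapping wall-bound scalar fields between meshes and cross-subject stats.

Subject-specific wall fields (static pressure, wall shear stress) are
carried onto the reference (average-geometry) triangulation with a nearest-
neighbor scheme — each reference vertex takes the value of its nearest
source vertex, ties broken deterministically by the lowest source index —
and then summarised vertex-wise across subjects (mean, median, sample SD
and coefficient of variation).  The CoV is suppressed where the mean is
close to zero, since sd/mean is noise-dominated at low signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DuctGeometry

FIELD_PRESSURE = "pressure"
FIELD_WSS = "wss"

#: default CoV suppression thresholds |mean| >= eps, per field kind (Pa)
DEFAULT_COV_EPS = {FIELD_WSS: 1e-3, FIELD_PRESSURE: 1e-2}


@dataclass
class WallField:
    """One scalar wall field (Pa) on a named mesh, one vertex per value."""

    values: np.ndarray
    field_name: str = FIELD_WSS
    phase: str = "inspiration"
    mesh_ref: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("field values must be a 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.field_name == FIELD_WSS and np.any(self.values < 0):
            raise ValueError("wall shear stress values must be non-negative")


@dataclass
class VertexStats:
    """Vertex-wise cross-subject statistics on the reference triangulation."""

    mean: np.ndarray
    median: np.ndarray
    sd: np.ndarray
    cov: np.ndarray  # NaN where masked
    cov_mask: np.ndarray  # True where CoV is suppressed (|mean| < eps)
    n_subjects: int
    eps: float

    @property
    def masked_fraction(self) -> float:
        return float(self.cov_mask.mean())


def nearest_source_indices(
    source_vertices: np.ndarray, target_vertices: np.ndarray
) -> np.ndarray:
    """Index of the nearest source vertex for each target vertex.

    Exact Euclidean nearest neighbor; exact ties resolve to the lowest
    source vertex index.  A k-d tree accelerates the query; tied candidates
    are re-examined explicitly so the tie-break is deterministic.
    """
    src = np.asarray(source_vertices, dtype=float)
    tgt = np.asarray(target_vertices, dtype=float)
    if src.size == 0:
        raise ValueError("source mesh is empty")
    tree = cKDTree(src)
    dist, idx = tree.query(tgt)
    idx = idx.astype(np.int64)
    # re-resolve possible ties at (numerically) identical distance
    for t in range(tgt.shape[0]):
        cand = tree.query_ball_point(tgt[t], dist[t] * (1 + 1e-12) + 1e-300)
        if len(cand) > 1:
            d = np.linalg.norm(src[cand] - tgt[t], axis=1)
            cand = np.asarray(cand)[d <= d.min()]
            idx[t] = cand.min()
    return idx


def map_field_nearest(
    source: WallField, source_geometry: DuctGeometry, target_geometry: DuctGeometry
) -> WallField:
    """Carry a wall field onto another triangulation by nearest neighbor."""
    if source.values.size != source_geometry.n_vertices:
        raise ValueError("field length does not match the source mesh")
    idx = nearest_source_indices(source_geometry.vertices, target_geometry.vertices)
    return WallField(
        values=source.values[idx],
        field_name=source.field_name,
        phase=source.phase,
        mesh_ref=f"{source.mesh_ref}->mapped",
    )


def vertexwise_stats(
    fields: Sequence[WallField], eps: Optional[float] = None
) -> VertexStats:
    """Per-vertex mean, median, sample SD (n−1) and CoV across subjects.

    The median of an even number of subjects is the midpoint of the central
    pair.  CoV = sd/mean only where |mean| >= eps, otherwise NaN and
    flagged in ``cov_mask``.
    """
    if len(fields) < 2:
        raise ValueError("vertex-wise statistics need at least 2 fields")
    n = fields[0].values.size
    for f in fields[1:]:
        if f.values.size != n:
            raise ValueError("all fields must live on the same triangulation")
    if eps is None:
        eps = DEFAULT_COV_EPS.get(fields[0].field_name, 1e-3)
    stack = np.stack([f.values for f in fields])  # (n_subjects, V)
    mean = stack.mean(axis=0)
    median = np.median(stack, axis=0)
    sd = stack.std(axis=0, ddof=1)
    mask = np.abs(mean) < eps
    cov = np.full(n, np.nan)
    cov[~mask] = sd[~mask] / mean[~mask]
    return VertexStats(
        mean=mean,
        median=median,
        sd=sd,
        cov=cov,
        cov_mask=mask,
        n_subjects=stack.shape[0],
        eps=float(eps),
    )
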