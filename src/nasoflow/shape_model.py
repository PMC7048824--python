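"""Statistical shape model over a corresponded corpus.

PCA on the stacked vertex coordinates of point-to-point corresponded
geometries yields the average shape, orthonormal shape modes and their
variances.  Also provides the surface-distance QC metrics (one-directional
Hausdorff and mean surface distance, exact point-to-triangle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .geometry import DuctGeometry, same_topology
from .synthetic_anatomy import Corpus

logger = logging.getLogger(__name__)

#: relative (to the largest) variance threshold below which a mode counts as zero
_VARIANCE_EPS = 1e-12


@dataclass
class ShapeModel:
    """Mean shape + orthonormal displacement modes over a corresponded corpus.

    ``modes`` has shape (k, 3V): unit-norm displacement directions over the
    stacked vertex coordinates; a weight in mm scales a mode into a
    displacement.  ``variances`` (mm², non-increasing) are the PCA weight
    variances with the n−1 denominator.
    """

    mean_vertices: np.ndarray  # (V, 3) mm
    modes: np.ndarray  # (k, 3V)
    variances: np.ndarray  # (k,) mm², non-increasing
    n_samples: int
    reference: DuctGeometry  # topology/metadata carrier

    @property
    def n_modes(self) -> int:
        return int(self.variances.size)

    @property
    def total_variance(self) -> float:
        return float(self.variances.sum())

    def project(self, g: Union[DuctGeometry, np.ndarray]) -> np.ndarray:
        """Mode weights (mm) of a geometry: wₖ = modeₖ · (x − mean)."""
        v = g.vertices if isinstance(g, DuctGeometry) else np.asarray(g)
        d = v.reshape(-1) - self.mean_vertices.reshape(-1)
        return self.modes @ d


def _rigid_align(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Kabsch rotation + translation (no scaling) of one vertex set onto another."""
    mc, tc = moving.mean(axis=0), target.mean(axis=0)
    h = (moving - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (moving - mc) @ rot.T + tc


def build_ssm(
    corpus: Union[Corpus, Sequence[DuctGeometry]], align: bool = False
) -> ShapeModel:
    """PCA shape model of a corresponded corpus.

    The mean is the vertex-wise arithmetic mean; modes/variances come from
    the SVD of the centered (n × 3V) coordinate matrix with variances
    s²/(n−1).  Retaining all modes reconstructs every member exactly.  With
    ``align`` an iterative generalized rigid alignment (rotation +
    translation, no scaling) is applied before the PCA; default off, since
    generated corpora are pre-aligned.
    """
    members = list(corpus.members) if isinstance(corpus, Corpus) else list(corpus)
    if len(members) < 2:
        raise ValueError("shape model needs at least 2 members")
    ref = members[0]
    for i, m in enumerate(members[1:], start=1):
        if m.vertices.shape != ref.vertices.shape or not same_topology(ref, m):
            raise ValueError(f"member {i} does not share the corpus topology")

    coords = np.stack([m.vertices for m in members])  # (n, V, 3)
    if align:
        mean = coords.mean(axis=0)
        for _ in range(10):
            coords = np.stack([_rigid_align(c, mean) for c in coords])
            new_mean = coords.mean(axis=0)
            if np.max(np.abs(new_mean - mean)) < 1e-10:
                mean = new_mean
                break
            mean = new_mean

    n = coords.shape[0]
    x = coords.reshape(n, -1)
    mean_flat = x.mean(axis=0)
    xc = x - mean_flat
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    variances = svals**2 / (n - 1)
    # numerical-zero cutoff: relative to the leading mode and absolute
    # against round-off at the coordinate scale (identical members must
    # yield an empty mode list)
    scale = max(1.0, float(np.abs(x).max()))
    floor = (1e-10 * scale) ** 2
    if variances.size and variances[0] > floor:
        keep = variances > max(variances[0] * _VARIANCE_EPS, floor)
    else:
        keep = np.zeros(variances.size, dtype=bool)
    modes = vt[keep]
    variances = variances[keep]
    # reproducible mode orientation: largest-magnitude component positive
    for row in modes:
        i = int(np.argmax(np.abs(row)))
        if row[i] < 0:
            row *= -1.0
    return ShapeModel(
        mean_vertices=mean_flat.reshape(-1, 3),
        modes=modes,
        variances=variances,
        n_samples=n,
        reference=ref,
    )


def mean_shape(model: ShapeModel) -> DuctGeometry:
    """The average geometry: mean vertices on the reference triangulation,
    with profiles recomputed from the mean rings."""
    return model.reference.with_vertices(model.mean_vertices)


def modes_for_variance(model: ShapeModel, fraction: float) -> int:
    """Smallest k whose cumulative variance share reaches ``fraction``."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    total = model.total_variance
    if total <= 0:
        raise ValueError("model has zero total variance")
    cum = np.cumsum(model.variances) / total
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def synthesize_shape(model: ShapeModel, weights: Sequence[float]) -> DuctGeometry:
    """mean + Σ wₖ·modeₖ as a geometry (weights in mm; may be shorter than
    the mode list; all-zero weights reproduce the mean shape)."""
    w = np.asarray(weights, dtype=float)
    if w.size > model.n_modes:
        raise ValueError(
            f"{w.size} weights supplied but the model has {model.n_modes} modes"
        )
    v = model.mean_vertices.reshape(-1) + w @ model.modes[: w.size]
    return model.reference.with_vertices(v.reshape(-1, 3))


# --- surface distances (QC) ------------------------------------------------


def _point_triangle_distances(points: np.ndarray, tri_verts: np.ndarray) -> np.ndarray:
    """Min distance from each point to a set of triangles (exact, vectorized).

    ``tri_verts``: (T, 3, 3).  Projects onto each triangle plane, clamps to
    the triangle via the standard region decomposition (project onto the
    three edges when outside), and returns the per-point minimum.
    """
    a = tri_verts[:, 0]
    ab = tri_verts[:, 1] - a
    ac = tri_verts[:, 2] - a
    d_out = np.empty(points.shape[0])
    # chunk over points to bound memory at ~points_chunk x T
    chunk = max(1, int(2e7 // max(tri_verts.shape[0], 1)))
    for lo in range(0, points.shape[0], chunk):
        p = points[lo : lo + chunk]
        ap = p[:, None, :] - a[None, :, :]  # (P, T, 3)
        d1 = np.einsum("tk,ptk->pt", ab, ap)
        d2 = np.einsum("tk,ptk->pt", ac, ap)
        dot_abab = np.einsum("tk,tk->t", ab, ab)
        dot_abac = np.einsum("tk,tk->t", ab, ac)
        dot_acac = np.einsum("tk,tk->t", ac, ac)
        denom = dot_abab * dot_acac - dot_abac**2
        denom = np.where(denom <= 0, 1.0, denom)  # degenerate tri -> edge fallback
        v = (dot_acac * d1 - dot_abac * d2) / denom
        w = (dot_abab * d2 - dot_abac * d1) / denom
        v = np.clip(v, 0.0, 1.0)
        w = np.clip(w, 0.0, 1.0)
        scale = np.clip(v + w, 1.0, None)
        v, w = v / scale, w / scale
        # refine: clamped barycentric point, then also try the three edges
        cand = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
        best = np.linalg.norm(p[:, None, :] - cand, axis=2)
        for e0, e1 in ((tri_verts[:, 0], tri_verts[:, 1]),
                       (tri_verts[:, 0], tri_verts[:, 2]),
                       (tri_verts[:, 1], tri_verts[:, 2])):
            ev = e1 - e0
            t = np.einsum("tk,ptk->pt", ev, p[:, None, :] - e0[None]) / np.maximum(
                np.einsum("tk,tk->t", ev, ev), 1e-300
            )
            t = np.clip(t, 0.0, 1.0)
            proj = e0[None] + t[..., None] * ev[None]
            best = np.minimum(best, np.linalg.norm(p[:, None, :] - proj, axis=2))
        d_out[lo : lo + chunk] = best.min(axis=1)
    return d_out


def _min_distances(a: DuctGeometry, b: DuctGeometry) -> np.ndarray:
    if a.n_vertices == 0 or b.n_vertices == 0:
        raise ValueError("cannot compute surface distance to an empty mesh")
    if b.triangles is not None and b.n_triangles > 0:
        return _point_triangle_distances(a.vertices, b.vertices[b.triangles])
    # point cloud fallback: vertex-to-vertex
    from scipy.spatial import cKDTree

    return cKDTree(b.vertices).query(a.vertices)[0]


def mean_surface_distance(a: DuctGeometry, b: DuctGeometry) -> float:
    """Mean over vertices of ``a`` of the minimal distance to surface ``b`` (mm)."""
    return float(_min_distances(a, b).mean())


def hausdorff_distance(a: DuctGeometry, b: DuctGeometry) -> float:
    """One-directional Hausdorff distance (mm): the maximum over the
    vertices of ``a`` of the minimal distance to the surface of ``b``."""
    return float(_min_distances(a, b).max())


def hausdorff_distance_symmetric(a: DuctGeometry, b: DuctGeometry) -> float:
    """max(H(a→b), H(b→a)) — the symmetric variant."""
    return max(hausdorff_distance(a, b), hausdorff_distance(b, a))
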