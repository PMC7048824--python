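"""Synthetic corpora of bilateral nasal-cavity-like duct geometries.

The generator emulates the statistical structure a corresponded shape-model
corpus provides: every member shares one triangulation (point-to-point
correspondence by construction), carries 24 anatomical patch labels (12 per
cavity), shows the anterior constriction (isthmus nasi) in its
cross-sectional-area profile, and varies across subjects through a small
number of smooth ground-truth shape modes plus i.i.d. vertex noise.
Mirrored (sagittally reflected) augmentation is supported through a
precomputed left-right vertex symmetry map, so mirrored members keep the
corpus triangulation.

Shape modes act per cross-sectional ring: each mode modulates ring centroid
position and the two ellipse semi-axes smoothly along the duct.  Rings
therefore stay ellipses in planes perpendicular to the flow axis, which
keeps the vertex-wise mean of a corpus an exact member of the same family —
the regime the averaging analysis assumes.  Torsion and ring rotation are
deliberately not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .geometry import (
    SIDE_LEFT,
    SIDE_RIGHT,
    SIDE_SHARED,
    DegenerateRingError,
    DuctGeometry,
    compute_profiles,
)

logger = logging.getLogger(__name__)

#: Number of anatomical patches (12 per nasal cavity).
N_PATCHES = 24


def _symmetric_ring_table(n_ring: int):
    """cos/sin tables that are *bitwise* symmetric under x-reflection.

    Reflection maps ring index j -> (n/2 - j) mod n; the tables are
    symmetrised so cos[j'] == -cos[j] and sin[j'] == sin[j] exactly, which
    makes the template an exact fixed point of mirroring.
    """
    if n_ring % 2:
        raise ValueError("n_ring must be even (left-right symmetry map)")
    j = np.arange(n_ring)
    theta = 2.0 * np.pi * j / n_ring
    c, s = np.cos(theta), np.sin(theta)
    m = (n_ring // 2 - j) % n_ring
    c = 0.5 * (c - c[m])
    s = 0.5 * (s + s[m])
    return c, s, m


@dataclass
class DuctTemplate:
    """Baseline bilateral duct geometry and its construction parameters.

    The template realises a symmetric anatomy: a left duct, its exact
    mirror image on the right, and a small shared pharynx tube on the
    mid-sagittal plane carrying the pharynx patch labels.  ``area_profile``
    and ``ellipse_aspect_profile`` are callables of the normalized
    nostril-to-choana distance s ∈ [0, 1] returning mm² and the
    (height/width) semi-axis ratio.
    """

    n_stations: int = 21
    n_ring: int = 24
    area_profile: Callable[[np.ndarray], np.ndarray] = None
    ellipse_aspect_profile: Callable[[np.ndarray], np.ndarray] = None
    centerline_curve: Callable[[np.ndarray], np.ndarray] = None  # left side, (n,3) mm
    isthmus_position: float = 0.15
    n_pharynx_stations: int = 3
    pharynx_length_mm: float = 15.0
    pharynx_area_mm2: float = 260.0
    validate_profile: bool = True

    # built artefacts
    base: DuctGeometry = field(init=False, repr=False, default=None)

    def __post_init__(self):
        if self.n_stations < 11:
            raise ValueError("n_stations must be >= 11")
        if self.n_ring < 8:
            raise ValueError("n_ring must be >= 8")
        if self.area_profile is None or self.ellipse_aspect_profile is None:
            raise ValueError("area_profile and ellipse_aspect_profile are required")
        if self.centerline_curve is None:
            raise ValueError("centerline_curve is required")
        s_fine = np.linspace(0.0, 1.0, 501)
        a_fine = np.asarray(self.area_profile(s_fine), dtype=float)
        if np.any(a_fine <= 0):
            raise ValueError("area_profile must be strictly positive")
        if self.validate_profile:
            k = int(np.argmin(a_fine))
            if k == 0 or k == s_fine.size - 1:
                raise ValueError("area_profile must have an interior minimum (isthmus)")
            if np.count_nonzero(np.abs(a_fine - a_fine[k]) < 1e-12 * a_fine[k]) > 1:
                raise ValueError("area_profile minimum must be unique")
        self.base = self._build()

    # --- construction -------------------------------------------------

    def _build(self) -> DuctGeometry:
        ns, nr = self.n_stations, self.n_ring
        s = np.linspace(0.0, 1.0, ns)
        area = np.asarray(self.area_profile(s), dtype=float)
        aspect = np.asarray(self.ellipse_aspect_profile(s), dtype=float)
        if np.any(aspect <= 0):
            raise ValueError("ellipse_aspect_profile must be positive")
        a_x = np.sqrt(area / (np.pi * aspect))  # lateral (x) semi-axis
        b_z = a_x * aspect  # vertical (z) semi-axis
        cl = np.asarray(self.centerline_curve(s), dtype=float)  # left centerline
        if cl.shape != (ns, 3):
            raise ValueError("centerline_curve must return an (n_stations, 3) array")
        if np.any(cl[:, 0] >= 0):
            raise ValueError("left centerline must satisfy x < 0")

        cos_t, sin_t, ring_mirror = _symmetric_ring_table(nr)

        def tube(centers, ax, bz):
            n = centers.shape[0]
            pts = np.empty((n * nr, 3))
            for k in range(n):
                pts[k * nr : (k + 1) * nr, 0] = centers[k, 0] + ax[k] * cos_t
                pts[k * nr : (k + 1) * nr, 1] = centers[k, 1]
                pts[k * nr : (k + 1) * nr, 2] = centers[k, 2] + bz[k] * sin_t
            return pts

        left = tube(cl, a_x, b_z)
        right = left.copy()
        right[:, 0] = -right[:, 0]  # exact mirror

        npx = self.n_pharynx_stations
        y0 = cl[-1, 1]
        z0 = cl[-1, 2]
        px_centers = np.column_stack(
            [
                np.zeros(npx),
                y0 + np.linspace(0.0, self.pharynx_length_mm, npx + 1)[1:],
                np.full(npx, z0),
            ]
        )
        r_px = np.sqrt(self.pharynx_area_mm2 / np.pi)
        pharynx = tube(px_centers, np.full(npx, r_px), np.full(npx, r_px))

        vertices = np.vstack([left, right, pharynx])
        n_side = ns * nr

        def tube_triangles(offset, n_st):
            tris = []
            for k in range(n_st - 1):
                for j in range(nr):
                    j2 = (j + 1) % nr
                    v00 = offset + k * nr + j
                    v01 = offset + k * nr + j2
                    v10 = offset + (k + 1) * nr + j
                    v11 = offset + (k + 1) * nr + j2
                    tris.append((v00, v01, v10))
                    tris.append((v01, v11, v10))
            return tris

        tris = (
            tube_triangles(0, ns)
            + tube_triangles(n_side, ns)
            + tube_triangles(2 * n_side, npx)
        )
        triangles = np.asarray(tris, dtype=np.int64)

        # patch labels: 4 longitudinal bands x 3 angular sectors per side
        n_seg = ns - 1
        band_of_seg = np.minimum(np.arange(n_seg) * 4 // n_seg, 3)
        labels = np.empty(triangles.shape[0], dtype=np.int32)
        per_side = 2 * n_seg * nr
        for t in range(2 * per_side):
            side_block, rem = divmod(t, per_side)
            quad, _ = divmod(rem, 2)
            k, j = divmod(quad, nr)
            sector = j * 3 // nr
            labels[t] = side_block * 12 + band_of_seg[k] * 3 + sector + 1
        # pharynx tube triangles join the posterior patch of their side
        px_tris = triangles[2 * per_side :]
        px_x = vertices[px_tris].mean(axis=1)[:, 0]
        labels[2 * per_side :] = np.where(px_x < 0, 12, 24)

        side_of_vertex = np.concatenate(
            [
                np.full(n_side, SIDE_LEFT, dtype=np.int8),
                np.full(n_side, SIDE_RIGHT, dtype=np.int8),
                np.full(npx * nr, SIDE_SHARED, dtype=np.int8),
            ]
        )
        station = np.concatenate(
            [
                np.repeat(np.arange(ns), nr),
                np.repeat(np.arange(ns), nr),
                np.repeat(np.arange(npx), nr),
            ]
        )
        ring_index = np.concatenate([np.tile(np.arange(nr), 2 * ns + npx)])

        # mirror map: left(k,j) <-> right(k,j); pharynx j -> (n/2 - j) mod n
        mirror = np.empty(vertices.shape[0], dtype=np.int64)
        mirror[:n_side] = np.arange(n_side) + n_side
        mirror[n_side : 2 * n_side] = np.arange(n_side)
        base_px = 2 * n_side
        for k in range(npx):
            row = base_px + k * nr
            mirror[row + np.arange(nr)] = row + ring_mirror

        g = DuctGeometry(
            vertices=vertices,
            triangles=triangles,
            patch_labels=labels,
            side_of_vertex=side_of_vertex,
            station_of_vertex=station,
            ring_index_of_vertex=ring_index,
            s_values=s,
            mirror_map=mirror,
        )
        g.profiles = compute_profiles(g)
        return g

    @property
    def n_vertices(self) -> int:
        return self.base.n_vertices


def default_template(
    n_stations: int = 21,
    n_ring: int = 24,
    nostril_area_mm2: float = 90.0,
    isthmus_position: float = 0.15,
    cavity_length_mm: float = 70.0,
    lateral_offset_mm: float = 8.0,
) -> DuctTemplate:
    """Nasal-like default: isthmus at s=0.15 with ~55% of the nostril area,
    mid-cavity ~2x the nostril area, slit-like (tall) mid-cavity sections.

    Magnitudes are of the same order as adult nasal anatomy but are
    synthetic generator choices, not measured data.
    """
    ctrl_s = np.array([0.0, isthmus_position, 0.5, 0.8, 1.0])
    ctrl_a = nostril_area_mm2 * np.array([1.0, 0.55, 2.0, 1.8, 1.45])
    area_itp = PchipInterpolator(ctrl_s, ctrl_a)
    asp_itp = PchipInterpolator(
        np.array([0.0, isthmus_position, 0.5, 1.0]),
        np.array([1.3, 2.2, 3.5, 1.8]),
    )

    def centerline(s):
        s = np.asarray(s, dtype=float)
        return np.column_stack(
            [
                np.full(s.shape, -lateral_offset_mm),
                cavity_length_mm * s,
                6.0 * np.sin(np.pi * s),
            ]
        )

    return DuctTemplate(
        n_stations=n_stations,
        n_ring=n_ring,
        area_profile=area_itp,
        ellipse_aspect_profile=asp_itp,
        centerline_curve=centerline,
        isthmus_position=isthmus_position,
    )


def tube_template(
    radius_left_mm: float = 3.0,
    radius_right_mm: float = None,
    length_mm: float = 80.0,
    n_stations: int = 21,
    n_ring: int = 24,
) -> DuctTemplate:
    """Straight bilateral circular tube — the analytic (Poiseuille) oracle
    geometry.  The constant area profile has no isthmus, so profile
    validation is relaxed."""
    if radius_right_mm is None:
        radius_right_mm = radius_left_mm
    rl, rr = float(radius_left_mm), float(radius_right_mm)

    def area(s):
        s = np.asarray(s, dtype=float)
        return np.full(s.shape, np.pi * rl**2)

    def aspect(s):
        s = np.asarray(s, dtype=float)
        return np.ones(s.shape)

    def centerline(s):
        s = np.asarray(s, dtype=float)
        off = max(3.0 * max(rl, rr), 6.0)
        return np.column_stack([np.full(s.shape, -off), length_mm * s, np.zeros(s.shape)])

    t = DuctTemplate(
        n_stations=n_stations,
        n_ring=n_ring,
        area_profile=area,
        ellipse_aspect_profile=aspect,
        centerline_curve=centerline,
        validate_profile=False,
        pharynx_area_mm2=np.pi * (rl**2 + rr**2),
    )
    if rr != rl:
        # scale the right tube's rings about their centroids
        g = t.base
        right = g.side_of_vertex == SIDE_RIGHT
        v = g.vertices.copy()
        for st in range(n_stations):
            idx = np.nonzero(right & (g.station_of_vertex == st))[0]
            c = v[idx].mean(axis=0)
            v[idx] = c + (v[idx] - c) * (rr / rl)
        t.base = g.with_vertices(v)
    return t


@dataclass
class ShapeVariationSpec:
    """Ground-truth low-rank shape variation for a synthetic corpus.

    ``mode_fields`` are orthonormal (after removal of their net
    translation) per-vertex displacement directions; ``mode_sd`` are the
    strictly decreasing standard deviations of the corresponding mode
    weights in mm.  ``standardize_weights`` makes a finite corpus realise
    the prescribed mode variances exactly (empirical whitening of the drawn
    weight matrix), so shape-model recovery checks are deterministic; raw
    sampling is available by switching it off.
    """

    n_true_modes: int
    mode_fields: np.ndarray  # (k, V, 3)
    mode_sd: np.ndarray  # (k,) mm, strictly decreasing
    noise_sd: float
    seed: int
    standardize_weights: bool = True

    def __post_init__(self):
        self.mode_sd = np.asarray(self.mode_sd, dtype=float)
        if self.n_true_modes != self.mode_sd.size:
            raise ValueError("mode_sd length must equal n_true_modes")
        if self.n_true_modes and np.any(np.diff(self.mode_sd) >= 0):
            raise ValueError("mode_sd must be strictly decreasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        k = self.n_true_modes
        if k:
            flat = self.mode_fields.reshape(k, -1)
            gram = flat @ flat.T
            if not np.allclose(gram, np.eye(k), atol=1e-8):
                raise ValueError("mode_fields must be orthonormal")


def random_smooth_modes(
    template: DuctTemplate,
    n_modes: int,
    seed: int,
    include_centroid: bool = True,
    bilateral_symmetric: bool = False,
) -> np.ndarray:
    """Smooth random per-ring-affine displacement fields, orthonormalised.

    Each raw mode perturbs, per side and smoothly in s (low-order cosine
    series), the ring centroid (3 dof) and the two ellipse semi-axes; with
    ``include_centroid=False`` only the semi-axes vary, so every member of
    a noise-free corpus keeps the template centerline — the regime in which
    the mean-geometry resistance bound is a strict convexity theorem rather
    than a statistical tendency.  The shared pharynx tube is left
    undeformed (fixed outlet).  Net translation is removed, then the
    stacked fields are orthonormalised by QR.

    With ``bilateral_symmetric`` each mode applies the *same* section
    modulation to both sides (mirror-equivariant fields), so every sampled
    subject is itself left-right symmetric — the variation regime in which
    averaging provably cannot raise the bilateral total resistance.
    """
    g = template.base
    V = g.n_vertices
    rng = np.random.default_rng(seed)
    cos_t, sin_t, _ = _symmetric_ring_table(template.n_ring)
    s = np.asarray(g.s_values)
    n_harm = 4
    basis = np.stack([np.cos(m * np.pi * s) for m in range(n_harm)])  # (H, ns)

    fields = np.zeros((n_modes, V, 3))
    for m in range(n_modes):
        fld = np.zeros((V, 3))
        per_side = {}
        for side_code in (SIDE_LEFT, SIDE_RIGHT):
            if bilateral_symmetric and side_code == SIDE_RIGHT:
                continue
            coef = rng.normal(size=(5, n_harm))  # cx, cy, cz, da, db
            if not include_centroid:
                coef[:3] = 0.0
            prof = coef @ basis  # (5, ns)
            vmask = g.side_of_vertex == side_code
            st = g.station_of_vertex[vmask]
            rj = g.ring_index_of_vertex[vmask]
            disp = np.column_stack(
                [
                    prof[0, st] + prof[3, st] * cos_t[rj],
                    prof[1, st],
                    prof[2, st] + prof[4, st] * sin_t[rj],
                ]
            )
            fld[vmask] = disp
            per_side[side_code] = disp
        if bilateral_symmetric:
            # right displacement = mirror image of the left displacement at
            # the corresponding (station, ring) vertex: sampled subjects are
            # themselves left-right symmetric
            right = g.side_of_vertex == SIDE_RIGHT
            disp = per_side[SIDE_LEFT].copy()
            disp[:, 0] = -disp[:, 0]
            fld[right] = disp
        fields[m] = fld

    flat = fields.reshape(n_modes, -1)
    flat -= flat.reshape(n_modes, V, 3).mean(axis=1).repeat(V, axis=0).reshape(n_modes, -1)
    q, r = np.linalg.qr(flat.T)
    q = q * np.sign(np.diag(r))  # deterministic orientation
    return np.ascontiguousarray(q.T.reshape(n_modes, V, 3))


#: default RMS surface displacement (mm) of each ground-truth mode
DEFAULT_MODE_RMS_MM = (0.8, 0.5, 0.3, 0.2, 0.13)


def default_variation_spec(
    template: DuctTemplate,
    n_modes: int = 3,
    mode_sd: Optional[Sequence[float]] = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    standardize_weights: bool = True,
    centroid_variation: bool = True,
    bilateral_symmetric: bool = False,
) -> ShapeVariationSpec:
    """Default study conditions: 3 smooth modes whose weight SDs correspond
    to sub-millimetre RMS surface displacements (0.8/0.5/0.3 mm — visible
    inter-subject variation that keeps the narrow isthmus sections valid),
    plus 0.05 mm vertex noise, of the order of a sub-voxel segmentation
    residual.  Because the mode fields are unit-norm over all vertices, the
    weight SD realising an RMS displacement r is r·sqrt(V); extra modes
    beyond the tabulated RMS values continue the geometric decay."""
    if mode_sd is None:
        rms = [
            DEFAULT_MODE_RMS_MM[i]
            if i < len(DEFAULT_MODE_RMS_MM)
            else DEFAULT_MODE_RMS_MM[-1] * 0.65 ** (i - len(DEFAULT_MODE_RMS_MM) + 1)
            for i in range(n_modes)
        ]
        mode_sd = [r * np.sqrt(template.n_vertices) for r in rms]
    fields = random_smooth_modes(
        template, n_modes, seed, centroid_variation, bilateral_symmetric
    )
    return ShapeVariationSpec(
        n_true_modes=n_modes,
        mode_fields=fields,
        mode_sd=np.asarray(mode_sd, dtype=float),
        noise_sd=noise_sd,
        seed=seed,
        standardize_weights=standardize_weights,
    )


def section_variation_spec(
    template: DuctTemplate, n_modes: int = 2, seed: int = 0, **kwargs
) -> ShapeVariationSpec:
    """Bilaterally symmetric, pure cross-sectional variation, noise-free by
    default: all members share the template centerline and are left-right
    symmetric, so the average geometry's total resistance is bounded above
    by the cohort mean total resistance as a strict convexity (Jensen)
    theorem whenever the shape variance is nonzero.  (With asymmetric or
    centerline variation the bound holds as a strong statistical tendency
    but not surely; see the methods note.)"""
    kwargs.setdefault("noise_sd", 0.0)
    kwargs.setdefault("bilateral_symmetric", True)
    return default_variation_spec(
        template, n_modes=n_modes, seed=seed, centroid_variation=False, **kwargs
    )


@dataclass
class Corpus:
    """An ordered corpus of corresponded duct geometries."""

    members: List[DuctGeometry]
    mirrored_flag: np.ndarray  # (N,) bool
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def originals(self) -> List[DuctGeometry]:
        return [m for m, f in zip(self.members, self.mirrored_flag) if not f]


def _subject_rng(spec: ShapeVariationSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng((int(spec.seed) + int(subject_index)) % 2**31)


def _draw_weights_and_noise(template, spec, subject_index):
    rng = _subject_rng(spec, subject_index)
    w = rng.normal(0.0, spec.mode_sd) if spec.n_true_modes else np.zeros(0)
    noise = np.zeros((template.n_vertices, 3))
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=noise.shape)
        noise[template.base.side_of_vertex == SIDE_SHARED] = 0.0
    return w, noise


def _realize(template: DuctTemplate, spec: ShapeVariationSpec, w, noise) -> DuctGeometry:
    v = template.base.vertices.copy()
    if spec.n_true_modes:
        v = v + np.tensordot(w, spec.mode_fields, axes=1)
    v = v + noise
    return template.base.with_vertices(v)


def generate_subject(
    template: DuctTemplate, spec: ShapeVariationSpec, subject_index: int
) -> DuctGeometry:
    """One synthetic subject: template + Σ wₖ·modeₖ + noise.

    Deterministic given (spec.seed, subject_index); mode weights are drawn
    raw (per-corpus weight standardisation happens in
    :func:`generate_corpus`).  Raises :class:`DegenerateRingError` naming
    the offending station if the deformation collapses a ring; reduce
    ``mode_sd`` in that case.
    """
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    w, noise = _draw_weights_and_noise(template, spec, subject_index)
    return _realize(template, spec, w, noise)


def generate_corpus(
    template: DuctTemplate, spec: ShapeVariationSpec, n_subjects: int
) -> Corpus:
    """A corpus of ``n_subjects`` un-mirrored members sharing one topology.

    With ``spec.standardize_weights`` (default) the drawn weight matrix is
    centered, orthogonalised across modes and rescaled so the sample
    covariance of the weights is exactly diag(mode_sd²) — the generated
    corpus then realises the specified variance structure exactly.  Falls
    back to raw draws (with a log note) when n_subjects ≤ n_true_modes.
    """
    if n_subjects < 2:
        raise ValueError("a shape-model corpus needs at least 2 subjects")
    k = spec.n_true_modes
    draws = [_draw_weights_and_noise(template, spec, i) for i in range(n_subjects)]
    W = np.stack([d[0] for d in draws]) if k else np.zeros((n_subjects, 0))
    if k and spec.standardize_weights:
        if n_subjects - 1 < k:
            logger.info(
                "corpus too small to standardize %d mode weights; using raw draws", k
            )
        else:
            Wc = W - W.mean(axis=0)
            q, r = np.linalg.qr(Wc)
            q = q * np.sign(np.diag(r))
            W = q * (np.sqrt(n_subjects - 1) * spec.mode_sd)
    members = [
        _realize(template, spec, W[i], draws[i][1]) for i in range(n_subjects)
    ]
    prov = {
        "n_subjects": n_subjects,
        "seed": int(spec.seed),
        "n_true_modes": k,
        "mode_sd": [float(x) for x in spec.mode_sd],
        "noise_sd": float(spec.noise_sd),
        "standardize_weights": bool(spec.standardize_weights),
        "n_stations": template.n_stations,
        "n_ring": template.n_ring,
    }
    return Corpus(
        members=members,
        mirrored_flag=np.zeros(n_subjects, dtype=bool),
        provenance=prov,
    )


def mirror_subject(g: DuctGeometry) -> DuctGeometry:
    """Sagittal reflection (x -> -x) with left-right vertex re-indexing.

    The permutation keeps the corpus triangulation and patch semantics
    (left patches become the reflected right anatomy).  An involution:
    ``mirror_subject(mirror_subject(g))`` returns the original exactly.
    """
    if g.mirror_map is None:
        raise ValueError("geometry has no left-right symmetry map; cannot mirror")
    v = g.vertices[g.mirror_map].copy()
    v[:, 0] = -v[:, 0]
    return g.with_vertices(v)


def mirror_augment(c: Corpus) -> Corpus:
    """Virtually enhance a corpus: each original followed by its mirror."""
    if np.any(c.mirrored_flag):
        raise ValueError("corpus already contains mirrored members")
    members: List[DuctGeometry] = []
    flags: List[bool] = []
    for m in c.members:
        members.append(m)
        flags.append(False)
        members.append(mirror_subject(m))
        flags.append(True)
    prov = dict(c.provenance)
    prov["mirror_augmented"] = True
    return Corpus(members=members, mirrored_flag=np.asarray(flags), provenance=prov)
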