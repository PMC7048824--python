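"""Integral aerodynamic measures, profiles, histograms and cohort summaries.

Answers the pipeline's central question — does the average geometry carry
the average airflow? — by reducing every subject's flow solution to a small
set of integral measures (lateral/total resistance, airflow partitioning,
volume-averaged and 99.9th-percentile velocity, surface-averaged and
99.9th-percentile wall shear stress), profiling cross-sectional areas along
the normalized nostril-to-choana axis, binning wall shear stress by the
surface area it affects, and placing the average-geometry values within the
cohort distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import DuctGeometry
from .flow_proxy import FlowSolution, total_resistance
from .field_mapping import VertexStats

#: Default WSS histogram bin edges (Pa).  Only the first bin, (0, 0.01], is
#: a fixed convention; the remaining edges span the restful-breathing WSS
#: range and are fully configurable.
DEFAULT_WSS_BIN_EDGES = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, np.inf)

#: printed precisions of the report tables
ROUND_RESISTANCE = 3
ROUND_VELOCITY = 2
ROUND_WSS = 2


def report_round(x: float, decimals: int) -> float:
    """Table rounding: round-half-even on the decimal value.

    Works on the shortest decimal representation and first quantizes six
    extra digits away so binary float noise cannot tip a tie (0.0155 ->
    0.016 and 0.0205 -> 0.020 at 3 decimals, where naive ``round`` on the
    underlying binary doubles does not)."""
    from decimal import ROUND_HALF_EVEN, Decimal

    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal(1).scaleb(-(decimals + 6)), rounding=ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_EVEN))


@dataclass
class IntegralMeasures:
    """Integral aerodynamic measures for one subject and one phase."""

    phase: str
    r_left: float  # Pa·s/ml
    r_right: float
    r_total: float
    ap_pct: float  # left share of bilateral flow, %
    u_avg_ms: float  # volume-averaged velocity
    u_p999_ms: float  # 99.9th percentile (volume-weighted)
    u_max_ms: float  # true maximum station velocity
    wss_avg_pa: float  # area-weighted mean wall shear stress
    wss_p999_pa: float  # 99.9th percentile (area-weighted)
    wss_max_pa: float


def weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Percentile by linear interpolation on the weighted empirical CDF.

    The CDF is evaluated at the sorted sample values with cumulative weight
    fractions; q in [0, 100].
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cdf = np.cumsum(w) / w.sum()
    return float(np.interp(q / 100.0, cdf, v))


def _station_volume_weights(g: DuctGeometry, side: str) -> np.ndarray:
    """Trapezoidal volume weight A·Δℓ of each station (mm³)."""
    prof = g.profiles[side]
    ell = prof.arclength_mm
    w = np.zeros(ell.size)
    w[:-1] += 0.5 * np.diff(ell)
    w[1:] += 0.5 * np.diff(ell)
    return prof.area_mm2 * w


def integral_measures(g: DuctGeometry, sol: FlowSolution) -> IntegralMeasures:
    """Reduce one flow solution to its integral measures.

    Velocities are station means u(s) = Q/A weighted by station volume
    A·Δℓ over both sides; WSS statistics are area-weighted over wall
    triangles (triangle value = mean of its vertex values).
    """
    if sol.wall_shear_stress_pa is None:
        raise ValueError("flow solution lacks wall fields")
    r_l = sol.dp_pa / sol.q_left_mls
    r_r = sol.dp_pa / sol.q_right_mls
    u = np.concatenate([sol.station_velocity_ms["left"], sol.station_velocity_ms["right"]])
    w_u = np.concatenate(
        [_station_volume_weights(g, "left"), _station_volume_weights(g, "right")]
    )
    tri_wss = sol.wall_shear_stress_pa[g.triangles].mean(axis=1)
    tri_area = g.triangle_areas_mm2()
    return IntegralMeasures(
        phase=sol.phase.label,
        r_left=r_l,
        r_right=r_r,
        r_total=total_resistance(r_l, r_r),
        ap_pct=sol.airflow_partitioning_pct,
        u_avg_ms=float(np.sum(u * w_u) / np.sum(w_u)),
        u_p999_ms=weighted_percentile(u, w_u, 99.9),
        u_max_ms=float(u.max()),
        wss_avg_pa=float(np.sum(tri_wss * tri_area) / np.sum(tri_area)),
        wss_p999_pa=weighted_percentile(tri_wss, tri_area, 99.9),
        wss_max_pa=float(tri_wss.max()),
    )


@dataclass
class CsaProfile:
    """Cross-sectional areas along the normalized nostril-to-choana axis."""

    s_grid: np.ndarray  # 5% increments, 0..1
    area_mm2: Dict[str, np.ndarray]  # per side
    min_csa_mm2: Dict[str, float]  # minimum over the fine station grid
    min_csa_s: Dict[str, float]


def csa_profile(g: DuctGeometry, increment: float = 0.05) -> CsaProfile:
    """Per-side CSA at each 5% increment (linear interpolation of A(s));
    the minimum is taken over the full station grid, not the 5% grid."""
    n = int(round(1.0 / increment)) + 1
    grid = np.linspace(0.0, 1.0, n)
    areas, mins, locs = {}, {}, {}
    for side in ("left", "right"):
        prof = g.profiles[side]
        areas[side] = np.interp(grid, prof.s, prof.area_mm2)
        k = int(np.argmin(prof.area_mm2))
        mins[side] = float(prof.area_mm2[k])
        locs[side] = float(prof.s[k])
    return CsaProfile(s_grid=grid, area_mm2=areas, min_csa_mm2=mins, min_csa_s=locs)


@dataclass
class SurfaceHistogram:
    """Share of wall surface area affected by each WSS band."""

    bin_edges: np.ndarray  # Pa, first bin (0, 0.01] by default
    area_fraction_pct: np.ndarray  # sums to 100 for strictly positive fields


def wss_histogram(
    wss_values: np.ndarray,
    g: DuctGeometry,
    bin_edges: Sequence[float] = DEFAULT_WSS_BIN_EDGES,
) -> SurfaceHistogram:
    """Area-weighted WSS histogram over wall triangles.

    Each triangle carries the mean of its vertex WSS values and the full
    triangle area; fractions are percentages of the total wall area.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    tri_vals = np.asarray(wss_values, dtype=float)[g.triangles].mean(axis=1)
    tri_area = g.triangle_areas_mm2()
    # half-open on the left, closed on the right: (e0, e1], (e1, e2], ...
    which = np.searchsorted(edges, tri_vals, side="left") - 1
    frac = np.zeros(edges.size - 1)
    valid = (which >= 0) & (which < frac.size)
    np.add.at(frac, which[valid], tri_area[valid])
    return SurfaceHistogram(
        bin_edges=edges, area_fraction_pct=100.0 * frac / tri_area.sum()
    )


@dataclass
class MeasureSummary:
    """Cohort statistics of one measure plus the average-geometry reading."""

    mean: float
    median: float
    sd: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    avg_geometry: float
    avg_below_median: bool
    avg_within_iqr: bool


@dataclass
class CorpusSummary:
    """Cohort mean/median/SD (and Tukey boxplot stats) per measure and the
    average-geometry value, for one breathing phase."""

    phase: str
    n_subjects: int
    measures: Dict[str, MeasureSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {k: asdict(v) for k, v in self.measures.items()}
        df = pd.DataFrame(rows).T
        df.index.name = "measure"
        return df


_MEASURE_KEYS = (
    "r_left", "r_right", "r_total", "ap_pct",
    "u_avg_ms", "u_p999_ms", "u_max_ms",
    "wss_avg_pa", "wss_p999_pa", "wss_max_pa",
)


def _tukey(vals: np.ndarray) -> Tuple[float, float, float, float]:
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo = vals[vals >= q1 - 1.5 * iqr].min()
    hi = vals[vals <= q3 + 1.5 * iqr].max()
    return float(q1), float(q3), float(lo), float(hi)


def corpus_summary(
    measures: Sequence[IntegralMeasures], avg_geom: IntegralMeasures
) -> CorpusSummary:
    """Summarise per-subject integral measures against the average geometry."""
    if len(measures) < 2:
        raise ValueError("cohort summary needs at least 2 subjects")
    phase = measures[0].phase
    for m in measures[1:]:
        if m.phase != phase:
            raise ValueError("mixed breathing phases in cohort summary")
    if avg_geom.phase != phase:
        raise ValueError("average-geometry phase does not match the cohort")
    out = CorpusSummary(phase=phase, n_subjects=len(measures))
    for key in _MEASURE_KEYS:
        vals = np.asarray([getattr(m, key) for m in measures], dtype=float)
        q1, q3, lo, hi = _tukey(vals)
        av = float(getattr(avg_geom, key))
        med = float(np.median(vals))
        out.measures[key] = MeasureSummary(
            mean=float(vals.mean()),
            median=med,
            sd=float(vals.std(ddof=1)),
            q1=q1,
            q3=q3,
            whisker_low=lo,
            whisker_high=hi,
            avg_geometry=av,
            avg_below_median=bool(av < med),
            avg_within_iqr=bool(q1 <= av <= q3),
        )
    return out


@dataclass
class ExpirationRatio:
    """Percent increase of expiration over inspiration total resistance."""

    cohort_mean_pct: float  # mean over subjects of (R_exp/R_insp − 1)·100
    cohort_median_pct: float  # median of the same per-subject ratios
    avg_geometry_pct: float
    per_subject_pct: np.ndarray


def expiration_ratio(
    insp: Sequence[IntegralMeasures],
    exp: Sequence[IntegralMeasures],
    avg_insp: IntegralMeasures,
    avg_exp: IntegralMeasures,
) -> ExpirationRatio:
    """Expiration/inspiration total-resistance asymmetry, from unrounded
    resistances.  Reported both as the mean and the median of the
    per-subject ratios (the two are not interchangeable for skewed
    cohorts); the average-geometry value comes from its own pair."""
    if len(insp) != len(exp):
        raise ValueError("phase lists differ in length")
    r_i = np.asarray([m.r_total for m in insp])
    r_e = np.asarray([m.r_total for m in exp])
    if np.any(r_i <= 0):
        raise ValueError("zero inspiration resistance")
    per = (r_e / r_i - 1.0) * 100.0
    return ExpirationRatio(
        cohort_mean_pct=float(per.mean()),
        cohort_median_pct=float(np.median(per)),
        avg_geometry_pct=float((avg_exp.r_total / avg_insp.r_total - 1.0) * 100.0),
        per_subject_pct=per,
    )


def round_for_report(summary: CorpusSummary) -> pd.DataFrame:
    """Report-table rounding: resistances to 3 decimals, velocities and WSS
    to 2, airflow partitioning to 1."""
    df = summary.to_frame()
    num = df.columns.drop(["avg_below_median", "avg_within_iqr"])
    for key in df.index:
        if key.startswith("r_"):
            dec = ROUND_RESISTANCE
        elif key.startswith("u_"):
            dec = ROUND_VELOCITY
        elif key.startswith("wss_"):
            dec = ROUND_WSS
        else:
            dec = 1
        df.loc[key, num] = [report_round(v, dec) for v in df.loc[key, num].astype(float)]
    return df


def comparison_report(
    cohort_insp: Sequence[IntegralMeasures],
    cohort_exp: Sequence[IntegralMeasures],
    avg_insp: IntegralMeasures,
    avg_exp: IntegralMeasures,
    cohort_csa: Sequence[CsaProfile],
    avg_csa: CsaProfile,
    field_stats: Dict[str, VertexStats],
    avg_fields: Dict[str, np.ndarray],
    histograms: Optional[Dict[str, SurfaceHistogram]] = None,
) -> dict:
    """Assemble the average-geometry-vs-cohort comparison bundle.

    Returns a dict with Table-1-style frames per phase, CSA boxplot data
    per 5% increment with the average-geometry curve, vertex-wise
    cohort-vs-average field differences, WSS histogram tables and a
    verdict block placing each average-geometry measure within the cohort
    distribution.  Writing to disk is handled by :mod:`nasoflow.io`.
    """
    missing = [
        name
        for name, val in (
            ("cohort inspiration measures", cohort_insp),
            ("cohort expiration measures", cohort_exp),
            ("cohort CSA profiles", cohort_csa),
        )
        if not len(val)
    ]
    if missing:
        raise ValueError("incomplete report inputs: " + ", ".join(missing))
    summaries = {
        "inspiration": corpus_summary(cohort_insp, avg_insp),
        "expiration": corpus_summary(cohort_exp, avg_exp),
    }
    ratio = expiration_ratio(cohort_insp, cohort_exp, avg_insp, avg_exp)

    # CSA boxplot data per 5% increment, pooled over sides (the per-side
    # curves of the average geometry ride alongside)
    grid = avg_csa.s_grid
    pooled = np.stack(
        [np.concatenate([c.area_mm2["left"], c.area_mm2["right"]]) for c in cohort_csa]
    )  # (n_subjects, 2 * n_grid)
    n_grid = grid.size
    csa_rows = []
    for i, s in enumerate(grid):
        vals = np.concatenate([pooled[:, i], pooled[:, n_grid + i]])
        q1, q3, lo, hi = _tukey(vals)
        csa_rows.append(
            {
                "s": float(s),
                "median": float(np.median(vals)),
                "q1": q1,
                "q3": q3,
                "whisker_low": lo,
                "whisker_high": hi,
                "avg_geometry_left": float(avg_csa.area_mm2["left"][i]),
                "avg_geometry_right": float(avg_csa.area_mm2["right"][i]),
            }
        )
    csa_table = pd.DataFrame(csa_rows)

    field_tables = {}
    for name, stats in field_stats.items():
        avg_vals = np.asarray(avg_fields[name], dtype=float)
        field_tables[name] = pd.DataFrame(
            {
                "vertex_id": np.arange(stats.mean.size),
                "cohort_mean": stats.mean,
                "cohort_median": stats.median,
                "cohort_sd": stats.sd,
                "cohort_cov": stats.cov,
                "cov_masked": stats.cov_mask,
                "avg_geometry": avg_vals,
                "diff_mean_minus_avg": stats.mean - avg_vals,
                "diff_median_minus_avg": stats.median - avg_vals,
            }
        )

    verdict = {
        "n_subjects": summaries["inspiration"].n_subjects,
        "phases": {},
        "expiration_over_inspiration_pct": {
            "cohort_mean": ratio.cohort_mean_pct,
            "cohort_median": ratio.cohort_median_pct,
            "average_geometry": ratio.avg_geometry_pct,
        },
    }
    for phase, summ in summaries.items():
        verdict["phases"][phase] = {
            key: {
                "average_geometry": ms.avg_geometry,
                "cohort_mean": ms.mean,
                "cohort_median": ms.median,
                "cohort_sd": ms.sd,
                "below_median": ms.avg_below_median,
                "within_iqr": ms.avg_within_iqr,
            }
            for key, ms in summ.measures.items()
        }
    verdict["average_r_total_below_cohort_mean"] = {
        phase: bool(
            summaries[phase].measures["r_total"].avg_geometry
            <= summaries[phase].measures["r_total"].mean
        )
        for phase in summaries
    }

    return {
        "summaries": summaries,
        "tables": {phase: round_for_report(s) for phase, s in summaries.items()},
        "expiration_ratio": ratio,
        "csa_table": csa_table,
        "field_tables": field_tables,
        "histograms": histograms or {},
        "verdict": verdict,
    }
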