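"""File formats, run configuration and the end-to-end pipeline.

Meshes travel as PLY (per-triangle patch labels and the ring/station
structure stored as integer attributes, full-precision coordinates as
float64 vertex attributes so binary round-trips are bit-exact); STL and OFF
load read-only with a logged warning that labels and stations are absent.
Profiles, wall fields and report tables are plain CSV; configuration is a
schema-versioned YAML mapping with unknown keys rejected; every output
bundle carries its resolved configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import __version__ as _pkg_version
from .geometry import (
    DuctGeometry,
    SideProfile,
    compute_profiles,
    semi_axes_from_area_perimeter,
)
from .synthetic_anatomy import (
    Corpus,
    default_template,
    default_variation_spec,
    generate_corpus,
    mirror_augment,
)
from .shape_model import ShapeModel, build_ssm, mean_shape
from .flow_proxy import FluidProperties, simulate_phases
from .field_mapping import (
    DEFAULT_COV_EPS,
    FIELD_PRESSURE,
    FIELD_WSS,
    WallField,
    map_field_nearest,
    vertexwise_stats,
)
from .metrics import (
    DEFAULT_WSS_BIN_EDGES,
    comparison_report,
    csa_profile,
    integral_measures,
    wss_histogram,
)

logger = logging.getLogger(__name__)

_STRUCT_VERTEX_ATTRS = ("side", "station", "ring", "mirror")


# --- meshes ----------------------------------------------------------------


def write_mesh(g: DuctGeometry, path: Union[str, Path], binary: bool = True) -> Path:
    """Write a geometry as PLY (labels + structure as attributes) or STL/OFF.

    STL/OFF drop patch labels and ring structure — logged as a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    mesh = trimesh.Trimesh(g.vertices.copy(), g.triangles.copy(), process=False)
    if suffix == ".ply":
        # float64 shadow coordinates: PLY x/y/z are float32 in trimesh
        for i, name in enumerate(("xd", "yd", "zd")):
            mesh.vertex_attributes[name] = g.vertices[:, i].astype(np.float64)
        if g.has_structure:
            mesh.vertex_attributes["side"] = g.side_of_vertex.astype(np.int32)
            mesh.vertex_attributes["station"] = g.station_of_vertex.astype(np.int32)
            mesh.vertex_attributes["ring"] = g.ring_index_of_vertex.astype(np.int32)
        if g.mirror_map is not None:
            mesh.vertex_attributes["mirror"] = g.mirror_map.astype(np.int32)
        if g.patch_labels is not None:
            mesh.face_attributes["patch"] = g.patch_labels.astype(np.int32)
        data = trimesh.exchange.ply.export_ply(
            mesh,
            encoding="binary_little_endian" if binary else "ascii",
            include_attributes=True,
        )
        path.write_bytes(data)
        if g.has_structure and g.s_values is not None:
            sidecar = {"s_values": [float(v) for v in g.s_values]}
            path.with_suffix(".json").write_text(json.dumps(sidecar))
    elif suffix in (".stl", ".off"):
        logger.warning(
            "[io] %s export drops patch labels and ring structure", suffix[1:].upper()
        )
        mesh.export(path)
    else:
        raise ValueError(f"unsupported mesh format: {suffix!r}")
    return path


def read_mesh(path: Union[str, Path]) -> DuctGeometry:
    """Read PLY/STL/OFF into a :class:`DuctGeometry`.

    PLY files written by :func:`write_mesh` restore labels, structure and
    full-precision coordinates; foreign PLY/STL/OFF meshes come back as
    surface-only geometries (usable for mapping, distances and histograms,
    but the flow proxy additionally needs profiles, e.g. via
    :func:`read_profiles`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix not in (".ply", ".stl", ".off"):
        raise ValueError(f"unsupported mesh format: {suffix!r}")
    try:
        if suffix == ".ply":
            with open(path, "rb") as fh:
                raw = trimesh.exchange.ply.load_ply(fh)
        else:
            mesh = trimesh.load(str(path), process=False, force="mesh")
            logger.warning(
                "[io] %s has no patch labels or ring structure; flow proxy "
                "unavailable unless profiles are supplied", path.name
            )
            return DuctGeometry(
                vertices=np.asarray(mesh.vertices, dtype=float),
                triangles=np.asarray(mesh.faces, dtype=np.int64),
            )
    except Exception as exc:  # unreadable/corrupt file
        raise ValueError(f"cannot read mesh {path}: {exc}") from exc

    vertices = np.asarray(raw["vertices"], dtype=float)
    triangles = np.asarray(raw["faces"], dtype=np.int64)
    if triangles.size == 0 or vertices.size == 0:
        raise ValueError(f"degenerate mesh in {path}: no vertices or faces")
    vdata = raw.get("metadata", {}).get("_ply_raw", {}).get("vertex", {}).get("data", {})
    fdata = raw.get("metadata", {}).get("_ply_raw", {}).get("face", {}).get("data", {})

    def _col(data, name):
        # trimesh hands back a dict of columns (ascii) or a structured
        # array (binary)
        if isinstance(data, dict):
            col = data.get(name)
        elif getattr(data, "dtype", None) is not None and data.dtype.names:
            col = data[name] if name in data.dtype.names else None
        else:
            col = None
        return None if col is None else np.asarray(col).reshape(-1)

    def vcol(name):
        return _col(vdata, name)

    xd, yd, zd = vcol("xd"), vcol("yd"), vcol("zd")
    if xd is not None and yd is not None and zd is not None:
        vertices = np.column_stack([xd, yd, zd]).astype(np.float64)

    g = DuctGeometry(vertices=vertices, triangles=triangles)
    patch = _col(fdata, "patch")
    if patch is not None:
        g.patch_labels = patch.astype(np.int32)
    struct = {name: vcol(name) for name in _STRUCT_VERTEX_ATTRS}
    if all(struct[n] is not None for n in ("side", "station", "ring")):
        g.side_of_vertex = struct["side"].astype(np.int8)
        g.station_of_vertex = struct["station"].astype(np.int64)
        g.ring_index_of_vertex = struct["ring"].astype(np.int64)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            g.s_values = np.asarray(
                json.loads(sidecar.read_text())["s_values"], dtype=float
            )
        else:
            n_st = int(g.station_of_vertex[g.side_of_vertex != 0].max()) + 1
            g.s_values = np.linspace(0.0, 1.0, n_st)
        if struct["mirror"] is not None:
            g.mirror_map = struct["mirror"].astype(np.int64)
        g.profiles = compute_profiles(g)
    return g


# --- profiles --------------------------------------------------------------


def write_profiles(g: DuctGeometry, path: Union[str, Path]) -> Path:
    """Station profiles as CSV: side, station, s, area_mm2, perimeter_mm,
    arclength_mm (the physical arc length column carries the duct length
    the flow integration needs)."""
    rows = []
    for side, prof in g.profiles.items():
        for k in range(prof.n_stations):
            rows.append(
                {
                    "side": side,
                    "station": k,
                    "s": prof.s[k],
                    "area_mm2": prof.area_mm2[k],
                    "perimeter_mm": prof.perimeter_mm[k],
                    "arclength_mm": prof.arclength_mm[k],
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def read_profiles(path: Union[str, Path]) -> Dict[str, SideProfile]:
    """Read a profiles CSV back into per-side :class:`SideProfile` objects;
    ellipse semi-axes are recovered from (area, perimeter)."""
    df = pd.read_csv(path)
    required = {"side", "station", "s", "area_mm2", "perimeter_mm", "arclength_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profiles CSV missing columns: {sorted(missing)}")
    out: Dict[str, SideProfile] = {}
    for side, grp in df.groupby("side"):
        grp = grp.sort_values("station")
        ab = np.array(
            [
                semi_axes_from_area_perimeter(a, p)
                for a, p in zip(grp["area_mm2"], grp["perimeter_mm"])
            ]
        )
        cents = np.column_stack(
            [np.zeros(len(grp)), grp["arclength_mm"].to_numpy(), np.zeros(len(grp))]
        )
        out[str(side)] = SideProfile(
            s=grp["s"].to_numpy(float),
            area_mm2=grp["area_mm2"].to_numpy(float),
            perimeter_mm=grp["perimeter_mm"].to_numpy(float),
            semi_axis_a_mm=ab[:, 0],
            semi_axis_b_mm=ab[:, 1],
            arclength_mm=grp["arclength_mm"].to_numpy(float),
            centroids_mm=cents,
        )
    return out


# --- wall fields -----------------------------------------------------------


def write_field(wf: WallField, path: Union[str, Path]) -> Path:
    """Wall field as CSV (vertex_id,value) at 17 significant digits."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("vertex_id,value\n")
        for i, v in enumerate(wf.values):
            fh.write(f"{i},{v:.17g}\n")
    return path


def read_field(
    path: Union[str, Path],
    mesh: Optional[DuctGeometry] = None,
    field_name: str = FIELD_WSS,
    phase: str = "inspiration",
) -> WallField:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["vertex_id", "value"]:
        raise ValueError(
            f"wall-field CSV must have columns vertex_id,value; got {list(df.columns)}"
        )
    values = df["value"].to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise ValueError("wall-field CSV contains non-finite values")
    if not np.array_equal(df["vertex_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("vertex_id column must be 0..V-1 in order")
    if mesh is not None and len(values) != mesh.n_vertices:
        raise ValueError(
            f"field length {len(values)} does not match mesh with {mesh.n_vertices} vertices"
        )
    return WallField(values=values, field_name=field_name, phase=phase, mesh_ref=str(path))


# --- shape model -----------------------------------------------------------


def write_shape_model(model: ShapeModel, out_dir: Union[str, Path]) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mesh(mean_shape(model), out / "mean.ply")
    np.savetxt(out / "variances.csv", model.variances, header="variance_mm2", comments="")
    np.savetxt(out / "modes.csv", model.modes, delimiter=",")
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "n_samples": model.n_samples,
                "n_modes": model.n_modes,
                "n_vertices": int(model.mean_vertices.shape[0]),
                "software_version": _pkg_version,
            },
            indent=2,
        )
    )
    return out


def read_shape_model(model_dir: Union[str, Path]) -> ShapeModel:
    d = Path(model_dir)
    ref = read_mesh(d / "mean.ply")
    variances = np.atleast_1d(np.loadtxt(d / "variances.csv", skiprows=1))
    modes = np.atleast_2d(np.loadtxt(d / "modes.csv", delimiter=","))
    manifest = json.loads((d / "manifest.json").read_text())
    return ShapeModel(
        mean_vertices=ref.vertices,
        modes=modes,
        variances=variances,
        n_samples=int(manifest["n_samples"]),
        reference=ref,
    )


# --- run configuration -----------------------------------------------------

SCHEMA_VERSION = 1


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class CorpusConfig:
    n_subjects: int = 25
    n_stations: int = 21
    n_ring: int = 24
    n_modes: int = 3
    mode_sd: Optional[Sequence[float]] = None
    noise_sd: float = 0.05
    mirror_augment: bool = True


@dataclass
class FluidConfig:
    density: float = 1.18
    viscosity_pas: float = 1.86e-5


@dataclass
class PhaseConfig:
    flow_mls: float = 200.0


@dataclass
class LossConfig:
    enabled: bool = True
    contraction_coefficient: float = 0.0


@dataclass
class MappingConfig:
    eps_wss: float = DEFAULT_COV_EPS[FIELD_WSS]
    eps_pressure: float = DEFAULT_COV_EPS[FIELD_PRESSURE]


@dataclass
class RunConfig:
    """Resolved configuration of an end-to-end pipeline run."""

    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    losses: LossConfig = field(default_factory=LossConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    histogram_bin_edges: Sequence[float] = DEFAULT_WSS_BIN_EDGES

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if int(data.get("schema_version", SCHEMA_VERSION)) != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema_version {data.get('schema_version')}"
            )
        sections = {
            "corpus": CorpusConfig,
            "fluid": FluidConfig,
            "phase": PhaseConfig,
            "losses": LossConfig,
            "mapping": MappingConfig,
        }
        kwargs = {}
        for key, val in data.items():
            if key in sections:
                kwargs[key] = _from_mapping(sections[key], val or {}, key)
            elif key == "histogram_bin_edges":
                kwargs[key] = tuple(
                    np.inf if e in ("inf", ".inf") else float(e) for e in val
                )
            elif key in ("seed", "schema_version"):
                kwargs[key] = val
            elif key == "software_version":
                pass  # informational echo in saved bundles
            else:
                raise ValueError(f"unknown config key: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["histogram_bin_edges"] = [
            "inf" if np.isinf(e) else float(e) for e in self.histogram_bin_edges
        ]
        d["software_version"] = _pkg_version
        return d


# --- end-to-end pipeline ---------------------------------------------------


def pipeline_run(config: RunConfig, out_dir: Union[str, Path]) -> dict:
    """Run the full workflow: corpus → mirror augmentation → shape model →
    average geometry → bilateral flow for every subject and the average
    (both phases) → field mapping onto the average → vertex statistics →
    comparison report.  Fully reproducible from (config, seed); the bundle
    written to ``out_dir`` includes the resolved config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        logger.info("[config] %s", json.dumps(config.resolved(), sort_keys=True))
        stage = "generate-corpus"
        template = default_template(
            n_stations=config.corpus.n_stations, n_ring=config.corpus.n_ring
        )
        spec = default_variation_spec(
            template,
            n_modes=config.corpus.n_modes,
            mode_sd=config.corpus.mode_sd,
            noise_sd=config.corpus.noise_sd,
            seed=config.seed,
        )
        corpus = generate_corpus(template, spec, config.corpus.n_subjects)
        logger.info("[generate-corpus] %d subjects", len(corpus))

        stage = "build-ssm"
        train = mirror_augment(corpus) if config.corpus.mirror_augment else corpus
        model = build_ssm(train)
        avg = mean_shape(model)
        logger.info("[build-ssm] %d training shapes, %d modes", len(train), model.n_modes)

        stage = "simulate-flow"
        fluid = FluidProperties(config.fluid.density, config.fluid.viscosity_pas)
        losses = config.losses.enabled
        kc = config.losses.contraction_coefficient
        flow = config.phase.flow_mls
        subjects = corpus.originals()
        sols = [
            simulate_phases(g, fluid, flow, losses, kc) for g in subjects
        ]
        avg_sols = simulate_phases(avg, fluid, flow, losses, kc)
        logger.info("[simulate-flow] %d subjects + average geometry", len(subjects))

        stage = "map-fields"
        field_stats = {}
        avg_fields = {}
        for phase_idx, phase in enumerate(("inspiration", "expiration")):
            for fname, attr, eps in (
                (FIELD_WSS, "wall_shear_stress_pa", config.mapping.eps_wss),
                (FIELD_PRESSURE, "wall_pressure_pa", config.mapping.eps_pressure),
            ):
                mapped = [
                    map_field_nearest(
                        WallField(getattr(s[phase_idx], attr), fname, phase), g, avg
                    )
                    for g, s in zip(subjects, sols)
                ]
                field_stats[f"{fname}_{phase}"] = vertexwise_stats(mapped, eps)
                avg_fields[f"{fname}_{phase}"] = getattr(avg_sols[phase_idx], attr)

        stage = "summarize"
        cohort_insp = [integral_measures(g, s[0]) for g, s in zip(subjects, sols)]
        cohort_exp = [integral_measures(g, s[1]) for g, s in zip(subjects, sols)]
        avg_insp = integral_measures(avg, avg_sols[0])
        avg_exp = integral_measures(avg, avg_sols[1])
        edges = tuple(config.histogram_bin_edges)
        hists = {
            "average_inspiration": wss_histogram(
                avg_sols[0].wall_shear_stress_pa, avg, edges
            ),
            "average_expiration": wss_histogram(
                avg_sols[1].wall_shear_stress_pa, avg, edges
            ),
        }
        report = comparison_report(
            cohort_insp,
            cohort_exp,
            avg_insp,
            avg_exp,
            [csa_profile(g) for g in subjects],
            csa_profile(avg),
            field_stats,
            avg_fields,
            hists,
        )

        stage = "write-bundle"
        write_report_bundle(report, config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    logger.info("[done] report bundle at %s", out)
    return report


def write_report_bundle(report: dict, config: RunConfig, out: Union[str, Path]) -> Path:
    """Write the comparison bundle: table1.csv, csa_profile.csv,
    histograms.csv, vertex_stats.csv, verdict.json, config.yaml, schema.md."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    tables = []
    for phase, df in report["tables"].items():
        df = df.copy()
        df.insert(0, "phase", phase)
        tables.append(df.reset_index())
    pd.concat(tables).to_csv(out / "table1.csv", index=False)
    report["csa_table"].to_csv(out / "csa_profile.csv", index=False, float_format="%.6g")

    hist_rows = []
    for name, h in report["histograms"].items():
        for i in range(h.area_fraction_pct.size):
            hist_rows.append(
                {
                    "case": name,
                    "bin_low_pa": h.bin_edges[i],
                    "bin_high_pa": h.bin_edges[i + 1],
                    "surface_area_pct": h.area_fraction_pct[i],
                }
            )
    pd.DataFrame(hist_rows).to_csv(out / "histograms.csv", index=False)

    stats_frames = []
    for name, df in report["field_tables"].items():
        df = df.copy()
        df.insert(0, "field", name)
        stats_frames.append(df)
    if stats_frames:
        pd.concat(stats_frames).to_csv(
            out / "vertex_stats.csv", index=False, float_format="%.9g"
        )

    (out / "verdict.json").write_text(json.dumps(report["verdict"], indent=2, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(config.resolved(), sort_keys=True))
    (out / "schema.md").write_text(_BUNDLE_SCHEMA)
    return out


_BUNDLE_SCHEMA = """\
# Report bundle schema

- `table1.csv` — cohort mean/median/SD, Tukey quartiles/whiskers and the
  average-geometry value per integral measure and phase (resistances in
  Pa·s/ml to 3 decimals, velocities m/s and WSS Pa to 2, AP % to 1).
- `csa_profile.csv` — cross-sectional-area boxplot data (both sides pooled)
  per 5% of the normalized nostril-to-choana distance, with the
  average-geometry left/right curves (mm²).
- `histograms.csv` — share of wall surface area per WSS band (Pa, first bin
  (0, 0.01]); rows per case.
- `vertex_stats.csv` — vertex-wise cohort mean/median/SD/CoV of each mapped
  wall field vs the average-geometry field and their differences; CoV is
  NaN where |mean| < eps (flagged in `cov_masked`).
- `verdict.json` — position of every average-geometry measure within the
  cohort distribution (below median? inside the IQR?), the
  expiration-over-inspiration resistance ratios, and whether the average
  geometry's total resistance lies at or below the cohort mean.
- `config.yaml` — resolved run configuration, seed and software version.
"""
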