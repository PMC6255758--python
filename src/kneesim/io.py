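"""File I/O: gait CSV schema, per-run artifact directory, VTK export.

All numeric outputs carry explicit unit names in their column headers.
The gait CSV schema is frozen (see :data:`kneesim.gait.GAIT_COLUMNS`);
readers tolerate extra unknown columns (with a logged warning) but reject
missing columns and non-monotone stance grids.  Surface maps go out as
legacy ASCII VTK PolyData (points + point data), which any VTK-aware
viewer reads.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import ComparisonReport, SNAPSHOT_FRACTIONS
from .config import RunConfig, config_hash
from .gait import GAIT_COLUMNS, GaitInputSeries
from .solver import SimulationResult

logger = logging.getLogger("kneesim")

__version__ = "0.1.0"


class GaitCSVError(ValueError):
    pass


def write_gait_csv(series: GaitInputSeries, path: str | Path) -> None:
    """Write the stance series with the canonical unit-bearing header."""
    data = {col: getattr(series, attr) for col, attr in GAIT_COLUMNS.items()}
    df = pd.DataFrame(data)
    df["body_weight_N"] = series.body_weight
    df.to_csv(path, index=False, float_format="%.17g")


def read_gait_csv(path: str | Path) -> GaitInputSeries:
    """Read a gait CSV; round-trips :func:`write_gait_csv` to 1e-12."""
    df = pd.read_csv(path)
    missing = [c for c in GAIT_COLUMNS if c not in df.columns]
    if missing:
        raise GaitCSVError(f"missing required column(s): {', '.join(missing)}")
    known = set(GAIT_COLUMNS) | {"body_weight_N"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("gait CSV %s: ignoring unknown column(s) %s", path, extra)
    t = df["stance_fraction"].to_numpy()
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise GaitCSVError(
            f"stance_fraction not strictly increasing at row {bad[0] + 1}"
        )
    if "body_weight_N" in df.columns:
        bw = float(df["body_weight_N"].iloc[0])
    else:
        bw = 700.0
        logger.warning("gait CSV %s: no body_weight_N column, assuming 700 N", path)
    kwargs = {
        attr: df[col].to_numpy(dtype=float)
        for col, attr in GAIT_COLUMNS.items()
        if attr != "t"
    }
    return GaitInputSeries(t=t.astype(float), body_weight=bw, **kwargs)


def result_frame(result: SimulationResult) -> pd.DataFrame:
    """Per-step pose and reaction table with units in the headers."""
    rot = result.rotations_deg
    df = pd.DataFrame(
        {
            "stance_fraction": result.t,
            "tx_mm": result.pose[:, 0],
            "ty_mm": result.pose[:, 1],
            "tz_mm": result.pose[:, 2],
            "theta_fe_deg": rot[:, 0],
            "theta_vv_deg": rot[:, 1],
            "theta_ie_deg": rot[:, 2],
            "R_ap_BW": result.reaction_bw[:, 0],
            "R_axial_BW": result.reaction_bw[:, 1],
            "R_ml_BW": result.reaction_bw[:, 2],
            "newton_iterations": result.iterations,
            "residual_BW": result.residual,
            "complementarity_MPa_mm": result.complementarity,
        }
    )
    if result.patella is not None:
        df["patella_x_mm"] = result.patella[:, 0]
        df["patella_y_mm"] = result.patella[:, 1]
        df["patella_z_mm"] = result.patella[:, 2]
    return df


def write_vtk_polydata(
    path: str | Path,
    points: np.ndarray,
    point_data: dict[str, np.ndarray],
    title: str = "kneesim surface map",
) -> None:
    """Minimal legacy ASCII VTK PolyData writer (points with vertices)."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    for p in points:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines.append(f"VERTICES {n} {2 * n}")
    lines.extend(f"1 {i}" for i in range(n))
    lines.append(f"POINT_DATA {n}")
    for name, vals in point_data.items():
        vals = np.asarray(vals, dtype=float)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" for v in vals)
    Path(path).write_text("\n".join(lines) + "\n")


def write_geometry_vtk(geometry, path: str | Path) -> None:
    """Column field of one geometry variant as a VTK point cloud."""
    cols = geometry.columns
    pts = np.stack([cols.x, cols.y_top, cols.z], axis=1)
    write_vtk_polydata(
        path,
        pts,
        {
            "thickness0_mm": cols.thickness0,
            "meniscal": cols.meniscal.astype(float),
            "compartment": cols.compartment.astype(float),
        },
        title=f"kneesim geometry {geometry.variant}",
    )


def write_result_dir(
    result: SimulationResult, out_dir: str | Path, write_vtk: bool = True
) -> Path:
    """Serialize one simulation: per-step CSV plus snapshot VTK maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode_id = result.mode.model_id
    result_frame(result).to_csv(
        out / f"model_{mode_id}_steps.csv", index=False, float_format="%.17g"
    )
    if write_vtk and result.geometry is not None:
        cols = result.geometry.columns
        pts = np.stack([cols.x, cols.y_top, cols.z], axis=1)
        for frac in SNAPSHOT_FRACTIONS:
            i = int(np.argmin(np.abs(result.t - frac)))
            write_vtk_polydata(
                out / f"model_{mode_id}_stance{int(round(frac * 100)):03d}.vtk",
                pts,
                {
                    "traction_MPa": result.traction[i],
                    "pore_pressure_MPa": result.pore_mean[i],
                    "overlap_mm": result.overlap[i],
                },
                title=f"kneesim model {mode_id} at {frac:.0%} stance",
            )
    return out


def write_manifest(
    cfg: RunConfig, out_dir: str | Path, modes_run: list[str]
) -> Path:
    """JSON run manifest: config hash, seed, version, modes.  Contains no
    timestamps so identical runs are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "modes": modes_run,
        "config": cfg.model_dump(mode="json"),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_comparison(report: ComparisonReport, out_dir: str | Path) -> Path:
    """Comparison report as CSV (long table) plus JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = report.to_frame()
    df.to_csv(out / "comparison.csv", index=False, float_format="%.17g")
    payload = {
        "reference": report.reference_id,
        "metrics": {
            model: {q: list(v) for q, v in qtys.items()}
            for model, qtys in report.metrics.items()
        },
    }
    (out / "comparison.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return out
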