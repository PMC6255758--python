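"""Run configuration: schema, defaults, TOML loading, hashing.

Every default is either a literature material constant (cartilage/meniscus
moduli, ligament stiffnesses and prestrains, moment scaling) or a package
design choice (synthetic geometry dimensions, gait waveform shapes, solver
tolerances).  All of them live here so a run is fully described by one
file; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

Bump = tuple[float, float, float]  # (amplitude, center, width) on stance [0,1]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ConfigError(ValueError):
    """Configuration failed validation; message carries the field path."""


class TIPEParams(_Strict):
    E_p: float = Field(24.0, gt=0)
    E_t: float = Field(0.46, gt=0)
    nu_p: float = 0.42
    nu_tp: float = 0.06
    G_t: float = Field(12.0, gt=0)
    permeability: float = Field(1.0, gt=0, description="1e-15 m^4/(N s)")
    void_ratio: float = Field(4.0, gt=0)


class TIEParams(_Strict):
    E_p: float = Field(20.0, gt=0)
    E_t: float = Field(159.6, gt=0)
    nu_p: float = 0.3
    nu_tp: float = 0.01
    G_t: float = Field(50.0, gt=0)


class SpringParams(_Strict):
    stiffness_k: float = Field(..., gt=0, description="N/mm")
    prestrain: float = Field(..., ge=0)


class TrussParams(_Strict):
    E: float = Field(..., gt=0, description="MPa")
    nu: float = 0.499  # recorded; does not enter the 1-D truss law
    area: float = Field(..., gt=0, description="mm^2")


class MaterialsConfig(_Strict):
    cartilage: TIPEParams = TIPEParams()
    meniscus: TIEParams = TIEParams()
    ACL: SpringParams = SpringParams(stiffness_k=380.0, prestrain=0.05)
    PCL: SpringParams = SpringParams(stiffness_k=200.0, prestrain=0.05)
    MCL: SpringParams = SpringParams(stiffness_k=100.0, prestrain=0.04)
    LCL: SpringParams = SpringParams(stiffness_k=100.0, prestrain=0.04)
    QT: SpringParams = SpringParams(stiffness_k=475.0, prestrain=0.04)
    PT: SpringParams = SpringParams(stiffness_k=545.0, prestrain=0.04)
    horn_stiffness: float = Field(350.0, gt=0, description="N/mm per horn")
    MPFL: TrussParams = TrussParams(E=19.1, nu=0.499, area=10.0)
    LPFL: TrussParams = TrussParams(E=17.0, nu=0.499, area=10.0)


class GeometryConfig(_Strict):
    """Parametric right-knee geometry in a tibia-fixed frame.

    +x anterior, +y proximal, +z lateral; lengths in mm.  The tibial
    plateau bone plane is y = 0; femoral condyles are ellipsoidal patches.
    """

    condyle_radius_ap: float = Field(26.0, gt=0)
    condyle_radius_vert: float = Field(24.0, gt=0)
    condyle_radius_ml: float = Field(21.0, gt=0)
    condyle_offset_ml: float = Field(22.0, gt=0)
    plateau_half_ap: float = Field(20.0, gt=0)
    plateau_half_ml: float = Field(14.0, gt=0)
    dish_radius: float = Field(28.0, gt=0)
    cartilage_thickness: float = Field(2.4, gt=0)
    thickness_band: tuple[float, float] = (1.5, 4.0)
    column_spacing: float = Field(1.0, gt=0)
    meniscus_rho: float = Field(0.62, gt=0, lt=1)
    meniscus_conformity: float = Field(0.85, gt=0, lt=1)
    meniscus_min_thickness: float = Field(0.3, gt=0)
    reference_gap: float = Field(0.3, ge=0)
    epicondyle_halfwidth: float = Field(40.0, gt=0)
    rp_femur_height: float = 26.0
    radius_jitter: float = Field(0.03, ge=0)
    insertion_jitter: float = Field(0.8, ge=0, description="mm")
    thickness_jitter: float = Field(0.25, ge=0, description="mm")
    symmetric: bool = False
    gap_tolerance: float = 1e-9
    # patellar mechanism (Geometry A only)
    trochlea_center: tuple[float, float, float] = (5.0, 25.0, 0.0)
    trochlea_radius: float = Field(20.0, gt=0)
    patella_ref: tuple[float, float, float] = (27.0, 30.0, 0.0)
    rp_quad: tuple[float, float, float] = (8.0, 72.0, 0.0)
    # beyond this flexion the quadriceps tendon wraps on the trochlea, so
    # the effective pull direction stops rotating with the femur
    quad_wrap_flexion_deg: float = Field(15.0, ge=0)
    # femoral insertions sit near the flexion axis (RP height) so ligament
    # lengths stay near-isometric over the stance flexion range
    femur_insertions: dict[str, tuple[float, float, float]] = {
        "ACL": (-5.0, 25.0, 6.0),
        "PCL": (-3.0, 24.0, -6.0),
        "MCL": (0.0, 26.0, -40.0),
        "LCL": (0.0, 26.0, 40.0),
    }
    tibia_insertions: dict[str, tuple[float, float, float]] = {
        "ACL": (8.0, 0.0, 0.0),
        "PCL": (-10.0, -4.0, -2.0),
        "MCL": (2.0, -42.0, -36.0),
        "LCL": (-4.0, -30.0, 42.0),
        "PT": (32.0, -18.0, 0.0),
    }


class GaitConfig(_Strict):
    """Stance-phase waveform generator settings.

    Every series is a sum of Gaussian bumps (amplitude, center, width) on
    the stance fraction grid; forces in BW, moments in N mm per BW,
    rotations in degrees.  The axial force is double-peaked with peak
    timings ``fdp_peak_times``.
    """

    n_grid: int = Field(101, ge=11)
    body_weight: float = Field(700.0, gt=0, description="N")
    noise_level: float = Field(0.03, ge=0)
    noise_bumps: int = Field(6, ge=0)
    noise_width: float = Field(0.08, gt=0)
    fdp_peak_times: tuple[float, float] = (0.20, 0.80)
    fdp_peak_values: tuple[float, float] = (1.05, 1.00)
    fdp_width: float = Field(0.16, gt=0)
    fdp_baseline: Bump = (0.10, 0.50, 0.30)
    fap_bumps: list[Bump] = [(-0.12, 0.15, 0.10), (0.14, 0.85, 0.10)]
    fml_bumps: list[Bump] = [(0.05, 0.30, 0.20), (0.04, 0.70, 0.20)]
    mvv_bumps: list[Bump] = [(40.0, 0.25, 0.13), (35.0, 0.75, 0.13)]
    mie_bumps: list[Bump] = [(-8.0, 0.20, 0.12), (15.0, 0.70, 0.15)]
    fe_offset: float = 8.0
    fe_bumps: list[Bump] = [(12.0, 0.18, 0.10), (-4.0, 0.45, 0.12), (30.0, 1.0, 0.12)]
    ie_bumps: list[Bump] = [(3.0, 0.20, 0.15), (-2.0, 0.90, 0.20)]
    qf_bumps: list[Bump] = [(1.0, 0.18, 0.09), (0.25, 0.75, 0.15)]

    @field_validator("fdp_peak_times")
    @classmethod
    def _peaks_inside_stance(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not all(0.0 < t < 1.0 for t in v):
            raise ValueError("fdp_peak_times must lie strictly inside (0, 1)")
        if not v[0] < v[1]:
            raise ValueError("fdp_peak_times must be increasing")
        return v


class SolverConfig(_Strict):
    n_steps: int = Field(100, ge=1)
    stance_duration: float = Field(0.6, gt=0, description="s")
    depth_layers: int = Field(3, ge=1)
    tol_force_bw: float = Field(1e-8, gt=0)
    tol_moment_bwmm: float = Field(1e-8, gt=0)
    max_newton_iter: int = Field(60, ge=1)
    fd_step_translation: float = Field(1e-6, gt=0, description="mm")
    fd_step_rotation: float = Field(1e-7, gt=0, description="rad")
    # per-iteration Newton update caps: quasi-static marching must follow
    # the continuous equilibrium branch, so one iteration may not jump
    # further than a load step could plausibly move the joint
    newton_cap_translation: float = Field(2.0, gt=0, description="mm")
    newton_cap_rotation: float = Field(0.1, gt=0, description="rad")
    settle_tolerance: float = Field(1.0, gt=0, description="N")
    settle_travel_bound: float = Field(25.0, gt=0, description="mm")
    patella_tol: float = Field(1e-7, gt=0, description="N")
    pf_stiffness: float = Field(200.0, gt=0, description="N/mm")
    cardan_sequence: Literal["fe-vv-ie"] = "fe-vv-ie"
    moment_scale: float = Field(0.5, ge=0)
    qf_scale: float = Field(1.0, ge=0)
    mode_b_vv_moment: bool = False
    overlap_warn_fraction: float = Field(0.9, gt=0, le=1)


class RunConfig(_Strict):
    materials: MaterialsConfig = MaterialsConfig()
    geometry: GeometryConfig = GeometryConfig()
    gait: GaitConfig = GaitConfig()
    solver: SolverConfig = SolverConfig()
    modes: list[Literal["A", "B", "C", "D"]] = ["A", "B", "C", "D"]
    seed: int = 0
    out_dir: str = "runs"


def default_config(**overrides) -> RunConfig:
    """The documented default run configuration."""
    return RunConfig(**overrides)


def coarse_preset(**overrides) -> RunConfig:
    """Coarse 2 mm column tessellation for quick runs and tests."""
    base = RunConfig(**overrides)
    geo = base.geometry.model_copy(update={"column_spacing": 2.0})
    return base.model_copy(update={"geometry": geo})


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"])
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Read a TOML run configuration; unknown keys are rejected with the
    offending field path in the error message."""
    raw = Path(path).read_bytes()
    data = tomllib.loads(raw.decode("utf-8"))
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def config_hash(cfg: RunConfig) -> str:
    """sha256 of the canonical JSON serialization; changes iff any
    configuration value changes."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()
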