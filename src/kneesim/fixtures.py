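"""Seeded, versioned test fixtures with oracle-computed expectations.

Each fixture writes its inputs together with expected outputs produced by
the independent closed-form / brute-force routines in
:mod:`kneesim.oracles` -- never by the production solver -- so the test
suite can regenerate and cross-check them at will.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import oracles
from .config import GeometryConfig, MaterialsConfig
from .materials import MaterialTIPE, confined_moduli


def _material_from_config(materials: MaterialsConfig) -> MaterialTIPE:
    m = materials.cartilage
    return MaterialTIPE(
        E_p=m.E_p, E_t=m.E_t, nu_p=m.nu_p, nu_tp=m.nu_tp, G_t=m.G_t,
        permeability_k=m.permeability, e0=m.void_ratio,
    )


def _single_column_step_load(seed: int, out: Path) -> dict:
    """Terzaghi-series pore-pressure table for a unit step load: 20 time
    points, mid-depth and base pressures plus settlement."""
    mat = _material_from_config(MaterialsConfig())
    H_A, _ = confined_moduli(mat)
    h, q0 = 2.5, 1.0
    c_v = mat.permeability_mm * H_A
    Tv = np.linspace(0.02, 1.0, 20)
    times = Tv * h**2 / c_v
    rows = []
    for tv, t in zip(Tv, times):
        p_mid = oracles.terzaghi_pore_pressure(q0, c_v, h, np.array([h / 2]), t)[0]
        p_base = oracles.terzaghi_pore_pressure(q0, c_v, h, np.array([h]), t)[0]
        s = oracles.terzaghi_settlement(q0, c_v, H_A, h, t)
        rows.append(
            {"Tv": tv, "time_s": t, "p_mid_MPa": p_mid, "p_base_MPa": p_base,
             "settlement_mm": s}
        )
    pd.DataFrame(rows).to_csv(out / "single_column_step_load.csv", index=False)
    return {"h_mm": h, "q0_MPa": q0, "c_v_mm2_s": c_v, "H_A_MPa": H_A}


def _one_dof_spring(seed: int, out: Path) -> dict:
    """Displacement table F/k for ten forces, found by bisection on the
    1-DOF spring residual."""
    k = 380.0
    forces = np.linspace(10.0, 1000.0, 10)
    rows = []
    for F in forces:
        u = oracles.brute_force_1dof_equilibrium(
            lambda x, F=F: F - k * x, 0.0, 10.0
        )
        rows.append({"force_N": F, "displacement_mm": u})
    pd.DataFrame(rows).to_csv(out / "one_dof_spring.csv", index=False)
    return {"stiffness_N_mm": k}


def _two_sphere_symmetric(seed: int, out: Path) -> dict:
    """Mirror-symmetric geometry configuration: under a pure axial load the
    equilibrium varus-valgus rotation is exactly zero by symmetry."""
    cfg = GeometryConfig(symmetric=True, column_spacing=2.0)
    payload = {
        "geometry": json.loads(cfg.model_dump_json()),
        "seed": seed,
        "expected": {"theta_vv_deg_under_axial_load": 0.0},
    }
    (out / "two_sphere_symmetric.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return {"symmetric": True}


REGISTRY = {
    "single_column_step_load": _single_column_step_load,
    "one_dof_spring": _one_dof_spring,
    "two_sphere_symmetric": _two_sphere_symmetric,
}


def make_fixture(name: str, seed: int, out_dir: str | Path) -> Path:
    """Generate one registered fixture (inputs + oracle expectations)."""
    if name not in REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; registered: {sorted(REGISTRY)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = REGISTRY[name](seed, out)
    manifest = {"name": name, "seed": seed, "parameters": meta}
    (out / f"{name}_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out
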