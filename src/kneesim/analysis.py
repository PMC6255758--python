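"""Post-processing: compartment responses, model comparison, QF sweep.

Extracts the quantities the driving-mode comparison is about: per-step
rotations, translations and tibial reaction components; average maximum
principal stress, logarithmic strain and pore pressure over the
cartilage-cartilage contact area of each compartment; contact area as a
column count; mean/max absolute inter-model differences over stance with
snapshot maps at 20/50/80% of stance; and the parametric sweep of the
mode-D quadriceps scaling factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MaterialsConfig, SolverConfig
from .gait import GaitInputSeries
from .geometry import LATERAL, MEDIAL, KneeGeometry
from .materials import MaterialTIPE, confined_moduli
from .solver import DrivingMode, SimulationResult, run_model

SNAPSHOT_FRACTIONS = (0.20, 0.50, 0.80)

#: quantities entering the sweep discrepancy (translations + reactions)
SWEEP_QUANTITIES = ("tx_mm", "ty_mm", "tz_mm", "R_ap_BW", "R_axial_BW", "R_ml_BW")

_COMPARTMENT_IDS = {"medial": MEDIAL, "lateral": LATERAL}


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class CompartmentSeries:
    """Per-step averages over the contacting cartilage-cartilage columns of
    one compartment.  Steps with an empty contact set hold NaN (an absent
    average, never a fabricated zero)."""

    compartment: str
    t: np.ndarray
    avg_max_principal_stress: np.ndarray  # MPa
    avg_log_strain: np.ndarray  # (-), negative in compression
    avg_pore_pressure: np.ndarray  # MPa
    contact_area_count: np.ndarray  # int, columns in contact
    contact_area_mm2: np.ndarray


def _cartilage_material(materials: MaterialsConfig) -> MaterialTIPE:
    m = materials.cartilage
    return MaterialTIPE(
        E_p=m.E_p, E_t=m.E_t, nu_p=m.nu_p, nu_tp=m.nu_tp, G_t=m.G_t,
        permeability_k=m.permeability, e0=m.void_ratio,
    )


def column_max_principal_stress(
    traction: np.ndarray, pore_mean: np.ndarray, stress_ratio: float
) -> np.ndarray:
    """Largest eigenvalue (tension-positive MPa) of the total stress tensor
    assembled from the confined-compression column state.

    The tensor is diagonal in the column frame: total axial stress
    -traction; effective axial stress -traction + p; laterally induced
    effective stress (C13/C33) * sigma'_ax; total lateral stress adds -p.
    """
    sig_ax_eff = -traction + pore_mean
    sig_lat = stress_ratio * sig_ax_eff - pore_mean
    sig_ax = -traction
    return np.maximum(sig_ax, sig_lat)


def compartment_response(
    result: SimulationResult, compartment: str
) -> CompartmentSeries:
    """Average stress/strain/pressure over the cartilage-cartilage contact
    area of one compartment, per stance step."""
    if result.geometry is None or result.materials is None:
        raise AnalysisError("result carries no geometry/materials reference")
    if compartment not in _COMPARTMENT_IDS:
        raise AnalysisError(f"unknown compartment {compartment!r}")
    cols = result.geometry.columns
    cart = _cartilage_material(result.materials)
    H_A, C13 = confined_moduli(cart)
    ratio = C13 / H_A

    sel = (cols.compartment == _COMPARTMENT_IDS[compartment]) & ~cols.meniscal
    n = result.t.size
    stress = np.full(n, np.nan)
    strain = np.full(n, np.nan)
    pressure = np.full(n, np.nan)
    count = np.zeros(n, dtype=int)
    area = np.zeros(n)
    log_strain_all = np.log1p(
        -np.minimum(result.cart_overlap / cols.thickness0, 0.999)
    )
    for i in range(n):
        mask = sel & (result.traction[i] > 0.0)
        count[i] = int(mask.sum())
        area[i] = float(cols.area[mask].sum())
        if count[i] == 0:
            continue
        sp = column_max_principal_stress(
            result.traction[i, mask], result.pore_mean[i, mask], ratio
        )
        stress[i] = float(sp.mean())
        strain[i] = float(log_strain_all[i, mask].mean())
        pressure[i] = float(result.pore_mean[i, mask].mean())
    return CompartmentSeries(
        compartment=compartment,
        t=result.t,
        avg_max_principal_stress=stress,
        avg_log_strain=strain,
        avg_pore_pressure=pressure,
        contact_area_count=count,
        contact_area_mm2=area,
    )


def extract_series(result: SimulationResult) -> dict[str, np.ndarray]:
    """The scalar stance series entering the inter-model comparison."""
    rot = result.rotations_deg
    out = {
        "theta_fe_deg": rot[:, 0],
        "theta_vv_deg": rot[:, 1],
        "theta_ie_deg": rot[:, 2],
        "tx_mm": result.pose[:, 0],
        "ty_mm": result.pose[:, 1],
        "tz_mm": result.pose[:, 2],
        "R_ap_BW": result.reaction_bw[:, 0],
        "R_axial_BW": result.reaction_bw[:, 1],
        "R_ml_BW": result.reaction_bw[:, 2],
    }
    for comp in ("medial", "lateral"):
        cs = compartment_response(result, comp)
        out[f"stress_{comp}_MPa"] = cs.avg_max_principal_stress
        out[f"strain_{comp}"] = cs.avg_log_strain
        out[f"pressure_{comp}_MPa"] = cs.avg_pore_pressure
        out[f"contact_{comp}_count"] = cs.contact_area_count.astype(float)
    return out


@dataclass
class ComparisonReport:
    """Mean and max absolute differences over stance, reference vs tests."""

    reference_id: str
    metrics: dict[str, dict[str, tuple[float, float]]]  # model -> qty -> (mean, max)
    snapshots: dict[str, dict[float, np.ndarray]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, qtys in self.metrics.items():
            for qty, (mean_d, max_d) in qtys.items():
                rows.append(
                    {
                        "model": model,
                        "quantity": qty,
                        "mean_abs_diff": mean_d,
                        "max_abs_diff": max_d,
                    }
                )
        return pd.DataFrame(rows)


def compare_models(
    reference: SimulationResult, others: list[SimulationResult]
) -> ComparisonReport:
    """Per-quantity |difference| statistics of each model vs the reference.

    All results must share the stance grid.  NaN steps (undefined averages
    over empty contact sets) are excluded pairwise; a model compared with
    itself yields exactly zero.
    """
    ref_series = extract_series(reference)
    metrics: dict[str, dict[str, tuple[float, float]]] = {}
    snapshots: dict[str, dict[float, np.ndarray]] = {
        reference.mode.model_id: _snapshot_maps(reference)
    }
    for res in others:
        if res.t.size != reference.t.size or not np.allclose(res.t, reference.t):
            raise AnalysisError("results are not on a common stance grid")
        series = extract_series(res)
        qmetrics: dict[str, tuple[float, float]] = {}
        for qty, ref_vals in ref_series.items():
            diff = np.abs(series[qty] - ref_vals)
            valid = ~np.isnan(diff)
            if valid.any():
                qmetrics[qty] = (float(diff[valid].mean()), float(diff[valid].max()))
            else:
                qmetrics[qty] = (float("nan"), float("nan"))
        metrics[res.mode.model_id] = qmetrics
        snapshots[res.mode.model_id] = _snapshot_maps(res)
    return ComparisonReport(
        reference_id=reference.mode.model_id,
        metrics=metrics,
        snapshots=snapshots,
    )


def _snapshot_maps(result: SimulationResult) -> dict[float, np.ndarray]:
    out = {}
    for frac in SNAPSHOT_FRACTIONS:
        i = int(np.argmin(np.abs(result.t - frac)))
        out[frac] = result.traction[i].copy()
    return out


@dataclass
class SweepResult:
    best_scale: float
    table: pd.DataFrame
    failures: list[float] = field(default_factory=list)


def qf_scale_sweep(
    geom_a: KneeGeometry,
    geom_b: KneeGeometry,
    gait: GaitInputSeries,
    scales: list[float],
    reference: SimulationResult,
    materials: MaterialsConfig,
    solver: SolverConfig,
    weights: dict[str, float] | None = None,
    n_steps: int | None = None,
) -> SweepResult:
    """Parametric study of the mode-D quadriceps scaling factor.

    Runs mode D once per scale and scores each run by a weighted sum of
    the mean absolute differences in translations and tibial reaction
    forces against the reference (mode A unless stated otherwise).
    Returns the argmin scale and the full discrepancy table; failed member
    runs are recorded and excluded from the argmin.
    """
    if any(not 0.0 < s <= 3.0 for s in scales):
        raise AnalysisError("scales must lie in (0, 3]")
    if weights is None:
        weights = {q: 1.0 for q in SWEEP_QUANTITIES}
    rows = []
    failures: list[float] = []
    for s in scales:
        mode = DrivingMode(
            "D", "B", ("FE", "IE"), {}, "ap_surrogate", qf_scale=float(s)
        )
        res = run_model(
            "D", geom_a, geom_b, gait, materials, solver,
            n_steps=n_steps, mode=mode,
        )
        if res.failure_index is not None:
            failures.append(float(s))
            rows.append({"scale": s, "discrepancy": np.nan, "failed": True})
            continue
        report = compare_models(reference, [res])
        qtys = report.metrics["D"]
        disc = sum(w * qtys[q][0] for q, w in weights.items())
        row = {"scale": s, "discrepancy": disc, "failed": False}
        row.update({q: qtys[q][0] for q in weights})
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise AnalysisError("all sweep members failed")
    best = float(ok.loc[ok["discrepancy"].idxmin(), "scale"])
    return SweepResult(best_scale=best, table=table, failures=failures)


def plot_stance_series(results: list[SimulationResult], path) -> None:
    """Stance-phase overview figure: rotations, translations, reactions
    and compartment stress for a set of driving-mode results."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("theta_vv_deg", "varus-valgus (deg)"),
        ("theta_ie_deg", "internal-external (deg)"),
        ("tx_mm", "anterior-posterior transl. (mm)"),
        ("R_axial_BW", "axial reaction (BW)"),
        ("R_ap_BW", "AP reaction (BW)"),
        ("stress_medial_MPa", "medial avg max principal stress (MPa)"),
    ]
    fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
    for res in results:
        series = extract_series(res)
        for ax, (qty, label) in zip(axes.flat, panels):
            ax.plot(res.t * 100.0, series[qty],
                    label=f"Model {res.mode.model_id}")
            ax.set_ylabel(label)
    for ax in axes[1]:
        ax.set_xlabel("stance (%)")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
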