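"""Synthetic stance-phase gait inputs.

Emulates the structure of motion-capture-derived knee loading during the
stance phase of walking: a double-peaked axial (distal-proximal) force,
braking/propulsion anterior-posterior force, small medial-lateral force,
double-peaked varus-valgus (adduction) moment, internal-external moment,
smooth flexion-extension and internal-external rotation curves, and a
quadriceps force peaking in early stance.  All series are sums of Gaussian
bumps on a uniform stance-fraction grid, optionally overlaid with smooth
seeded noise, so they are C-infinity and cheap to regenerate.

Forces are normalized to body weight (BW), moments to N mm/BW, rotations
in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GaitConfig
from .geometry import KneeGeometry

#: canonical CSV column schema (name -> attribute)
GAIT_COLUMNS = {
    "stance_fraction": "t",
    "F_ap_BW": "F_ap",
    "F_ml_BW": "F_ml",
    "F_dp_BW": "F_dp",
    "M_ie_Nmm_per_BW": "M_ie",
    "M_vv_Nmm_per_BW": "M_vv",
    "theta_fe_deg": "theta_fe",
    "theta_ie_deg": "theta_ie",
    "QF_BW": "QF",
}


@dataclass(frozen=True)
class GaitInputSeries:
    """Stance-phase input waveforms on a common uniform grid."""

    t: np.ndarray  # stance fraction in [0, 1]
    F_ap: np.ndarray  # BW, +anterior
    F_ml: np.ndarray  # BW, +lateral
    F_dp: np.ndarray  # BW, compressive magnitude, >= 0
    M_ie: np.ndarray  # N mm / BW
    M_vv: np.ndarray  # N mm / BW
    theta_fe: np.ndarray  # deg, flexion positive
    theta_ie: np.ndarray  # deg
    QF: np.ndarray  # BW, quadriceps force magnitude
    body_weight: float  # N

    def __post_init__(self) -> None:
        n = self.t.size
        for name in GAIT_COLUMNS.values():
            if getattr(self, name).size != n:
                raise ValueError(f"series {name} not on the common grid")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("stance grid must be strictly increasing")
        if np.any(self.F_dp < 0):
            raise ValueError("F_dp must be non-negative throughout stance")

    @property
    def n(self) -> int:
        return self.t.size

    def resample(self, t_new: np.ndarray) -> "GaitInputSeries":
        """Linear interpolation of every series onto a new grid."""
        kw = {
            name: np.interp(t_new, self.t, getattr(self, name))
            for name in GAIT_COLUMNS.values()
            if name != "t"
        }
        return GaitInputSeries(t=t_new, body_weight=self.body_weight, **kw)


def _bumps(t: np.ndarray, bumps) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, center, width in bumps:
        out += amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))
    return out


def generate_gait(gait: GaitConfig, seed: int = 0) -> GaitInputSeries:
    """Deterministic-per-seed synthetic stance waveforms."""
    t = np.linspace(0.0, 1.0, gait.n_grid)
    rng = np.random.default_rng(seed)

    def noisy(base: np.ndarray) -> np.ndarray:
        if gait.noise_level == 0.0 or gait.noise_bumps == 0:
            return base
        scale = np.max(np.abs(base))
        if scale == 0.0:
            return base
        centers = rng.uniform(0.05, 0.95, gait.noise_bumps)
        amps = rng.normal(0.0, gait.noise_level * scale, gait.noise_bumps)
        return base + _bumps(t, zip(amps, centers, np.full(gait.noise_bumps, gait.noise_width)))

    (t1, t2), (a1, a2) = gait.fdp_peak_times, gait.fdp_peak_values
    w = gait.fdp_width
    f_dp = _bumps(t, [(a1, t1, w), (a2, t2, w), gait.fdp_baseline])
    f_dp = np.maximum(noisy(f_dp), 0.0)

    series = GaitInputSeries(
        t=t,
        F_ap=noisy(_bumps(t, gait.fap_bumps)),
        F_ml=noisy(_bumps(t, gait.fml_bumps)),
        F_dp=f_dp,
        M_ie=noisy(_bumps(t, gait.mie_bumps)),
        M_vv=noisy(_bumps(t, gait.mvv_bumps)),
        theta_fe=noisy(gait.fe_offset + _bumps(t, gait.fe_bumps)),
        theta_ie=noisy(_bumps(t, gait.ie_bumps)),
        QF=np.maximum(noisy(_bumps(t, gait.qf_bumps)), 0.0),
        body_weight=gait.body_weight,
    )
    return series


def flexion_rotation(theta_fe_deg: float) -> np.ndarray:
    """Rotation about +z (flexion) used by the quadriceps decomposition."""
    th = np.deg2rad(theta_fe_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def decompose_quadriceps(
    QF: np.ndarray | float,
    theta_fe: np.ndarray | float,
    geometry: KneeGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the quadriceps force along its line of action into
    anterior-posterior and distal-proximal components (BW).

    The line of action runs from RP_Quad, the quadriceps pull point on the
    femur (rotated with the flexion angle about the femoral reference
    point), to the patellar reference position.  QF_ap is positive
    anteriorly, QF_dp positive distally (compressive sense, matching the
    F_dp convention).  The medial-lateral remainder is discarded, so
    QF_ap^2 + QF_dp^2 <= QF^2.
    """
    if geometry.rp_quad is None:
        raise ValueError("geometry has no quadriceps mechanism (variant B)")
    QF = np.atleast_1d(np.asarray(QF, dtype=float))
    theta = np.atleast_1d(np.asarray(theta_fe, dtype=float))
    if np.any(QF < 0):
        raise ValueError("QF must be non-negative")
    qf_ap = np.empty_like(QF)
    qf_dp = np.empty_like(QF)
    rp = geometry.rp_femur
    wrap = geometry.quad_wrap_flexion_deg
    for i, (q, th) in enumerate(zip(QF, np.broadcast_to(theta, QF.shape))):
        # beyond the wrap angle the tendon bears on the trochlea and the
        # pull direction stops rotating with the femur
        R = flexion_rotation(min(th, wrap))
        rp_quad_w = rp + R @ (geometry.rp_quad - rp)
        line = geometry.patella_ref - rp_quad_w
        L = np.linalg.norm(line)
        if L <= 1e-9:
            raise ValueError("zero-length quadriceps line of action")
        u = line / L
        qf_ap[i] = q * u[0]
        qf_dp[i] = -q * u[1]
    if qf_ap.size == 1 and np.isscalar(theta_fe):
        return float(qf_ap[0]), float(qf_dp[0])
    return qf_ap, qf_dp
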