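"""Quasi-static rigid-femur equilibrium against the poroelastic column field.

The femur is a rigid body with up to six degrees of freedom (three
translations, three Cardan rotations about the femoral reference point
RP_Femur; sequence flexion-extension -> varus-valgus -> internal-external,
i.e. z, then rotated x, then doubly-rotated y).  At every stance step the
prescribed rotations are imposed, the mode's forces and moments are
applied, and a damped semismooth Newton iteration drives the residual
(applied loads + contact column forces + ligament springs + patellar
mechanism, reduced to RP_Femur) on the free DOFs to zero.  Contact is
frictionless and compressive-only: each column pushes along its surface
normal with the affine traction law produced by one implicit consolidation
step, clamped at zero.

Driving modes (the four models compared):

    A: geometry A; prescribe FE; apply scaled IE and VV moments; apply
       translational forces; quadriceps through the patella mechanism.
    B: geometry A; prescribe FE and IE; VV free (no VV moment by default);
       forces and quadriceps as A.
    C: geometry B; prescribe FE and IE; VV free; translational forces only.
    D: geometry B; as C plus s * QF_ap added to the anterior-posterior
       force (default s = 1).

The simulation follows the three-step protocol: (1) settle soft tissues
into first contact, (2) rotate to the initial orientation and apply the
initial loads, (3) march the stance phase as a consolidation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root as scipy_root

from .config import MaterialsConfig, SolverConfig
from .gait import GaitInputSeries, decompose_quadriceps
from .geometry import LATERAL, MEDIAL, KneeGeometry, ellipsoid_lower_surface
from .materials import (
    MaterialTIE,
    MaterialTIPE,
    column_affine_response,
    column_update,
    confined_moduli,
    spring_force,
    truss_force,
)

TX, TY, TZ, FE, VV, IE = range(6)


class SolverError(RuntimeError):
    """Equilibrium iteration failed; carries the residual history."""

    def __init__(self, message: str, history: list[float] | None = None):
        super().__init__(message)
        self.history = history or []


@dataclass(frozen=True)
class DrivingMode:
    """One row of the driving-mode table."""

    model_id: str
    geometry_variant: str
    prescribed_rotations: tuple[str, ...]
    applied_moments: dict[str, float]  # name -> moment scale
    quadriceps: str  # "none" | "patella_mechanism" | "ap_surrogate"
    qf_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in "ABCD":
            raise ValueError(f"unknown model_id {self.model_id!r}")


def driving_mode(model_id: str, solver: SolverConfig) -> DrivingMode:
    """Build the driving mode for a model id from the solver settings."""
    ms = solver.moment_scale
    if model_id == "A":
        return DrivingMode("A", "A", ("FE",), {"IE": ms, "VV": ms},
                           "patella_mechanism")
    if model_id == "B":
        moments = {"VV": ms} if solver.mode_b_vv_moment else {}
        return DrivingMode("B", "A", ("FE", "IE"), moments,
                           "patella_mechanism")
    if model_id == "C":
        return DrivingMode("C", "B", ("FE", "IE"), {}, "none")
    if model_id == "D":
        return DrivingMode("D", "B", ("FE", "IE"), {}, "ap_surrogate",
                           qf_scale=solver.qf_scale)
    raise ValueError(f"unknown model_id {model_id!r}")


@dataclass
class JointState:
    """Femur pose plus the full poroelastic column state at one instant.

    pose = [tx, ty, tz (mm), theta_fe, theta_vv, theta_ie (rad)].
    """

    pose: np.ndarray
    pore: np.ndarray  # (ncol, depth_layers + 1)
    traction: np.ndarray  # (ncol,) cartilage surface traction, MPa
    cart_overlap: np.ndarray  # (ncol,) consolidation-consistent compression
    patella: np.ndarray | None = None
    time: float = 0.0


@dataclass
class SimulationResult:
    """Per-step joint state and derived fields for one driving mode."""

    mode: DrivingMode
    t: np.ndarray
    pose: np.ndarray  # (n, 6); translations mm, rotations rad
    reaction_bw: np.ndarray  # (n, 3) contact force on femur / BW
    traction: np.ndarray  # (n, ncol) MPa
    overlap: np.ndarray  # (n, ncol) geometric overlap, mm
    cart_overlap: np.ndarray  # (n, ncol) cartilage compression, mm
    pore_mean: np.ndarray  # (n, ncol) thickness-averaged pore pressure, MPa
    patella: np.ndarray | None
    residual: np.ndarray  # (n,) final residual (BW / BW mm, inf-norm)
    iterations: np.ndarray  # (n,)
    complementarity: np.ndarray  # (n,) max traction * gap, MPa mm
    geometry: "KneeGeometry | None" = None
    materials: MaterialsConfig | None = None
    failure_index: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def rotations_deg(self) -> np.ndarray:
        return np.rad2deg(self.pose[:, 3:])

    @property
    def n_steps(self) -> int:
        return self.t.size


def cardan_rotation(fe: float, vv: float, ie: float) -> np.ndarray:
    """R = Rz(fe) @ Rx(vv) @ Ry(ie)."""
    cf, sf = np.cos(fe), np.sin(fe)
    cv, sv = np.cos(vv), np.sin(vv)
    ci, si = np.cos(ie), np.sin(ie)
    Rz = np.array([[cf, -sf, 0.0], [sf, cf, 0.0], [0.0, 0.0, 1.0]])
    Rx = np.array([[1.0, 0.0, 0.0], [0.0, cv, -sv], [0.0, sv, cv]])
    Ry = np.array([[ci, 0.0, si], [0.0, 1.0, 0.0], [-si, 0.0, ci]])
    return Rz @ Rx @ Ry


def cardan_axes(fe: float, vv: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation axes conjugate to (fe, vv, ie) for the z-x-y sequence."""
    cf, sf = np.cos(fe), np.sin(fe)
    a_fe = np.array([0.0, 0.0, 1.0])
    a_vv = np.array([cf, sf, 0.0])  # Rz @ ex
    cv, sv = np.cos(vv), np.sin(vv)
    ey_r = np.array([0.0, cv, sv])  # Rx @ ey
    a_ie = np.array(
        [cf * 0.0 - sf * ey_r[1], sf * 0.0 + cf * ey_r[1], ey_r[2]]
    )
    return a_fe, a_vv, a_ie


class JointModel:
    """Bundles one geometry variant with materials and solver settings."""

    def __init__(
        self,
        geometry: KneeGeometry,
        materials: MaterialsConfig,
        solver: SolverConfig,
        body_weight: float,
        ligaments: dict | None = None,
    ):
        from .geometry import attach_ligaments

        self.geometry = geometry
        self.materials = materials
        self.solver = solver
        self.bw = body_weight
        self.ligaments = ligaments or attach_ligaments(geometry, materials)

        m = materials.cartilage
        self.cartilage = MaterialTIPE(
            E_p=m.E_p, E_t=m.E_t, nu_p=m.nu_p, nu_tp=m.nu_tp, G_t=m.G_t,
            permeability_k=m.permeability, e0=m.void_ratio,
        )
        mm = materials.meniscus
        self.meniscus = MaterialTIE(
            E_p=mm.E_p, E_t=mm.E_t, nu_p=mm.nu_p, nu_tp=mm.nu_tp, G_t=mm.G_t
        )
        self.H_A, self.C13 = confined_moduli(self.cartilage)
        H_men, _ = confined_moduli(self.meniscus)

        cols = geometry.columns
        self._imed = np.flatnonzero(cols.compartment == MEDIAL)
        self._ilat = np.flatnonzero(cols.compartment == LATERAL)
        # series stiffness of the elastic meniscus spacer, MPa/mm
        self.k_meniscus = np.where(
            cols.meniscal,
            H_men / np.maximum(cols.meniscus_thickness, 1e-6),
            np.inf,
        )
        self.rp_ref = geometry.rp_femur
        self._spring_names = ("ACL", "PCL", "MCL", "LCL")

    # --- kinematics -------------------------------------------------------

    def _pose_transform(self, pose: np.ndarray):
        R = cardan_rotation(pose[FE], pose[VV], pose[IE])
        rp_w = self.rp_ref + pose[:3]
        return R, rp_w

    def femur_point(self, pose: np.ndarray, p_femur: np.ndarray) -> np.ndarray:
        R, rp_w = self._pose_transform(pose)
        return rp_w + R @ (p_femur - self.rp_ref)

    def column_overlaps(self, pose: np.ndarray) -> np.ndarray:
        """Geometric overlap (mm) of the femoral surface into each column;
        -inf where the vertical line misses the condyle."""
        cols = self.geometry.columns
        R, rp_w = self._pose_transform(pose)
        y_cond = np.full(cols.n, np.inf)
        for idx, condyle in zip(
            (self._imed, self._ilat), self.geometry.condyles
        ):
            y_cond[idx] = ellipsoid_lower_surface(
                condyle, R, self.rp_ref, rp_w, cols.x[idx], cols.z[idx]
            )
        return cols.y_top - y_cond

    # --- force assembly ---------------------------------------------------

    def _effective_affine(self, alpha: np.ndarray, beta: np.ndarray):
        """Fold the elastic meniscus spacer (series) into the cartilage
        affine step law; returns the law in terms of total column overlap."""
        r = beta / self.k_meniscus
        return alpha / (1.0 + r), beta / (1.0 + r)

    def contact_forces(
        self, pose: np.ndarray, alpha: np.ndarray, beta: np.ndarray
    ):
        """Column tractions and their resultant at the current pose.

        alpha/beta: cartilage affine step law.  Returns (F, M, traction,
        overlap, colforce) with F, M the resultant force (N) and moment
        (N mm) about RP_Femur on the femur.
        """
        cols = self.geometry.columns
        overlap = self.column_overlaps(pose)
        d = np.maximum(overlap, 0.0)
        a_eff, b_eff = self._effective_affine(alpha, beta)
        t_raw = a_eff + b_eff * d
        traction = np.where(overlap > 0.0, np.maximum(t_raw, 0.0), 0.0)
        colforce = traction * cols.area + np.where(
            overlap > 0.0, cols.horn_stiffness * d, 0.0
        )
        F_vec = colforce[:, None] * cols.normal
        _, rp_w = self._pose_transform(pose)
        r = np.stack([cols.x, cols.y_top - d, cols.z], axis=1) - rp_w
        F = F_vec.sum(axis=0)
        M = np.cross(r, F_vec).sum(axis=0)
        return F, M, traction, overlap, colforce

    def ligament_forces(self, pose: np.ndarray):
        """Resultant of the tibiofemoral springs on the femur."""
        R, rp_w = self._pose_transform(pose)
        F = np.zeros(3)
        M = np.zeros(3)
        for name in self._spring_names:
            lig = self.ligaments[name]
            p_f = self.geometry.insertions[f"{name}_femur"][1]
            p_t = self.geometry.insertions[f"{name}_tibia"][1]
            p_fw = rp_w + R @ (p_f - self.rp_ref)
            vec = p_t - p_fw
            L = float(np.linalg.norm(vec))
            T = spring_force(lig, L)
            if T > 0.0:
                f = (T / L) * vec
                F += f
                M += np.cross(p_fw - rp_w, f)
        return F, M

    # --- patellar mechanism ----------------------------------------------

    def _patella_elements(self, pose: np.ndarray):
        R, rp_w = self._pose_transform(pose)
        g = self.geometry
        # quadriceps anchor: its rotation saturates at the wrap angle (the
        # tendon bears on the trochlea in deeper flexion)
        fe_eff = min(pose[FE], np.deg2rad(g.quad_wrap_flexion_deg))
        R_wrap = cardan_rotation(fe_eff, pose[VV], pose[IE])
        rpq_w = rp_w + R_wrap @ (g.rp_quad - self.rp_ref)
        troch_w = rp_w + R @ (g.trochlea_center - self.rp_ref)
        mpfl_w = rp_w + R @ (g.insertions["MPFL_femur"][1] - self.rp_ref)
        lpfl_w = rp_w + R @ (g.insertions["LPFL_femur"][1] - self.rp_ref)
        pt_tib = g.insertions["PT_tibia"][1]
        return rpq_w, troch_w, mpfl_w, lpfl_w, pt_tib

    def _patella_residual(self, p: np.ndarray, anchors, qf_vec: np.ndarray):
        """Net force (N) on the patella point body."""
        rpq_w, troch_w, mpfl_w, lpfl_w, pt_tib = anchors
        F = qf_vec.copy()
        for lig_name, target in (("QT", rpq_w), ("PT", pt_tib)):
            lig = self.ligaments[lig_name]
            vec = target - p
            L = float(np.linalg.norm(vec))
            T = spring_force(lig, L)
            if T > 0.0:
                F += (T / L) * vec
        for lig_name, target in (("MPFL", mpfl_w), ("LPFL", lpfl_w)):
            lig = self.ligaments[lig_name]
            vec = target - p
            L = float(np.linalg.norm(vec))
            T = truss_force(lig, L)
            if T > 0.0:
                F += (T / L) * vec
        dvec = p - troch_w
        dist = float(np.linalg.norm(dvec))
        pen = self.geometry.trochlea_radius - dist
        if pen > 0.0:
            F += self.solver.pf_stiffness * pen * (dvec / dist)
        return F

    def solve_patella(
        self,
        pose: np.ndarray,
        qf_ap_bw: float,
        qf_dp_bw: float,
        guess: np.ndarray | None = None,
    ):
        """Equilibrate the patella point body; return its position and the
        reaction force/moment it exerts on the femur (about RP_Femur)."""
        anchors = self._patella_elements(pose)
        rpq_w, troch_w, mpfl_w, lpfl_w, _ = anchors
        # muscle pull on the patella, directed from patella toward RP_Quad:
        # QF_ap is anterior-positive and QF_dp distal-positive along the
        # RP_Quad -> patella line, so the pull reverses both signs
        qf_vec = self.bw * np.array([-qf_ap_bw, qf_dp_bw, 0.0])
        tol = self.solver.patella_tol
        starts = [
            np.array(guess if guess is not None else self.geometry.patella_ref,
                     dtype=float),
            np.array(self.geometry.patella_ref, dtype=float),
        ]
        p = None
        for p0 in starts:
            sol = scipy_root(
                lambda x: self._patella_residual(x, anchors, qf_vec),
                p0,
                method="hybr",
                options={"xtol": 1e-13, "maxfev": 400},
            )
            if np.max(np.abs(sol.fun)) < tol:
                p = sol.x
                break
        if p is None:
            raise SolverError(
                f"patellar equilibrium did not converge (|r| = "
                f"{np.max(np.abs(sol.fun)):.3g} N)"
            )

        # reactions on the femur
        _, rp_w = self._pose_transform(pose)
        F = np.zeros(3)
        M = np.zeros(3)
        for lig_name, target in (("QT", rpq_w),):
            lig = self.ligaments[lig_name]
            vec = target - p
            L = float(np.linalg.norm(vec))
            T = spring_force(lig, L)
            if T > 0.0:
                f = -(T / L) * vec  # reaction at RP_Quad, toward patella
                F += f
                M += np.cross(target - rp_w, f)
        for lig_name, target in (("MPFL", mpfl_w), ("LPFL", lpfl_w)):
            lig = self.ligaments[lig_name]
            vec = target - p
            L = float(np.linalg.norm(vec))
            T = truss_force(lig, L)
            if T > 0.0:
                f = -(T / L) * vec
                F += f
                M += np.cross(target - rp_w, f)
        dvec = p - troch_w
        dist = float(np.linalg.norm(dvec))
        pen = self.geometry.trochlea_radius - dist
        if pen > 0.0:
            f = -self.solver.pf_stiffness * pen * (dvec / dist)
            F += f
            M += np.cross(p - rp_w, f)
        return p, F, M

    # --- step assembly ----------------------------------------------------

    def assemble_loads(
        self,
        mode: DrivingMode,
        gait: GaitInputSeries,
        i: int,
        qf_ap: np.ndarray | None,
        qf_dp: np.ndarray | None,
    ):
        """Applied force (N), applied world moment (N mm), prescribed
        rotations (rad), and patellar QF components (BW) for step i."""
        bw = self.bw
        f_ap = gait.F_ap[i]
        if mode.quadriceps == "ap_surrogate":
            f_ap = f_ap + mode.qf_scale * qf_ap[i]
        F = bw * np.array([f_ap, -gait.F_dp[i], gait.F_ml[i]])
        M = np.zeros(3)
        if "VV" in mode.applied_moments:
            M[0] += mode.applied_moments["VV"] * gait.M_vv[i] * bw
        if "IE" in mode.applied_moments:
            M[1] += mode.applied_moments["IE"] * gait.M_ie[i] * bw
        prescribed = {FE: np.deg2rad(gait.theta_fe[i])}
        if "IE" in mode.prescribed_rotations:
            prescribed[IE] = np.deg2rad(gait.theta_ie[i])
        qf = (
            (float(qf_ap[i]), float(qf_dp[i]))
            if mode.quadriceps == "patella_mechanism"
            else None
        )
        return F, M, prescribed, qf

    def free_dofs(self, mode: DrivingMode) -> list[int]:
        free = [TX, TY, TZ, VV]
        if "IE" not in mode.prescribed_rotations:
            free.append(IE)
        return free

    # --- equilibrium ------------------------------------------------------

    def residual(
        self,
        pose: np.ndarray,
        F_app: np.ndarray,
        M_app: np.ndarray,
        alpha: np.ndarray,
        beta: np.ndarray,
        free: list[int],
        qf: tuple[float, float] | None,
        patella_guess: np.ndarray | None = None,
    ):
        """Normalized residual on the free DOFs plus diagnostics."""
        Fc, Mc, traction, overlap, colforce = self.contact_forces(
            pose, alpha, beta
        )
        Fl, Ml = self.ligament_forces(pose)
        F = F_app + Fc + Fl
        M = M_app + Mc + Ml
        patella = None
        if qf is not None:
            patella, Fp, Mp = self.solve_patella(
                pose, qf[0], qf[1], patella_guess
            )
            F = F + Fp
            M = M + Mp
        _, a_vv, a_ie = cardan_axes(pose[FE], pose[VV])
        res = []
        for dof in free:
            if dof in (TX, TY, TZ):
                res.append(F[dof] / self.bw)
            elif dof == VV:
                res.append(float(M @ a_vv) / self.bw)
            elif dof == IE:
                res.append(float(M @ a_ie) / self.bw)
        diagnostics = {
            "traction": traction,
            "overlap": overlap,
            "colforce": colforce,
            "contact_force": Fc,
            "patella": patella,
        }
        return np.array(res), diagnostics

    def solve_equilibrium(
        self,
        pose0: np.ndarray,
        F_app: np.ndarray,
        M_app: np.ndarray,
        alpha: np.ndarray,
        beta: np.ndarray,
        free: list[int],
        qf: tuple[float, float] | None = None,
        patella_guess: np.ndarray | None = None,
    ):
        """Damped Newton iteration on the free DOFs.

        Returns (pose, diagnostics, iterations, residual_norm).  The
        Jacobian is finite-difference with per-DOF steps; a state already
        in equilibrium is accepted with zero iterations.
        """
        cfg = self.solver
        pose = pose0.copy()
        tol = min(cfg.tol_force_bw, cfg.tol_moment_bwmm)
        history: list[float] = []

        def _eval(p):
            return self.residual(
                p, F_app, M_app, alpha, beta, free, qf, patella_guess
            )

        r, diag = _eval(pose)
        nr = float(np.max(np.abs(r)))
        history.append(nr)
        it = 0
        while nr >= tol:
            if it >= cfg.max_newton_iter:
                raise SolverError(
                    f"Newton diverged after {it} iterations "
                    f"(residual {nr:.3g})",
                    history,
                )
            J = np.empty((len(free), len(free)))
            for k, dof in enumerate(free):
                h = (
                    cfg.fd_step_translation
                    if dof in (TX, TY, TZ)
                    else cfg.fd_step_rotation
                )
                dp = pose.copy()
                dp[dof] += h
                r_k, _ = _eval(dp)
                J[:, k] = (r_k - r) / h
            try:
                step = np.linalg.solve(J, -r)
            except np.linalg.LinAlgError as exc:
                raise SolverError(
                    f"singular Jacobian on free DOFs {free}", history
                ) from exc
            # trust-region style cap so the iteration tracks the local
            # equilibrium branch instead of jumping basins
            scale = 1.0
            for k, dof in enumerate(free):
                cap = (
                    cfg.newton_cap_translation
                    if dof in (TX, TY, TZ)
                    else cfg.newton_cap_rotation
                )
                if abs(step[k]) > 0.0:
                    scale = min(scale, cap / abs(step[k]))
            step = step * scale
            lam = 1.0
            while True:
                pose_new = pose.copy()
                for k, dof in enumerate(free):
                    pose_new[dof] += lam * step[k]
                r_new, diag_new = _eval(pose_new)
                nr_new = float(np.max(np.abs(r_new)))
                if nr_new < nr or lam <= 1.0 / 256.0:
                    break
                lam *= 0.5
            pose, r, nr, diag = pose_new, r_new, nr_new, diag_new
            if diag["patella"] is not None:
                patella_guess = diag["patella"]
            history.append(nr)
            it += 1
        return pose, diag, it, nr

    # --- three-step protocol ----------------------------------------------

    def settle_contact(self) -> JointState:
        """Step 1: translate the femur distally to first surface touch."""
        cfg = self.solver
        cols = self.geometry.columns
        pose = np.zeros(6)
        overlap = self.column_overlaps(pose)
        gaps = -overlap[np.isfinite(overlap)]
        if gaps.size == 0:
            raise SolverError("no contact achievable: condyles miss all columns")
        g_min = float(gaps.min())
        if g_min > cfg.settle_travel_bound:
            raise SolverError(
                f"no contact achievable within travel bound "
                f"({g_min:.1f} mm > {cfg.settle_travel_bound} mm)"
            )
        pose[TY] = -max(g_min, 0.0)
        n_nodes = cfg.depth_layers + 1
        return JointState(
            pose=pose,
            pore=np.zeros((cols.n, n_nodes)),
            traction=np.zeros(cols.n),
            cart_overlap=np.zeros(cols.n),
            patella=(
                np.array(self.geometry.patella_ref, dtype=float)
                if self.geometry.has_patella
                else None
            ),
            time=0.0,
        )

    def step_affine(self, state: JointState, dt: float):
        """Cartilage affine step law from the previous column state."""
        cols = self.geometry.columns
        return column_affine_response(
            self.cartilage,
            cols.thickness0,
            state.pore,
            state.traction,
            dt,
            self.solver.depth_layers,
        )

    def advance_columns(
        self, state: JointState, traction: np.ndarray, dt: float
    ):
        """Consolidate all columns one step under their final tractions
        (zero traction lets unloaded columns recover)."""
        p_new, sigma, d_new = column_update(
            self.cartilage,
            self.geometry.columns.thickness0,
            state.pore,
            state.traction,
            dt,
            self.solver.depth_layers,
            traction=traction,
        )
        return p_new, sigma, d_new

    def apply_initial_state(
        self,
        state: JointState,
        gait: GaitInputSeries,
        mode: DrivingMode,
        qf_ap: np.ndarray | None,
        qf_dp: np.ndarray | None,
        dt: float,
    ) -> tuple[JointState, dict, int, float]:
        """Step 2: rotate to the initial orientation, apply the t = 0 loads
        and equilibrate the free DOFs.  Ligament slack lengths stay frozen
        at the reference-pose values (the prestrain definition)."""
        F, M, prescribed, qf = self.assemble_loads(mode, gait, 0, qf_ap, qf_dp)
        pose = state.pose.copy()
        for dof, val in prescribed.items():
            pose[dof] = val
        alpha, beta = self.step_affine(state, dt)
        free = self.free_dofs(mode)
        pose, diag, it, nr = self.solve_equilibrium(
            pose, F, M, alpha, beta, free, qf, state.patella
        )
        p_new, sigma, d_new = self.advance_columns(
            state, diag["traction"], dt
        )
        new = JointState(
            pose=pose,
            pore=p_new,
            traction=sigma,
            cart_overlap=d_new,
            patella=diag["patella"] if qf is not None else state.patella,
            time=0.0,
        )
        return new, diag, it, nr

    def simulate_stance(
        self,
        gait: GaitInputSeries,
        mode: DrivingMode,
        n_steps: int | None = None,
        ref_geometry: KneeGeometry | None = None,
    ) -> SimulationResult:
        """Step 3: march t = 0 -> 1 of stance under the driving mode.

        Records n_steps + 1 states on a uniform stance grid; consolidation
        advances with the physical step duration stance_duration/n_steps.
        ``ref_geometry`` supplies the quadriceps reference points for the
        decomposition (needed by the mode-D surrogate, whose own geometry
        has no patella); defaults to this model's geometry.  On a step
        failure a partial result is returned with failure_index set.
        """
        cfg = self.solver
        n = n_steps if n_steps is not None else cfg.n_steps
        t_grid = np.linspace(0.0, 1.0, n + 1)
        g = gait.resample(t_grid)
        dt = cfg.stance_duration / n

        qf_ap = qf_dp = None
        if mode.quadriceps in ("patella_mechanism", "ap_surrogate"):
            ref = ref_geometry if ref_geometry is not None else self.geometry
            qf_ap, qf_dp = decompose_quadriceps(g.QF, g.theta_fe, ref)

        ncol = self.geometry.columns.n
        n_rec = n + 1
        out = SimulationResult(
            mode=mode,
            t=t_grid,
            pose=np.zeros((n_rec, 6)),
            reaction_bw=np.zeros((n_rec, 3)),
            traction=np.zeros((n_rec, ncol)),
            overlap=np.zeros((n_rec, ncol)),
            cart_overlap=np.zeros((n_rec, ncol)),
            pore_mean=np.zeros((n_rec, ncol)),
            patella=(
                np.zeros((n_rec, 3)) if mode.quadriceps == "patella_mechanism"
                else None
            ),
            residual=np.zeros(n_rec),
            iterations=np.zeros(n_rec, dtype=int),
            complementarity=np.zeros(n_rec),
            geometry=self.geometry,
            materials=self.materials,
        )

        state = self.settle_contact()
        i = 0
        try:
            state, diag, it, nr = self.apply_initial_state(
                state, g, mode, qf_ap, qf_dp, dt
            )
            self._record(out, 0, state, diag, it, nr)
            for i in range(1, n + 1):
                F, M, prescribed, qf = self.assemble_loads(
                    mode, g, i, qf_ap, qf_dp
                )
                pose = state.pose.copy()
                for dof, val in prescribed.items():
                    pose[dof] = val
                alpha, beta = self.step_affine(state, dt)
                free = self.free_dofs(mode)
                pose, diag, it, nr = self.solve_equilibrium(
                    pose, F, M, alpha, beta, free, qf, state.patella
                )
                p_new, sigma, d_new = self.advance_columns(
                    state, diag["traction"], dt
                )
                state = JointState(
                    pose=pose,
                    pore=p_new,
                    traction=sigma,
                    cart_overlap=d_new,
                    patella=(
                        diag["patella"] if qf is not None else state.patella
                    ),
                    time=t_grid[i],
                )
                self._record(out, i, state, diag, it, nr)
        except SolverError as exc:
            out.failure_index = i
            out.meta["failure"] = str(exc)
            return out
        return out

    def _record(self, out, i, state, diag, it, nr):
        cols = self.geometry.columns
        out.pose[i] = state.pose
        out.reaction_bw[i] = diag["contact_force"] / self.bw
        out.traction[i] = state.traction
        out.overlap[i] = np.maximum(diag["overlap"], 0.0)
        out.cart_overlap[i] = state.cart_overlap
        # thickness-averaged pore pressure (trapezoid over nodes)
        w = np.full(self.solver.depth_layers + 1, 1.0)
        w[0] = w[-1] = 0.5
        out.pore_mean[i] = (state.pore @ w) / w.sum()
        if out.patella is not None and state.patella is not None:
            out.patella[i] = state.patella
        out.residual[i] = nr
        out.iterations[i] = it
        trac = diag["traction"]
        gap = np.maximum(-diag["overlap"], 0.0)
        active = trac > 0.0
        out.complementarity[i] = (
            float(np.max(trac[active] * gap[active])) if active.any() else 0.0
        )
        frac = out.overlap[i] / cols.thickness0
        if np.any(frac > self.solver.overlap_warn_fraction):
            out.meta.setdefault("overlap_warnings", []).append(i)


def run_model(
    model_id: str,
    geom_a: KneeGeometry,
    geom_b: KneeGeometry,
    gait: GaitInputSeries,
    materials: MaterialsConfig,
    solver: SolverConfig,
    n_steps: int | None = None,
    mode: DrivingMode | None = None,
) -> SimulationResult:
    """Run one driving mode end-to-end on the matching geometry variant."""
    mode = mode or driving_mode(model_id, solver)
    geometry = geom_a if mode.geometry_variant == "A" else geom_b
    model = JointModel(geometry, materials, solver, gait.body_weight)
    ref = geom_a if mode.quadriceps == "ap_surrogate" else None
    return model.simulate_stance(gait, mode, n_steps, ref_geometry=ref)
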