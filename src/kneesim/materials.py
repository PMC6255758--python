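"""Constitutive models for the joint simulator.

Cartilage is transversely isotropic poroelastic (TIPE): a transversely
isotropic drained skeleton (plane of isotropy = local articular tangent
plane, out-of-plane axis = local surface normal) plus Darcy fluid flow.
Menisci are transversely isotropic elastic (TIE) -- same skeleton, no fluid.
Ligaments and tendons are tension-only bilinear springs with prestrain;
the patellofemoral retinacular ligaments are tension-only linear trusses.

The contact discretization is a field of independent 1-D through-thickness
poroelastic columns (elastic-foundation / discrete-element style).  Each
column deforms in confined compression (zero lateral strain), drains at the
articular surface and is sealed at the bone interface.  One implicit time
step of the column consolidation problem yields an *affine* relation
between surface overlap and total surface traction, which is what the
rigid-body equilibrium solver consumes.

Units: N, mm, MPa, s throughout.  Permeability is carried in the
conventional 1e-15 m^4/(N s) of the material tables and converted here
(1e-15 m^4/(N s) == 1e-3 mm^4/(N s)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: mm^4/(N s) per 1e-15 m^4/(N s)
PERMEABILITY_UNIT = 1.0e-3

_VOIGT = 6


class MaterialError(ValueError):
    """Raised when constitutive parameters violate a thermodynamic bound."""


@dataclass(frozen=True)
class MaterialTIE:
    """Transversely isotropic elastic solid (drained skeleton).

    Parameters
    ----------
    E_p, E_t : float
        In-plane and out-of-plane Young's moduli (MPa).
    nu_p, nu_tp : float
        In-plane and out-of-plane Poisson's ratios (-).  ``nu_tp`` couples
        out-of-plane stress to in-plane strain through ``E_t``.
    G_t : float
        Out-of-plane shear modulus (MPa).  The in-plane shear modulus is
        the transverse-isotropy closure ``G_p = E_p / (2 (1 + nu_p))``.
    """

    E_p: float
    E_t: float
    nu_p: float
    nu_tp: float
    G_t: float

    def __post_init__(self) -> None:
        _check_ti_bounds(self)

    @property
    def G_p(self) -> float:
        return self.E_p / (2.0 * (1.0 + self.nu_p))


@dataclass(frozen=True)
class MaterialTIPE(MaterialTIE):
    """TIE skeleton plus fluid phase (biphasic / poroelastic).

    permeability_k is hydraulic permeability in 1e-15 m^4/(N s); e0 is the
    initial void ratio (porosity = e0 / (1 + e0)).
    """

    permeability_k: float = 1.0
    e0: float = 4.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.permeability_k <= 0.0:
            raise MaterialError("permeability_k must be positive")
        if self.e0 <= 0.0:
            raise MaterialError(
                f"void ratio e0={self.e0} gives porosity outside (0, 1)"
            )

    @property
    def porosity(self) -> float:
        return self.e0 / (1.0 + self.e0)

    @property
    def permeability_mm(self) -> float:
        """Permeability in internal units, mm^4/(N s)."""
        return self.permeability_k * PERMEABILITY_UNIT


def _check_ti_bounds(mat: MaterialTIE) -> None:
    """Thermodynamic admissibility of the transversely isotropic skeleton."""
    if mat.E_p <= 0.0 or mat.E_t <= 0.0:
        raise MaterialError("Young's moduli E_p, E_t must be positive")
    if mat.G_t <= 0.0:
        raise MaterialError("out-of-plane shear modulus G_t must be positive")
    if not -1.0 < mat.nu_p < 1.0:
        raise MaterialError(
            f"in-plane Poisson's ratio nu_p={mat.nu_p} violates |nu_p| < 1"
        )
    # PD of the normal-stress compliance block requires
    # (1 - nu_p) E_t > 2 nu_tp^2 E_p.
    lhs = (1.0 - mat.nu_p) * mat.E_t
    rhs = 2.0 * mat.nu_tp**2 * mat.E_p
    if lhs <= rhs:
        raise MaterialError(
            "violated thermodynamic bound (1 - nu_p) E_t > 2 nu_tp^2 E_p: "
            f"{lhs:.6g} <= {rhs:.6g}"
        )


def ti_compliance_matrix(mat: MaterialTIE) -> np.ndarray:
    """6x6 Voigt compliance (1/MPa); axes (1,2) in-plane, 3 out-of-plane.

    Voigt order (11, 22, 33, 23, 13, 12); engineering shear strains.
    """
    S = np.zeros((_VOIGT, _VOIGT))
    S[0, 0] = S[1, 1] = 1.0 / mat.E_p
    S[2, 2] = 1.0 / mat.E_t
    S[0, 1] = S[1, 0] = -mat.nu_p / mat.E_p
    c = -mat.nu_tp / mat.E_t
    S[0, 2] = S[2, 0] = S[1, 2] = S[2, 1] = c
    S[3, 3] = S[4, 4] = 1.0 / mat.G_t
    S[5, 5] = 1.0 / mat.G_p
    return S


def tipe_elasticity_matrix(mat: MaterialTIE) -> np.ndarray:
    """Drained (effective-stress) 6x6 elasticity operator in MPa.

    Inverse of the transversely isotropic compliance; symmetrized to kill
    round-off and checked for positive definiteness.
    """
    C = np.linalg.inv(ti_compliance_matrix(mat))
    C = 0.5 * (C + C.T)
    eig = np.linalg.eigvalsh(C)
    if eig[0] <= 0.0:
        raise MaterialError(
            f"elasticity operator not positive definite (min eig {eig[0]:.3g})"
        )
    return C


def confined_moduli(mat: MaterialTIE) -> tuple[float, float]:
    """(H_A, C13): out-of-plane aggregate modulus and the axial-lateral
    coupling stiffness of the drained skeleton under zero lateral strain."""
    C = tipe_elasticity_matrix(mat)
    return float(C[2, 2]), float(C[0, 2])


# ---------------------------------------------------------------------------
# tension-only structural elements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpringLigament:
    """Bilinear (tension-only) ligament or tendon spring.

    ``slack_length`` is derived from the reference length and the prestrain
    at the reference (imaging) pose: slack = ref / (1 + prestrain).
    """

    name: str
    stiffness_k: float  # N/mm
    prestrain: float  # engineering strain at reference pose
    endpoints: tuple[str, str]
    reference_length: float  # mm
    slack_length: float = field(init=False)

    def __post_init__(self) -> None:
        if self.stiffness_k <= 0.0:
            raise MaterialError(f"{self.name}: stiffness_k must be positive")
        if self.prestrain < 0.0:
            raise MaterialError(f"{self.name}: prestrain must be >= 0")
        if self.reference_length <= 0.0:
            raise MaterialError(f"{self.name}: reference_length must be > 0")
        object.__setattr__(
            self, "slack_length", self.reference_length / (1.0 + self.prestrain)
        )


def spring_force(lig: SpringLigament, current_length: float) -> float:
    """Tension (N) of a bilinear spring; zero below slack length."""
    if current_length <= 0.0:
        raise ValueError(
            f"{lig.name}: degenerate geometry, current_length <= 0"
        )
    return lig.stiffness_k * max(0.0, current_length - lig.slack_length)


@dataclass(frozen=True)
class TrussLigament:
    """Linear elastic truss with no compressive stiffness (MPFL / LPFL).

    nu is recorded for completeness but does not enter the 1-D force law.
    """

    name: str
    E: float  # MPa
    nu: float
    cross_section_area: float  # mm^2
    endpoints: tuple[str, str]
    reference_length: float  # mm

    def __post_init__(self) -> None:
        if self.E <= 0.0 or self.cross_section_area <= 0.0:
            raise MaterialError(f"{self.name}: E and area must be positive")
        if self.reference_length <= 0.0:
            raise MaterialError(f"{self.name}: reference_length must be > 0")


def truss_force(lig: TrussLigament, current_length: float) -> float:
    """Tension (N): E * A * max(0, strain), strain = (L - L_ref) / L_ref."""
    if current_length <= 0.0:
        raise ValueError(
            f"{lig.name}: degenerate geometry, current_length <= 0"
        )
    strain = (current_length - lig.reference_length) / lig.reference_length
    return lig.E * lig.cross_section_area * max(0.0, strain)


# ---------------------------------------------------------------------------
# 1-D poroelastic column consolidation
# ---------------------------------------------------------------------------
#
# Through-thickness nodes j = 0..N at depth z_j = j * dz measured from the
# articular surface; p_0 = 0 (drained surface), no flux at the bone node N.
# Compression-positive scalars: overlap d >= 0, traction sigma >= 0, pore
# pressure p >= 0, nodal engineering strain eps_j = (sigma - p_j) / H_A.
# Implicit-Euler continuity at nodes 1..N plus the settlement constraint
# trapz(eps) = d yields a linear system in (p_1..p_N, sigma).


@dataclass
class ColumnState:
    """Poroelastic state of one contact column."""

    thickness0: float  # undeformed thickness (mm)
    depth_layers: int = 3
    pore_pressure: np.ndarray = None  # (N+1,) nodal, index 0 = surface
    traction: float = 0.0  # total surface traction (MPa)
    overlap: float = 0.0  # current surface overlap (mm)

    def __post_init__(self) -> None:
        if self.pore_pressure is None:
            self.pore_pressure = np.zeros(self.depth_layers + 1)

    @property
    def axial_strain(self) -> float:
        """Logarithmic through-thickness strain (negative in compression)."""
        return float(np.log1p(-self.overlap / self.thickness0))

    def effective_stress(self, mat: MaterialTIPE) -> np.ndarray:
        """Per-node effective stress (axial, lateral) in tension-positive
        MPa under the confined-compression kinematics."""
        H_A, C13 = confined_moduli(mat)
        sig_ax = -(self.traction - self.pore_pressure)  # = -H_A * eps
        sig_lat = (C13 / H_A) * sig_ax
        return np.stack([sig_ax, sig_lat], axis=-1)


def _column_matrix(
    H_A: float, k_mm: float, thickness: np.ndarray, n_layers: int, dt: float
) -> np.ndarray:
    """Stacked linear systems for the implicit column step.

    thickness may be any shape; returns (..., N+1, N+1) with unknowns
    u = [p_1..p_N, sigma].  The last row is the settlement constraint; its
    RHS carries the prescribed overlap.  For traction-driven stepping the
    last row is replaced by sigma = q.
    """
    th = np.asarray(thickness, dtype=float)
    N = n_layers
    dz = th / N
    r = k_mm * dt / dz**2  # (...,)
    A = np.zeros(th.shape + (N + 1, N + 1))
    invH = 1.0 / H_A
    # continuity rows, node j = 1..N at row j-1 (unknown p_j at column j-1).
    # Compression-positive strain: d(eps)/dt = -k p'' (pressure decay at the
    # sealed base drives further settlement), so implicitly
    #   eps_j^+ + dt k p''_j^+ = eps_j_old,  eps_j = (sigma - p_j)/H_A
    for j in range(1, N + 1):
        row = j - 1
        A[..., row, j - 1] = -invH
        A[..., row, N] = invH
        if j < N:
            # p''_j = (p_{j+1} - 2 p_j + p_{j-1}) / dz^2; p_0 = 0 (drained)
            if j >= 2:
                A[..., row, j - 2] += r
            A[..., row, j - 1] += -2.0 * r
            A[..., row, j] += r
        else:
            # sealed base: ghost p_{N+1} = p_{N-1} -> p'' = 2(p_{N-1}-p_N)/dz^2
            if N >= 2:
                A[..., row, N - 2] += 2.0 * r
            A[..., row, N - 1] += -2.0 * r
    # settlement constraint: dz * (eps_0/2 + eps_1 + .. + eps_{N-1} + eps_N/2)
    w = np.full(N + 1, 1.0)
    w[0] = w[-1] = 0.5
    for j in range(1, N + 1):
        A[..., N, j - 1] = -w[j] * invH
    A[..., N, N] = invH * w.sum()
    A[..., N, :] *= dz[..., None]
    return A


def _column_rhs_base(
    H_A: float,
    pore: np.ndarray,
    traction: np.ndarray,
    n_layers: int,
) -> np.ndarray:
    """RHS rows 0..N-1 (old strains); constraint row left at zero."""
    N = n_layers
    eps_old = (np.asarray(traction)[..., None] - pore[..., 1:]) / H_A
    b = np.zeros(pore.shape[:-1] + (N + 1,))
    b[..., :N] = eps_old
    return b


def column_affine_response(
    mat: MaterialTIPE,
    thickness: np.ndarray,
    pore: np.ndarray,
    traction: np.ndarray,
    dt: float,
    n_layers: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Affine traction law sigma = alpha + beta * overlap for one implicit
    step of duration dt, given the previous column state.

    Vectorized over leading dimensions of thickness/pore/traction.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    H_A, _ = confined_moduli(mat)
    A = _column_matrix(H_A, mat.permeability_mm, thickness, n_layers, dt)
    b0 = _column_rhs_base(H_A, pore, traction, n_layers)
    b1 = np.zeros_like(b0)
    b1[..., n_layers] = 1.0
    try:
        sol = np.linalg.solve(A, np.stack([b0, b1], axis=-1))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise RuntimeError(
            "column consolidation step failed to solve; refine dt or "
            "depth_layers"
        ) from exc
    alpha = sol[..., n_layers, 0]
    beta = sol[..., n_layers, 1]
    return alpha, beta


def column_update(
    mat: MaterialTIPE,
    thickness: np.ndarray,
    pore: np.ndarray,
    traction_old: np.ndarray,
    dt: float,
    n_layers: int = 3,
    *,
    overlap: np.ndarray | None = None,
    traction: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance columns one implicit step.

    Exactly one of ``overlap`` (displacement-driven) or ``traction``
    (load-driven) must be given.  Returns (pore_new, traction_new,
    overlap_new); pore_new keeps the drained surface node at zero.
    """
    if (overlap is None) == (traction is None):
        raise ValueError("give exactly one of overlap or traction")
    H_A, _ = confined_moduli(mat)
    th = np.asarray(thickness, dtype=float)
    N = n_layers
    A = _column_matrix(H_A, mat.permeability_mm, th, N, dt)
    b = _column_rhs_base(H_A, pore, traction_old, N)
    if overlap is not None:
        b[..., N] = overlap
    else:
        q = np.broadcast_to(np.asarray(traction, dtype=float), th.shape).copy()
        A[..., N, :] = 0.0
        A[..., N, N] = 1.0
        b[..., N] = q
    u = np.linalg.solve(A, b[..., None])[..., 0]
    p_new = np.zeros(b.shape[:-1] + (N + 1,))
    p_new[..., 1:] = u[..., :N]
    sigma = u[..., N]
    dz = th / N
    w = np.full(N + 1, 1.0)
    w[0] = w[-1] = 0.5
    eps = (sigma[..., None] - p_new) / H_A
    d_new = dz * np.einsum("...j,j->...", eps, w)
    return p_new, sigma, d_new


def column_consolidation_step(
    state: ColumnState, mat: MaterialTIPE, new_overlap: float, dt: float
) -> tuple[ColumnState, float]:
    """Single-column convenience wrapper around :func:`column_update`.

    Prescribes the surface overlap for one step of duration dt and returns
    the updated state together with the total surface traction (MPa).
    """
    if new_overlap < 0.0:
        raise ValueError("new_overlap must be >= 0")
    th = np.asarray(state.thickness0)
    p_new, sigma, d = column_update(
        mat,
        th,
        state.pore_pressure,
        np.asarray(state.traction),
        dt,
        state.depth_layers,
        overlap=np.asarray(new_overlap),
    )
    new = ColumnState(
        thickness0=state.thickness0,
        depth_layers=state.depth_layers,
        pore_pressure=p_new,
        traction=float(sigma),
        overlap=float(d),
    )
    return new, float(sigma)


def drained_column_stiffness(mat: MaterialTIE, thickness: float) -> float:
    """Long-time (fully drained) surface stiffness H_A / h in MPa/mm."""
    H_A, _ = confined_moduli(mat)
    return H_A / thickness


def step_column_stiffness(
    mat: MaterialTIPE, thickness: float, dt: float, n_layers: int = 3
) -> float:
    """Instantaneous tangent stiffness d(traction)/d(overlap) of one
    implicit step from a virgin state (MPa/mm).  Bounded below by the
    drained stiffness and grows as dt shrinks (undrained limit)."""
    p0 = np.zeros(n_layers + 1)
    _, beta = column_affine_response(
        mat, np.asarray(thickness), p0, np.asarray(0.0), dt, n_layers
    )
    return float(beta)
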