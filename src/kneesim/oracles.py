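"""Independent closed-form and brute-force reference solutions.

These routines deliberately share no code with the production solvers: the
consolidation series is the classical closed form, the uniaxial-strain
stresses are computed from the compliance definition by a small direct
solve, and the 1-DOF equilibrium search is a bisection on the residual.
They exist so the test suite can check the main implementation against an
independent route.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def isotropic_hooke_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic Hooke operator (Voigt, engineering shear) from the
    Lame constants -- independent of the compliance-inversion route."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2.0 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def terzaghi_pore_pressure(
    q0: float,
    c_v: float,
    h: float,
    z: np.ndarray,
    t: float,
    n_terms: int = 200,
) -> np.ndarray:
    """Classical one-dimensional consolidation series.

    Step surface load ``q0`` (MPa) applied at t = 0 to a column of height
    ``h`` drained at z = 0 and sealed at z = h; ``c_v`` is the coefficient
    of consolidation (mm^2/s).  Returns the excess pore pressure at depths
    ``z`` (measured from the drained surface) at time ``t``.
    """
    z = np.asarray(z, dtype=float)
    if t <= 0.0:
        p = np.full_like(z, q0)
        p[z == 0.0] = 0.0
        return p
    Tv = c_v * t / h**2
    m = np.arange(n_terms)
    M = 0.5 * np.pi * (2 * m + 1)
    terms = (2.0 / M) * np.sin(np.outer(z / h, M)) * np.exp(-(M**2) * Tv)
    return q0 * terms.sum(axis=1)


def terzaghi_settlement(
    q0: float, c_v: float, H_A: float, h: float, t: float, n_terms: int = 200
) -> float:
    """Surface settlement (mm) of the same step-load problem; tends to the
    drained value q0 h / H_A as t -> infinity."""
    if t <= 0.0:
        return 0.0
    Tv = c_v * t / h**2
    m = np.arange(n_terms)
    M = 0.5 * np.pi * (2 * m + 1)
    U = 1.0 - np.sum((2.0 / M**2) * np.exp(-(M**2) * Tv))
    return q0 * h / H_A * U


def uniaxial_strain_stresses(
    E_p: float, E_t: float, nu_p: float, nu_tp: float, eps_axial: float
) -> tuple[float, float]:
    """Drained stresses (sigma_axial, sigma_lateral), tension-positive MPa,
    for a prescribed out-of-plane strain with zero in-plane strain.

    Solves the compliance relations directly for the two unknown stresses
    (sigma_lat acting equally on both in-plane axes):

        eps_p  = (1 - nu_p)/E_p * sig_lat - nu_tp/E_t * sig_ax = 0
        eps_ax = -2 nu_tp/E_t * sig_lat + sig_ax/E_t           = eps_axial
    """
    A = np.array(
        [
            [(1.0 - nu_p) / E_p, -nu_tp / E_t],
            [-2.0 * nu_tp / E_t, 1.0 / E_t],
        ]
    )
    sig_lat, sig_ax = np.linalg.solve(A, np.array([0.0, eps_axial]))
    return float(sig_ax), float(sig_lat)


def brute_force_1dof_equilibrium(
    residual: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Bisection root of a scalar residual; the independent check for
    single-DOF equilibrium problems (e.g. displacement F/k of one spring)."""
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        return lo
    if r_hi == 0.0:
        return hi
    if np.sign(r_lo) == np.sign(r_hi):
        raise ValueError("residual does not bracket a root on [lo, hi]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = residual(mid)
        if r_mid == 0.0 or (hi - lo) < tol:
            return mid
        if np.sign(r_mid) == np.sign(r_lo):
            lo, r_lo = mid, r_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
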