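"""Constitutive layer: elasticity operator, springs, trusses, consolidation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneesim import oracles
from kneesim.materials import (
    ColumnState,
    MaterialError,
    MaterialTIE,
    MaterialTIPE,
    SpringLigament,
    TrussLigament,
    column_consolidation_step,
    column_update,
    confined_moduli,
    drained_column_stiffness,
    spring_force,
    step_column_stiffness,
    tipe_elasticity_matrix,
    truss_force,
)


class TestElasticityOperator:
    def test_isotropy_limit_matches_hooke(self, rng):
        """In the isotropy limit the TI operator must reduce to the
        isotropic Hooke operator built independently from Lame constants."""
        for _ in range(100):
            E = rng.uniform(0.5, 50.0)
            nu = rng.uniform(0.05, 0.45)
            mat = MaterialTIE(
                E_p=E, E_t=E, nu_p=nu, nu_tp=nu, G_t=E / (2 * (1 + nu))
            )
            C = tipe_elasticity_matrix(mat)
            C_ref = oracles.isotropic_hooke_matrix(E, nu)
            err = np.max(np.abs(C - C_ref)) / np.max(np.abs(C_ref))
            assert err < 1e-12

    def test_cartilage_parameters_positive_definite(self, cartilage):
        eig = np.linalg.eigvalsh(tipe_elasticity_matrix(cartilage))
        assert np.all(eig > 0)

    def test_meniscus_parameters_positive_definite(self):
        mat = MaterialTIE(E_p=20.0, E_t=159.6, nu_p=0.3, nu_tp=0.01, G_t=50.0)
        assert np.all(np.linalg.eigvalsh(tipe_elasticity_matrix(mat)) > 0)

    def test_operator_symmetric(self, rng):
        for _ in range(20):
            mat = MaterialTIE(
                E_p=rng.uniform(1, 40),
                E_t=rng.uniform(0.2, 40),
                nu_p=rng.uniform(0.0, 0.45),
                nu_tp=rng.uniform(0.0, 0.05),
                G_t=rng.uniform(1, 40),
            )
            C = tipe_elasticity_matrix(mat)
            assert np.max(np.abs(C - C.T)) < 1e-12

    def test_thermodynamic_bound_violation_named(self):
        with pytest.raises(MaterialError, match="thermodynamic bound"):
            MaterialTIE(E_p=24.0, E_t=0.05, nu_p=0.42, nu_tp=0.5, G_t=12.0)

    def test_negative_modulus_rejected(self):
        with pytest.raises(MaterialError, match="positive"):
            MaterialTIE(E_p=-1.0, E_t=1.0, nu_p=0.3, nu_tp=0.1, G_t=1.0)


class TestSpringLigament:
    def _acl(self, ref=30.0, prestrain=0.05):
        return SpringLigament(
            name="ACL", stiffness_k=380.0, prestrain=prestrain,
            endpoints=("ACL_femur", "ACL_tibia"), reference_length=ref,
        )

    def test_slack_limit_zero_tension(self):
        lig = self._acl()
        assert spring_force(lig, lig.slack_length) == 0.0

    def test_hand_calculated_tension(self):
        """ref 30 mm at 5% prestrain: slack 28.5714 mm; at 30 mm the
        tension is 380 * 1.4286 = 542.9 N."""
        lig = self._acl()
        assert lig.slack_length == pytest.approx(28.5714, abs=1e-4)
        assert spring_force(lig, 30.0) == pytest.approx(542.857, abs=0.1)

    def test_no_compression(self):
        lig = self._acl()
        assert spring_force(lig, 0.5 * lig.slack_length) == 0.0

    def test_degenerate_length_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            spring_force(self._acl(), -1.0)

    @settings(max_examples=60, derandomize=True)
    @given(
        L=st.floats(0.1, 100.0),
        dL=st.floats(1e-3, 1.0),
    )
    def test_piecewise_linear_and_continuous(self, L, dL):
        """Force is continuous, piecewise linear, with slope 0 below slack
        and k above; the only derivative jump sits at the slack length."""
        lig = self._acl(ref=50.0)
        f0, f1 = spring_force(lig, L), spring_force(lig, L + dL)
        slope = (f1 - f0) / dL
        s = lig.slack_length
        if L + dL <= s:
            assert slope == 0.0
        elif L >= s:
            assert slope == pytest.approx(lig.stiffness_k, rel=1e-6)
        else:  # straddles the kink
            assert 0.0 <= slope <= lig.stiffness_k + 1e-9

    def test_negative_prestrain_rejected(self):
        with pytest.raises(MaterialError):
            self._acl(prestrain=-0.1)


class TestTrussLigament:
    def _mpfl(self, area=10.0):
        return TrussLigament(
            name="MPFL", E=19.1, nu=0.499, cross_section_area=area,
            endpoints=("patella", "MPFL_femur"), reference_length=50.0,
        )

    def test_hand_calculated_tension(self):
        lig = self._mpfl()
        assert truss_force(lig, 50.0 * 1.01) == pytest.approx(1.91, rel=1e-9)

    def test_no_compression(self):
        assert truss_force(self._mpfl(), 49.0) == 0.0

    def test_linearity_in_area(self):
        f1 = truss_force(self._mpfl(10.0), 51.0)
        f2 = truss_force(self._mpfl(20.0), 51.0)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)


class TestConsolidation:
    def test_zero_history_zero_fields(self, cartilage):
        state = ColumnState(thickness0=2.5)
        for _ in range(5):
            state, trac = column_consolidation_step(state, cartilage, 0.0, 0.01)
            assert trac == 0.0
            assert np.all(state.pore_pressure == 0.0)

    def test_drained_limit(self, cartilage):
        """Constant overlap, t -> inf: pore pressure drains to zero and
        traction approaches drained stiffness x overlap within 0.1%."""
        state = ColumnState(thickness0=2.5)
        d0 = 0.1
        for _ in range(400):
            state, trac = column_consolidation_step(state, cartilage, d0, 100.0)
        expected = drained_column_stiffness(cartilage, 2.5) * d0
        assert trac == pytest.approx(expected, rel=1e-3)
        assert np.max(state.pore_pressure) < 1e-6 * expected

    def test_terzaghi_series_32_layers(self, cartilage):
        """Step surface load: FD pore-pressure profile matches the
        closed-form consolidation series within 2% RMS at 32 layers."""
        N, h, q0 = 32, 2.5, 1.0
        H_A, _ = confined_moduli(cartilage)
        c_v = cartilage.permeability_mm * H_A
        pore = np.zeros(N + 1)
        trac = np.asarray(0.0)
        t = 0.0
        th = np.asarray(h)
        for Tv_target in (0.05, 0.2, 0.5):
            t_end = Tv_target * h**2 / c_v
            dt = (0.05 * h**2 / c_v) / 400
            while t < t_end - 1e-9:
                step = min(dt, t_end - t)
                pore, trac, _ = column_update(
                    cartilage, th, pore, trac, step, N, traction=q0
                )
                t += step
            z = np.linspace(0.0, h, N + 1)
            p_ref = oracles.terzaghi_pore_pressure(q0, c_v, h, z, t)
            rms = np.sqrt(np.mean((pore - p_ref) ** 2)) / q0
            assert rms < 0.02, f"Tv={Tv_target}: RMS {rms:.4f}"

    def test_traction_monotone_under_constant_overlap(self, cartilage):
        state = ColumnState(thickness0=2.5)
        tracs, totals = [], []
        for _ in range(50):
            state, trac = column_consolidation_step(state, cartilage, 0.2, 20.0)
            tracs.append(trac)
            totals.append(state.pore_pressure.sum())
        assert np.all(np.diff(tracs) <= 1e-12)
        assert np.all(np.diff(totals) <= 1e-12)

    def test_pore_pressure_nonnegative_under_compression(self, cartilage):
        state = ColumnState(thickness0=2.5)
        for d in (0.05, 0.12, 0.2, 0.2, 0.15):
            state, _ = column_consolidation_step(state, cartilage, d, 0.01)
            assert np.all(state.pore_pressure >= -1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        E_t=st.floats(0.35, 5.0),  # stays inside the PD bound for nu_tp=0.06
        perm=st.floats(0.2, 10.0),
        h=st.floats(1.5, 4.0),
        dt=st.floats(1e-3, 1.0),
    )
    def test_step_stiffness_at_least_drained(self, E_t, perm, h, dt):
        mat = MaterialTIPE(
            E_p=24.0, E_t=E_t, nu_p=0.42, nu_tp=0.06, G_t=12.0,
            permeability_k=perm, e0=4.0,
        )
        k_step = step_column_stiffness(mat, h, dt)
        k_drained = drained_column_stiffness(mat, h)
        assert k_step >= k_drained * (1.0 - 1e-9)

    def test_effective_stress_zero_at_rest(self, cartilage):
        state = ColumnState(thickness0=2.5)
        assert np.all(state.effective_stress(cartilage) == 0.0)

    def test_invalid_dt_rejected(self, cartilage):
        from kneesim.materials import column_affine_response

        with pytest.raises(ValueError):
            column_affine_response(
                cartilage, np.asarray(2.5), np.zeros(4), np.asarray(0.0), -1.0
            )
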