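"""Constitutive-model tests: homogenization, energies, stresses, shear."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.testing import assert_allclose

from cardiomech import materials as M
from cardiomech.materials import (
    ActiveParams,
    DeformationState,
    LocalFrame,
    PassiveParams,
    SHEAR_MODES,
)


def random_deformation(rng, scale=0.1):
    """Random F with J in a physiological band around 1."""
    while True:
        F = np.eye(3) + scale * rng.uniform(-1.0, 1.0, (3, 3))
        J = np.linalg.det(F)
        if 0.9 <= J <= 1.1:
            return F


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


class TestHomogenization:
    def test_healthy_recovers_baseline(self, shear_params):
        assert_allclose(
            M.homogenize_params(shear_params, 1.0), shear_params.a_coeffs
        )

    def test_infarct_scales_by_p(self, shear_params):
        assert_allclose(
            M.homogenize_params(shear_params, 0.0),
            shear_params.a_coeffs * shear_params.p,
        )

    def test_linear_midpoint(self):
        p = PassiveParams(2.0, 7.542, 3.465, 14.472, 0.481, 12.548,
                          0.283, 3.088)
        assert_allclose(M.homogenize_params(p, 0.5)[0], 5.56)

    def test_affine_in_h(self, shear_params, rng):
        h = rng.uniform(0.0, 1.0, 50)
        vals = M.homogenize_params(shear_params, h)
        # affine: value at h equals linear blend of the endpoint values
        lo = M.homogenize_params(shear_params, 0.0)
        hi = M.homogenize_params(shear_params, 1.0)
        assert_allclose(vals, np.outer(1 - h, lo) + np.outer(h, hi))

    def test_monotone_nonincreasing_in_h(self, shear_params):
        h = np.linspace(0.0, 1.0, 11)
        a_bar = M.homogenize_params(shear_params, h)[:, 0]
        assert np.all(np.diff(a_bar) <= 0.0)

    @pytest.mark.parametrize("h", [-0.1, 1.1])
    def test_h_domain_error(self, shear_params, h):
        with pytest.raises(ValueError):
            M.homogenize_params(shear_params, h)

    @settings(deadline=None, derandomize=True)
    @given(
        h=st.floats(0.0, 1.0),
        p=st.floats(1.0, 10.0),
        A=st.floats(0.01, 5.0),
    )
    def test_homogenization_bounds_property(self, h, p, A):
        """a·A ≤ ā ≤ a·A·p for any admissible (h, p, A)."""
        params = PassiveParams(1.05, 7.542, 3.465, 14.472, 0.481,
                               12.548, 0.283, 3.088, A=A, p=p)
        a_bar = M.homogenize_params(params, h)
        assert np.all(a_bar >= params.a_coeffs * A - 1e-12)
        assert np.all(a_bar <= params.a_coeffs * A * p + 1e-12)

    def test_subject_multiplier_applied_uniformly(self, shear_params):
        scaled = shear_params.scaled(1.69, 0.87)
        assert_allclose(
            M.homogenize_params(scaled, 0.7),
            1.69 * M.homogenize_params(shear_params, 0.7),
        )


class TestEnergies:
    def test_isochoric_reference_value(self, shear_params):
        state = DeformationState(np.eye(3))
        frame = LocalFrame.cardinal()
        w = M.isochoric_energy(state, frame, shear_params)
        assert_allclose(w, shear_params.a / (2 * shear_params.b))

    def test_fiber_compression_contributes_nothing(self, shear_params):
        F = np.diag([0.95, 1.0 / np.sqrt(0.95), 1.0 / np.sqrt(0.95)])
        frame = LocalFrame.cardinal()
        w = M.isochoric_energy(DeformationState(F), frame, shear_params)
        # same energy as an equal-I1 state with the fiber term removed
        soft = PassiveParams(
            shear_params.a, shear_params.b, 1e-12 + 1e-13, shear_params.b_f,
            shear_params.a_s, shear_params.b_s, shear_params.a_fs,
            shear_params.b_fs,
        )
        w_no_fiber = M.isochoric_energy(DeformationState(F), frame, soft)
        assert_allclose(w, w_no_fiber, rtol=1e-9)

    def test_fs_shear_energy_against_symbolic_oracle(self, shear_params):
        """Closed-form evaluation with sympy at γ = 0.1, mode fs."""
        import sympy as sp

        g = sp.Rational(1, 10)
        a, b = sp.Float(1.05), sp.Float(7.542)
        a_f, b_f = sp.Float(3.465), sp.Float(14.472)
        a_s, b_s = sp.Float(0.481), sp.Float(12.548)
        a_fs, b_fs = sp.Float(0.283), sp.Float(3.088)
        I1, I4f, I8 = 3 + g**2, 1 + g**2, g
        w_sym = (
            a / (2 * b) * sp.exp(b * (I1 - 3))
            + a_f / (2 * b_f) * (sp.exp(b_f * (I4f - 1) ** 2) - 1)
            + a_fs / (2 * b_fs) * (sp.exp(b_fs * I8**2) - 1)
        )
        F = M.shear_deformation_gradient("fs", 0.1)
        w = M.isochoric_energy(
            DeformationState(F), LocalFrame.cardinal(), shear_params
        )
        assert_allclose(w, float(w_sym.evalf(30)), rtol=1e-12)

    def test_volumetric_zero_and_stationary_at_identity(self):
        assert M.volumetric_energy(1.0, 0.2) == 0.0
        eps = 1e-6
        deriv = (
            M.volumetric_energy(1.0 + eps, 0.2)
            - M.volumetric_energy(1.0 - eps, 0.2)
        ) / (2 * eps)
        assert abs(deriv) < 1e-6

    def test_volumetric_scalar_value(self):
        # (1/0.2 MPa)·((1.21-1)/2 − ln 1.1) = 48.449 kPa
        assert_allclose(M.volumetric_energy(1.1, 0.2), 48.449101, rtol=1e-6)

    def test_volumetric_domain_error(self):
        with pytest.raises(ValueError):
            M.volumetric_energy(-0.5, 0.2)

    def test_bulk_modulus_from_curvature(self):
        # numerical curvature at J=1 equals 2/D = 10 MPa for D = 0.2 MPa^-1
        eps = 1e-4
        curv = (
            M.volumetric_energy(1 + eps, 0.2)
            - 2 * M.volumetric_energy(1.0, 0.2)
            + M.volumetric_energy(1 - eps, 0.2)
        ) / eps**2
        assert_allclose(curv, 10.0e3, rtol=1e-5)
        assert_allclose(PassiveParams(
            1, 1, 1, 1, 1, 1, 1, 1, D=0.2
        ).bulk_modulus_kpa, 1.0e4)

    def test_overflow_guard_names_term(self, shear_params):
        F = np.eye(3)
        F[0, 0] = 3.5  # extreme fiber stretch
        with pytest.raises(OverflowError, match="fiber"):
            M.isochoric_energy(
                DeformationState(F), LocalFrame.cardinal(), shear_params
            )


class TestPassiveStress:
    def test_stress_free_reference(self, shear_params):
        sig = M.passive_cauchy_stress(
            DeformationState(np.eye(3)), LocalFrame.cardinal(), shear_params
        )
        assert np.linalg.norm(sig) == 0.0

    def test_objectivity(self, shear_params, rng):
        frame = LocalFrame.cardinal()
        F = random_deformation(rng)
        sig = M.passive_cauchy_stress(DeformationState(F), frame,
                                      shear_params)
        for _ in range(100):
            Q = random_rotation(rng)
            sig_rot = M.passive_cauchy_stress(
                DeformationState(Q @ F), frame, shear_params
            )
            assert np.abs(sig_rot - Q @ sig @ Q.T).max() < 1e-8

    @pytest.mark.parametrize("h", [1.0, 0.4])
    def test_finite_difference_consistency(self, shear_params, rng, h):
        """Analytic Cauchy stress vs central differences of total energy."""
        frame = LocalFrame.cardinal()
        eps = 1e-5
        for _ in range(100):
            F = random_deformation(rng)
            state = DeformationState(F)
            sig = M.passive_cauchy_stress(state, frame, shear_params, h)
            P_fd = np.empty((3, 3))
            for i in range(3):
                for j in range(3):
                    for sgn, store in ((1, "p"), (-1, "m")):
                        Fp = F.copy()
                        Fp[i, j] += sgn * eps
                        w = M.isochoric_energy(
                            DeformationState(Fp), frame, shear_params, h
                        ) + M.volumetric_energy(
                            np.linalg.det(Fp), shear_params.D
                        )
                        if sgn == 1:
                            wp = w
                        else:
                            wm = w
                    P_fd[i, j] = (wp - wm) / (2 * eps)
            sig_fd = P_fd @ F.T / np.linalg.det(F)
            sig_fd = 0.5 * (sig_fd + sig_fd.T)
            err = np.abs(sig - sig_fd).max() / max(np.abs(sig).max(), 1.0)
            assert err < 1e-6

    def test_symmetry(self, shear_params, rng):
        F = random_deformation(rng)
        sig = M.passive_cauchy_stress(
            DeformationState(F), LocalFrame.cardinal(), shear_params
        )
        assert_allclose(sig, sig.T, atol=1e-12)

    def test_nonfinite_deformation_rejected(self):
        with pytest.raises(ValueError):
            DeformationState(np.full((3, 3), np.nan))


class TestActiveTension:
    def test_infarct_produces_zero(self):
        ap = ActiveParams()
        assert M.active_tension(100.0, 2.0, 0.0, ap) == 0.0

    def test_zero_phase_angle(self):
        ap = ActiveParams()
        assert M.active_tension(0.0, 2.0, 1.0, ap) == 0.0

    def test_peak_value_at_omega_pi(self):
        ap = ActiveParams()
        l = 2.0
        eca50 = ap.Ca0max / np.sqrt(np.expm1(ap.B_len * (l - ap.l0)))
        expected = ap.Tmax * ap.Ca0**2 / (ap.Ca0**2 + eca50**2)
        assert_allclose(M.active_tension(ap.t0, l, 1.0, ap), expected)

    def test_bounds_on_dense_grid(self):
        ap = ActiveParams()
        t = np.linspace(0.0, 1000.0, 201)
        l = np.linspace(1.6, 2.3, 29)
        tt, ll = np.meshgrid(t, l)
        Ta = M.active_tension(tt, ll, 1.0, ap)
        assert np.all(Ta >= 0.0)
        assert np.all(Ta <= ap.Tmax + 1e-12)
        h = 0.3
        Ta_h = M.active_tension(tt, ll, h, ap)
        assert np.all(Ta_h <= h * ap.Tmax + 1e-12)

    def test_outside_activation_window_zero(self):
        ap = ActiveParams()
        t_r = ap.m_slope * 2.0 + ap.b_intercept
        assert M.active_tension(ap.t0 + t_r + 1.0, 2.0, 1.0, ap) == 0.0

    def test_slack_sarcomere_warns_and_returns_zero(self):
        ap = ActiveParams()
        with pytest.warns(UserWarning, match="zero-tension"):
            assert M.active_tension(100.0, ap.l0 - 0.05, 1.0, ap) == 0.0

    def test_periodic_wrap(self):
        ap = ActiveParams()
        v1 = M.active_tension(100.0, 2.0, 1.0, ap)
        v2 = M.active_tension(100.0 + 780.0, 2.0, 1.0, ap, period=780.0)
        assert_allclose(v1, v2)


class TestTotalStress:
    def test_reduces_to_passive_without_tension(self, shear_params, rng):
        F = random_deformation(rng)
        frame = LocalFrame.cardinal()
        sig_t = M.total_stress(
            DeformationState(F), frame, shear_params, 1.0, 0.0, 0.3
        )
        sig_p = M.passive_cauchy_stress(
            DeformationState(F), frame, shear_params
        )
        assert_allclose(sig_t, sig_p)

    def test_trace_increment(self, shear_params, rng):
        F = random_deformation(rng)
        frame = LocalFrame.cardinal()
        Ta, n_s = 37.5, 0.07
        sig_t = M.total_stress(
            DeformationState(F), frame, shear_params, 1.0, Ta, n_s
        )
        sig_p = M.passive_cauchy_stress(
            DeformationState(F), frame, shear_params
        )
        assert_allclose(
            np.trace(sig_t) - np.trace(sig_p), Ta * (1 + n_s), rtol=1e-12
        )

    def test_sheet_receives_no_stress_when_ns_zero(self, shear_params):
        frame = LocalFrame.cardinal()
        sig = M.total_stress(
            DeformationState(np.eye(3)), frame, shear_params, 1.0, 50.0, 0.0
        )
        assert sig[1, 1] == 0.0
        assert sig[0, 0] == 50.0

    def test_negative_tension_rejected(self, shear_params):
        with pytest.raises(ValueError):
            M.total_stress(
                DeformationState(np.eye(3)), LocalFrame.cardinal(),
                shear_params, 1.0, -1.0, 0.0,
            )


class TestSimpleShear:
    def test_zero_at_reference(self, shear_params):
        for mode in SHEAR_MODES:
            assert M.simple_shear_curve(mode, [0.0], shear_params)[0] == 0.0

    def test_odd_symmetry(self, shear_params):
        g = np.linspace(0.05, 0.5, 6)
        for mode in SHEAR_MODES:
            plus = M.simple_shear_curve(mode, g, shear_params)
            minus = M.simple_shear_curve(mode, -g, shear_params)
            assert_allclose(minus, -plus, rtol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        gamma=st.floats(0.01, 0.5),
        mode=st.sampled_from(SHEAR_MODES),
    )
    def test_odd_symmetry_property(self, gamma, mode):
        params = M.HUMAN_SHEAR_PARAMS
        plus = M.simple_shear_curve(mode, [gamma], params)[0]
        minus = M.simple_shear_curve(mode, [-gamma], params)[0]
        assert plus > 0.0
        assert_allclose(minus, -plus, rtol=1e-12)

    def test_orthotropic_stiffness_ordering(self, shear_params):
        """f-normal > s-normal > n-normal at γ = 0.5."""
        at = {
            m: M.simple_shear_curve(m, [0.5], shear_params)[0]
            for m in SHEAR_MODES
        }
        assert min(at["fs"], at["fn"]) > max(at["sf"], at["sn"])
        assert min(at["sf"], at["sn"]) > max(at["nf"], at["ns"])

    def test_homogeneous_assembly_equivalence(self, shear_params):
        """Single-point value equals a 27-cell assembly under affine BCs.

        With uniform material and affine face displacement the
        deformation is spatially constant, so the volume-averaged stress
        over a 3×3×3 cell subdivision equals the single-point value.
        """
        gamma = 0.3
        F = M.shear_deformation_gradient("fs", gamma)
        centres = (np.arange(3) + 0.5) / 3.0
        sigs = []
        frame = LocalFrame.cardinal()
        for cx in centres:
            for cy in centres:
                for cz in centres:
                    X = np.array([cx, cy, cz])
                    # affine displacement u = (F - I) X: gradient is F - I
                    # everywhere, so each cell sees the same F
                    sigs.append(
                        M.passive_cauchy_stress(
                            DeformationState(F), frame, shear_params
                        )[1, 0]
                    )
        assert_allclose(
            np.mean(sigs),
            M.simple_shear_curve("fs", [gamma], shear_params)[0],
            rtol=1e-12,
        )

    def test_unknown_mode_lists_valid(self, shear_params):
        with pytest.raises(ValueError, match="fs, fn, sf, sn, nf, ns"):
            M.simple_shear_curve("xy", [0.1], shear_params)

    def test_gamma_range_enforced(self, shear_params):
        with pytest.raises(ValueError):
            M.simple_shear_curve("fs", [0.7], shear_params)

    def test_infarct_stiffens_shear(self, shear_params):
        healthy = M.simple_shear_curve("fs", [0.3], shear_params, h=1.0)[0]
        infarct = M.simple_shear_curve("fs", [0.3], shear_params, h=0.0)[0]
        assert_allclose(infarct / healthy, shear_params.p, rtol=1e-12)


class TestFrameAndStateValidation:
    def test_frame_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            LocalFrame(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]),
                       np.array([0, 0, 1.0]))

    def test_right_handedness_enforced(self):
        with pytest.raises(ValueError, match="right-handed"):
            LocalFrame(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                       np.array([0, 0, -1.0]))

    def test_from_fiber_sheet_orthonormalizes(self):
        fr = LocalFrame.from_fiber_sheet([2.0, 0, 0], [1.0, 1.0, 0])
        assert_allclose(fr.e_f, [1, 0, 0])
        assert_allclose(fr.e_s, [0, 1, 0])
        assert_allclose(fr.e_n, [0, 0, 1])

    def test_invariants_at_identity(self):
        inv = DeformationState(np.eye(3)).invariants(LocalFrame.cardinal())
        assert inv == {"I1": 3.0, "I4f": 1.0, "I4s": 1.0, "I8fs": 0.0}

    def test_negative_jacobian_rejected(self):
        with pytest.raises(ValueError):
            DeformationState(np.diag([-1.0, 1.0, 1.0]))

    def test_parameter_positivity(self):
        with pytest.raises(ValueError):
            PassiveParams(-1.0, 7.5, 3.4, 14.4, 0.5, 12.5, 0.3, 3.1)
        with pytest.raises(ValueError):
            ActiveParams(n_s=1.5)

    def test_extreme_D_warns(self):
        with pytest.warns(UserWarning, match="validated range"):
            PassiveParams(1, 1, 1, 1, 1, 1, 1, 1, D=0.01)
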