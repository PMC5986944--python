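"""Reduced-ventricle tests: geometry, kinematics, equilibrium, limits."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from cardiomech.materials import (
    ActiveParams,
    HUMAN_SHEAR_PARAMS,
    PassiveParams,
)
from cardiomech.ventricle import (
    VentricleModel,
    build_geometry,
    lvls,
)
from cardiomech.units import KPA_TO_MMHG


def isotropic_params(a=2.0, b=4.0):
    """Passive set with negligible anisotropic terms."""
    tiny = 1e-9
    return PassiveParams(a, b, tiny, 1.0, tiny, 1.0, tiny, 1.0)


class TestGeometry:
    def test_sphere_degenerate_volume(self):
        r = 20.0
        g = build_geometry(
            a_endo=r, c_endo=r, a_epi=r + 4, c_epi=r + 4, z_base=r + 4
        )
        assert_allclose(g.V0_mm3, 4.0 / 3.0 * np.pi * r**3, rtol=1e-12)

    def test_cavity_volume_monte_carlo(self, rng):
        g = build_geometry()
        n = 400000
        box_lo = np.array([-g.a_endo, -g.a_endo, -g.c_endo])
        box_hi = np.array([g.a_endo, g.a_endo, g.z_base])
        pts = rng.uniform(box_lo, box_hi, (n, 3))
        inside = (
            (pts[:, 0] ** 2 + pts[:, 1] ** 2) / g.a_endo**2
            + pts[:, 2] ** 2 / g.c_endo**2
        ) <= 1.0
        vol_box = np.prod(box_hi - box_lo)
        mc = vol_box * inside.mean()
        assert abs(mc - g.V0_mm3) / g.V0_mm3 < 1e-2  # MC noise ~0.3%

    def test_doubling_lengths_scales_volume_by_eight(self):
        g1 = build_geometry()
        g2 = build_geometry(
            a_endo=2 * g1.a_endo, c_endo=2 * g1.c_endo,
            a_epi=2 * g1.a_epi, c_epi=2 * g1.c_epi, z_base=2 * g1.z_base,
        )
        assert_allclose(g2.V0_mm3, 8.0 * g1.V0_mm3, rtol=1e-12)

    def test_quadrature_matches_wall_volume(self):
        g = build_geometry()
        assert abs(
            g.weights.sum() - g.wall_volume_mm3
        ) / g.wall_volume_mm3 < 5e-3

    def test_non_nested_surfaces_rejected(self):
        with pytest.raises(ValueError):
            build_geometry(a_endo=20.0, a_epi=15.0)

    def test_frames_orthonormal(self):
        g = build_geometry()
        for e in (g.e_f, g.e_s, g.e_n):
            assert_allclose(np.linalg.norm(e, axis=1), 1.0, atol=1e-9)
        assert np.abs(np.sum(g.e_f * g.e_s, axis=1)).max() < 1e-9
        assert_allclose(
            np.sum(np.cross(g.e_f, g.e_s) * g.e_n, axis=1), 1.0, atol=1e-9
        )

    def test_fiber_rule_endpoints(self):
        g = build_geometry(n_transmural=7)
        assert g.alpha_deg[np.argmin(g.depth)] > 50.0
        assert g.alpha_deg[np.argmax(g.depth)] < -50.0


class TestKinematics:
    def test_reference_state_is_identity(self):
        g = build_geometry()
        F = g.deformation_gradients(g.V0_ml, 1.0)
        assert np.abs(F - np.eye(3)).max() < 1e-8

    def test_isochoric_everywhere(self):
        g = build_geometry()
        for V, lam in ((25.0, 1.05), (45.0, 1.2), (12.0, 0.95)):
            J = np.linalg.det(g.deformation_gradients(V, lam))
            assert np.abs(J - 1.0).max() < 1e-8

    def test_shell_volume_conservation(self):
        """Enclosed volume of every transmural shell is conserved."""
        g = build_geometry()
        V, lam = 40.0, 1.1
        V_mm3 = V * 1000.0
        for xi in np.linspace(0.0, 1.0, 6):
            # enclosed volume via divergence theorem on the deformed shell
            u_b = min(g.z_base / g._axes(xi)[1], 1.0)
            u = np.linspace(-1.0, u_b, 2000)
            v = 2.0 * (u + 1.0) / (1.0 + u_b) - 1.0
            q = np.stack([np.full_like(v, xi), v, np.zeros_like(v)], axis=1)
            x = g.deformed_map(q, V_mm3, lam)
            r, z = x[:, 0], x[:, 2]
            vol = -np.pi * np.trapezoid(r**2, z)  # z decreases toward apex?
            vol = abs(vol)
            expected = V_mm3 + g._enclosed_ref(xi) - g.V0_mm3
            assert abs(vol - expected) / expected < 1e-4

    def test_cavity_volume_from_deformed_surface(self):
        """Meridian-profile oracle: V = ∫ π r(z)² dz over the deformed
        endocardial surface up to the base plane."""
        g = build_geometry()
        V, lam = 42.0, 1.12
        verts, _ = g.endocardial_surface(V, lam, n_u=4000, n_theta=4)
        meridian = verts.reshape(4000, 4, 3)[:, 0, :]
        r = np.hypot(meridian[:, 0], meridian[:, 1])
        z = meridian[:, 2]
        vol = np.pi * np.trapezoid(r**2, z)
        assert abs(vol - V * 1000.0) / (V * 1000.0) < 1e-3

    def test_shell_inversion_detected(self):
        g = build_geometry()
        with pytest.raises(RuntimeError, match="shell inversion"):
            g.deformation_gradients(0.5, 1.0)

    def test_thick_sphere_inflation_limit(self):
        """Spherical degenerate case tracks r³ = R³ + a³ − A³.

        The two-DOF family cannot represent the closed-sphere solution
        pointwise at the poles, so agreement is checked in the
        equatorial band at modest inflation (a few percent is the
        family's intrinsic fidelity there).
        """
        R_in, wall = 20.0, 1.0
        g = build_geometry(
            a_endo=R_in, c_endo=R_in, a_epi=R_in + wall, c_epi=R_in + wall,
            z_base=0.3 * R_in, n_transmural=3, n_longitudinal=6,
        )
        vm = VentricleModel(g, isotropic_params())
        V = 1.1 * g.V0_ml
        _, lam = vm.equilibrium_pressure(V)
        F = g.deformation_gradients(V, lam)
        hoop = np.einsum("ni,nij,nj->n", g.e_circ, F, g.e_circ)
        d = (V - g.V0_ml) * 1000.0 * 3.0 / (4.0 * np.pi)
        rho = np.linalg.norm(g.points, axis=1)
        classic = ((rho**3 + d) / rho**3) ** (1.0 / 3.0)
        band = np.abs(g.points[:, 2]) < 0.5 * R_in
        err = np.abs(hoop - classic)[band]
        assert err.mean() < 0.04
        assert err.max() < 0.05


class TestEquilibrium:
    def test_zero_pressure_at_reference(self, lv_geometry, shear_params):
        vm = VentricleModel(lv_geometry, shear_params)
        P, lam = vm.equilibrium_pressure(lv_geometry.V0_ml)
        assert abs(P) < 1e-6
        assert abs(lam - 1.0) < 1e-5

    def test_laplace_thin_wall_limit(self):
        """P within 5% of Laplace's law 2σt/r for a thin isotropic shell.

        Independent closed-form oracle: the equibiaxial membrane stress
        of the isotropic incompressible material at stretch
        s = (V/V0)^(1/3) (plane stress, σ = 2ψ1(s² − s⁻⁴)), with
        incompressible wall thinning t/s² and radius R·s.
        """
        R, t = 50.0, 1.0  # wall/radius = 0.02
        a_iso, b_iso = 2.0, 4.0
        g = build_geometry(
            a_endo=R, c_endo=R, a_epi=R + t, c_epi=R + t, z_base=0.3 * R,
            n_transmural=3, n_longitudinal=6,
        )
        vm = VentricleModel(g, isotropic_params(a_iso, b_iso))
        V = 1.1 * g.V0_ml
        P_mmhg, _ = vm.equilibrium_pressure(V)
        s = (V / g.V0_ml) ** (1.0 / 3.0)
        I1 = 2.0 * s**2 + s**-4
        sig_wall = a_iso * np.exp(b_iso * (I1 - 3.0)) * (s**2 - s**-4)
        P_laplace = 2.0 * sig_wall * (t / s**2) / (R * s) * KPA_TO_MMHG
        assert abs(P_mmhg - P_laplace) / P_laplace < 0.05

    def test_pressure_monotone_in_active_tension(self, shear_params):
        g = build_geometry(n_transmural=3, n_longitudinal=4)
        vm = VentricleModel(g, shear_params.scaled(0.1, 0.2))
        V = 1.5 * g.V0_ml
        pressures = []
        for Ta in (0.0, 5.0, 10.0, 20.0, 40.0):
            P, _ = vm.equilibrium_pressure(V, Ta)
            pressures.append(P)
        assert np.all(np.diff(pressures) > 0.0)

    def test_passive_curve_increasing_convex(self, shear_params):
        g = build_geometry(n_transmural=3, n_longitudinal=4)
        vm = VentricleModel(g, shear_params.scaled(0.1, 0.2))
        V = np.linspace(g.V0_ml, 2.8 * g.V0_ml, 12)
        curve = vm.passive_inflation_curve(V)
        P = curve[:, 1]
        assert P[0] == pytest.approx(0.0, abs=1e-6)
        assert np.all(np.diff(P) > 0.0)
        # convex beyond the low-pressure toe of the exponential response
        assert np.all(np.diff(P, 2)[1:] > 0.0)

    def test_a_scaling_homogeneity(self, shear_params):
        """Scaling all a-type terms by c scales P(V) by exactly c."""
        g = build_geometry(n_transmural=3, n_longitudinal=4)
        V = np.linspace(g.V0_ml, 2.0 * g.V0_ml, 5)
        base = VentricleModel(g, shear_params).passive_inflation_curve(V)
        c = 3.7
        scaled = VentricleModel(
            g, shear_params.scaled(c, 1.0)
        ).passive_inflation_curve(V)
        assert_allclose(scaled[:, 1], c * base[:, 1], rtol=1e-6)

    def test_b_scaling_stiffens(self, shear_params):
        g = build_geometry(n_transmural=3, n_longitudinal=4)
        V = np.linspace(g.V0_ml, 2.0 * g.V0_ml, 5)
        soft = VentricleModel(
            g, shear_params.scaled(1.0, 0.8)
        ).passive_inflation_curve(V)
        stiff = VentricleModel(
            g, shear_params.scaled(1.0, 1.2)
        ).passive_inflation_curve(V)
        assert np.all(stiff[1:, 1] >= soft[1:, 1])

    def test_inflate_deflate_loop_closes(self, shear_params):
        """∮P dV = 0 over a closed passive loop (path independence)."""
        g = build_geometry(n_transmural=3, n_longitudinal=4)
        vm = VentricleModel(g, shear_params.scaled(0.1, 0.2))
        V_up = np.linspace(g.V0_ml, 2.0 * g.V0_ml, 15)
        P_up = vm.passive_inflation_curve(V_up)[:, 1]
        # deflation pass with warm starts from the inflated state
        P_down = np.empty_like(P_up)
        lam = vm._lam_warm
        for i, V in enumerate(V_up[::-1]):
            P_down[i], lam = vm.equilibrium_pressure(V, 0.0, lam0=lam)
        work = np.trapezoid(P_up, V_up) + np.trapezoid(
            P_down, V_up[::-1]
        )
        scale = abs(np.trapezoid(P_up, V_up))
        assert abs(work) / scale < 1e-4

    def test_infarct_patch_reduces_ejection(self, shear_params):
        """A stiff non-contractile patch never increases ejected volume."""
        from cardiomech.circulation import CirculationParams, CoupledHeart

        def make_heart(h_fn):
            g_lv = build_geometry(
                n_transmural=3, n_longitudinal=4,
                n_circumferential=1 if h_fn is None else 8, h_fn=h_fn,
            )
            g_rv = build_geometry(
                a_endo=14.0, c_endo=42.0, a_epi=19.0, c_epi=47.0,
                z_base=10.0, n_transmural=3, n_longitudinal=4,
            )
            pp = shear_params.scaled(0.098, 0.1635)
            ap = ActiveParams(Tmax=85.0, n_s=0.07)
            return CoupledHeart(
                VentricleModel(g_lv, pp, ap),
                VentricleModel(g_rv, pp, ap),
                CirculationParams(kappa_p=8.0),
            )

        def infarct(points):
            centre = np.array([0.0, 17.0, -10.0])
            d = np.linalg.norm(points - centre, axis=1)
            return np.clip((d - 6.0) / 6.0, 0.0, 1.0)

        sv_healthy = make_heart(None).simulate(
            1, edv_lv=57.8, edv_rv=35.0, dt=4.0
        ).pv_loops()[0].sv
        sv_infarct = make_heart(infarct).simulate(
            1, edv_lv=57.8, edv_rv=35.0, dt=4.0
        ).pv_loops()[0].sv
        assert sv_infarct <= sv_healthy + 1e-9

    def test_rv_same_machinery(self, shear_params):
        g = build_geometry(
            a_endo=14.0, c_endo=42.0, a_epi=19.0, c_epi=47.0, z_base=10.0,
            n_transmural=3, n_longitudinal=4,
        )
        vm = VentricleModel(g, shear_params.scaled(0.1, 0.2))
        P, lam = vm.equilibrium_pressure(1.4 * g.V0_ml)
        assert P > 0.0


class TestLVLS:
    def test_constant_stretch(self):
        assert lvls(1.0, 1.0) == 0.0

    def test_shortening(self):
        assert_allclose(lvls(1.0, 0.85), 15.0)

    def test_elongation_negative(self):
        assert_allclose(lvls(1.0, 1.05), -5.0)
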