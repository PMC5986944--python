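"""Reduced-order thick-walled ventricle.

The ventricle is a thick-walled truncated prolate ellipsoid with a
transmural fiber rule and exactly two kinematic degrees of freedom: the
cavity volume V and the long-axis stretch λL.  The wall deforms by the
exactly incompressible axisymmetric map z = λL·Z, r² = R²/λL + φ0·g(Z)
(no torsion), whose Jacobian is identically one for any meridional
inflation profile g; the amplitude φ0 follows from the cavity volume in
closed form.  Every transmural shell therefore conserves its enclosed
volume (cavity plus inner wall material) exactly, and in the thin-walled
spherical limit the equilibrium deformation approaches the classic
incompressible thick-sphere inflation solution r³ ≈ R³ + a³ − A³.

Cavity pressure and the long-axis force balance follow from the virtual
work of the total (passive + active) Cauchy stress over a Gauss quadrature
of the wall:

    P = ∂W_int/∂V      at the λL that solves ∂W_int/∂λL = 0.

The volumetric penalty of the constitutive law is excluded from W_int
here: the two-DOF kinematics conserve shell volumes exactly by
construction, so incompressibility needs no penalty, and its exclusion
makes P(V) exactly homogeneous of degree one in the a-type coefficients.
Pointwise |J − 1| remains available as a kinematic diagnostic.

Geometry is in mm, volumes in ml at the interface (mm³ internally),
pressures in mmHg, stresses in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

from cardiomech import materials
from cardiomech.units import KPA_TO_MMHG, ML_TO_MM3, MM3_TO_ML

__all__ = [
    "VentricleGeometry",
    "VentricleModel",
    "build_geometry",
    "lvls",
]


def _cap_volume(a, c, zb):
    """Volume of the ellipsoid cap x²/a² + y²/a² + z²/c² <= 1, z <= zb."""
    zb = np.minimum(zb, c)
    return np.pi * a**2 * (zb - zb**3 / (3.0 * c**2) + 2.0 * c / 3.0)


def default_fiber_rule(depth, alpha_endo=60.0, alpha_epi=-60.0):
    """Linear transmural inclination-angle rule, degrees.

    ``depth`` is the normalized transmural coordinate: −1 endocardium,
    +1 epicardium.
    """
    w = (np.asarray(depth) + 1.0) / 2.0
    return alpha_endo + w * (alpha_epi - alpha_endo)


@dataclass
class VentricleGeometry:
    """Truncated prolate ellipsoid wall with quadrature and fiber frames.

    ``a_*``/``c_*`` are equatorial/long semi-axes (mm); the wall is
    truncated by the base plane z = z_base.  Quadrature points carry a
    reference position, local (circumferential, longitudinal, radial)
    directions, the fiber frame from the transmural angle rule, a tissue
    health value h and an integration weight in mm³.
    """

    a_endo: float
    c_endo: float
    a_epi: float
    c_epi: float
    z_base: float
    n_transmural: int = 5
    n_longitudinal: int = 8
    n_circumferential: int = 1
    # filled by build()
    V0_mm3: float = 0.0
    q: np.ndarray = field(default=None, repr=False)        # (N,3) chart coords
    points: np.ndarray = field(default=None, repr=False)   # (N,3) reference mm
    weights: np.ndarray = field(default=None, repr=False)  # (N,) mm^3
    depth: np.ndarray = field(default=None, repr=False)    # (N,) in [-1,1]
    alpha_deg: np.ndarray = field(default=None, repr=False)
    e_f: np.ndarray = field(default=None, repr=False)
    e_s: np.ndarray = field(default=None, repr=False)
    e_n: np.ndarray = field(default=None, repr=False)
    e_circ: np.ndarray = field(default=None, repr=False)
    e_long: np.ndarray = field(default=None, repr=False)
    h: np.ndarray = field(default=None, repr=False)

    @property
    def V0_ml(self) -> float:
        """Unloaded cavity volume (ml)."""
        return self.V0_mm3 * MM3_TO_ML

    @property
    def wall_volume_mm3(self) -> float:
        return float(
            _cap_volume(self.a_epi, self.c_epi, self.z_base) - self.V0_mm3
        )

    # -- shell interpolation ------------------------------------------------
    def _axes(self, xi):
        a = self.a_endo + xi * (self.a_epi - self.a_endo)
        c = self.c_endo + xi * (self.c_epi - self.c_endo)
        return a, c

    def _enclosed_ref(self, xi):
        a, c = self._axes(xi)
        return _cap_volume(a, c, self.z_base)

    # -- maps ---------------------------------------------------------------
    def reference_map(self, q):
        """Chart (ξ, v, θ) → reference position (mm)."""
        xi, v, th = q[..., 0], q[..., 1], q[..., 2]
        a, c = self._axes(xi)
        ub = np.minimum(self.z_base / c, 1.0)
        u = -1.0 + 0.5 * (v + 1.0) * (1.0 + ub)
        s = np.sqrt(np.maximum(1.0 - u * u, 0.0))
        return np.stack(
            [a * s * np.cos(th), a * s * np.sin(th), c * u], axis=-1
        )

    def _inflation_shape(self, Z):
        """Meridional inflation profile g(Z) = ((1 − Z²/c_endo²)₊)².

        Vanishes C¹-smoothly at and below the endocardial apex, so the
        solid apex column stays on the axis and no shear concentration
        appears where outer shells pass the endocardial pole.
        """
        e = np.maximum(1.0 - (Z / self.c_endo) ** 2, 0.0)
        return e * e

    def _inflation_shape_integral(self) -> float:
        """∫ g(Z) dZ from −c_endo to z_base (closed form)."""
        c = self.c_endo

        def antideriv(z):
            return z - 2 * z**3 / (3 * c**2) + z**5 / (5 * c**4)

        return antideriv(self.z_base) - antideriv(-c)

    def deform_positions(self, X, V_mm3, lam_l):
        """Apply the exactly incompressible two-DOF map to reference points.

        The deformation is

            z = λL·Z,     r² = R²/λL + φ0·g(Z),

        which has det F ≡ 1 for any meridional profile g(Z); the
        amplitude φ0 = (V − V0)/(π·λL·∫g dZ) delivers the requested
        cavity volume in closed form.  ``V_mm3`` and ``lam_l`` may be
        scalars or arrays broadcastable against the leading axes of
        ``X``.
        """
        X = np.asarray(X, dtype=float)
        R2 = X[..., 0] ** 2 + X[..., 1] ** 2
        Z = X[..., 2]
        phi0 = (V_mm3 - self.V0_mm3) / (
            np.pi * lam_l * self._inflation_shape_integral()
        )
        r2 = R2 / lam_l + phi0 * self._inflation_shape(Z)
        if np.any(r2 < 0.0):
            raise RuntimeError(
                "shell inversion: cavity volume too small for the wall"
            )
        scale = np.sqrt(r2 / np.maximum(R2, 1e-30))
        return np.stack(
            [scale * X[..., 0], scale * X[..., 1], lam_l * Z], axis=-1
        )

    def deformed_map(self, q, V_mm3, lam_l):
        """Chart → deformed position at cavity volume V and stretch λL."""
        return self.deform_positions(self.reference_map(q), V_mm3, lam_l)

    _CHART_STEP = 1e-6

    def _chart_cache(self):
        """Cached perturbed chart stack and inverse reference Jacobian."""
        if getattr(self, "_dXinv", None) is None:
            N = len(self.q)
            d = self._CHART_STEP
            pert = np.empty((3, 2, N, 3))
            for k in range(3):
                qp = self.q.copy()
                qm = self.q.copy()
                qp[:, k] += d
                qm[:, k] -= d
                pert[k, 0], pert[k, 1] = qp, qm
            dX = np.empty((N, 3, 3))
            for k in range(3):
                dX[:, :, k] = (
                    self.reference_map(pert[k, 0])
                    - self.reference_map(pert[k, 1])
                ) / (2 * d)
            self._q_pert = pert.reshape(6 * N, 3)
            self._X_pert = self.reference_map(self._q_pert)
            self._dXinv = np.linalg.inv(dX)
        return self._X_pert, self._dXinv

    def gradients_batch(self, V_ml, lam_l) -> np.ndarray:
        """F (S,N,3,3) for S kinematic states in one vectorized pass.

        F = (∂x/∂q)(∂X/∂q)⁻¹ with central finite differences in the chart
        coordinates; ``V_ml`` and ``lam_l`` are arrays of length S.
        """
        V_mm3 = np.atleast_1d(np.asarray(V_ml, dtype=float)) * ML_TO_MM3
        lam = np.atleast_1d(np.asarray(lam_l, dtype=float))
        S, N, d = len(V_mm3), len(self.q), self._CHART_STEP
        X_pert, dXinv = self._chart_cache()
        xs = self.deform_positions(
            X_pert[None], V_mm3[:, None], lam[:, None]
        ).reshape(S, 3, 2, N, 3)
        dx = (xs[:, :, 0] - xs[:, :, 1]) / (2 * d)  # (S,3dim_q,N,3dim_x)
        dx = np.moveaxis(dx, 1, 3)  # (S,N,3,3): dx[s,n,i,k]=∂x_i/∂q_k
        return dx @ dXinv

    def deformation_gradients(self, V_ml: float, lam_l: float) -> np.ndarray:
        """Per-quadrature-point F (N,3,3) at one kinematic state."""
        return self.gradients_batch([V_ml], [lam_l])[0]

    def endocardial_surface(
        self, V_ml: float, lam_l: float, n_u: int = 24, n_theta: int = 48
    ):
        """Triangulated deformed endocardial surface (vertices mm, faces).

        Open at the base plane; the apex pole is a shared vertex.
        """
        V_mm3 = V_ml * ML_TO_MM3
        ub = min(self.z_base / self.c_endo, 1.0)
        u = np.linspace(-1.0, ub, n_u)
        th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
        uu, tt = np.meshgrid(u, th, indexing="ij")
        v = 2.0 * (uu + 1.0) / (1.0 + ub) - 1.0
        q = np.stack([np.zeros_like(uu), v, tt], axis=-1)
        verts = self.deformed_map(q.reshape(-1, 3), V_mm3, lam_l)
        faces = []
        idx = lambda i, j: i * n_theta + (j % n_theta)
        for i in range(n_u - 1):
            for j in range(n_theta):
                faces.append([idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)])
                faces.append([idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)])
        return verts, np.array(faces, dtype=int)


def build_geometry(
    a_endo: float = 12.4,
    c_endo: float = 40.0,
    a_epi: float = 22.0,
    c_epi: float = 48.0,
    z_base: float = 10.0,
    *,
    n_transmural: int = 5,
    n_longitudinal: int = 8,
    n_circumferential: int = 1,
    fiber_rule: Callable | None = None,
    h_fn: Callable | None = None,
) -> VentricleGeometry:
    """Build a truncated-ellipsoid ventricular wall with Gauss quadrature.

    Defaults approximate a porcine LV with unloaded cavity volume near
    17.5 ml and ~10 mm wall.  ``fiber_rule`` maps the normalized
    transmural depth (−1 endo, +1 epi) to the inclination angle in degrees
    (default linear +60° → −60°); ``h_fn`` maps reference positions (N,3)
    to tissue health in [0,1] (default healthy).  Axisymmetric runs use a
    single circumferential station; supply ``n_circumferential=16`` when
    the h-field breaks axisymmetry.
    """
    if min(a_endo, c_endo, a_epi, c_epi, z_base) <= 0.0:
        raise ValueError("all geometric lengths must be > 0")
    if not (a_epi > a_endo and c_epi >= c_endo):
        raise ValueError("epicardial surface must enclose the endocardium")
    if z_base > c_epi:
        raise ValueError("base truncation must intersect the wall")

    geom = VentricleGeometry(
        a_endo, c_endo, a_epi, c_epi, z_base,
        n_transmural, n_longitudinal, n_circumferential,
    )
    geom.V0_mm3 = float(_cap_volume(a_endo, c_endo, z_base))

    # Gauss-Legendre in transmural and longitudinal chart coords, midpoint
    # in the (axisymmetric) circumferential coordinate.
    x_t, w_t = leggauss(geom.n_transmural)
    xi = 0.5 * (x_t + 1.0)
    w_xi = 0.5 * w_t
    v, w_v = leggauss(geom.n_longitudinal)
    nth = geom.n_circumferential
    th = (np.arange(nth) + 0.5) * 2.0 * np.pi / nth
    w_th = np.full(nth, 2.0 * np.pi / nth)

    Q, W = [], []
    for i, wx in enumerate(w_xi):
        for j, wv in enumerate(w_v):
            for k, wt in enumerate(w_th):
                Q.append([xi[i], v[j], th[k]])
                W.append(wx * wv * wt)
    geom.q = np.array(Q)
    chart_w = np.array(W)

    # metric: |det dX/dq| by central differences
    dX = np.empty((len(geom.q), 3, 3))
    for k in range(3):
        qp = geom.q.copy()
        qm = geom.q.copy()
        qp[:, k] += 1e-6
        qm[:, k] -= 1e-6
        dX[:, :, k] = (geom.reference_map(qp) - geom.reference_map(qm)) / 2e-6
    geom.weights = chart_w * np.abs(np.linalg.det(dX))
    geom.points = geom.reference_map(geom.q)

    wall = geom.wall_volume_mm3
    err = abs(geom.weights.sum() - wall) / wall
    if err > 5e-3:
        raise RuntimeError(
            f"quadrature weights miss the wall volume by {100 * err:.2f}%; "
            "increase quadrature orders"
        )

    # local directions and fiber frames
    th_q = geom.q[:, 2]
    e_c = np.stack([-np.sin(th_q), np.cos(th_q), np.zeros_like(th_q)], axis=1)
    # longitudinal: tangent along u at fixed xi, theta
    a_q, c_q = geom._axes(geom.q[:, 0])
    ub = np.minimum(geom.z_base / c_q, 1.0)
    u = -1.0 + 0.5 * (geom.q[:, 1] + 1.0) * (1.0 + ub)
    s = np.sqrt(np.maximum(1.0 - u * u, 1e-12))
    t_u = np.stack(
        [
            -a_q * u / s * np.cos(th_q),
            -a_q * u / s * np.sin(th_q),
            c_q,
        ],
        axis=1,
    )
    e_l = t_u / np.linalg.norm(t_u, axis=1, keepdims=True)
    e_r = np.cross(e_c, e_l)  # outward radial

    geom.depth = 2.0 * geom.q[:, 0] - 1.0
    rule = fiber_rule or default_fiber_rule
    geom.alpha_deg = np.asarray(rule(geom.depth), dtype=float)
    al = np.deg2rad(geom.alpha_deg)
    geom.e_circ, geom.e_long = e_c, e_l
    geom.e_f = np.cos(al)[:, None] * e_c + np.sin(al)[:, None] * e_l
    geom.e_s = e_r
    geom.e_n = np.cross(geom.e_f, geom.e_s)
    geom.h = (
        np.clip(np.asarray(h_fn(geom.points), dtype=float), 0.0, 1.0)
        if h_fn is not None
        else np.ones(len(geom.points))
    )
    return geom


class VentricleModel:
    """Mechanical ventricle: geometry + materials + quasistatic balance.

    ``equilibrium_pressure`` solves the long-axis generalized-force balance
    ∂W_int/∂λL = 0 for λL and returns the cavity pressure P = ∂W_int/∂V
    (mmHg) by quadrature of the stress-power conjugates.
    """

    #: relative DOF perturbations for the generalized-force derivatives
    _dv_rel = 1e-4
    _dlam = 1e-5

    def __init__(
        self,
        geometry: VentricleGeometry,
        passive: materials.PassiveParams,
        active: materials.ActiveParams | None = None,
        *,
        split_i1: bool = True,
        tension_only: bool = True,
    ):
        self.geometry = geometry
        self.passive = passive
        self.active = active or materials.ActiveParams()
        self.split_i1 = split_i1
        self.tension_only = tension_only
        self._lam_warm = 1.0

    # -- pointwise machinery ------------------------------------------------
    def stress_field(self, F: np.ndarray, Ta=0.0) -> np.ndarray:
        g = self.geometry
        return materials.stress_batch(
            F, g.e_f, g.e_s, self.passive, g.h, Ta=Ta, n_s=self.active.n_s,
            split_i1=self.split_i1, tension_only=self.tension_only,
            include_volumetric=False, validate=False,
        )

    def sarcomere_lengths(self, F: np.ndarray) -> np.ndarray:
        """l = lR·√I4f per quadrature point (µm)."""
        f = np.einsum("nij,nj->ni", F, self.geometry.e_f)
        return self.active.lR * np.linalg.norm(f, axis=1)

    def active_tension_field(self, t_ms: float, F: np.ndarray) -> np.ndarray:
        """Ta per point at phase time t, with sarcomere lengths from F."""
        import warnings as _w

        l = self.sarcomere_lengths(F)
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # transient slack sarcomeres are benign
            return materials.active_tension(
                t_ms, l, self.geometry.h, self.active
            )

    # -- generalized forces -------------------------------------------------
    def _long_axis_force(self, V_ml: float, lam_l: float, Ta) -> float:
        """∂W_int/∂λL (kPa·mm³): the long-axis generalized force."""
        g = self.geometry
        dl = self._dlam
        F_all = g.gradients_batch(
            [V_ml, V_ml, V_ml], [lam_l, lam_l + dl, lam_l - dl]
        )
        sig = self.stress_field(F_all[0], Ta)
        Finv = np.linalg.inv(F_all[0])
        dF_dl = (F_all[1] - F_all[2]) / (2 * dl)
        return float(
            np.einsum("n,nij,nij->", g.weights, sig, dF_dl @ Finv)
        )

    def _cavity_force(self, V_ml: float, lam_l: float, Ta) -> float:
        """∂W_int/∂V (kPa): the cavity pressure conjugate.

        Caches the equilibrium F field in ``self._last_F`` for reuse by
        the coupled simulation (sarcomere lengths of the next step).
        """
        g = self.geometry
        dv = max(self._dv_rel * g.V0_ml, 1e-6)
        F_all = g.gradients_batch(
            [V_ml, V_ml + dv, V_ml - dv], [lam_l, lam_l, lam_l]
        )
        F0 = F_all[0]
        self._last_F = F0
        sig = self.stress_field(F0, Ta)
        Finv = np.linalg.inv(F0)
        dF_dV = (F_all[1] - F_all[2]) / (2 * dv * ML_TO_MM3)
        return float(
            np.einsum("n,nij,nij->", g.weights, sig, dF_dV @ Finv)
        )

    def _generalized_forces(self, V_ml: float, lam_l: float, Ta):
        """(∂W/∂V in kPa, ∂W/∂λL in kPa·mm³) at the given state."""
        return (
            self._cavity_force(V_ml, lam_l, Ta),
            self._long_axis_force(V_ml, lam_l, Ta),
        )

    def equilibrium_pressure(
        self, V_ml: float, Ta=0.0, *, lam0: float | None = None
    ) -> tuple[float, float]:
        """Cavity pressure (mmHg) and equilibrium long-axis stretch.

        ``Ta`` is a scalar or per-point active-tension field (kPa).  Raises
        RuntimeError with the residual history if the λL root search fails.
        """
        lam = lam0 if lam0 is not None else self._lam_warm
        history = []

        def residual(l):
            G = self._long_axis_force(V_ml, l, Ta)
            history.append((l, G))
            return G

        # quasi-Newton from the warm start (slope carried across calls),
        # bracketed fallback
        slope = getattr(self, "_lam_slope", None)
        r = residual(lam)
        if slope is None or slope == 0.0:
            l1 = lam + 1e-5
            r1 = residual(l1)
            slope = (r1 - r) / 1e-5
            lam, r = l1, r1
        lam_sol = None
        for _ in range(30):
            if slope == 0.0 or not np.isfinite(slope):
                break
            step = -r / slope
            step = float(np.clip(step, -0.05, 0.05))
            lam_new = lam + step
            if not (0.3 < lam_new < 2.5):
                break
            if abs(step) < 3e-6:
                lam_sol = lam_new
                break
            r_new = residual(lam_new)
            # secant slope update only from steps above the FD noise floor
            if abs(step) > 3e-7 and r_new != r:
                slope = (r_new - r) / (lam_new - lam)
            lam, r = lam_new, r_new
            if r == 0.0:
                lam_sol = lam
                break
        if lam_sol is not None:
            self._lam_slope = slope
        if lam_sol is None:
            from scipy.optimize import brentq

            grid = np.linspace(0.6, 1.6, 21)
            vals = [residual(x) for x in grid]
            sign = np.sign(vals)
            idx = np.where(np.diff(sign) != 0)[0]
            if len(idx) == 0:
                raise RuntimeError(
                    "long-axis force balance has no root in [0.6, 1.6]; "
                    f"residual history: {history}"
                )
            lam_sol = brentq(
                residual, grid[idx[0]], grid[idx[0] + 1], xtol=1e-9
            )
        self._lam_warm = lam_sol
        P_kpa = self._cavity_force(V_ml, lam_sol, Ta)
        return P_kpa * KPA_TO_MMHG, lam_sol

    def passive_inflation_curve(self, V_grid_ml) -> np.ndarray:
        """Passive P(V) table: columns (V ml, P mmHg), warm-started in λL."""
        V_grid_ml = np.asarray(V_grid_ml, dtype=float)
        if np.any(np.diff(V_grid_ml) <= 0.0):
            raise ValueError("V_grid must be strictly increasing")
        out = np.empty((len(V_grid_ml), 2))
        lam = 1.0
        for i, V in enumerate(V_grid_ml):
            P, lam = self.equilibrium_pressure(V, 0.0, lam0=lam)
            out[i] = (V, P)
        return out

    def j_diagnostic(self, V_ml: float, lam_l: float) -> np.ndarray:
        """Pointwise |J − 1| of the kinematic ansatz (expected small)."""
        F = self.geometry.deformation_gradients(V_ml, lam_l)
        return np.abs(np.linalg.det(F) - 1.0)


def lvls(lam_ed: float, lam_es: float) -> float:
    """Left-ventricular long-axis shortening, percent.

    LVLS = 100·(L_ED − L_ES)/L_ED with base-to-apex length L ∝ λL;
    negative values indicate systolic elongation.
    """
    return 100.0 * (lam_ed - lam_es) / lam_ed
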