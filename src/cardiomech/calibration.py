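"""Three-stage material calibration.

Stage 1 (shear): the eight passive orthotropic parameters are fitted to
six-mode simple-shear stress data by bounded trust-region nonlinear least
squares,

    min_v1  Σ_modes Σ_j (σ_model − σ_data)²,   v1 = {a, b, a_f, b_f,
                                                     a_s, b_s, a_fs, b_fs}.

Stage 2 (passive scaling): uniform multipliers (A, B) of the a-type and
b-type coefficients are fitted so that the reduced ventricle's passive
inflation curve matches the single-beat Klotz end-diastolic pressure-
volume relation through the subject's (EDV, EDP) anchor,

    min_{A,B}  Σ_j (P_j − P̄_j)² + (EDV − ĒDV)².

Stage 3 (active): maximum tension Tmax and the cross-fiber fraction n_s
are fitted on the first simulated beat of the coupled closed-loop model so
the stroke volume matches its target, with long-axis shortening as a low-
weighted secondary target,

    min_{Tmax,n_s}  (SV − S̄V)² + 0.2·(LVLS − L̄VLS)².

Each stage is exposed as a model object whose ``fit()`` returns a
:class:`CalibrationResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from cardiomech import materials
from cardiomech.materials import PassiveParams, SHEAR_MODES
from cardiomech.ventricle import VentricleGeometry, VentricleModel

__all__ = [
    "ShearDataset",
    "KlotzTarget",
    "HemodynamicTargets",
    "CalibrationResult",
    "ShearCalibration",
    "PassiveScaling",
    "ActiveCalibration",
    "klotz_edpvr",
    "goodness_of_fit",
]

#: Empirical constants of the normalized end-diastolic PV relation
#: P = An * Vnorm**Bn (mmHg); overridable in :func:`klotz_edpvr`.
KLOTZ_AN = 28.2
KLOTZ_BN = 2.79

_SHEAR_PARAM_NAMES = ("a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs")


def goodness_of_fit(model_values, data_values) -> float:
    """Coefficient of determination R² = 1 − SS_res/SS_tot."""
    m = np.asarray(model_values, dtype=float).ravel()
    d = np.asarray(data_values, dtype=float).ravel()
    if m.shape != d.shape or len(d) < 2:
        raise ValueError("need equal-length arrays with at least 2 points")
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("data has zero variance; R^2 undefined")
    return 1.0 - float(np.sum((m - d) ** 2)) / ss_tot


@dataclass
class ShearDataset:
    """Six-mode simple-shear data: mode -> (strain amounts γ, stress kPa)."""

    curves: dict

    def __post_init__(self) -> None:
        missing = set(SHEAR_MODES) - set(self.curves)
        if missing:
            raise ValueError(f"missing shear modes: {sorted(missing)}")
        for mode, (g, s) in self.curves.items():
            g = np.asarray(g, dtype=float)
            s = np.asarray(s, dtype=float)
            if np.any(np.diff(g) <= 0.0):
                raise ValueError(f"gamma must be strictly increasing ({mode})")
            if g.shape != s.shape:
                raise ValueError(f"gamma/stress length mismatch ({mode})")
            self.curves[mode] = (g, s)

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.curves[m][1] for m in SHEAR_MODES])

    def to_frame(self):
        import pandas as pd

        rows = [
            (m, g, s)
            for m in SHEAR_MODES
            for g, s in zip(*self.curves[m])
        ]
        return pd.DataFrame(rows, columns=["mode", "gamma", "stress_kpa"])

    @classmethod
    def from_frame(cls, df) -> "ShearDataset":
        curves = {}
        for mode, grp in df.groupby("mode"):
            grp = grp.sort_values("gamma")
            curves[mode] = (
                grp["gamma"].to_numpy(), grp["stress_kpa"].to_numpy()
            )
        return cls(curves)


@dataclass(frozen=True)
class KlotzTarget:
    """Sampled single-beat EDPVR through one (EDV, EDP) anchor."""

    volumes: np.ndarray   # ml, spanning [V0, EDV]
    pressures: np.ndarray  # mmHg, non-decreasing, P(EDV) = EDP
    edv: float
    edp: float
    v0: float
    v30: float
    an: float = KLOTZ_AN
    bn: float = KLOTZ_BN


def klotz_edpvr(
    edv: float,
    edp: float,
    v0: float,
    n: int = 20,
    *,
    an: float = KLOTZ_AN,
    bn: float = KLOTZ_BN,
) -> KlotzTarget:
    """Analytic single-beat end-diastolic PV relation through (EDV, EDP).

    Uses the normalized-volume form P = An·V̄^Bn with
    V̄ = (V − V0)/(V30 − V0) and the single-beat estimate
    V30 = V0 + (EDV − V0)/(EDP/An)^(1/Bn), so the curve passes exactly
    through the anchor and is zero at the unloaded volume V0.
    """
    if edp <= 0.0:
        raise ValueError("EDP must be > 0")
    if v0 >= edv:
        raise ValueError("need V0 < EDV")
    if edp > 50.0:
        warnings.warn(
            "EDP above 50 mmHg is outside the empirical relation's "
            "validated range", stacklevel=2,
        )
    v30 = v0 + (edv - v0) / (edp / an) ** (1.0 / bn)
    volumes = np.linspace(v0, edv, n)
    vnorm = (volumes - v0) / (v30 - v0)
    pressures = an * vnorm**bn
    return KlotzTarget(volumes, pressures, edv, edp, v0, v30, an, bn)


@dataclass(frozen=True)
class HemodynamicTargets:
    """Subject hemodynamic calibration targets."""

    edv: float              # ml
    edp: float              # mmHg (assumed when no catheter value exists)
    sv: float               # ml
    lvls: float = 15.0      # %, low-weighted secondary target
    rv_edp: float = 4.0     # mmHg
    esv: float | None = None
    rv_edv: float | None = None

    def __post_init__(self) -> None:
        if self.esv is not None and abs(
            (self.edv - self.esv) - self.sv
        ) > 1e-6:
            raise ValueError("SV must equal EDV - ESV")
        if not 0.0 < self.ef < 1.0:
            raise ValueError("implied ejection fraction outside (0, 1)")

    @property
    def ef(self) -> float:
        return self.sv / self.edv


@dataclass
class CalibrationResult:
    """Outcome of one calibration stage.

    ``params`` maps parameter names to fitted values; ``objective`` is the
    final sum of squared residuals (never above ``initial_objective``).
    """

    params: dict
    objective: float
    initial_objective: float
    converged: bool
    n_evaluations: int
    r_squared: float | None = None
    message: str = ""
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"{'parameter':<12} {'estimate':>12}",
            "-" * 25,
        ]
        for k, v in self.params.items():
            lines.append(f"{k:<12} {v:>12.6g}")
        lines.append("-" * 25)
        lines.append(f"objective    {self.objective:>12.6g}")
        if self.r_squared is not None:
            lines.append(f"R^2          {self.r_squared:>12.6g}")
        lines.append(f"converged    {str(self.converged):>12}")
        lines.append(f"evaluations  {self.n_evaluations:>12d}")
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)


class ShearCalibration:
    """Stage-1 model: eight passive parameters from six-mode shear data.

    Forward model: :func:`cardiomech.materials.simple_shear_curve` at the
    data's strain amounts.  Bounded trust-region-reflective least squares.
    """

    def __init__(
        self,
        data: ShearDataset,
        init: dict | None = None,
        bounds: tuple = (1e-4, 1e3),
        **material_kwargs,
    ):
        self.data = data
        init = init or {
            k: getattr(materials.HUMAN_SHEAR_PARAMS, k)
            for k in _SHEAR_PARAM_NAMES
        }
        self.x0 = np.array([init[k] for k in _SHEAR_PARAM_NAMES])
        self.bounds = bounds
        self.material_kwargs = material_kwargs
        lo, hi = bounds
        if np.any(self.x0 < lo) or np.any(self.x0 > hi):
            raise ValueError("initial guess outside bounds")

    def _params(self, x) -> PassiveParams:
        return PassiveParams(**dict(zip(_SHEAR_PARAM_NAMES, x)))

    def model_curves(self, params: PassiveParams) -> np.ndarray:
        return np.concatenate(
            [
                materials.simple_shear_curve(
                    m, self.data.curves[m][0], params, **self.material_kwargs
                )
                for m in SHEAR_MODES
            ]
        )

    def _residuals(self, x) -> np.ndarray:
        return self.model_curves(self._params(x)) - self.data.stacked()

    def fit(self, max_iter: int = 200, ftol: float = 1e-10):
        r0 = self._residuals(self.x0)
        res = least_squares(
            self._residuals,
            self.x0,
            bounds=self.bounds,
            method="trf",
            x_scale=np.maximum(self.x0, 1e-3),
            max_nfev=max_iter * (len(self.x0) + 1),
            ftol=ftol,
            xtol=1e-12,
            gtol=1e-12,
        )
        fitted = self._params(res.x)
        r2 = goodness_of_fit(self.model_curves(fitted), self.data.stacked())
        return CalibrationResult(
            params=dict(zip(_SHEAR_PARAM_NAMES, res.x)),
            objective=float(2 * res.cost),
            initial_objective=float(np.sum(r0**2)),
            converged=bool(res.success),
            n_evaluations=int(res.nfev),
            r_squared=r2,
            message=res.message,
            extras={"passive_params": fitted},
        )


class PassiveScaling:
    """Stage-2 model: subject multipliers (A, B) against a Klotz target.

    Forward model: the reduced ventricle's passive inflation curve with
    the scaled parameters, evaluated at the Klotz sample volumes; the
    model EDV (volume where the curve reaches the target EDP) enters as an
    extra residual.  RV pressurization is represented by an optional
    trans-septal pressure offset on the LV curve (the reduced geometry has
    no shared septum), zero by default.
    """

    def __init__(
        self,
        geometry: VentricleGeometry,
        base_params: PassiveParams,
        klotz: KlotzTarget,
        *,
        rv_edp: float = 4.0,
        transseptal_coeff: float = 0.0,
    ):
        self.geometry = geometry
        self.base = base_params
        self.klotz = klotz
        self.rv_edp = rv_edp
        self.transseptal_coeff = transseptal_coeff

    def model(self, A: float, B: float) -> VentricleModel:
        return VentricleModel(self.geometry, self.base.scaled(A, B))

    def _forward(self, A: float, B: float):
        """(pressures at the Klotz volumes, achieved model EDV)."""
        vm = self.model(A, B)
        offset = self.transseptal_coeff * self.rv_edp
        vols = self.klotz.volumes.copy()
        vols[0] = max(vols[0], self.geometry.V0_ml)
        curve = vm.passive_inflation_curve(vols)
        P = curve[:, 1] + offset
        # extend until the target EDP is bracketed to locate model EDV
        v_hi, p_hi = vols[-1], P[-1]
        vols_ext, P_ext = list(vols), list(P)
        lam = vm._lam_warm
        while p_hi < self.klotz.edp and v_hi < 3.0 * self.klotz.edv:
            v_hi *= 1.05
            p, lam = vm.equilibrium_pressure(v_hi, 0.0, lam0=lam)
            vols_ext.append(v_hi)
            P_ext.append(p + offset)
            p_hi = P_ext[-1]
        edv_model = float(np.interp(self.klotz.edp, P_ext, vols_ext))
        return P, edv_model

    def _residuals(self, x) -> np.ndarray:
        try:
            P, edv_model = self._forward(*x)
        except (RuntimeError, OverflowError) as exc:  # penalized trial point
            warnings.warn(
                f"forward model failed at (A, B) = {tuple(x)}: {exc}",
                stacklevel=2,
            )
            big = 1e3 * (1.0 + abs(self.klotz.edp))
            return np.full(len(self.klotz.pressures) + 1, big)
        return np.concatenate(
            [P - self.klotz.pressures, [edv_model - self.klotz.edv]]
        )

    def fit(self, x0=(1.0, 1.0), bounds=((1e-3, 1e-2), (1e3, 10.0))):
        x0 = np.asarray(x0, dtype=float)
        r0 = self._residuals(x0)
        res = least_squares(
            self._residuals,
            x0,
            bounds=bounds,
            method="trf",
            diff_step=1e-4,
            ftol=1e-10,
            xtol=1e-10,
        )
        P, edv_model = self._forward(*res.x)
        r2 = goodness_of_fit(P, self.klotz.pressures)
        return CalibrationResult(
            params={"A": res.x[0], "B": res.x[1]},
            objective=float(2 * res.cost),
            initial_objective=float(np.sum(r0**2)),
            converged=bool(res.success),
            n_evaluations=int(res.nfev),
            r_squared=r2,
            message=res.message,
            extras={"achieved_edv": edv_model},
        )


class ActiveCalibration:
    """Stage-3 model: (Tmax, n_s) on the first beat of the coupled model.

    The forward model runs one active+filling cycle of the closed-loop
    coupled heart from the ED state (calibration on beat one); stroke
    volume and long-axis shortening come from that beat's PV loop.
    Forward-model failures at trial points are penalized, not fatal.
    Calibration beats default to a 2 ms step (the converged stroke
    volume is insensitive to halving the step, so the coarser
    calibration resolution is adequate).
    """

    def __init__(
        self,
        heart,
        targets: HemodynamicTargets,
        *,
        lvls_weight: float = 0.2,
        dt: float | None = 2.0,
    ):
        self.heart = heart
        self.targets = targets
        self.lvls_weight = lvls_weight
        self.dt = dt
        self._nfail = 0

    def _forward(self, tmax: float, n_s: float):
        for vent in (self.heart.lv, self.heart.rv):
            vent.active = replace(vent.active, Tmax=tmax, n_s=n_s)
        t = self.targets
        rv_edv = t.rv_edv if t.rv_edv is not None else 0.6 * t.edv
        beat = self.heart.first_beat(t.edv, rv_edv, dt=self.dt)
        loop = beat.pv_loops()[0]
        return loop.sv, loop.lvls_pct

    def _residuals(self, x) -> np.ndarray:
        w = np.sqrt(self.lvls_weight)
        try:
            sv, lv_short = self._forward(*x)
        except RuntimeError as exc:  # penalized trial point
            self._nfail += 1
            warnings.warn(f"forward model failed at {x}: {exc}", stacklevel=2)
            return np.array([10.0 * self.targets.sv, 10.0 * w * 100.0])
        return np.array(
            [sv - self.targets.sv, w * (lv_short - self.targets.lvls)]
        )

    def _bracket_tmax(self, n_s: float, tmax_lo=5.0, tmax_hi=400.0):
        """Locate Tmax delivering the target SV by bracketing + bisection.

        The stroke volume rises steeply once peak ventricular pressure
        crosses the afterload, so a gradient start far from that
        threshold sees a flat objective; a log-spaced scan followed by
        bisection on SV(Tmax) − S̄V is robust to the steepness.
        """
        target = self.targets.sv
        grid = np.geomspace(tmax_lo, tmax_hi, 8)
        t_lo = grid[0]
        t_hi = None
        for tm in grid:
            try:
                sv, _ = self._forward(tm, n_s)
            except RuntimeError:
                # ventricle emptied beyond the admissible range: treat a
                # failed forward run at high tension as an overshoot
                t_hi = tm
                break
            if sv < target:
                t_lo = tm
            else:
                t_hi = tm
                break
        if t_hi is None:
            return t_lo  # target unreachable; let the polish report it
        for _ in range(18):
            tm = 0.5 * (t_lo + t_hi)
            try:
                sv, _ = self._forward(tm, n_s)
            except RuntimeError:
                t_hi = tm
                continue
            if sv < target:
                t_lo = tm
            else:
                t_hi = tm
            if abs(sv - target) < 5e-3 * target:
                break
        return 0.5 * (t_lo + t_hi)

    def fit(self, x0=(60.0, 0.1), bounds=((1.0, 0.0), (500.0, 1.0)),
            n_passes: int = 2):
        """Bracket Tmax on the stroke-volume target, then polish (Tmax,
        n_s) by bounded trust-region least squares; the bracket+polish
        pair is repeated (``n_passes``) so a ridge-stalled first polish
        is restarted with the stroke-volume target re-bracketed at the
        updated n_s."""
        x0 = np.asarray(x0, dtype=float)
        r0 = self._residuals(x0)
        best = None
        ns = x0[1]
        for _ in range(n_passes):
            tmax0 = self._bracket_tmax(ns)
            res = least_squares(
                self._residuals,
                np.array([tmax0, ns]),
                bounds=bounds,
                method="trf",
                diff_step=(1e-2, 5e-2),
                ftol=1e-6,
                xtol=1e-8,
                max_nfev=8,
            )
            if best is None or res.cost < best.cost:
                best = res
            ns = res.x[1]
            if best.cost < 1e-12:
                break
        res = best
        sv, lv_short = self._forward(*res.x)
        return CalibrationResult(
            params={"Tmax": res.x[0], "n_s": res.x[1]},
            objective=float(2 * res.cost),
            initial_objective=float(np.sum(r0**2)),
            converged=bool(res.success),
            n_evaluations=int(res.nfev),
            message=res.message,
            extras={
                "achieved_sv": sv,
                "achieved_lvls": lv_short,
                "forward_failures": self._nfail,
            },
        )
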