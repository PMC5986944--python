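"""Closed-loop lumped-parameter circulation coupled to mechanical ventricles.

Three linear compliance compartments — systemic arteries (SA), systemic
veins (SV) and the pulmonary circuit (P) — are connected to the two
mechanical ventricles by five unidirectional resistive elements:

    P ──R_M──> LV ──R_A──> SA ──R_SYS──> SV ──R_T──> RV ──R_P──> P

Compartment pressures follow P = (V − V(0))/κ; flows are Ohmic,
Q = max(ΔP, 0)/R, hence strictly unidirectional.  Ventricular inflows
(R_M, R_T) are additionally gated shut during the entire active phase;
outflows are purely pressure-gated at all times.  Each cardiac cycle is
480 ms of active contraction followed by 300 ms of passive filling
(780 ms period, 77 bpm).  Volume updates are pairwise transfers, so total
circulatory volume is conserved to round-off by construction.

Pressures in mmHg, volumes in ml, times in ms, resistances in mmHg·ms/ml,
compliances in ml/mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cardiomech.ventricle import VentricleModel, lvls

__all__ = [
    "CirculationParams",
    "CirculationState",
    "PVLoop",
    "SimulationResult",
    "CoupledHeart",
    "compartment_pressure",
    "valve_flow",
]


@dataclass(frozen=True)
class CirculationParams:
    """Lumped circulation constants.

    Defaults target physiological porcine hemodynamics at the study scale
    (MAP ≈ 90 mmHg, pulse pressure ≈ 40 mmHg for a ~31 ml stroke volume,
    central venous ≈ 5 mmHg); the compartment reference volumes ``V0_*``
    set absolute volume levels only and drop out of all pressure
    differences.
    """

    kappa_sa: float = 0.8      # ml/mmHg
    kappa_sv: float = 25.0
    kappa_p: float = 8.0
    R_M: float = 40.0          # mmHg*ms/ml, mitral (P -> LV)
    R_A: float = 60.0          # aortic (LV -> SA)
    R_SYS: float = 2000.0      # systemic (SA -> SV)
    R_T: float = 40.0          # tricuspid (SV -> RV)
    R_P: float = 50.0          # pulmonary valve (RV -> P)
    V0_sa: float = 60.0        # ml, zero-pressure volumes
    V0_sv: float = 250.0
    V0_p: float = 80.0
    P_sa_ed: float = 80.0      # mmHg, ED initialization pressures
    P_sv_ed: float = 6.0
    P_p_ed: float = 12.0
    T_active: float = 480.0    # ms
    T_fill: float = 300.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kappa_sa", "kappa_sv", "kappa_p",
                     "R_M", "R_A", "R_SYS", "R_T", "R_P", "dt"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")

    @property
    def period(self) -> float:
        return self.T_active + self.T_fill

    @property
    def heart_rate_bpm(self) -> float:
        return 60000.0 / self.period


@dataclass
class CirculationState:
    """Volumes of the five fluid chambers plus clock and phase."""

    V_lv: float
    V_rv: float
    V_sa: float
    V_sv: float
    V_p: float
    t: float = 0.0

    @property
    def total_volume(self) -> float:
        return self.V_lv + self.V_rv + self.V_sa + self.V_sv + self.V_p

    def copy(self) -> "CirculationState":
        return replace(self)


def compartment_pressure(V: float, V0: float, kappa: float) -> float:
    """Linear compliance-vessel pressure P = (V − V0)/κ (mmHg)."""
    if kappa <= 0.0:
        raise ValueError("compliance must be > 0")
    return (V - V0) / kappa


def valve_flow(P_up: float, P_down: float, R: float, open_: bool = True):
    """Unidirectional Ohmic flow Q = max(P_up − P_down, 0)/R (ml/ms)."""
    if R <= 0.0:
        raise ValueError("resistance must be > 0")
    if not open_:
        return 0.0
    return max(P_up - P_down, 0.0) / R


@dataclass
class PVLoop:
    """One cardiac cycle of ventricular pressure-volume history."""

    cycle: int
    t: np.ndarray
    V_lv: np.ndarray
    P_lv: np.ndarray
    V_rv: np.ndarray
    P_rv: np.ndarray
    lam_lv: np.ndarray

    @property
    def edv(self) -> float:
        return float(self.V_lv[0])

    @property
    def esv(self) -> float:
        return float(self.V_lv.min())

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    @property
    def ef(self) -> float:
        return self.sv / self.edv

    @property
    def lvls_pct(self) -> float:
        i_es = int(np.argmin(self.V_lv))
        return lvls(float(self.lam_lv[0]), float(self.lam_lv[i_es]))

    def corners(self) -> dict:
        """Indices of the four labeled PV-loop corners, in cycle order:
        end diastole, start ejection, end systole, end relaxation."""
        i_ed = 0
        dV = np.diff(self.V_lv)
        ejecting = np.where(dV < -1e-9)[0]
        i_se = int(ejecting[0]) if len(ejecting) else i_ed
        i_es = int(np.argmin(self.V_lv))
        filling = np.where(dV[i_es:] > 1e-9)[0]
        i_er = int(i_es + filling[0]) if len(filling) else len(self.t) - 1
        return {"ED": i_ed, "SE": i_se, "ES": i_es, "ER": i_er}


class SimulationResult:
    """Per-step history of a multi-cycle closed-loop run.

    Provides per-cycle PV loops, hemodynamic summaries and the limit-cycle
    convergence metric (relative SV change between the last two cycles).
    """

    def __init__(self, params: CirculationParams, history: dict):
        self.params = params
        self.history = {k: np.asarray(v) for k, v in history.items()}

    def to_frame(self) -> pd.DataFrame:
        h = self.history
        return pd.DataFrame(
            {
                "cycle": h["cycle"].astype(int),
                "t_ms": h["t"],
                "V_lv_ml": h["V_lv"],
                "P_lv_mmHg": h["P_lv"],
                "V_rv_ml": h["V_rv"],
                "P_rv_mmHg": h["P_rv"],
            }
        )

    def pv_loops(self) -> list[PVLoop]:
        h = self.history
        loops = []
        for c in np.unique(h["cycle"].astype(int)):
            m = h["cycle"] == c
            loops.append(
                PVLoop(
                    int(c), h["t"][m], h["V_lv"][m], h["P_lv"][m],
                    h["V_rv"][m], h["P_rv"][m], h["lam_lv"][m],
                )
            )
        return loops

    @property
    def volume_drift_ml(self) -> float:
        """|ΣV(end) − ΣV(start)| over the whole run (ml)."""
        tot = self.history["V_total"]
        return float(abs(tot[-1] - tot[0]))

    @property
    def sv_convergence(self) -> float:
        """Relative SV change between the last two cycles."""
        loops = self.pv_loops()
        if len(loops) < 2:
            return np.nan
        return abs(loops[-1].sv - loops[-2].sv) / loops[-2].sv

    def summary(self) -> str:
        lines = [
            "Closed-loop simulation "
            f"({self.params.heart_rate_bpm:.0f} bpm, dt={self.params.dt} ms)",
            f"{'cycle':>5} {'EDV':>8} {'ESV':>8} {'SV':>8} {'EF':>7} "
            f"{'LVLS%':>7}",
        ]
        for lp in self.pv_loops():
            lines.append(
                f"{lp.cycle:>5} {lp.edv:>8.2f} {lp.esv:>8.2f} "
                f"{lp.sv:>8.2f} {lp.ef:>7.3f} {lp.lvls_pct:>7.2f}"
            )
        lines.append(f"volume drift: {self.volume_drift_ml:.3g} ml")
        if len(self.pv_loops()) > 1:
            lines.append(f"SV convergence: {100 * self.sv_convergence:.3f}%")
        return "\n".join(lines)

    def plot_pv(self, ax=None):
        """PV loops for all cycles, final cycle highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        loops = self.pv_loops()
        for lp in loops[:-1]:
            ax.plot(lp.V_lv, lp.P_lv, color="0.7", lw=0.8)
        ax.plot(loops[-1].V_lv, loops[-1].P_lv, color="k", lw=1.5)
        ax.set_xlabel("LV volume (ml)")
        ax.set_ylabel("LV pressure (mmHg)")
        return ax


class CoupledHeart:
    """Two mechanical ventricles coupled to the closed-loop circulation.

    The model object binds LV and RV :class:`VentricleModel` instances and
    a :class:`CirculationParams` set; ``simulate`` integrates n cardiac
    cycles with explicit Euler (phase boundaries fall on exact step
    multiples) and returns a :class:`SimulationResult`.  Active tension in
    a step uses sarcomere lengths from the previous step's equilibrium
    deformation (explicit staggered coupling).
    """

    def __init__(
        self,
        lv: VentricleModel,
        rv: VentricleModel,
        params: CirculationParams | None = None,
    ):
        self.lv = lv
        self.rv = rv
        self.params = params or CirculationParams()

    def initial_state(
        self, edv_lv: float, edv_rv: float
    ) -> CirculationState:
        """End-diastolic start: each compliance vessel loaded to its ED
        pressure by inverting P = (V − V0)/κ; ventricles at their EDVs."""
        p = self.params
        return CirculationState(
            V_lv=edv_lv,
            V_rv=edv_rv,
            V_sa=p.V0_sa + p.kappa_sa * p.P_sa_ed,
            V_sv=p.V0_sv + p.kappa_sv * p.P_sv_ed,
            V_p=p.V0_p + p.kappa_p * p.P_p_ed,
        )

    def _ventricular_pressures(self, state: CirculationState, tc: float):
        """Equilibrium LV/RV pressures at within-cycle time tc."""
        active = tc < self.params.T_active
        out = []
        for vent, V in ((self.lv, state.V_lv), (self.rv, state.V_rv)):
            if active:
                F_prev = getattr(vent, "_last_F", None)
                if F_prev is None:
                    F_prev = vent.geometry.deformation_gradients(
                        V, vent._lam_warm
                    )
                Ta = vent.active_tension_field(tc, F_prev)
            else:
                Ta = 0.0
            P, lam = vent.equilibrium_pressure(V, Ta)
            out.append((P, lam))
        return out[0], out[1], active

    def step(
        self, state: CirculationState, dt: float | None = None
    ) -> CirculationState:
        """Advance the five chamber volumes by one explicit-Euler step."""
        new, _ = self._advance(state, dt)
        return new

    def _advance(self, state: CirculationState, dt: float | None = None):
        """One explicit-Euler step; returns (new state, step record)."""
        p = self.params
        dt = dt if dt is not None else p.dt
        if dt <= 0.0:
            raise ValueError("dt must be > 0")
        tc = state.t % p.period
        (P_lv, lam_lv), (P_rv, lam_rv), active = (
            self._ventricular_pressures(state, tc)
        )
        P_sa = compartment_pressure(state.V_sa, p.V0_sa, p.kappa_sa)
        P_sv = compartment_pressure(state.V_sv, p.V0_sv, p.kappa_sv)
        P_p = compartment_pressure(state.V_p, p.V0_p, p.kappa_p)

        Q_m = valve_flow(P_p, P_lv, p.R_M, open_=not active)
        Q_a = valve_flow(P_lv, P_sa, p.R_A)
        Q_sys = valve_flow(P_sa, P_sv, p.R_SYS)
        Q_t = valve_flow(P_sv, P_rv, p.R_T, open_=not active)
        Q_pv = valve_flow(P_rv, P_p, p.R_P)

        new = state.copy()
        new.V_lv += dt * (Q_m - Q_a)
        new.V_sa += dt * (Q_a - Q_sys)
        new.V_sv += dt * (Q_sys - Q_t)
        new.V_rv += dt * (Q_t - Q_pv)
        new.V_p += dt * (Q_pv - Q_m)
        new.t = state.t + dt
        for name in ("V_lv", "V_rv", "V_sa", "V_sv", "V_p"):
            if getattr(new, name) < 0.0:
                raise RuntimeError(
                    f"negative volume in {name}: unphysical circulation "
                    "parameters or too large a time step"
                )
        record = {
            "t": state.t,
            "cycle": int(state.t // p.period) + 1,
            "V_lv": state.V_lv,
            "P_lv": P_lv,
            "V_rv": state.V_rv,
            "P_rv": P_rv,
            "lam_lv": lam_lv,
            "lam_rv": lam_rv,
            "V_total": state.total_volume,
            "phase_active": active,
        }
        return new, record

    def simulate(
        self,
        n_cycles: int = 6,
        *,
        initial: CirculationState | None = None,
        edv_lv: float | None = None,
        edv_rv: float | None = None,
        dt: float | None = None,
    ) -> SimulationResult:
        """Run n cardiac cycles from an end-diastolic initial state."""
        p = self.params
        dt = dt if dt is not None else p.dt
        if initial is None:
            if edv_lv is None or edv_rv is None:
                raise ValueError("provide either initial state or EDVs")
            initial = self.initial_state(edv_lv, edv_rv)
        state = initial.copy()
        # reset warm starts so repeated simulations are reproducible
        for vent in (self.lv, self.rv):
            vent._lam_warm = 1.0
            vent._last_F = None

        n_steps = int(round(n_cycles * p.period / dt))
        keys = (
            "t", "cycle", "V_lv", "P_lv", "V_rv", "P_rv", "lam_lv",
            "lam_rv", "V_total", "phase_active",
        )
        hist = {k: [] for k in keys}
        for _ in range(n_steps):
            state, rec = self._advance(state, dt)
            for k in keys:
                hist[k].append(rec[k])
        # closing sample at the final time
        _, rec = self._advance(state, dt)
        rec["cycle"] = hist["cycle"][-1]
        for k in keys:
            hist[k].append(rec[k])
        return SimulationResult(replace(self.params, dt=dt), hist)

    def first_beat(
        self, edv_lv: float, edv_rv: float, dt: float | None = None
    ) -> SimulationResult:
        """Single calibration beat from the ED state (active + filling)."""
        return self.simulate(1, edv_lv=edv_lv, edv_rv=edv_rv, dt=dt)
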