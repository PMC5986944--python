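"""Orthotropic myocardium constitutive model with infarct homogenization.

Passive behaviour follows the Holzapfel–Ogden strain-energy function for
myocardium, written in terms of the isochoric isotropic invariant and the
fiber/sheet pseudo-invariants, with every linear (a-type) coefficient
homogenized between its healthy value and a pathologically stiffened value
through a tissue-health scalar ``h``::

    a_bar_i = a_i * A * [h + (1 - h) * p]

so that fully healthy tissue (h = 1) recovers ``a_i * A`` and fully
infarcted tissue (h = 0) is ``p`` times stiffer.  ``A`` and ``B`` are
subject-specific uniform multipliers of the a-type and b-type coefficients
determined in the second calibration stage.

Active contraction uses a time-varying elastance law: developed tension is
the maximum tension scaled by a calcium-sensitivity factor (dependent on
sarcomere length through the length-dependent calcium sensitivity ECa50)
and a cosine time course, and is multiplied by ``h`` so infarcted tissue
cannot contract.  Active stress acts along the deformed fiber direction,
with a fraction ``n_s`` transferred to the sheet direction.

Units: stresses and energy densities in kPa, lengths in µm (sarcomere) or
mm (continuum), times in ms.  The volumetric penalty coefficient ``D``
carries MPa⁻¹ (see :class:`PassiveParams`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PassiveParams",
    "ActiveParams",
    "LocalFrame",
    "DeformationState",
    "HUMAN_SHEAR_PARAMS",
    "DEFAULT_PATHOLOGICAL_RATIO",
    "SHEAR_MODES",
    "homogenize_params",
    "isochoric_energy",
    "volumetric_energy",
    "passive_cauchy_stress",
    "active_tension",
    "total_stress",
    "simple_shear_curve",
]

#: Infarct-to-remote passive stiffness ratio applied to all a-type terms.
DEFAULT_PATHOLOGICAL_RATIO = 4.56

#: Valid simple-shear mode names: "ij" = faces with normal e_i displaced
#: along e_j (f = fiber, s = sheet, n = sheet-normal).
SHEAR_MODES = ("fs", "fn", "sf", "sn", "nf", "ns")

_AXIS = {"f": 0, "s": 1, "n": 2}
_MAX_EXPONENT = 700.0


def _check_exponent(arg, term: str) -> None:
    if np.any(np.asarray(arg) > _MAX_EXPONENT):
        raise OverflowError(
            f"exponent overflow in strain-energy term '{term}' "
            f"(argument > {_MAX_EXPONENT:g}); check material parameters"
        )


@dataclass(frozen=True)
class PassiveParams:
    """Passive orthotropic parameters.

    a-type values in kPa, b-type dimensionless, ``D`` in MPa⁻¹ (the
    volumetric penalty 1/D·((J²−1)/2 − ln J) then has units of MPa; it is
    converted to kPa internally).  ``A``/``B`` are the uniform subject
    multipliers of a-type/b-type coefficients; ``p`` is the pathological
    stiffness ratio of fully infarcted tissue.
    """

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float
    b_s: float
    a_fs: float
    b_fs: float
    D: float = 0.2
    A: float = 1.0
    B: float = 1.0
    p: float = DEFAULT_PATHOLOGICAL_RATIO

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"passive parameter {name} must be > 0")
        if self.p < 1.0:
            raise ValueError("pathological ratio p must be >= 1")
        if self.A <= 0.0 or self.B <= 0.0:
            raise ValueError("subject multipliers A and B must be > 0")
        if self.D <= 0.0:
            raise ValueError("volumetric coefficient D must be > 0")
        if not (0.02 < self.D < 20.0):
            warnings.warn(
                f"D = {self.D} MPa^-1 lies outside the validated range "
                "(0.02, 20); near-incompressibility may be compromised",
                stacklevel=3,
            )

    @property
    def a_coeffs(self) -> np.ndarray:
        return np.array([self.a, self.a_f, self.a_s, self.a_fs])

    @property
    def b_coeffs(self) -> np.ndarray:
        """b-type coefficients with the subject multiplier B applied."""
        return self.B * np.array([self.b, self.b_f, self.b_s, self.b_fs])

    @property
    def bulk_modulus_kpa(self) -> float:
        """Small-strain bulk modulus 2/D of the volumetric penalty, in kPa."""
        return 2.0e3 / self.D

    def scaled(self, A: float, B: float) -> "PassiveParams":
        """Return a copy with the subject multipliers replaced."""
        return replace(self, A=A, B=B)


#: Parameter set calibrated against human triaxial simple-shear data.
HUMAN_SHEAR_PARAMS = PassiveParams(
    a=1.05, b=7.542, a_f=3.465, b_f=14.472,
    a_s=0.481, b_s=12.548, a_fs=0.283, b_fs=3.088,
)


@dataclass(frozen=True)
class ActiveParams:
    """Time-varying elastance active-tension parameters.

    ``Tmax`` (kPa) and ``n_s`` are the subject-calibrated quantities.  The
    remaining internals are literature defaults of the underlying elastance
    model, all overridable: calcium amplitudes ``Ca0``/``Ca0max`` (µM),
    length-sensitivity ``B_len`` (µm⁻¹), zero-tension sarcomere length
    ``l0`` (µm), unloaded reference length ``lR`` (µm), time-to-peak ``t0``
    (ms) and the linear relaxation-duration law t_r = m_slope·l +
    b_intercept (ms).
    """

    Tmax: float = 118.0
    n_s: float = 0.07
    Ca0: float = 4.35
    Ca0max: float = 4.35
    B_len: float = 4.75
    l0: float = 1.58
    lR: float = 1.85
    t0: float = 160.0
    m_slope: float = 524.45
    b_intercept: float = -714.5

    def __post_init__(self) -> None:
        if self.Tmax < 0.0:
            raise ValueError("Tmax must be >= 0")
        if not 0.0 <= self.n_s <= 1.0:
            raise ValueError("n_s must lie in [0, 1]")
        if not self.lR > self.l0 > 0.0:
            raise ValueError("need lR > l0 > 0")


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal material frame (fiber, sheet, sheet-normal)."""

    e_f: np.ndarray
    e_s: np.ndarray
    e_n: np.ndarray

    def __post_init__(self) -> None:
        for name in ("e_f", "e_s", "e_n"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")
        if (
            abs(self.e_f @ self.e_s) > 1e-9
            or abs(self.e_f @ self.e_n) > 1e-9
            or abs(self.e_s @ self.e_n) > 1e-9
        ):
            raise ValueError("frame vectors must be pairwise orthogonal")
        if np.cross(self.e_f, self.e_s) @ self.e_n <= 0.0:
            raise ValueError("frame must be right-handed (e_f x e_s . e_n > 0)")

    @classmethod
    def from_fiber_sheet(cls, fiber, sheet) -> "LocalFrame":
        """Orthonormalize a fiber/sheet pair into a right-handed frame."""
        f = np.asarray(fiber, dtype=float)
        f = f / np.linalg.norm(f)
        s = np.asarray(sheet, dtype=float)
        s = s - (s @ f) * f
        n = np.linalg.norm(s)
        if n < 1e-12:
            raise ValueError("sheet direction parallel to fiber direction")
        s = s / n
        return cls(f, s, np.cross(f, s))

    @classmethod
    def cardinal(cls) -> "LocalFrame":
        return cls(np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])


@dataclass
class DeformationState:
    """Deformation gradient with derived invariants relative to a frame."""

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F contains non-finite entries")
        if self.J <= 0.0:
            raise ValueError(f"det F = {self.J:g} must be > 0")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    def invariants(self, frame: LocalFrame) -> dict:
        C = self.C
        return {
            "I1": float(np.trace(C)),
            "I4f": float(frame.e_f @ C @ frame.e_f),
            "I4s": float(frame.e_s @ C @ frame.e_s),
            "I8fs": float(frame.e_f @ C @ frame.e_s),
        }


def homogenize_params(params: PassiveParams, h) -> np.ndarray:
    """Effective a-type coefficients (ā, ā_f, ā_s, ā_fs) at tissue health h.

    ā_i = a_i · A · [h + (1 − h) p]; affine in h, equal to a_i·A at h = 1
    and to a_i·A·p at h = 0.  Accepts scalar or array h.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0.0) or np.any(h > 1.0):
        raise ValueError("tissue health h must lie in [0, 1]")
    factor = params.A * (h + (1.0 - h) * params.p)
    return np.multiply.outer(factor, params.a_coeffs) if h.ndim else (
        factor * params.a_coeffs
    )


def _energy_terms(I1_bar, I4f, I4s, I8fs, a_eff, b_eff, tension_only=True):
    a, af, as_, afs = a_eff
    b, bf, bs, bfs = b_eff
    _check_exponent(b * (I1_bar - 3.0), "isotropic")
    w = a / (2.0 * b) * np.exp(b * (I1_bar - 3.0))
    for ai, bi, I4, term in ((af, bf, I4f, "fiber"), (as_, bs, I4s, "sheet")):
        e4 = I4 - 1.0
        if tension_only:
            e4 = np.maximum(e4, 0.0)
        _check_exponent(bi * e4 * e4, term)
        w = w + ai / (2.0 * bi) * (np.exp(bi * e4 * e4) - 1.0)
    _check_exponent(bfs * I8fs * I8fs, "fiber-sheet")
    w = w + afs / (2.0 * bfs) * (np.exp(bfs * I8fs * I8fs) - 1.0)
    return w


def isochoric_energy(
    state: DeformationState,
    frame: LocalFrame,
    params: PassiveParams,
    h: float = 1.0,
    *,
    split_i1: bool = True,
    tension_only: bool = True,
) -> float:
    """Isochoric strain-energy density (kPa) at a material point.

    The isotropic term uses the isochorically split invariant
    Ī1 = J^(−2/3)·I1 by default; the anisotropic terms use unsplit I4/I8
    (``split_i1`` toggles the isotropic split; ``tension_only`` restricts
    the I4 terms to fiber/sheet tension, I4 > 1).
    """
    inv = state.invariants(frame)
    J = state.J
    I1 = inv["I1"] * J ** (-2.0 / 3.0) if split_i1 else inv["I1"]
    a_eff = homogenize_params(params, h)
    return float(
        _energy_terms(I1, inv["I4f"], inv["I4s"], inv["I8fs"],
                      a_eff, params.b_coeffs, tension_only)
    )


def volumetric_energy(J, D: float) -> float:
    """Volumetric penalty (1/D)·((J²−1)/2 − ln J) in kPa, D in MPa⁻¹."""
    J = np.asarray(J, dtype=float)
    if D <= 0.0:
        raise ValueError("D must be > 0")
    if np.any(J <= 0.0):
        raise ValueError("J must be > 0")
    w = (1.0e3 / D) * (0.5 * (J * J - 1.0) - np.log(J))
    return float(w) if w.ndim == 0 else w


def stress_batch(
    F: np.ndarray,
    e_f: np.ndarray,
    e_s: np.ndarray,
    params: PassiveParams,
    h,
    Ta=0.0,
    n_s: float = 0.0,
    *,
    split_i1: bool = True,
    tension_only: bool = True,
    include_volumetric: bool = True,
    validate: bool = True,
) -> np.ndarray:
    """Vectorized total Cauchy stress (kPa) for N material points.

    ``F`` is (N,3,3), ``e_f``/``e_s`` are (N,3) reference unit directions,
    ``h`` and ``Ta`` broadcast over points.  Active tension acts along the
    deformed (renormalized) fiber/sheet directions.  This is the single
    code path behind :func:`passive_cauchy_stress` and :func:`total_stress`.
    ``validate=False`` defers input/overflow checking to a single
    finiteness check on the result (hot loops); errors are still raised,
    with a second validating pass to name the offending term.
    """
    F = np.asarray(F, dtype=float)
    if validate and not np.all(np.isfinite(F)):
        raise ValueError("F contains non-finite entries")
    N = F.shape[0]
    J = np.linalg.det(F)
    if validate and np.any(J <= 0.0):
        raise ValueError("det F must be > 0 at every point")
    b_left = np.einsum("nik,njk->nij", F, F)
    I1 = np.einsum("nij,nij->n", F, F)
    f = np.einsum("nij,nj->ni", F, e_f)  # deformed, unnormalized
    s = np.einsum("nij,nj->ni", F, e_s)
    I4f = np.einsum("ni,ni->n", f, f)
    I4s = np.einsum("ni,ni->n", s, s)
    I8 = np.einsum("ni,ni->n", f, s)

    h_arr = np.asarray(h, dtype=float)
    if validate and (np.any(h_arr < 0.0) or np.any(h_arr > 1.0)):
        raise ValueError("tissue health h must lie in [0, 1]")
    factor = params.A * (h_arr + (1.0 - h_arr) * params.p)
    a0, af0, as0, afs0 = params.a_coeffs
    bb, bf, bs, bfs = params.b_coeffs

    eye = np.eye(3)
    if split_i1:
        I1_bar = J ** (-2.0 / 3.0) * I1
        if validate:
            _check_exponent(bb * (I1_bar - 3.0), "isotropic")
        psi1 = 0.5 * factor * a0 * np.exp(bb * (I1_bar - 3.0))
        sig = (2.0 * psi1 * J ** (-5.0 / 3.0))[:, None, None] * (
            b_left - (I1 / 3.0)[:, None, None] * eye
        )
    else:
        if validate:
            _check_exponent(bb * (I1 - 3.0), "isotropic")
        psi1 = 0.5 * factor * a0 * np.exp(bb * (I1 - 3.0))
        sig = (2.0 * psi1 / J)[:, None, None] * b_left

    for ai, bi, I4, d, term in (
        (af0, bf, I4f, f, "fiber"), (as0, bs, I4s, s, "sheet")
    ):
        e4 = I4 - 1.0
        if tension_only:
            e4 = np.maximum(e4, 0.0)
        arg = bi * e4 * e4
        if validate:
            _check_exponent(arg, term)
        psi4 = factor * ai * e4 * np.exp(arg)
        sig += (2.0 * psi4 / J)[:, None, None] * (
            d[:, :, None] * d[:, None, :]
        )

    arg = bfs * I8 * I8
    if validate:
        _check_exponent(arg, "fiber-sheet")
    psi8 = factor * afs0 * I8 * np.exp(arg)
    fs_sym = f[:, :, None] * s[:, None, :]
    fs_sym += np.swapaxes(fs_sym, 1, 2).copy()
    sig += (psi8 / J)[:, None, None] * fs_sym

    if include_volumetric:
        dpsi_dJ = (1.0e3 / params.D) * (J - 1.0 / J)
        sig += dpsi_dJ[:, None, None] * eye

    Ta_arr = np.asarray(Ta, dtype=float)
    if np.any(Ta_arr != 0.0):
        Ta_arr = np.broadcast_to(Ta_arr, (N,))
        fn = f / np.linalg.norm(f, axis=1, keepdims=True)
        sig += Ta_arr[:, None, None] * (fn[:, :, None] * fn[:, None, :])
        if n_s != 0.0:
            sn = s / np.linalg.norm(s, axis=1, keepdims=True)
            sig += (n_s * Ta_arr)[:, None, None] * (
                sn[:, :, None] * sn[:, None, :]
            )
    sig = 0.5 * (sig + np.swapaxes(sig, 1, 2))
    if not validate and not np.all(np.isfinite(sig)):
        # re-run with full validation to raise a descriptive error
        return stress_batch(
            F, e_f, e_s, params, h, Ta, n_s,
            split_i1=split_i1, tension_only=tension_only,
            include_volumetric=include_volumetric, validate=True,
        )
    return sig


def passive_cauchy_stress(
    state: DeformationState,
    frame: LocalFrame,
    params: PassiveParams,
    h: float = 1.0,
    *,
    split_i1: bool = True,
    tension_only: bool = True,
) -> np.ndarray:
    """Passive Cauchy stress (kPa): push-forward of the isochoric energy
    plus the volumetric penalty.  Symmetric, zero at F = identity."""
    return stress_batch(
        state.F[None], frame.e_f[None], frame.e_s[None], params, h,
        split_i1=split_i1, tension_only=tension_only,
    )[0]


def active_tension(t, l, h, ap: ActiveParams, *, period: float | None = None):
    """Active fiber tension Ta(t, l) in kPa.

    Time course: ω rises linearly to π over ``t0`` then returns to 2π over
    the length-dependent relaxation time t_r = m_slope·l + b_intercept;
    (1 − cos ω)/2 is the resulting twitch shape.  The calcium factor is
    Ca0²/(Ca0² + ECa50(l)²) with ECa50 = Ca0max/√(exp(B_len(l−l0)) − 1).
    Tension scales with tissue health ``h`` and vanishes for sarcomere
    lengths at or below the zero-tension length ``l0`` (with a warning).
    If ``period`` is given, ``t`` is taken modulo the cycle period.
    """
    t = np.asarray(t, dtype=float)
    l = np.asarray(l, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time t must be >= 0")
    if period is not None:
        t = np.mod(t, period)

    scalar = t.ndim == 0 and l.ndim == 0 and h.ndim == 0
    t, l, h = np.atleast_1d(t), np.atleast_1d(l), np.atleast_1d(h)
    t, l, h = np.broadcast_arrays(t, l, h)

    slack = l <= ap.l0
    if np.any(slack):
        warnings.warn(
            "sarcomere length at or below the zero-tension length l0; "
            "active tension set to 0 there",
            stacklevel=2,
        )
    l_safe = np.where(slack, ap.l0 + 1e-9, l)
    eca50 = ap.Ca0max / np.sqrt(np.expm1(ap.B_len * (l_safe - ap.l0)))
    ca_factor = ap.Ca0**2 / (ap.Ca0**2 + eca50**2)

    t_r = np.maximum(ap.m_slope * l_safe + ap.b_intercept, 1e-9)
    omega = np.zeros_like(t)
    rising = t < ap.t0
    omega[rising] = np.pi * t[rising] / ap.t0
    falling = (~rising) & (t < ap.t0 + t_r)
    omega[falling] = np.pi * (t[falling] - ap.t0 + t_r[falling]) / t_r[falling]

    Ta = ap.Tmax * ca_factor * 0.5 * (1.0 - np.cos(omega)) * h
    Ta = np.where(slack, 0.0, Ta)
    return float(Ta[0]) if scalar else Ta


def total_stress(
    state: DeformationState,
    frame: LocalFrame,
    params: PassiveParams,
    h: float,
    Ta: float,
    n_s: float,
    **kwargs,
) -> np.ndarray:
    """Total Cauchy stress: passive + Ta·(f̂⊗f̂) + n_s·Ta·(ŝ⊗ŝ), with f̂, ŝ
    the deformed renormalized fiber and sheet directions."""
    if Ta < 0.0:
        raise ValueError("active tension Ta must be >= 0")
    return stress_batch(
        state.F[None], frame.e_f[None], frame.e_s[None], params, h,
        Ta=Ta, n_s=n_s, **kwargs,
    )[0]


def shear_deformation_gradient(mode: str, gamma: float) -> np.ndarray:
    """F = I + γ·e_dir⊗e_normal for mode "ij": faces with normal e_i
    displaced along e_j (f→x, s→y, n→z)."""
    if mode not in SHEAR_MODES:
        raise ValueError(
            f"unknown shear mode {mode!r}; valid modes: {', '.join(SHEAR_MODES)}"
        )
    normal, direction = _AXIS[mode[0]], _AXIS[mode[1]]
    F = np.eye(3)
    F[direction, normal] += gamma
    return F


def simple_shear_curve(
    mode: str,
    gammas,
    params: PassiveParams,
    h: float = 1.0,
    **kwargs,
) -> np.ndarray:
    """Work-conjugate Cauchy shear stress (kPa) for one simple-shear mode.

    Mode "ij" shears faces with normal e_i along e_j and reports σ_ij.
    Simple shear is isochoric (J = 1), so the volumetric penalty does not
    contribute.  The response is odd in γ and zero at γ = 0.
    """
    if mode not in SHEAR_MODES:
        raise ValueError(
            f"unknown shear mode {mode!r}; valid modes: {', '.join(SHEAR_MODES)}"
        )
    gammas = np.asarray(gammas, dtype=float)
    if np.any(np.abs(gammas) > 0.6):
        raise ValueError("|gamma| must be <= 0.6")
    normal, direction = _AXIS[mode[0]], _AXIS[mode[1]]
    frame = LocalFrame.cardinal()
    Fs = np.array([shear_deformation_gradient(mode, g) for g in gammas])
    sig = stress_batch(
        Fs,
        np.broadcast_to(frame.e_f, (len(gammas), 3)),
        np.broadcast_to(frame.e_s, (len(gammas), 3)),
        params,
        h,
        **kwargs,
    )
    return sig[:, normal, direction]
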