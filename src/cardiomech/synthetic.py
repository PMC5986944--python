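"""Seeded synthetic-data generators for every pipeline input class.

Each generator emulates one input modality at desk scale and emits
machine-readable ground truth alongside the data, so every downstream
stage can be validated without any external download:

* ``gen_dt_grid`` — a diffusion-tensor voxel phantom of the ellipsoidal
  LV wall with a prescribed transmural helix-angle rule, seeded
  orientation noise and isotropic background voxels (FA below the tissue
  gate by construction);
* ``gen_infarct`` — an ellipsoidal infarct blob as a binary segmentation
  plus the exact trilinear ground-truth h-field;
* ``gen_shear_data`` — six-mode simple-shear curves from a known
  parameter set with seeded multiplicative noise;
* ``gen_motion_sequence`` — an analytic beating-ellipsoid endocardial
  surface (circumferential shortening, long-axis shortening, torsion)
  with closed-form per-segment strain ground truth;
* ``gen_targets`` — the normal / heart-failure hemodynamic target sets.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from cardiomech import materials
from cardiomech.calibration import HemodynamicTargets, ShearDataset
from cardiomech.strainmap import SurfaceSequence, _BANDS
from cardiomech.tissue_fields import (
    DTVoxelGrid,
    health_field_from_segmentation,
)
from cardiomech.ventricle import VentricleGeometry, build_geometry

__all__ = [
    "PhantomSpec",
    "gen_dt_grid",
    "gen_infarct",
    "gen_shear_data",
    "gen_motion_sequence",
    "gen_targets",
]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic LV phantom.

    Geometry defaults mirror the reduced ventricle; DT eigenvalues are
    typical myocardial values (mm²/s); the fiber rule is linear from
    ``alpha_endo`` at the endocardium to ``alpha_epi`` at the epicardium.
    ``background_fraction`` of wall voxels are replaced by isotropic
    (non-fibrous) tensors; motion amplitudes define the analytic
    endocardial surface sequence.  A seed is mandatory.
    """

    seed: int
    a_endo: float = 12.4
    c_endo: float = 40.0
    a_epi: float = 22.0
    c_epi: float = 48.0
    z_base: float = 10.0
    alpha_endo: float = 60.0
    alpha_epi: float = -60.0
    dt_eigenvalues: tuple = (1.0e-3, 0.7e-3, 0.5e-3)
    orientation_noise_deg: float = 5.0
    background_fraction: float = 0.1
    spacing_mm: float = 1.0
    infarct_centre: tuple | None = None
    infarct_radii: tuple | None = None
    torsion_deg: float = 8.0
    long_axis_shortening: float = 0.15
    circ_shortening: float = 0.15
    n_frames: int = 11

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for frac in (self.background_fraction,):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    def geometry(self, **kwargs) -> VentricleGeometry:
        return build_geometry(
            self.a_endo, self.c_endo, self.a_epi, self.c_epi, self.z_base,
            fiber_rule=lambda d: self.alpha_endo
            + (np.asarray(d) + 1.0) / 2.0 * (self.alpha_epi - self.alpha_endo),
            **kwargs,
        )


def _wall_coordinates(spec: PhantomSpec, pts: np.ndarray):
    """Transmural ξ∈[0,1] (NaN outside the wall) for world points.

    ξ solves (x²+y²)/a(ξ)² + z²/c(ξ)² = 1 by vectorized bisection over
    the nested shell family.
    """
    r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
    z = pts[:, 2]

    def shell_fn(xi):
        a = spec.a_endo + xi * (spec.a_epi - spec.a_endo)
        c = spec.c_endo + xi * (spec.c_epi - spec.c_endo)
        return r2 / a**2 + z**2 / c**2 - 1.0

    f0 = shell_fn(np.zeros(len(pts)))
    f1 = shell_fn(np.ones(len(pts)))
    in_wall = (f0 >= 0.0) & (f1 <= 0.0) & (z <= spec.z_base)
    lo = np.zeros(len(pts))
    hi = np.ones(len(pts))
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        fm = shell_fn(mid)
        lo = np.where(fm > 0.0, mid, lo)
        hi = np.where(fm > 0.0, hi, mid)
    xi = 0.5 * (lo + hi)
    xi[~in_wall] = np.nan
    return xi


def _local_directions(spec: PhantomSpec, pts: np.ndarray, xi: np.ndarray):
    """Circumferential / longitudinal / radial unit vectors on shells."""
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    e_c = np.stack(
        [-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=1
    )
    a = spec.a_endo + xi * (spec.a_epi - spec.a_endo)
    c = spec.c_endo + xi * (spec.c_epi - spec.c_endo)
    u = np.clip(pts[:, 2] / c, -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - u * u, 1e-12))
    t_u = np.stack(
        [
            -a * u / s * np.cos(theta),
            -a * u / s * np.sin(theta),
            c * np.ones_like(u),
        ],
        axis=1,
    )
    e_l = t_u / np.linalg.norm(t_u, axis=1, keepdims=True)
    e_r = np.cross(e_c, e_l)
    return e_c, e_l, e_r


def _grid_points(spec: PhantomSpec):
    """Voxel-centre world coordinates and the grid affine."""
    sp = spec.spacing_mm
    margin = 2.0 * sp
    lo = np.array([-spec.a_epi - margin, -spec.a_epi - margin,
                   -spec.c_epi - margin])
    hi = np.array([spec.a_epi + margin, spec.a_epi + margin,
                   spec.z_base + margin])
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] = sp * np.eye(3)
    affine[:3, 3] = lo
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    pts = ijk * sp + lo
    return pts, shape, affine


def _noise_rotations(rng, n, sd_deg):
    """Rotations about random axes with N(0, sd) angles (degrees)."""
    from scipy.spatial.transform import Rotation

    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = np.deg2rad(rng.normal(0.0, sd_deg, size=n))
    return Rotation.from_rotvec(axes * angles[:, None]).as_matrix()


def gen_dt_grid(spec: PhantomSpec):
    """Diffusion-tensor phantom grid plus ground truth.

    Wall voxels carry tensors whose primary eigenvector follows the
    transmural helix-angle rule with seeded orientation noise; background
    voxels (outside the wall, plus ``background_fraction`` of wall
    voxels) are isotropic, hence FA ≈ 0, and are removed by the FA gate.
    Returns (grid, ground_truth) with the noise-free rule angles, the
    wall mask and per-voxel transmural coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    pts, shape, affine = _grid_points(spec)
    xi = _wall_coordinates(spec, pts)
    wall = ~np.isnan(xi)
    n_vox = len(pts)

    lam = np.asarray(spec.dt_eigenvalues, dtype=float)
    iso = np.mean(lam)
    tensors = np.zeros((n_vox, 3, 3))
    # isotropic background with slight eigenvalue jitter (FA << 0.12)
    jitter = 1.0 + 0.01 * rng.standard_normal((n_vox, 3))
    for k in range(3):
        tensors[:, k, k] = iso * jitter[:, k]

    idx_wall = np.where(wall)[0]
    demoted = rng.random(len(idx_wall)) < spec.background_fraction
    fibrous = idx_wall[~demoted]

    xi_f = xi[fibrous]
    depth = 2.0 * xi_f - 1.0
    alpha = spec.alpha_endo + (depth + 1.0) / 2.0 * (
        spec.alpha_epi - spec.alpha_endo
    )
    e_c, e_l, e_r = _local_directions(spec, pts[fibrous], xi_f)
    al = np.deg2rad(alpha)
    e_f = np.cos(al)[:, None] * e_c + np.sin(al)[:, None] * e_l
    e_s = e_r
    e_n = np.cross(e_f, e_s)
    R = np.stack([e_f, e_s, e_n], axis=-1)  # columns
    noise = _noise_rotations(rng, len(fibrous), spec.orientation_noise_deg)
    R = noise @ R
    T = np.einsum("nik,k,njk->nij", R, lam, R)
    tensors[fibrous] = 0.5 * (T + np.swapaxes(T, 1, 2))  # exact symmetry

    grid = DTVoxelGrid(
        tensors.reshape(*shape, 3, 3), affine,
        mask=np.ones(shape, dtype=bool),
    )
    fibrous_mask = np.zeros(n_vox, dtype=bool)
    fibrous_mask[fibrous] = True
    truth = {
        "alpha_rule_deg": np.where(
            wall,
            spec.alpha_endo
            + xi * (spec.alpha_epi - spec.alpha_endo),
            np.nan,
        ).reshape(shape),
        "wall_mask": wall.reshape(shape),
        "fibrous_mask": fibrous_mask.reshape(shape),
        "transmural_xi": xi.reshape(shape),
        "spec": asdict(spec),
    }
    return grid, truth


def gen_infarct(spec: PhantomSpec):
    """Binary infarct segmentation (1 = infarct) plus ground-truth h.

    The infarct is an ellipsoidal blob (centre/radii from the
    :class:`PhantomSpec`, mm);
    ground-truth h at arbitrary points uses the same trilinear rule as
    the h-field construction.  Raises if the blob centre lies outside
    the wall.
    """
    if spec.infarct_centre is None or spec.infarct_radii is None:
        raise ValueError("spec must define infarct_centre and infarct_radii")
    centre = np.asarray(spec.infarct_centre, dtype=float)
    radii = np.asarray(spec.infarct_radii, dtype=float)
    if np.isnan(_wall_coordinates(spec, centre[None])[0]):
        raise ValueError("infarct blob centre lies outside the wall")
    pts, shape, affine = _grid_points(spec)
    xi = _wall_coordinates(spec, pts)
    wall = ~np.isnan(xi)
    inside_blob = (
        np.sum(((pts - centre) / radii) ** 2, axis=1) <= 1.0
    )
    mask = (inside_blob & wall).reshape(shape).astype(np.uint8)

    def h_truth(points):
        hf = health_field_from_segmentation(
            1.0 - mask.astype(float), affine, points
        )
        return hf.h

    return mask, affine, h_truth


def gen_shear_data(
    params: materials.PassiveParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    gammas=None,
    h: float = 1.0,
) -> ShearDataset:
    """Six-mode simple-shear dataset from the forward model.

    Strain amounts default to 20 points over γ ∈ [0, 0.5] (the range of
    the triaxial myocardium shear experiments); noise is multiplicative,
    N(1, noise_sd) per sample.
    """
    rng = np.random.default_rng(seed)
    if gammas is None:
        gammas = np.linspace(0.0, 0.5, 20)
    gammas = np.asarray(gammas, dtype=float)
    if np.any(gammas < 0.0) or np.any(gammas > 0.5):
        raise ValueError("gamma grid must lie in [0, 0.5]")
    curves = {}
    for mode in materials.SHEAR_MODES:
        sigma = materials.simple_shear_curve(mode, gammas, params, h)
        if noise_sd > 0.0:
            sigma = sigma * (
                1.0 + noise_sd * rng.standard_normal(len(gammas))
            )
        curves[mode] = (gammas.copy(), sigma)
    return ShearDataset(curves)


def _motion_map(spec: PhantomSpec, verts: np.ndarray, m: float):
    """Analytic systolic deformation at amplitude m ∈ [0, 1].

    Circumferential shortening scales radii by (1 − m·cs); long-axis
    shortening scales base-to-apex distances by (1 − m·ls) about the base
    plane; torsion rotates each level about the axis proportionally to
    its distance from the base (apex twists most).
    """
    cs, ls = spec.circ_shortening, spec.long_axis_shortening
    x, y, z = verts[:, 0], verts[:, 1], verts[:, 2]
    r_scale = 1.0 - m * cs
    z_new = spec.z_base + (z - spec.z_base) * (1.0 - m * ls)
    span = spec.z_base + spec.c_endo
    twist = np.deg2rad(m * spec.torsion_deg) * (spec.z_base - z) / span
    ct, st = np.cos(twist), np.sin(twist)
    return np.stack(
        [r_scale * (ct * x - st * y), r_scale * (st * x + ct * y), z_new],
        axis=1,
    )


def _meridian_arc(spec: PhantomSpec, theta, ell_lo, ell_hi, m, n=400):
    """Arc length of the deformed endocardial meridian between two
    normalized heights, by dense sampling of the analytic map."""
    u_lo, u_hi = -1.0, spec.z_base / spec.c_endo
    uu = np.linspace(
        u_lo + (u_hi - u_lo) * ell_lo, u_lo + (u_hi - u_lo) * ell_hi, n
    )
    s = np.sqrt(np.maximum(1.0 - uu**2, 0.0))
    pts = np.stack(
        [
            spec.a_endo * s * np.cos(theta),
            spec.a_endo * s * np.sin(theta),
            spec.c_endo * uu,
        ],
        axis=1,
    )
    x = _motion_map(spec, pts, m)
    return float(np.linalg.norm(np.diff(x, axis=0), axis=1).sum())


def gen_motion_sequence(spec: PhantomSpec, n_u: int = 24, n_theta: int = 36):
    """Analytic endocardial motion sequence plus strain ground truth.

    Frames ramp the deformation amplitude as sin²(π·t/(T−1)): frame 0 is
    ED (zero strain), the middle frame is ES (full amplitude).  Ground
    truth: circumferential engineering strain is exactly
    −100·circ_shortening in every segment (rings scale uniformly and
    torsion is isometric on rings); longitudinal ground truth integrates
    the deformed meridian arc per band from the analytic map.
    """
    ub = spec.z_base / spec.c_endo
    u = np.linspace(-1.0, ub, n_u)[1:]  # exclude the pole (added below)
    # half-step azimuthal offset keeps vertices off segment boundaries
    th = (np.arange(n_theta) + 0.5) * 2.0 * np.pi / n_theta
    uu, tt = np.meshgrid(u, th, indexing="ij")
    s = np.sqrt(np.maximum(1.0 - uu**2, 0.0))
    ring_verts = np.stack(
        [
            spec.a_endo * s * np.cos(tt),
            spec.a_endo * s * np.sin(tt),
            spec.c_endo * uu,
        ],
        axis=-1,
    ).reshape(-1, 3)
    apex = np.array([0.0, 0.0, -spec.c_endo])
    verts0 = np.vstack([apex, ring_verts])

    faces = []
    idx = lambda i, j: 1 + i * n_theta + (j % n_theta)
    for j in range(n_theta):  # apex fan
        faces.append([0, idx(0, j), idx(0, j + 1)])
    for i in range(len(u) - 1):
        for j in range(n_theta):
            faces.append([idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)])
            faces.append([idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)])
    faces = np.asarray(faces, dtype=int)

    T = spec.n_frames
    amp = np.sin(np.pi * np.arange(T) / (T - 1)) ** 2
    frames = np.stack([_motion_map(spec, verts0, m) for m in amp])
    es_index = int(np.argmax(amp))
    seq = SurfaceSequence(
        frames=frames,
        faces=faces,
        ed_index=0,
        apex=apex,
        base_centre=np.array([0.0, 0.0, spec.z_base]),
        es_index=es_index,
        times_ms=np.linspace(0.0, 480.0, T),
        sector_ref=np.array([spec.a_endo, 0.0, 0.0]),
    )

    m_es = float(amp[es_index])
    circ_truth = -100.0 * m_es * spec.circ_shortening
    long_truth = {}
    for name, lo, hi, n_sec, first_id in _BANDS:
        width = 2.0 * np.pi / n_sec
        for sct in range(n_sec):
            theta_c = (sct + 0.5) * width
            L0 = _meridian_arc(spec, theta_c, lo, hi, 0.0)
            L1 = _meridian_arc(spec, theta_c, lo, hi, m_es)
            long_truth[first_id + sct] = 100.0 * (L1 / L0 - 1.0)
    truth = {
        "circ_strain_pct": circ_truth,
        "long_strain_pct": long_truth,
        "amplitude_es": m_es,
        "es_index": es_index,
    }
    return seq, truth


#: printed hemodynamic profiles; LV EDP values are stated assumptions
#: (normal ≈ 10 mmHg, heart failure roughly double).
_TARGET_PROFILES = {
    "normal": dict(edv=57.8, sv=30.9, edp=10.0, rv_edp=4.0, lvls=15.0),
    "heart_failure": dict(edv=103.0, sv=33.0, edp=20.0, rv_edp=8.0,
                          lvls=10.0),
}


def gen_targets(profile: str = "normal") -> HemodynamicTargets:
    """Hemodynamic target set for the 'normal' or 'heart_failure' profile.

    EDV/SV (and hence EF) follow the printed subject values; the RV EDP
    is 4 mmHg for the normal subject and doubled with the roughly doubled
    LV EDP in heart failure.  LV EDP values are documented assumptions.
    """
    if profile not in _TARGET_PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; use one of "
            f"{sorted(_TARGET_PROFILES)}"
        )
    p = _TARGET_PROFILES[profile]
    return HemodynamicTargets(
        edv=p["edv"], edp=p["edp"], sv=p["sv"], lvls=p["lvls"],
        rv_edp=p["rv_edp"], esv=p["edv"] - p["sv"],
    )
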