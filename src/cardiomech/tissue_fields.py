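"""Diffusion-tensor voxel fields, fiber angles, AHA-17 maps and h-fields.

Voxelwise diffusion tensors are decomposed into eigenvalues and
eigenvectors; the primary eigenvector is the local myofiber direction.
Quality control keeps a voxel only if all eigenvalues are strictly
positive and the fractional anisotropy exceeds a tissue threshold
(FA > 0.12).  Tensors are interpolated to arbitrary points by an
invariant-interpolation scheme: eigenvalues trilinearly, orientations by
sign-aligned weighted quaternion averaging, then reassembly as
R·diag(λ)·Rᵀ.

The inclination (helix) angle α_h is the angle between the fiber
projected into the circumferential-longitudinal tangent plane and the
circumferential direction, mapped to (−90°, 90°] using the fiber sign
ambiguity.  Regional statistics use the standard AHA 17-segment left-
ventricular map and a normalized transmural coordinate (−1 endocardium,
+1 epicardium).

The continuous tissue-health field h ∈ [0, 1] is built from a binary
(1 healthy / 0 infarct) segmentation by trilinear interpolation, so
intermediate values appear only in the border zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

__all__ = [
    "DTVoxelGrid",
    "FiberFrameField",
    "AHASegmentMap",
    "HealthField",
    "tensor_eigen_fa",
    "fractional_anisotropy",
    "qc_filter",
    "interpolate_tensor",
    "inclination_angle",
    "aha17_assign",
    "transmural_profile",
    "health_field_from_segmentation",
]

#: FA threshold separating fibrous tissue from background.
FA_TISSUE_THRESHOLD = 0.12


@dataclass
class DTVoxelGrid:
    """Voxel grid of symmetric diffusion tensors (mm²/s) with an affine.

    ``tensors`` has shape (nx, ny, nz, 3, 3); ``affine`` maps voxel
    indices (homogeneous) to world mm (RAS+); ``mask`` flags valid voxels.
    """

    tensors: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        asym = np.abs(
            self.tensors - np.swapaxes(self.tensors, -1, -2)
        ).max()
        if asym > 1e-12:
            raise ValueError(f"tensors not symmetric (max asymmetry {asym:g})")
        if self.mask is None:
            self.mask = np.ones(self.tensors.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.tensors.shape[:3]:
                raise ValueError("mask shape mismatch")
        sp = self.spacing
        if np.any(sp <= 0.0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple:
        return self.tensors.shape[:3]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (x @ inv[:3, :3].T) + inv[:3, 3]

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T) + self.affine[:3, 3]


def fractional_anisotropy(eigenvalues) -> np.ndarray:
    """FA = √(3/2)·‖λ − λ̄‖/‖λ‖ of eigenvalue triples (last axis)."""
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = np.sqrt(1.5) * num[nz] / den[nz]
    return out


def tensor_eigen_fa(tensor, reference_dir=None):
    """Eigen-decomposition of one symmetric tensor plus its FA.

    Returns (eigenvalues descending, eigenvectors as columns, FA); the
    primary eigenvector's sign is chosen to have a non-negative dot
    product with ``reference_dir`` (if given).
    """
    T = np.asarray(tensor, dtype=float)
    if T.shape != (3, 3) or np.abs(T - T.T).max() > 1e-12:
        raise ValueError("tensor must be symmetric 3x3")
    lam, vec = np.linalg.eigh(T)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    if reference_dir is not None and vec[:, 0] @ np.asarray(
        reference_dir, dtype=float
    ) < 0.0:
        vec[:, 0] = -vec[:, 0]
        vec[:, 1] = -vec[:, 1]  # keep right-handed
    return lam, vec, float(fractional_anisotropy(lam))


def qc_filter(grid: DTVoxelGrid, fa_min: float = FA_TISSUE_THRESHOLD):
    """Validity mask: all eigenvalues strictly positive AND FA > fa_min."""
    lam = np.linalg.eigvalsh(grid.tensors)
    positive = np.all(lam > 0.0, axis=-1)
    fa = fractional_anisotropy(lam)
    return positive & (fa > fa_min) & grid.mask


def _rotation_from_eigvecs(vec: np.ndarray) -> np.ndarray:
    """Proper rotation matrix from an eigenvector column matrix."""
    if np.linalg.det(vec) < 0.0:
        vec = vec.copy()
        vec[:, 2] = -vec[:, 2]
    return vec


def interpolate_tensor(grid: DTVoxelGrid, x, validity=None) -> np.ndarray:
    """Invariant interpolation of the tensor field at world point x (mm).

    Eigenvalues are combined with trilinear weights over the (up to 8)
    valid neighbouring voxels; orientations are combined by weighted
    quaternion averaging after aligning quaternion signs to the
    largest-weight neighbour.  The result R·diag(λ)·Rᵀ is symmetric and
    positive-definite whenever the contributing voxels are.
    """
    if validity is None:
        validity = grid.mask
    ijk = grid.world_to_voxel(x)[0]
    base = np.floor(ijk).astype(int)
    frac = ijk - base
    shape = grid.shape

    lam_acc = np.zeros(3)
    quats, qweights = [], []
    wsum = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                idx = base + (di, dj, dk)
                if np.any(idx < 0) or np.any(idx >= shape):
                    continue
                w = (
                    (frac[0] if di else 1 - frac[0])
                    * (frac[1] if dj else 1 - frac[1])
                    * (frac[2] if dk else 1 - frac[2])
                )
                if w <= 0.0 or not validity[tuple(idx)]:
                    continue
                lam, vec, _ = tensor_eigen_fa(grid.tensors[tuple(idx)])
                R = _rotation_from_eigvecs(vec)
                quats.append(Rotation.from_matrix(R).as_quat())
                qweights.append(w)
                lam_acc += w * lam
                wsum += w
    if wsum <= 0.0:
        raise ValueError("no tissue support: all neighbouring voxels invalid")
    lam = lam_acc / wsum
    qweights = np.asarray(qweights)
    quats = np.asarray(quats)
    ref = quats[np.argmax(qweights)]
    sign = np.where(quats @ ref < 0.0, -1.0, 1.0)
    q_mean = (quats * (sign * qweights)[:, None]).sum(axis=0)
    q_mean /= np.linalg.norm(q_mean)
    R = Rotation.from_quat(q_mean).as_matrix()
    return R @ np.diag(lam) @ R.T


def inclination_angle(e_f, circ_dir, long_dir) -> float:
    """Inclination (helix) angle α_h in degrees, in (−90, 90].

    The fiber is projected into the circumferential-longitudinal tangent
    plane; 0° is circumferential, ±90° longitudinal.  The ±e_f sign
    ambiguity is removed by folding into (−90, 90].  Returns NaN (with a
    warning) when the fiber is essentially radial.
    """
    e_f = np.asarray(e_f, dtype=float)
    comp_c = float(e_f @ np.asarray(circ_dir, dtype=float))
    comp_l = float(e_f @ np.asarray(long_dir, dtype=float))
    if np.hypot(comp_c, comp_l) < 1e-6:
        warnings.warn(
            "fiber nearly radial: inclination angle undefined", stacklevel=2
        )
        return float("nan")
    ang = np.degrees(np.arctan2(comp_l, comp_c))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return float(ang)


@dataclass
class FiberFrameField:
    """Per-point fiber data sampled from a DT grid."""

    points: np.ndarray            # (N,3) world mm
    e_f: np.ndarray               # (N,3) fiber directions
    fa: np.ndarray                # (N,)
    alpha_deg: np.ndarray         # (N,) helix angles, NaN if undefined
    h: np.ndarray | None = None   # (N,) tissue health

    @classmethod
    def from_grid(
        cls, grid, points, circ_dirs, long_dirs, validity=None, h=None
    ) -> "FiberFrameField":
        points = np.atleast_2d(np.asarray(points, dtype=float))
        e_f = np.empty_like(points)
        fa = np.empty(len(points))
        alpha = np.empty(len(points))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, x in enumerate(points):
                T = interpolate_tensor(grid, x, validity)
                lam, vec, fa_i = tensor_eigen_fa(T, reference_dir=circ_dirs[i])
                e_f[i] = vec[:, 0]
                fa[i] = fa_i
                alpha[i] = inclination_angle(
                    e_f[i], circ_dirs[i], long_dirs[i]
                )
        return cls(points, e_f, fa, alpha, h)


@dataclass
class AHASegmentMap:
    """AHA 17-segment ids plus transmural coordinates for LV points."""

    region: np.ndarray            # (N,) ints 1..17, 0 = excluded
    transmural: np.ndarray        # (N,) in [-1, +1]
    n_excluded: int = 0


def aha17_assign(
    points,
    apex,
    base_centre,
    anterior_rv_insertion,
    transmural=None,
    cap_fraction: float = 1.0 / 6.0,
) -> AHASegmentMap:
    """Standard AHA 17-segment assignment from anatomical landmarks.

    The long axis runs apex → base centre; basal/mid/apical thirds are
    split into 6/6/4 circumferential sectors (60°/60°/90°), the apex-most
    ``cap_fraction`` of the axis is region 17, and the sector origin is
    the direction of the anterior RV insertion point.  Points beyond the
    base plane are excluded (region 0) and counted.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    apex = np.asarray(apex, dtype=float)
    base_centre = np.asarray(base_centre, dtype=float)
    axis = base_centre - apex
    L = np.linalg.norm(axis)
    if L < 1e-9:
        raise ValueError("degenerate landmarks: apex equals base centre")
    axis = axis / L
    ref = np.asarray(anterior_rv_insertion, dtype=float) - apex
    ref = ref - (ref @ axis) * axis
    if np.linalg.norm(ref) < 1e-9:
        raise ValueError("RV insertion lies on the long axis")
    ref = ref / np.linalg.norm(ref)
    ref2 = np.cross(axis, ref)

    rel = points - apex
    ell = (rel @ axis) / L
    in_plane = rel - np.outer(rel @ axis, axis)
    theta = np.degrees(
        np.arctan2(in_plane @ ref2, in_plane @ ref)
    ) % 360.0

    region = np.zeros(len(points), dtype=int)
    excluded = ell > 1.0 + 1e-9
    region[excluded] = 0
    cap = (~excluded) & (ell < cap_fraction)
    region[cap] = 17
    basal = (~excluded) & (ell >= 2.0 / 3.0)
    mid = (~excluded) & (ell >= 1.0 / 3.0) & (ell < 2.0 / 3.0)
    apical = (~excluded) & (~cap) & (ell < 1.0 / 3.0)
    region[basal] = 1 + (theta[basal] // 60.0).astype(int)
    region[mid] = 7 + (theta[mid] // 60.0).astype(int)
    region[apical] = 13 + (theta[apical] // 90.0).astype(int)

    tm = (
        np.asarray(transmural, dtype=float)
        if transmural is not None
        else np.zeros(len(points))
    )
    return AHASegmentMap(region, tm, int(excluded.sum()))


def transmural_profile(
    field: FiberFrameField, seg_map: AHASegmentMap, n_bins: int = 5
) -> pd.DataFrame:
    """Per-region, per-depth-bin helix-angle statistics + infarct fraction.

    Returns a table with columns region, depth_bin (bin-centre transmural
    coordinate), alpha_mean, alpha_sd, n and infarct_fraction (the
    region-wide 1 − mean(h); zero when no h field is attached).  Empty
    bins are reported as NaN rows with a warning.
    """
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for region in range(1, 18):
        sel = seg_map.region == region
        if not np.any(sel):
            warnings.warn(f"AHA region {region} empty", stacklevel=2)
        if field.h is not None and np.any(sel):
            infarct = 1.0 - float(np.mean(field.h[sel]))
        else:
            infarct = 0.0 if np.any(sel) else np.nan
        for b in range(n_bins):
            in_bin = (
                sel
                & (seg_map.transmural >= edges[b])
                & (seg_map.transmural <= edges[b + 1])
                & ~np.isnan(field.alpha_deg)
            )
            n = int(in_bin.sum())
            rows.append(
                {
                    "region": region,
                    "depth_bin": centres[b],
                    "alpha_mean": (
                        float(np.mean(field.alpha_deg[in_bin])) if n else np.nan
                    ),
                    "alpha_sd": (
                        float(np.std(field.alpha_deg[in_bin], ddof=1))
                        if n > 1
                        else np.nan
                    ),
                    "n": n,
                    "infarct_fraction": infarct,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class HealthField:
    """Continuous tissue-health values at target points."""

    points: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.h < -1e-12) or np.any(self.h > 1.0 + 1e-12):
            raise ValueError("h values must lie in [0, 1]")
        self.h = np.clip(self.h, 0.0, 1.0)


def health_field_from_segmentation(
    binary_grid: np.ndarray, affine: np.ndarray, target_points
) -> HealthField:
    """Continuous h at target points from a binary health grid.

    ``binary_grid`` holds 1 for healthy and 0 for infarcted voxels;
    trilinear interpolation produces values strictly between 0 and 1 only
    in the border zone.  Points outside the grid fall back to the nearest
    voxel with a warning.
    """
    grid = np.asarray(binary_grid, dtype=float)
    pts = np.atleast_2d(np.asarray(target_points, dtype=float))
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    ijk = pts @ inv[:3, :3].T + inv[:3, 3]
    outside = np.any(
        (ijk < 0) | (ijk > np.asarray(grid.shape) - 1), axis=1
    )
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} target point(s) outside the segmentation "
            "grid; using nearest-voxel values", stacklevel=2,
        )
    h = map_coordinates(grid, ijk.T, order=1, mode="nearest")
    return HealthField(pts, np.clip(h, 0.0, 1.0))
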