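"""Format readers/writers and run provenance.

NIfTI (via nibabel) for voxel data — diffusion-tensor grids stored either
as 6-component lower-triangular symmetric images (dxx, dxy, dyy, dxz,
dyz, dzz) or as full (…,3,3) arrays — with world coordinates through the
NIfTI affine (RAS+, mm).  Surface sequences are ASCII PLY files (via
trimesh) plus a JSON manifest carrying frame times, ED/ES indices and
landmarks.  Tables (shear curves, PV traces, strain reports) are CSV with
stable column orders and full-precision floats; parameter sets are JSON
with explicit unit annotations.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import sys
import time

import numpy as np
import pandas as pd

from cardiomech import __version__
from cardiomech.materials import ActiveParams, PassiveParams
from cardiomech.circulation import CirculationParams
from cardiomech.strainmap import SegmentStrainReport, SurfaceSequence
from cardiomech.tissue_fields import DTVoxelGrid

__all__ = [
    "read_tensor_grid",
    "write_tensor_grid",
    "read_mask",
    "write_mask",
    "write_surface_sequence",
    "read_surface_sequence",
    "save_params",
    "load_params",
    "write_strain_report",
    "write_provenance",
]

_LOWER_TRI = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]

_PARAM_TYPES = {
    "PassiveParams": PassiveParams,
    "ActiveParams": ActiveParams,
    "CirculationParams": CirculationParams,
}

_PARAM_UNITS = {
    "PassiveParams": {
        "a": "kPa", "a_f": "kPa", "a_s": "kPa", "a_fs": "kPa",
        "b": "1", "b_f": "1", "b_s": "1", "b_fs": "1",
        "D": "MPa^-1", "A": "1", "B": "1", "p": "1",
    },
    "ActiveParams": {
        "Tmax": "kPa", "n_s": "1", "Ca0": "uM", "Ca0max": "uM",
        "B_len": "um^-1", "l0": "um", "lR": "um", "t0": "ms",
        "m_slope": "ms/um", "b_intercept": "ms",
    },
    "CirculationParams": {
        "kappa_sa": "ml/mmHg", "kappa_sv": "ml/mmHg", "kappa_p": "ml/mmHg",
        "R_M": "mmHg*ms/ml", "R_A": "mmHg*ms/ml", "R_SYS": "mmHg*ms/ml",
        "R_T": "mmHg*ms/ml", "R_P": "mmHg*ms/ml",
        "V0_sa": "ml", "V0_sv": "ml", "V0_p": "ml",
        "P_sa_ed": "mmHg", "P_sv_ed": "mmHg", "P_p_ed": "mmHg",
        "T_active": "ms", "T_fill": "ms", "dt": "ms",
    },
}


# -- NIfTI voxel data -----------------------------------------------------

def write_tensor_grid(grid: DTVoxelGrid, path, mask_path=None) -> None:
    """Write a tensor grid as a 6-component lower-triangular NIfTI."""
    import nibabel as nib

    data = np.stack(
        [grid.tensors[..., i, j] for i, j in _LOWER_TRI], axis=-1
    )
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))
    if mask_path is not None:
        write_mask(grid.mask, grid.affine, mask_path)


def read_tensor_grid(path, mask_path=None) -> DTVoxelGrid:
    """Read a DT grid from NIfTI (lower-triangular 6-comp or full 3×3).

    Accepted layouts: (nx,ny,nz,6) or (nx,ny,nz,1,6) lower-triangular
    symmetric storage, or (nx,ny,nz,3,3) full tensors.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    if data.ndim == 4 and data.shape[-1] == 6:
        tensors = np.zeros(data.shape[:3] + (3, 3))
        for comp, (i, j) in enumerate(_LOWER_TRI):
            tensors[..., i, j] = data[..., comp]
            tensors[..., j, i] = data[..., comp]
    elif data.ndim == 5 and data.shape[-2:] == (3, 3):
        tensors = data
    else:
        raise ValueError(
            f"unrecognized tensor layout {data.shape}; accepted layouts: "
            "(nx,ny,nz,6) / (nx,ny,nz,1,6) lower-triangular or "
            "(nx,ny,nz,3,3) full"
        )
    mask = None
    if mask_path is not None:
        mask, mask_affine = read_mask(mask_path)
        if mask.shape != tensors.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid "
                f"{tensors.shape[:3]}"
            )
        mask = mask.astype(bool)
    return DTVoxelGrid(tensors, img.affine, mask)


def write_mask(mask, affine, path) -> None:
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path)
    )


def read_mask(path):
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.uint8), img.affine


# -- surfaces -------------------------------------------------------------

def write_surface_sequence(seq: SurfaceSequence, out_dir, prefix="frame"):
    """One ASCII PLY per frame plus a JSON manifest."""
    import trimesh

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for t, verts in enumerate(seq.frames):
        name = f"{prefix}_{t:03d}.ply"
        mesh = trimesh.Trimesh(
            vertices=verts, faces=seq.faces, process=False
        )
        mesh.export(out / name, encoding="ascii")
        files.append(name)
    manifest = {
        "frames": files,
        "ed_index": int(seq.ed_index),
        "es_index": None if seq.es_index is None else int(seq.es_index),
        "times_ms": (
            None if seq.times_ms is None else list(map(float, seq.times_ms))
        ),
        "apex": list(map(float, seq.apex)),
        "base_centre": list(map(float, seq.base_centre)),
        "sector_ref": (
            None
            if seq.sector_ref is None
            else list(map(float, seq.sector_ref))
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out / "manifest.json"


def read_surface_sequence(manifest_path) -> SurfaceSequence:
    import trimesh

    manifest_path = pathlib.Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    with open(manifest_path) as fh:
        man = json.load(fh)
    base = manifest_path.parent
    frames, faces = [], None
    for name in man["frames"]:
        mesh = trimesh.load(base / name, process=False)
        frames.append(np.asarray(mesh.vertices, dtype=float))
        if faces is None:
            faces = np.asarray(mesh.faces, dtype=int)
    return SurfaceSequence(
        frames=np.stack(frames),
        faces=faces,
        ed_index=man["ed_index"],
        es_index=man.get("es_index"),
        times_ms=(
            None if man.get("times_ms") is None
            else np.asarray(man["times_ms"])
        ),
        apex=np.asarray(man["apex"]),
        base_centre=np.asarray(man["base_centre"]),
        sector_ref=(
            None if man.get("sector_ref") is None
            else np.asarray(man["sector_ref"])
        ),
    )


# -- parameter sets -------------------------------------------------------

def save_params(obj, path) -> None:
    """Serialize a parameter dataclass as JSON with unit annotations."""
    tname = type(obj).__name__
    if tname not in _PARAM_TYPES:
        raise TypeError(f"unsupported parameter type {tname}")
    payload = {
        "type": tname,
        "values": dataclasses.asdict(obj),
        "units": _PARAM_UNITS[tname],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_params(path):
    with open(path) as fh:
        payload = json.load(fh)
    cls = _PARAM_TYPES.get(payload.get("type"))
    if cls is None:
        raise ValueError(
            f"unknown parameter type {payload.get('type')!r}; expected one "
            f"of {sorted(_PARAM_TYPES)}"
        )
    return cls(**payload["values"])


# -- reports --------------------------------------------------------------

def write_strain_report(report: SegmentStrainReport, out_dir, stem="strain"):
    """CSV table (segment, frame, strains) plus a JSON GLS/GCS summary."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = ["segment", "frame", "long_strain_pct", "circ_strain_pct"]
    report.table[cols].to_csv(out / f"{stem}.csv", index=False)
    summary = {
        "ed_index": int(report.ed_index),
        "es_index": (
            None if report.es_index is None else int(report.es_index)
        ),
        "gls_pct": list(map(float, report.gls)),
        "gcs_pct": list(map(float, report.gcs)),
    }
    with open(out / f"{stem}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)


# -- provenance -----------------------------------------------------------

def write_provenance(out_dir, *, config=None, seed=None, inputs=None,
                     wall_time_s=None, stem="provenance") -> None:
    """Machine-readable record sufficient to reproduce a run."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "cardiomech_version": __version__,
        "python": sys.version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "argv": sys.argv,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config,
        "inputs": inputs,
        "wall_time_s": wall_time_s,
    }
    with open(out / f"{stem}.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
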