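"""NIfTI readers/writers for images, label maps and transforms.

Scalar volumes map onto the internal unit-domain grid derived from their
shape; 2D problems are stored as single-slice volumes.  Displacement fields
are written as multi-component NIfTI volumes (one component per spatial axis,
last array axis) in *voxel units* under the package's own coordinate
convention (0-based voxel centers, axes in array order); the JSON sidecar
records the convention and the full configuration so a run can be replayed.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import GridSpec, ScalarField, VectorField
from .evaluate import LabelVolume

__all__ = [
    "read_volume",
    "read_labels",
    "write_volume",
    "write_vector_field",
    "read_vector_field",
    "write_transform",
]


def _load(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if np.iscomplexobj(data) or data.dtype.fields is not None:
        raise ValueError(f"{path}: only scalar-valued NIfTI volumes are supported")
    return np.asarray(data, dtype=float), img.affine


def _squeeze(data: np.ndarray) -> np.ndarray:
    # accept single-slice 3D volumes as 2D problems
    if data.ndim == 3 and data.shape[2] == 1:
        return data[:, :, 0]
    return data


def read_volume(path) -> ScalarField:
    """Read a scalar NIfTI volume as a :class:`ScalarField` on the unit domain."""
    data, _ = _load(path)
    data = _squeeze(data)
    if data.ndim not in (2, 3):
        raise ValueError(f"{path}: expected a 2D or 3D scalar volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite values")
    return ScalarField(GridSpec(data.shape), data)


def read_labels(path) -> LabelVolume:
    """Read an integer-valued NIfTI label volume."""
    data, _ = _load(path)
    data = _squeeze(data)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label volume must be integer-valued")
    return LabelVolume(GridSpec(data.shape), np.round(data).astype(np.int32))


def _to_3d(arr: np.ndarray) -> np.ndarray:
    return arr[:, :, None] if arr.ndim == 2 else arr


def write_volume(field, path) -> None:
    """Write a ScalarField / LabelVolume / ndarray as NIfTI-1."""
    if isinstance(field, ScalarField):
        arr = field.data
    elif isinstance(field, LabelVolume):
        arr = field.labels.astype(np.int16)
    else:
        arr = np.asarray(field)
    nib.save(nib.Nifti1Image(_to_3d(arr), np.eye(4)), str(path))


def write_vector_field(v: VectorField, path) -> None:
    """Write a displacement/velocity field: components stacked on the last
    axis, values converted from the unit domain to voxel units."""
    scale = np.asarray(v.grid.shape, dtype=float).reshape((-1,) + (1,) * v.grid.dim)
    vox = v.data * scale
    arr = np.stack([_to_3d(c) for c in vox], axis=-1)
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))


def read_vector_field(path) -> VectorField:
    data, _ = _load(path)
    comps = [
        _squeeze(np.ascontiguousarray(data[..., c])) for c in range(data.shape[-1])
    ]
    grid = GridSpec(comps[0].shape)
    scale = np.asarray(grid.shape, dtype=float).reshape((-1,) + (1,) * grid.dim)
    return VectorField(grid, np.stack(comps) / scale)


def write_transform(result, outdir, config: dict | None = None) -> dict:
    """Write the full transform bundle of a RegistrationResult plus a JSON
    sidecar; returns the mapping of artifact names to paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "velocity": outdir / "velocity.nii.gz",
        "phi_disp": outdir / "phi_displacement.nii.gz",
        "psi_disp": outdir / "psi_displacement.nii.gz",
        "jacobian": outdir / "jacobian.nii.gz",
        "warped": outdir / "warped.nii.gz",
        "sidecar": outdir / "registration.json",
    }
    write_vector_field(result.v_spatial, paths["velocity"])
    write_vector_field(result.phi_disp, paths["phi_disp"])
    write_vector_field(result.psi_disp, paths["psi_disp"])
    from .transport import cgl_nodes, solve_jacobian

    write_volume(result.warped, paths["warped"])
    jac = solve_jacobian(result.v_spatial, cgl_nodes(5))[0]
    write_volume(jac, paths["jacobian"])
    sidecar = {
        "convention": {
            "displacement_units": "voxels",
            "coordinates": "0-based voxel centers, array axis order, periodic",
            "warp": "m(1) = I0 o (id + phi_displacement)",
        },
        "config": config or {},
        "energy_trace": list(map(float, result.energy_trace)),
        "e_img_trace": list(map(float, result.e_img_trace)),
        "grad_rel_trace": list(map(float, result.grad_rel_trace)),
        "stop_reason": result.stop_reason,
        "jacobian_min": result.jac_min,
        "jacobian_max": result.jac_max,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths
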