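"""File formats: NIfTI volumes and fields, VTK/PLY meshes, CSV, YAML.

Conventions (written into every file this package produces):

* 0-based indices, voxel-center coordinates, world = origin + index *
  spacing;
* NIfTI affines are diagonal (axis-aligned, positive spacings, mm);
  oblique affines are rejected on read with a clear error;
* displacement fields are 4D NIfTI with the vector dimension last,
  component order (x, y, z), values in mm (NIfTI intent: vector);
* tagged images are float32 in [0, 1]; labels are int16.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .anatomy import LabelVolume, SurfaceMesh
from .errors import FormatError
from .grids import GridSpec
from .motion import MotionParams, PhaseField, BiophysicsMeta
from .strain import StrainCurves
from .tagging import TaggedImage

__all__ = [
    "save_image",
    "load_image",
    "save_labels",
    "load_labels",
    "save_field",
    "load_field",
    "save_mesh_vtk",
    "save_mesh_ply",
    "save_strain_curves",
    "load_strain_curves",
    "save_manifest",
    "load_manifest",
    "motion_params_to_yaml",
    "motion_params_from_yaml",
]


def _affine(grid: GridSpec) -> np.ndarray:
    return grid.affine


def _grid_from_affine(affine: np.ndarray, shape) -> GridSpec:
    R = affine[:3, :3]
    if not np.allclose(R, np.diag(np.diag(R)), atol=1e-6):
        raise FormatError(
            "oblique/rotated NIfTI affines are not supported; this package "
            "uses axis-aligned grids only"
        )
    spacing = np.diag(R)
    if np.any(spacing <= 0):
        raise FormatError("NIfTI affine must have positive diagonal spacings")
    return GridSpec(shape=tuple(shape[:3]), spacing=tuple(spacing), origin=tuple(affine[:3, 3]))


def save_image(path, image: TaggedImage):
    img = nib.Nifti1Image(image.intensities.astype(np.float32), _affine(image.grid))
    img.header["descrip"] = b"0-based voxel-center grid; world=origin+idx*spacing"
    nib.save(img, str(path))


def load_image(path, phase_index: int = 0) -> TaggedImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D image, got shape {data.shape}")
    return TaggedImage(_grid_from_affine(img.affine, data.shape), data, phase_index)


def save_labels(path, labels: LabelVolume):
    img = nib.Nifti1Image(labels.labels.astype(np.int16), _affine(labels.grid))
    nib.save(img, str(path))


def load_labels(path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D label volume, got shape {data.shape}")
    return LabelVolume(_grid_from_affine(img.affine, data.shape), data.astype(np.int16))


def save_field(path, field: PhaseField):
    """4D NIfTI, vector dimension last, (x, y, z) order, mm."""
    img = nib.Nifti1Image(field.vectors.astype(np.float32), _affine(field.grid))
    img.header.set_intent("vector")
    img.header["descrip"] = b"Lagrangian displacement u(X), mm, (x,y,z) last"
    nib.save(img, str(path))


def load_field(path, phase_index: int = 0) -> PhaseField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"expected a (nx, ny, nz, 3) field, got {data.shape}")
    return PhaseField(_grid_from_affine(img.affine, data.shape), data, phase_index)


# -- meshes --------------------------------------------------------------


def save_mesh_vtk(path, mesh: SurfaceMesh):
    """Legacy-VTK ASCII polydata with a per-vertex surface label array."""
    v, f = mesh.vertices, mesh.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "LV surface; mm; 0-based voxel-center world coordinates",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} float",
    ]
    lines += [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in f]
    lines += [
        f"POINT_DATA {len(v)}",
        "SCALARS surface_label short 1",
        "LOOKUP_TABLE default",
    ]
    lines += [str(int(l)) for l in mesh.vertex_labels]
    Path(path).write_text("\n".join(lines) + "\n")


def save_mesh_ply(path, mesh: SurfaceMesh):
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


# -- tables and configs --------------------------------------------------


def save_strain_curves(path, curves: StrainCurves):
    df = pd.DataFrame(
        {
            "phase": np.arange(len(curves.e_r)),
            "e_r": curves.e_r,
            "e_c": curves.e_c,
            "e_l": curves.e_l,
        }
    )
    df.to_csv(path, index=False)


def load_strain_curves(path) -> StrainCurves:
    df = pd.read_csv(path)
    return StrainCurves(
        e_r=df["e_r"].to_numpy(), e_c=df["e_c"].to_numpy(), e_l=df["e_l"].to_numpy()
    )


def save_manifest(path, manifest: dict):
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def load_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def motion_params_to_yaml(path, params: MotionParams):
    doc = {
        "contraction": params.contraction,
        "twist_deg": params.twist_deg,
        "shortening": params.shortening,
        "n_phases": params.n_phases,
        "peak_phase_fraction": params.peak_phase_fraction,
        "biophysics": params.biophysics.as_dict(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def motion_params_from_yaml(path) -> MotionParams:
    doc = yaml.safe_load(Path(path).read_text())
    bio = doc.pop("biophysics", {})
    return MotionParams(biophysics=BiophysicsMeta(**bio), **doc)
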