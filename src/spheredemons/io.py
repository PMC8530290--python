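"""File-format adapters: GIFTI (canonical), FreeSurfer (import), CSV, HDF5.

GIFTI is the interchange format of the HCP surface ecosystem and the
canonical one here: surfaces as .surf.gii, per-vertex scalars as
.func.gii / .shape.gii, labels as .label.gii with a label table.
FreeSurfer binary sphere / curv / annot files are read-only imports.
Deformation fields serialize as a CSV of warped unit coordinates plus a
JSON sidecar carrying the source-mesh hash and configuration; dense time
series go to HDF5.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np
import nibabel as nib
from nibabel import gifti

from .connectivity import TimeSeriesMatrix
from .deformation import DeformationField
from .mesh import SphericalMesh
from .parcellation import ParcellationMap

__all__ = [
    "FormatError",
    "read_surface",
    "write_surface",
    "read_scalars",
    "write_scalars",
    "read_labels",
    "write_labels",
    "read_deformation_csv",
    "read_deformation_gifti",
    "write_deformation_gifti",
    "write_deformation_csv",
    "read_timeseries_h5",
    "write_timeseries_h5",
    "mesh_hash",
]


class FormatError(ValueError):
    """Raised when a file does not parse as the expected format."""


def mesh_hash(mesh: SphericalMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(mesh.faces).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def read_surface(path, normalize: bool = False) -> SphericalMesh:
    """Read a spherical surface from GIFTI .surf.gii or FreeSurfer binary.

    Coordinates are rescaled to the unit sphere (FreeSurfer spheres have
    radius 100).  A surface whose radii vary by more than 1% is rejected
    unless ``normalize=True``, which projects vertices radially with a
    warning.
    """
    path = Path(path)
    if path.suffix == ".gii":
        from nibabel.nifti1 import intent_codes

        img = nib.load(str(path))
        coords = faces = None
        for arr in img.darrays:
            if arr.intent == intent_codes["NIFTI_INTENT_POINTSET"]:
                coords = np.asarray(arr.data, dtype=np.float64)
            elif arr.intent == intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(arr.data, dtype=np.int64)
        if coords is None or faces is None:
            raise FormatError(
                f"{path}: missing POINTSET or TRIANGLE data array"
            )
    else:
        try:
            coords, faces = nib.freesurfer.read_geometry(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error detail
            raise FormatError(f"{path}: not a FreeSurfer surface ({exc})") from exc
        coords = np.asarray(coords, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)

    radii = np.linalg.norm(coords, axis=1)
    mean_r = radii.mean()
    if mean_r == 0:
        raise FormatError(f"{path}: degenerate surface at the origin")
    if np.abs(radii / mean_r - 1).max() > 0.01:
        if not normalize:
            raise FormatError(
                f"{path}: surface is not spherical (radius spread > 1%); "
                "pass normalize=True to project radially"
            )
        import warnings

        warnings.warn(f"{path}: non-spherical surface normalized to unit radius")
    coords = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    return SphericalMesh(coords, faces)


def write_surface(path, mesh: SphericalMesh) -> None:
    """Write a surface as GIFTI .surf.gii (float32 coordinates)."""
    img = gifti.GiftiImage()
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32),
            intent="NIFTI_INTENT_POINTSET",
            datatype="NIFTI_TYPE_FLOAT32",
        )
    )
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            mesh.faces.astype(np.int32),
            intent="NIFTI_INTENT_TRIANGLE",
            datatype="NIFTI_TYPE_INT32",
        )
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# per-vertex scalars
# ---------------------------------------------------------------------------

def read_scalars(path) -> np.ndarray:
    """Read per-vertex scalars: GIFTI .func/.shape.gii or FreeSurfer curv.

    Multi-column GIFTI files return an (N, C) array, one column per data
    array.
    """
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        if not img.darrays:
            raise FormatError(f"{path}: no data arrays")
        cols = [np.asarray(d.data, dtype=np.float64) for d in img.darrays]
        return cols[0] if len(cols) == 1 else np.column_stack(cols)
    try:
        return np.asarray(nib.freesurfer.read_morph_data(str(path)), dtype=np.float64)
    except Exception as exc:
        raise FormatError(f"{path}: not a FreeSurfer curv file ({exc})") from exc


def write_scalars(path, values: np.ndarray, names: Optional[list] = None) -> None:
    """Write per-vertex scalars as GIFTI .func.gii (one array per column)."""
    values = np.atleast_2d(np.asarray(values, dtype=np.float64).T).T
    img = gifti.GiftiImage()
    for c in range(values.shape[1]):
        arr = gifti.GiftiDataArray(
            values[:, c].astype(np.float32),
            intent="NIFTI_INTENT_NONE",
            datatype="NIFTI_TYPE_FLOAT32",
        )
        if names is not None:
            arr.meta["Name"] = names[c]
        img.add_gifti_data_array(arr)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def read_labels(path, mesh: SphericalMesh) -> ParcellationMap:
    """Read a parcellation: GIFTI .label.gii or FreeSurfer .annot."""
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        if not img.darrays:
            raise FormatError(f"{path}: no data arrays")
        labels = np.asarray(img.darrays[0].data, dtype=np.int64)
        names = {}
        seen = set()
        for lab in img.labeltable.labels:
            if lab.key in seen:
                raise FormatError(f"{path}: duplicate label id {lab.key}")
            seen.add(lab.key)
            if lab.label and lab.key != 0:  # 0 = unassigned/medial wall
                names[int(lab.key)] = lab.label
        return ParcellationMap(mesh, labels, names)
    if path.suffix == ".annot":
        labels, ctab, annot_names = nib.freesurfer.read_annot(str(path))
        labels = np.asarray(labels, dtype=np.int64)
        labels[labels < 0] = 0
        names = {
            i: (n.decode() if isinstance(n, bytes) else str(n))
            for i, n in enumerate(annot_names)
            if i > 0
        }
        return ParcellationMap(mesh, labels, names)
    raise FormatError(f"{path}: unsupported label format")


def write_labels(path, parc: ParcellationMap) -> None:
    """Write a parcellation as GIFTI .label.gii with a label table."""
    img = gifti.GiftiImage()
    table = gifti.GiftiLabelTable()
    rng = np.random.default_rng(0)  # stable colors derived from the ids
    for key in [0] + [int(k) for k in parc.region_ids()]:
        r, g, b = rng.uniform(0.1, 0.9, size=3)
        lab = gifti.GiftiLabel(key, r, g, b, 1.0)
        lab.label = "???" if key == 0 else parc.names[key]
        table.labels.append(lab)
    img.labeltable = table
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            parc.labels.astype(np.int32),
            intent="NIFTI_INTENT_LABEL",
            datatype="NIFTI_TYPE_INT32",
        )
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# deformation fields
# ---------------------------------------------------------------------------

def write_deformation_csv(
    path, field: DeformationField, config: Optional[dict] = None
) -> None:
    """Write warped positions as CSV plus a JSON sidecar with the mesh hash."""
    path = Path(path)
    n = field.mesh.n_vertices
    with open(path, "w") as fh:
        fh.write("vertex,x,y,z\n")
        for i in range(n):
            x, y, z = field.warped[i]
            fh.write(f"{i},{x:.17g},{y:.17g},{z:.17g}\n")
    sidecar = {"source_mesh_hash": mesh_hash(field.mesh), "config": config or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_deformation_csv(path, mesh: SphericalMesh) -> DeformationField:
    """Read a deformation CSV back onto its source mesh (hash-checked)."""
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    if data.ndim != 2 or data.shape[1] != 4:
        raise FormatError(f"{path}: expected 4 columns (vertex, x, y, z)")
    order = np.argsort(data[:, 0])
    warped = data[order, 1:4]
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar.get("source_mesh_hash") not in (None, mesh_hash(mesh)):
            raise FormatError(f"{path}: deformation belongs to a different mesh")
    return DeformationField(mesh, warped)


def write_deformation_gifti(
    path, field: DeformationField, config: Optional[dict] = None
) -> None:
    """Write warped positions as a 3-column .func.gii plus a JSON sidecar."""
    write_scalars(path, field.warped, names=["warped_x", "warped_y", "warped_z"])
    sidecar = {"source_mesh_hash": mesh_hash(field.mesh), "config": config or {}}
    Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_deformation_gifti(path, mesh: SphericalMesh) -> DeformationField:
    warped = np.asarray(read_scalars(path), dtype=np.float64)
    if warped.ndim != 2 or warped.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 scalar columns (x, y, z)")
    warped /= np.linalg.norm(warped, axis=1, keepdims=True)
    return DeformationField(mesh, warped)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def write_timeseries_h5(path, ts: TimeSeriesMatrix) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("timeseries", data=ts.data)
        d.attrs["n_vertices"] = ts.n_vertices
        d.attrs["sampling_interval"] = ts.sampling_interval


def read_timeseries_h5(path) -> TimeSeriesMatrix:
    with h5py.File(path, "r") as f:
        if "timeseries" not in f:
            raise FormatError(f"{path}: missing 'timeseries' dataset")
        d = f["timeseries"]
        data = np.asarray(d)
        interval = float(d.attrs.get("sampling_interval", 1.0))
        n_vertices = int(d.attrs.get("n_vertices", data.shape[1]))
    if data.shape[1] != n_vertices:
        raise FormatError(f"{path}: vertex-count attribute disagrees with layout")
    return TimeSeriesMatrix(data, interval)
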