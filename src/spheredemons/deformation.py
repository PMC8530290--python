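"""Diffeomorphic deformation fields on the sphere and their algebra.

A :class:`DeformationField` stores, for every vertex of its source mesh,
the warped position on the unit sphere.  A field is diffeomorphic when no
face of the warped mesh reverses orientation relative to the source mesh
(signed origin-tetrahedron volume keeps its sign on every face).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import (
    GeometryError,
    SphericalMesh,
    geodesic_distance,
    interpolate_scalar,
    resample_labels,
)

__all__ = [
    "DeformationField",
    "identity_field",
    "rotation_field",
    "apply_deformation",
    "compose_deformations",
    "invert_deformation",
]


@dataclass
class DeformationField:
    """Per-vertex mapping of a source mesh onto the sphere."""

    mesh: SphericalMesh
    warped: np.ndarray  # (N, 3) unit vectors

    def __post_init__(self) -> None:
        self.warped = np.ascontiguousarray(self.warped, dtype=np.float64)
        if self.warped.shape != self.mesh.vertices.shape:
            raise ValueError("warped positions must match source vertex count")

    def validate(self) -> None:
        norms = np.linalg.norm(self.warped, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise GeometryError("warped positions deviate from unit norm")
        if not self.is_diffeomorphic():
            raise GeometryError("deformation folds the mesh")

    def is_diffeomorphic(self) -> bool:
        """True when every warped face keeps the source orientation sign."""
        ref = np.sign(self.mesh.signed_volumes())
        cur = np.sign(self.mesh.signed_volumes(positions=self.warped))
        return bool((ref == cur).all())

    def displacement_magnitude(self) -> np.ndarray:
        """Geodesic displacement of each vertex, radians."""
        return geodesic_distance(self.mesh.vertices, self.warped, check=False)

    def copy(self) -> "DeformationField":
        return DeformationField(self.mesh, self.warped.copy())


def identity_field(mesh: SphericalMesh) -> DeformationField:
    return DeformationField(mesh, mesh.vertices.copy())


def rotation_field(mesh: SphericalMesh, axis, angle: float) -> DeformationField:
    """Rigid rotation of the sphere by ``angle`` radians about ``axis``."""
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=np.float64)
    rot = Rotation.from_rotvec(angle * axis / np.linalg.norm(axis))
    return DeformationField(mesh, rot.apply(mesh.vertices))


def apply_deformation(
    field: DeformationField,
    payload: np.ndarray,
    payload_mesh: SphericalMesh,
    mode: str = "linear",
) -> np.ndarray:
    """Pull per-vertex data back through a deformation.

    ``payload`` lives on ``payload_mesh`` (the sphere the field maps
    *into*); the result has one value per source vertex of ``field``,
    sampled at the warped positions.  ``mode='linear'`` interpolates
    barycentrically; ``mode='nearest'`` transfers labels and is mandatory
    for integer data (labels must never be averaged).
    """
    payload = np.asarray(payload)
    if mode == "linear":
        if np.issubdtype(payload.dtype, np.integer):
            raise ValueError("mode='linear' on integer labels; use mode='nearest'")
        return interpolate_scalar(payload_mesh, payload, field.warped)
    if mode == "nearest":
        return resample_labels(payload_mesh, payload, field.warped)
    raise ValueError(f"unknown mode {mode!r}")


def compose_deformations(
    first: DeformationField, second: DeformationField
) -> DeformationField:
    """Composition ``x -> second(first(x))``.

    ``second``'s warp, a per-vertex field on its own source mesh, is
    interpolated at ``first``'s warped positions and renormalized.  The
    identity field is a two-sided unit.
    """
    sampled = interpolate_scalar(second.mesh, second.warped, first.warped)
    sampled /= np.linalg.norm(sampled, axis=1, keepdims=True)
    out = DeformationField(first.mesh, sampled)
    if not out.is_diffeomorphic():
        raise GeometryError("composition produced a folded deformation")
    return out


def invert_deformation(field: DeformationField) -> DeformationField:
    """Inverse of a diffeomorphic field by scattered interpolation.

    The warped vertex positions form a valid triangulation of the sphere
    (no folds), so the inverse map is obtained by interpolating the
    *original* vertex positions over the warped mesh at each query vertex.
    """
    if not field.is_diffeomorphic():
        raise ValueError("cannot invert a folded deformation field")
    orig = interpolate_scalar(
        field.mesh,
        field.mesh.vertices,
        field.mesh.vertices,
        positions=field.warped,
    )
    orig /= np.linalg.norm(orig, axis=1, keepdims=True)
    inv = DeformationField(field.mesh, orig)
    if not inv.is_diffeomorphic():
        raise GeometryError("inverse field folds the mesh")
    return inv
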