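"""Cortical parcellation maps: per-vertex region labels with a label table."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .mesh import SphericalMesh

__all__ = ["ParcellationMap"]


@dataclass
class ParcellationMap:
    """Per-vertex integer region labels on a spherical mesh.

    Label 0 is reserved for unassigned / medial-wall vertices.  ``names``
    maps label id to region name; missing names are synthesized as
    ``region_<id>``.
    """

    mesh: SphericalMesh
    labels: np.ndarray
    names: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.mesh.n_vertices,):
            raise ValueError("labels must have one entry per vertex")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 = unassigned)")
        for lab in self.region_ids():
            self.names.setdefault(int(lab), f"region_{int(lab)}")

    def region_ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the map."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids())

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label
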