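"""Multi-channel registration features and the structural/functional blend.

The demons similarity payload is a per-vertex feature matrix combining
structural maps — curvature (C), sulcal depth (SD), myelin (MY) — with
functional-network channels: node degree (FD) and eigenvalue-weighted
connectivity principal components (lambda_i * PC_i).  Across the iterative
registration the blend shifts from structural toward functional channels
with the schedule w_i = i / (i + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .mesh import SphericalMesh

__all__ = [
    "FeatureSet",
    "iteration_weight",
    "weight_pcs",
    "assemble_features",
    "STRUCTURAL_CHANNELS",
]

STRUCTURAL_CHANNELS = ("C", "SD", "MY")


@dataclass
class FeatureSet:
    """Named per-vertex feature channels on a spherical mesh.

    ``weights`` records the multiplier already applied to each (z-scored)
    channel; the demons similarity uses the channel values as stored.
    """

    mesh: SphericalMesh
    channels: Dict[str, np.ndarray]
    weights: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.mesh.n_vertices
        for name, v in self.channels.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (n,):
                raise ValueError(f"channel {name!r} has shape {v.shape}, expected ({n},)")
            self.channels[name] = v
        for name in self.channels:
            self.weights.setdefault(name, 1.0)
        for name, w in self.weights.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"weight for {name!r} must be finite and >= 0")

    @property
    def channel_names(self) -> List[str]:
        return list(self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def data(self) -> np.ndarray:
        """(N, C) matrix in channel order."""
        return np.column_stack([self.channels[c] for c in self.channels])

    def subset(self, names) -> "FeatureSet":
        return FeatureSet(
            self.mesh,
            {n: self.channels[n].copy() for n in names},
            {n: self.weights[n] for n in names},
        )


def iteration_weight(iteration: int) -> float:
    """Functional-channel blend weight w_i = i / (i + 1)."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return iteration / (iteration + 1.0)


def weight_pcs(components: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Scale unit-norm component columns by their eigenvalue proportions.

    Returns an (N, K) matrix whose column i is lambda_i * PC_i, so each
    column's L2 norm equals lambda_i.
    """
    components = np.asarray(components, dtype=np.float64)
    if lambdas is None:
        raise ValueError("eigenvalue proportions are required")
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if components.ndim != 2 or components.shape[1] != lambdas.shape[0]:
        raise ValueError("components and lambdas disagree on component count")
    return components * lambdas[None, :]


def _zscore(v: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    """z-score over unmasked vertices; constant channels map to zero."""
    sel = v if mask is None else v[~mask]
    mu = sel.mean()
    sd = sel.std()
    if sd < 1e-12:
        return np.zeros_like(v)
    return (v - mu) / sd


def assemble_features(
    mesh: SphericalMesh,
    structural: Dict[str, np.ndarray],
    functional: Optional[Dict[str, np.ndarray]] = None,
    iteration: int = 0,
    channel_scales: Optional[Dict[str, float]] = None,
) -> FeatureSet:
    """Build the demons feature matrix for a registration iteration.

    ``iteration=0`` is the structural-only stage (unit weights on whatever
    structural channels are supplied).  For ``iteration >= 1`` the blended
    matrix multiplies z-scored structural channels by (1 - w_i) and
    z-scored functional channels by w_i, with w_i = i/(i+1).  Each raw
    channel is z-scored over non-medial-wall vertices first so channels
    with incommensurate units contribute comparably.  Channel order is
    structural (C, SD, MY) then functional (FD, PC1..PCk), fixed.

    ``channel_scales`` multiplies selected channels after z-scoring;
    the pipeline uses it to restore the eigenvalue weighting of the PC
    channels (relative to the leading component), which a plain z-score
    would erase.
    """
    mask = mesh.medial_wall
    ordered_struct = {k: structural[k] for k in STRUCTURAL_CHANNELS if k in structural}
    for k in structural:
        if k not in ordered_struct:
            ordered_struct[k] = structural[k]
    if not ordered_struct:
        raise ValueError("at least one structural channel is required")

    if iteration == 0:
        channels = {k: _zscore(np.asarray(v, float), mask) for k, v in ordered_struct.items()}
        weights = {k: 1.0 for k in channels}
        return FeatureSet(mesh, channels, weights)

    if not functional:
        raise ValueError("functional channels required for iteration >= 1")
    scales = channel_scales or {}
    w = iteration_weight(iteration)
    channels: Dict[str, np.ndarray] = {}
    weights: Dict[str, float] = {}
    for k, v in ordered_struct.items():
        s = scales.get(k, 1.0)
        channels[k] = (1.0 - w) * s * _zscore(np.asarray(v, float), mask)
        weights[k] = (1.0 - w) * s
    for k, v in functional.items():
        s = scales.get(k, 1.0)
        channels[k] = w * s * _zscore(np.asarray(v, float), mask)
        weights[k] = w * s
    return FeatureSet(mesh, channels, weights)
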