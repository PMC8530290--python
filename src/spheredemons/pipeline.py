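"""The full iterative functional-network registration algorithm.

Stage one matches the two spheres on structural features alone.  Stage
two alternates, up to ``max_iters`` times: transfer the fixed-sphere
parcellation to the moving sphere through the current alignment, rebuild
the moving sphere's functional channels (node degree and dual-regression
projected connectivity components) from its raw time series under that
parcellation, blend structural and functional channels with the
w_i = i/(i+1) schedule, and re-run demons registration warm-started from
the current field.  The fixed sphere's functional channels are computed
once and frozen.  The output is the final diffeomorphic deformation, the
moving-sphere parcellation, and a per-iteration trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .connectivity import (
    ConnectivityMatrix,
    PCSet,
    TimeSeriesMatrix,
    dual_regression_project,
    node_degree,
    node_roi_connectivity,
)
from .deformation import DeformationField, apply_deformation, identity_field
from .demons import DemonsConfig, demons_register
from .features import FeatureSet, assemble_features, iteration_weight
from .mesh import SphericalMesh, interpolate_scalar
from .parcellation import ParcellationMap

logger = logging.getLogger(__name__)

__all__ = [
    "IterationTrace",
    "structural_match",
    "build_parcellation",
    "IterativeRegistration",
    "run_iterative_registration",
]


@dataclass
class IterationTrace:
    """Per-iteration bookkeeping: blend weight, SSD, optional truth errors."""

    records: List[Dict] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def __len__(self) -> int:
        return len(self.records)


def structural_match(
    moving: FeatureSet, fixed: FeatureSet, config: Optional[DemonsConfig] = None
) -> DeformationField:
    """Stage-one registration on structural channels only."""
    return demons_register(fixed, moving, config=config)


def build_parcellation(
    p_fixed: ParcellationMap, t_current: DeformationField
) -> ParcellationMap:
    """Transfer the fixed parcellation onto the moving sphere.

    Each moving vertex takes the fixed-sphere label at its warped
    position (nearest-vertex transfer; label 0 propagates).
    """
    labels = apply_deformation(
        t_current, p_fixed.labels, p_fixed.mesh, mode="nearest"
    )
    return ParcellationMap(t_current.mesh, labels, dict(p_fixed.names))


def _resample_reference_pcs(
    pcs: PCSet, fixed_mesh: SphericalMesh, t_current: DeformationField
) -> PCSet:
    """Sample the fixed-side reference components at the warped positions."""
    comps = interpolate_scalar(fixed_mesh, pcs.components, t_current.warped)
    norms = np.linalg.norm(comps, axis=0)
    if (norms == 0).any():
        raise ValueError("reference component degenerated to zero after resampling")
    return PCSet(comps / norms, pcs.lambdas, provenance="projected")


class IterativeRegistration(BaseEstimator):
    """Iterative structural-to-functional spherical registration.

    Parameters
    ----------
    max_iters : int
        Functional (stage-two) iterations; default 5 — a small cap avoids
        overfitting highly folded cortices.
    retain_fraction : float
        Top fraction of connectivity entries kept in the node-degree
        binarization (default 0.25).
    demons_config / structural_config : DemonsConfig, optional
        Engine settings for the functional iterations and the structural
        stage.  The structural default regularizes heavily (the
        structural maps are smooth and band-limited); the functional
        default regularizes lightly so localized functional-only warps
        remain recoverable.

    A functional iteration is accepted only if it lowers the
    weight-normalized feature SSD (the weighted SSD divided by the summed
    squared channel weights, which makes the changing w_i blends
    comparable); a non-improving iteration is rejected and stops the
    loop.  This guards against the overfitting that the w_i schedule
    invites once the genuinely recoverable warp has been absorbed.

    After ``fit``: ``deformation_`` (moving vertex -> fixed sphere),
    ``parcellation_`` (final moving-sphere labels), ``trace_``.
    """

    def __init__(
        self,
        max_iters: int = 5,
        retain_fraction: float = 0.25,
        demons_config: Optional[DemonsConfig] = None,
        structural_config: Optional[DemonsConfig] = None,
    ):
        self.max_iters = max_iters
        self.retain_fraction = retain_fraction
        self.demons_config = demons_config
        self.structural_config = structural_config

    @staticmethod
    def default_structural_config() -> DemonsConfig:
        """Heavily regularized engine settings for the structural stage."""
        return DemonsConfig(
            field_smoothing_passes=10,
            update_smoothing_passes=2,
            outer_iterations=15,
            convergence_tol=1e-4,
        )

    def fit(
        self,
        moving_structural: Dict[str, np.ndarray],
        moving_ts: TimeSeriesMatrix,
        moving_mesh: SphericalMesh,
        fixed_structural: Dict[str, np.ndarray],
        fixed_fd: np.ndarray,
        fixed_pcs: PCSet,
        fixed_parcellation: ParcellationMap,
        evaluate_cb: Optional[Callable] = None,
    ) -> "IterativeRegistration":
        """Run stage one and the stage-two loop.

        ``fixed_fd`` and ``fixed_pcs`` are the fixed sphere's precomputed
        functional channels (for cross-species runs, the group-average
        human channels); they stay frozen across iterations.  The moving
        side supplies raw time series so its channels are recomputed each
        iteration under the updated parcellation.  ``evaluate_cb(field,
        parcellation)``, if given, returns extra quantities (e.g. ground
        truth errors) merged into each trace record.
        """
        cfg = self.demons_config or DemonsConfig()
        scfg = self.structural_config or self.default_structural_config()
        fixed_mesh = fixed_parcellation.mesh
        trace = IterationTrace()

        # -- stage one: structural matching --------------------------------
        mov_fs0 = assemble_features(moving_mesh, moving_structural, iteration=0)
        fix_fs0 = assemble_features(fixed_mesh, fixed_structural, iteration=0)
        ssd0_before = _weighted_ssd(fix_fs0, mov_fs0, identity_field(moving_mesh))
        t_cur = structural_match(mov_fs0, fix_fs0, config=scfg)
        ssd0_after = _weighted_ssd(fix_fs0, mov_fs0, t_cur)
        rec = dict(
            iteration=0, w=0.0, ssd_before=ssd0_before, ssd_after=ssd0_after,
            n_empty_regions=0, stopped_early=False, accepted=True,
        )
        if evaluate_cb is not None:
            rec.update(evaluate_cb(t_cur, build_parcellation(fixed_parcellation, t_cur)))
        trace.add(**rec)

        # PC channel scales: eigenvalue proportions of the fixed reference,
        # normalized so the leading component has scale 1; shared by both
        # sides so the channels stay commensurate.
        lam = fixed_pcs.lambdas
        pc_scales = lam / lam.max() if lam.max() > 0 else np.ones_like(lam)
        pc_names = [f"PC{i + 1}" for i in range(fixed_pcs.n_components)]
        scales = {name: s for name, s in zip(pc_names, pc_scales)}

        fixed_functional = {"FD": np.asarray(fixed_fd, dtype=np.float64)}
        for i_pc, name in enumerate(pc_names):
            fixed_functional[name] = fixed_pcs.components[:, i_pc]

        prev_after = None
        # -- stage two: functional iterations ------------------------------
        for i in range(1, self.max_iters + 1):
            parc_m = build_parcellation(fixed_parcellation, t_cur)
            n_expected = fixed_parcellation.n_regions
            n_empty = n_expected - parc_m.n_regions
            if n_empty:
                logger.info("iteration %d: %d regions empty on moving sphere", i, n_empty)

            conn_m = node_roi_connectivity(moving_ts, parc_m)
            fd_m = node_degree(conn_m, retain_fraction=self.retain_fraction)
            ref_on_moving = _resample_reference_pcs(fixed_pcs, fixed_mesh, t_cur)
            proj = dual_regression_project(ref_on_moving, _pad_regions(
                conn_m, fixed_parcellation.region_ids()))

            moving_functional = {"FD": fd_m.astype(np.float64)}
            for i_pc, name in enumerate(pc_names):
                moving_functional[name] = proj.components[:, i_pc]

            mov_fs = assemble_features(
                moving_mesh, moving_structural, moving_functional,
                iteration=i, channel_scales=scales,
            )
            fix_fs = assemble_features(
                fixed_mesh, fixed_structural, fixed_functional,
                iteration=i, channel_scales=scales,
            )

            ssd_before = _weighted_ssd(fix_fs, mov_fs, t_cur)
            t_next = demons_register(fix_fs, mov_fs, config=cfg, init=t_cur)
            ssd_after = _weighted_ssd(fix_fs, mov_fs, t_next)
            weight_norm = sum(w**2 for w in mov_fs.weights.values())
            ssd_norm = ssd_after / weight_norm

            if prev_after is not None and ssd_norm >= prev_after:
                # normalized SSD no longer decreasing: reject and stop
                logger.info(
                    "early stop at iteration %d: normalized SSD %.4f >= %.4f",
                    i, ssd_norm, prev_after,
                )
                rec = dict(
                    iteration=i, w=iteration_weight(i), ssd_before=ssd_before,
                    ssd_after=ssd_after, n_empty_regions=n_empty,
                    stopped_early=True, accepted=False,
                )
                if evaluate_cb is not None:
                    rec.update(
                        evaluate_cb(t_cur, build_parcellation(fixed_parcellation, t_cur))
                    )
                trace.add(**rec)
                break
            prev_after = ssd_norm
            t_cur = t_next

            rec = dict(
                iteration=i, w=iteration_weight(i), ssd_before=ssd_before,
                ssd_after=ssd_after, n_empty_regions=n_empty,
                stopped_early=False, accepted=True,
            )
            if evaluate_cb is not None:
                rec.update(
                    evaluate_cb(t_cur, build_parcellation(fixed_parcellation, t_cur))
                )
            trace.add(**rec)

        self.deformation_ = t_cur
        self.parcellation_ = build_parcellation(fixed_parcellation, t_cur)
        self.trace_ = trace
        return self


def _pad_regions(conn: ConnectivityMatrix, expected_ids: np.ndarray) -> ConnectivityMatrix:
    """Insert zero columns for regions that are empty on the moving sphere.

    Keeps the region dimension aligned with the fixed-side reference when
    a label transfer leaves some regions without vertices.
    """
    if len(conn.region_ids) == len(expected_ids) and (
        conn.region_ids == expected_ids
    ).all():
        return conn
    values = np.zeros((conn.values.shape[0], len(expected_ids)))
    pos = {int(r): k for k, r in enumerate(expected_ids)}
    for k, r in enumerate(conn.region_ids):
        values[:, pos[int(r)]] = conn.values[:, k]
    return ConnectivityMatrix(values, expected_ids, conn.n_zero_variance)


def _weighted_ssd(fixed: FeatureSet, moving: FeatureSet, field: DeformationField) -> float:
    ff = interpolate_scalar(fixed.mesh, fixed.data(), field.warped)
    return float(((moving.data() - ff) ** 2).sum())


def run_iterative_registration(
    moving_structural: Dict[str, np.ndarray],
    moving_ts: TimeSeriesMatrix,
    moving_mesh: SphericalMesh,
    fixed_structural: Dict[str, np.ndarray],
    fixed_fd: np.ndarray,
    fixed_pcs: PCSet,
    fixed_parcellation: ParcellationMap,
    max_iters: int = 5,
    demons_config: Optional[DemonsConfig] = None,
    structural_config: Optional[DemonsConfig] = None,
    evaluate_cb: Optional[Callable] = None,
    retain_fraction: float = 0.25,
):
    """Functional wrapper over :class:`IterativeRegistration`.

    Returns ``(deformation, parcellation, trace)``.
    """
    est = IterativeRegistration(
        max_iters=max_iters,
        retain_fraction=retain_fraction,
        demons_config=demons_config,
        structural_config=structural_config,
    )
    est.fit(
        moving_structural, moving_ts, moving_mesh,
        fixed_structural, fixed_fd, fixed_pcs, fixed_parcellation,
        evaluate_cb=evaluate_cb,
    )
    return est.deformation_, est.parcellation_, est.trace_
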