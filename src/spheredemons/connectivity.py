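"""Vertex-to-region functional connectivity and dual-regression group PCA.

The functional payload of the registration comes from resting-state BOLD
time series.  For every vertex, Pearson correlation with the mean series
of each parcellation region yields an N x R connectivity matrix; from it
come the node-degree channel (count of supra-threshold connections) and
the principal connectivity components.  Because individual PCA components
do not correspond across subjects or species, correspondence is recovered
by a dual-regression scheme: individual PCA, group-level PCA of the
concatenated eigenvalue-weighted components, and regression of each
subject's connectivity matrix back onto the group components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .deformation import DeformationField
from .features import weight_pcs
from .mesh import SphericalMesh, interpolate_scalar
from .parcellation import ParcellationMap

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "PCSet",
    "node_roi_connectivity",
    "node_degree",
    "individual_pca",
    "group_pca",
    "select_shared_pcs",
    "dual_regression_project",
    "group_average_pcs",
    "DualRegressionGroupPCA",
]


@dataclass
class TimeSeriesMatrix:
    """BOLD samples, timepoints x vertices, with the sampling interval."""

    data: np.ndarray
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("time series needs >= 2 timepoints (T x N layout)")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """N vertices x R regions Pearson correlations."""

    values: np.ndarray
    region_ids: np.ndarray
    n_zero_variance: int = 0

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
        if self.values.shape[1] != len(self.region_ids):
            raise ValueError("column count must equal number of regions")
        if not np.isfinite(self.values).all():
            raise ValueError("connectivity entries must be finite")
        if np.abs(self.values).max() > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class PCSet:
    """Unit-norm per-vertex component loadings with eigenvalue proportions.

    ``provenance`` is 'individual', 'group', or 'projected'; lambdas are
    non-increasing for the first two.
    """

    components: np.ndarray  # (N, K), columns unit norm
    lambdas: np.ndarray  # (K,) variance proportions
    provenance: str = "individual"

    def __post_init__(self) -> None:
        self.components = np.ascontiguousarray(self.components, dtype=np.float64)
        self.lambdas = np.asarray(self.lambdas, dtype=np.float64)
        norms = np.linalg.norm(self.components, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("component columns must be unit norm")
        if (self.lambdas < -1e-12).any() or self.lambdas.sum() > 1 + 1e-9:
            raise ValueError("lambdas must be non-negative with sum <= 1")
        if self.provenance in ("individual", "group") and (
            np.diff(self.lambdas) > 1e-12
        ).any():
            raise ValueError("lambdas must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def weighted(self) -> np.ndarray:
        """(N, K) matrix of lambda_i-scaled components."""
        return weight_pcs(self.components, self.lambdas)


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def node_roi_connectivity(
    ts: TimeSeriesMatrix, parc: ParcellationMap
) -> ConnectivityMatrix:
    """Pearson correlation of every vertex series with every region-mean series.

    Regions are the nonzero labels of ``parc``; label 0 (medial wall /
    unassigned) defines no region but its vertices still get a row.
    Zero-variance vertex or region series produce 0 entries and are
    counted in ``n_zero_variance`` with a warning.
    """
    if ts.n_vertices != parc.mesh.n_vertices:
        raise ValueError("time series vertex count does not match parcellation")
    ids = parc.region_ids()
    if len(ids) == 0:
        raise ValueError("parcellation has no nonzero region")

    x = ts.data - ts.data.mean(axis=0)  # (T, N)
    region_means = np.column_stack(
        [ts.data[:, parc.labels == r].mean(axis=1) for r in ids]
    )
    y = region_means - region_means.mean(axis=0)  # (T, R)

    sx = np.linalg.norm(x, axis=0)
    sy = np.linalg.norm(y, axis=0)
    n_zero = int((sx == 0).sum() + (sy == 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero-variance series set to correlation 0")
    sx = np.where(sx == 0, 1.0, sx)
    sy = np.where(sy == 0, 1.0, sy)
    corr = (x / sx).T @ (y / sy)
    corr = np.clip(corr, -1.0, 1.0)
    zero_rows = np.linalg.norm(ts.data - ts.data.mean(axis=0), axis=0) == 0
    corr[zero_rows] = 0.0
    return ConnectivityMatrix(corr, ids, n_zero_variance=n_zero)


def node_degree(conn: ConnectivityMatrix, retain_fraction: float = 0.25) -> np.ndarray:
    """Per-vertex count of connections surviving a global top-fraction cut.

    A single threshold — the k-th largest of all N x R entries with
    k = round(retain_fraction * N * R) — binarizes the whole matrix; the
    degree of a vertex is the number of surviving entries in its row.
    """
    if not 0 < retain_fraction < 1:
        raise ValueError("retain_fraction must be in (0, 1)")
    flat = conn.values.ravel()
    if np.ptp(flat) == 0:
        raise ValueError("degenerate connectivity matrix: all entries equal")
    k = int(round(retain_fraction * flat.size))
    k = max(k, 1)
    threshold = np.partition(flat, flat.size - k)[flat.size - k]
    return (conn.values >= threshold).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# PCA steps
# ---------------------------------------------------------------------------

def _column_centered_svd(matrix: np.ndarray):
    """SVD of the column-centered matrix; spatial modes are U's columns."""
    x = matrix - matrix.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    return u, s, total


def individual_pca(conn: ConnectivityMatrix, n_components: int = 20) -> PCSet:
    """Leading spatial modes of one subject's connectivity matrix.

    Columns (regions) are centered over vertices; components are the
    left singular vectors, lambdas the eigenvalue proportions of total
    variance.  Requests beyond the matrix rank are truncated with a
    warning.
    """
    n, r = conn.values.shape
    if n_components > min(n, r):
        raise ValueError("n_components must be <= min(N, R)")
    u, s, total = _column_centered_svd(conn.values)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating"
        )
        n_components = rank
    lam = s[:n_components] ** 2 / total
    return PCSet(u[:, :n_components], lam, provenance="individual")


def group_pca(individual_sets: Sequence[PCSet], n_group: int = 10) -> PCSet:
    """Group-level PCA of all subjects' eigenvalue-weighted components.

    Every individual component column, scaled by its lambda, is
    concatenated into one vertices x (n_subjects * n_individual) matrix
    and decomposed the same way as an individual matrix.
    """
    if not individual_sets:
        raise ValueError("need at least one individual PCSet")
    n_vertices = individual_sets[0].components.shape[0]
    for s in individual_sets:
        if s.components.shape[0] != n_vertices:
            raise ValueError("all PCSets must share the vertex dimension")
    stacked = np.hstack([s.weighted() for s in individual_sets])
    u, sv, total = _column_centered_svd(stacked)
    n_group = min(n_group, u.shape[1])
    lam = sv[:n_group] ** 2 / total
    return PCSet(u[:, :n_group], lam, provenance="group")


def pullback_positions(field: DeformationField, queries: np.ndarray) -> np.ndarray:
    """Positions on the field's source sphere that map to ``queries``.

    Interpolates the source vertex coordinates over the warped
    triangulation (the scattered-data inverse of the field) at each query.
    """
    pos = interpolate_scalar(
        field.mesh, field.mesh.vertices, queries, positions=field.warped
    )
    pos = np.atleast_2d(pos)
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def select_shared_pcs(
    group_a: PCSet,
    group_b: PCSet,
    correspondence: DeformationField,
    mesh_a: SphericalMesh,
    mesh_b: SphericalMesh,
    min_abs_corr: float = 0.5,
) -> List[Tuple[int, int, float]]:
    """Pair group components shared across the two spheres.

    ``correspondence`` maps mesh_b vertices into mesh_a's sphere (the
    structural alignment); group_b components are resampled through it
    onto mesh_a's vertices, correlated pairwise with group_a components,
    and paired greedily by descending absolute correlation.  Pairs with
    |corr| >= ``min_abs_corr`` are kept, each component used at most once;
    the signed correlation records the sign of the pairing.
    """
    queries = pullback_positions(correspondence, mesh_a.vertices)
    b_on_a = interpolate_scalar(mesh_b, group_b.components, queries)

    a = group_a.components - group_a.components.mean(axis=0)
    b = b_on_a - b_on_a.mean(axis=0)
    a = a / np.linalg.norm(a, axis=0)
    b = b / np.linalg.norm(b, axis=0)
    corr = a.T @ b  # (Ka, Kb)

    order = np.argsort(-np.abs(corr).ravel())
    used_a, used_b = set(), set()
    pairs: List[Tuple[int, int, float]] = []
    for flat in order:
        i, j = divmod(int(flat), corr.shape[1])
        if i in used_a or j in used_b:
            continue
        if abs(corr[i, j]) < min_abs_corr:
            break
        pairs.append((i, j, float(corr[i, j])))
        used_a.add(i)
        used_b.add(j)
    if not pairs:
        raise ValueError(
            "no component pair reaches the correlation threshold; "
            "consider lowering min_abs_corr"
        )
    return pairs


def dual_regression_project(group: PCSet, conn: ConnectivityMatrix) -> PCSet:
    """Project group components onto one subject's connectivity matrix.

    Two regression stages: the column-centered matrix is regressed onto
    the group spatial components (joint multivariate fit, giving each
    component a region profile), then regressed onto those profiles to
    reconstruct subject-specific spatial maps.  Maps are renormalized to
    unit norm; lambdas are each component's share of the matrix's total
    variance explained by its rank-one term.  Component order follows the
    group set (no reordering — correspondence is the point).
    """
    g = group.components
    if np.linalg.matrix_rank(g) < g.shape[1]:
        raise ValueError("group component set is rank deficient")
    x = conn.values - conn.values.mean(axis=0, keepdims=True)
    if g.shape[0] != x.shape[0]:
        raise ValueError("group components and connectivity disagree on vertex count")

    b, *_ = np.linalg.lstsq(g, x, rcond=None)  # (K, R) region profiles
    p, *_ = np.linalg.lstsq(b.T, x.T, rcond=None)  # (K, N)
    p = p.T  # (N, K) subject spatial maps
    total = (x**2).sum()
    # share of the jointly explained variance, split across components in
    # proportion to their rank-one terms (which overlap when correlated)
    explained = 1.0 - ((x - p @ b) ** 2).sum() / total
    raw = np.array(
        [
            (np.linalg.norm(p[:, i]) * np.linalg.norm(b[i])) ** 2
            for i in range(g.shape[1])
        ]
    )
    lam = explained * raw / raw.sum() if raw.sum() > 0 else raw
    norms = np.linalg.norm(p, axis=0)
    if (norms == 0).any():
        raise ValueError("degenerate projected component (zero map)")
    return PCSet(p / norms, np.minimum(lam, 1.0), provenance="projected")


def group_average_pcs(
    projected_sets: Sequence[PCSet], reference: Optional[PCSet] = None
) -> PCSet:
    """Vertex-wise mean of projected components across subjects.

    Each subject's component is sign-harmonized against the reference
    (the group set the projections came from; defaults to the first
    subject) before averaging, so sign-indeterminate copies reinforce
    instead of cancelling.  The mean is renormalized to unit norm and the
    lambdas averaged.
    """
    if not projected_sets:
        raise ValueError("need at least one projected PCSet")
    ref = (reference or projected_sets[0]).components
    acc = np.zeros_like(projected_sets[0].components)
    for s in projected_sets:
        if s.components.shape != ref.shape:
            raise ValueError("all projected sets must share shape")
        signs = np.sign(np.einsum("nk,nk->k", s.components, ref))
        signs[signs == 0] = 1.0  # tie: keep positive first-loading convention
        acc += s.components * signs
    acc /= len(projected_sets)
    norms = np.linalg.norm(acc, axis=0)
    if (norms == 0).any():
        raise ValueError("components cancelled to zero in averaging")
    lam = np.mean([s.lambdas for s in projected_sets], axis=0)
    return PCSet(acc / norms, lam, provenance="projected")


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class DualRegressionGroupPCA(BaseEstimator):
    """Dual-regression group PCA over a cohort of connectivity matrices.

    ``fit`` runs individual PCA per subject and the group-level PCA of
    the concatenated weighted components; ``transform`` projects the
    fitted group components onto any subject's connectivity matrix.

    Parameters
    ----------
    n_individual : int
        Components kept per subject (default 20, capturing >90%% of
        variance in typical connectivity matrices).
    n_group : int
        Group components kept (default 10).
    """

    def __init__(self, n_individual: int = 20, n_group: int = 10):
        self.n_individual = n_individual
        self.n_group = n_group

    def fit(self, conns: Sequence[ConnectivityMatrix]) -> "DualRegressionGroupPCA":
        self.individual_sets_ = [
            individual_pca(c, n_components=self.n_individual) for c in conns
        ]
        self.group_ = group_pca(self.individual_sets_, n_group=self.n_group)
        return self

    def transform(self, conn: ConnectivityMatrix) -> PCSet:
        if not hasattr(self, "group_"):
            raise RuntimeError("fit must be called before transform")
        return dual_regression_project(self.group_, conn)

    def fit_transform(self, conns: Sequence[ConnectivityMatrix]) -> List[PCSet]:
        self.fit(conns)
        return [self.transform(c) for c in conns]
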