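"""Areal change/asymmetry indices, region statistics, registration errors.

Areal indices compare the per-vertex attached surface area F(S) (sum of
incident triangle areas) before/after registration (ACI) or between the
left hemisphere and the registered right hemisphere (AAI); both are
signed ratios bounded in (-1, 1).  Region tables report one- and
two-sample t statistics per parcellation region, with a signed
-log10(p) map for rendering.  Ground-truth registration errors are the
summed geodesic displacement difference and the wrong-label count.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .deformation import DeformationField
from .mesh import geodesic_distance
from .parcellation import ParcellationMap

__all__ = [
    "areal_change_index",
    "areal_asymmetry_index",
    "region_aggregate",
    "one_sample_ttest",
    "two_sample_ttest",
    "geodesic_error",
    "label_error",
]


def _areal_ratio(numer_area: np.ndarray, denom_area: np.ndarray) -> np.ndarray:
    a = np.asarray(numer_area, dtype=np.float64)
    b = np.asarray(denom_area, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("area maps must have the same vertex count")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("vertex areas must be positive")
    return (a - b) / (a + b)


def areal_change_index(area_before: np.ndarray, area_after: np.ndarray) -> np.ndarray:
    """ACI = (F(S_reg) - F(S)) / (F(S_reg) + F(S)) per vertex.

    Positive where registration expanded the attached area, negative
    where it shrank; antisymmetric in its arguments, bounded in (-1, 1).
    """
    return _areal_ratio(area_after, area_before)


def areal_asymmetry_index(
    area_left: np.ndarray, area_right_registered: np.ndarray
) -> np.ndarray:
    """AAI = (F(S_left) - F(S_right)) / (F(S_left) + F(S_right)) per vertex.

    The right-hemisphere areas must already be resampled into left-vertex
    correspondence through the interhemispheric registration.  Positive
    where the left hemisphere is larger.
    """
    return _areal_ratio(area_left, area_right_registered)


def region_aggregate(
    vertex_values: np.ndarray, parc: ParcellationMap
) -> pd.Series:
    """Unweighted mean of a vertex map within each region (label 0 excluded).

    Empty regions are omitted with a warning.  Returns a Series indexed
    by region name.
    """
    v = np.asarray(vertex_values, dtype=np.float64)
    if v.shape[0] != parc.labels.shape[0]:
        raise ValueError("vertex values do not match parcellation size")
    out = {}
    for r in parc.region_ids():
        mask = parc.labels == r
        if not mask.any():  # pragma: no cover - region_ids implies nonempty
            warnings.warn(f"region {r} is empty; omitted")
            continue
        out[parc.names[int(r)]] = v[mask].mean()
    return pd.Series(out, dtype=np.float64)


def _finalize_table(names, means, stds, ts, ps, fdr=False) -> pd.DataFrame:
    table = pd.DataFrame(
        {"region": names, "mean": means, "std": stds, "t": ts, "p": ps}
    ).set_index("region")
    if fdr:
        # Benjamini-Hochberg adjusted p-values; raw p stays the default
        table["p_fdr"] = stats.false_discovery_control(np.clip(ps, 0, 1))
    return table


def one_sample_ttest(values: np.ndarray, region_names=None, fdr: bool = False) -> pd.DataFrame:
    """Per-region one-sample t-test against zero across subjects.

    ``values`` is subjects x regions.  t = mean / (std / sqrt(n)) with the
    sample (ddof=1) standard deviation; two-sided p from Student's t with
    n-1 degrees of freedom.  Zero-variance degenerate cases: all-zero
    values give t = 0 / p = 1 with a warning; zero std around a nonzero
    mean gives t = +/-inf and p = 0 with a warning.
    """
    x = np.atleast_2d(np.asarray(values, dtype=np.float64))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects per region")
    if region_names is None:
        region_names = [f"region_{i + 1}" for i in range(x.shape[1])]
    means = x.mean(axis=0)
    stds = x.std(axis=0, ddof=1)
    ts = np.empty(x.shape[1])
    ps = np.empty(x.shape[1])
    for k in range(x.shape[1]):
        if stds[k] == 0:
            if means[k] == 0:
                warnings.warn(f"region {region_names[k]}: 0/0 t statistic set to 0")
                ts[k], ps[k] = 0.0, 1.0
            else:
                warnings.warn(f"region {region_names[k]}: zero std, t set to +/-inf")
                ts[k] = np.inf * np.sign(means[k])
                ps[k] = 0.0
        else:
            ts[k] = means[k] / (stds[k] / np.sqrt(n))
            ps[k] = 2 * stats.t.sf(abs(ts[k]), df=n - 1)
    return _finalize_table(region_names, means, stds, ts, ps, fdr=fdr)


def two_sample_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    absolute: bool = False,
    equal_var: bool = False,
    region_names=None,
    fdr: bool = False,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Per-region two-sample t-test (Welch by default) between two groups.

    With ``absolute=True`` the test runs on |values|, disregarding sign
    (e.g. hemispheric dominance).  Returns the statistics table (mean/std
    are of group_a minus group_b differences of means; per-group moments
    are in extra columns) and the signed map -log10(p) * sign(t) for
    rendering.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups disagree on region count")
    if absolute:
        a, b = np.abs(a), np.abs(b)
    if region_names is None:
        region_names = [f"region_{i + 1}" for i in range(a.shape[1])]

    res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    ts = np.asarray(res.statistic, dtype=np.float64)
    ps = np.asarray(res.pvalue, dtype=np.float64)
    degenerate = ~np.isfinite(ts)
    if degenerate.any():
        diff = a.mean(axis=0) - b.mean(axis=0)
        warnings.warn("zero pooled variance in some regions")
        ts[degenerate] = np.where(
            diff[degenerate] == 0, 0.0, np.inf * np.sign(diff[degenerate])
        )
        ps[degenerate] = np.where(diff[degenerate] == 0, 1.0, 0.0)

    table = _finalize_table(
        region_names, a.mean(axis=0) - b.mean(axis=0),
        np.sqrt(a.var(axis=0, ddof=1) / a.shape[0] + b.var(axis=0, ddof=1) / b.shape[0]),
        ts, ps, fdr=fdr,
    )
    table["mean_a"] = a.mean(axis=0)
    table["std_a"] = a.std(axis=0, ddof=1)
    table["mean_b"] = b.mean(axis=0)
    table["std_b"] = b.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        signed_map = -np.log10(np.maximum(ps, np.finfo(float).tiny)) * np.sign(ts)
    signed_map[ts == 0] = 0.0
    return table, signed_map


def geodesic_error(
    estimated: DeformationField,
    truth: DeformationField,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Summed great-circle distance between estimated and true warped positions.

    Zero iff the fields agree everywhere.  ``mask`` restricts the sum to
    selected vertices.
    """
    if estimated.warped.shape != truth.warped.shape:
        raise ValueError("deformation fields live on different meshes")
    d = geodesic_distance(estimated.warped, truth.warped, check=False)
    if mask is not None:
        d = d[np.asarray(mask, dtype=bool)]
    return float(d.sum())


def label_error(estimated: ParcellationMap, truth: ParcellationMap) -> int:
    """Count of vertices whose labels differ (label 0 excluded on both sides)."""
    a, b = estimated.labels, truth.labels
    if a.shape != b.shape:
        raise ValueError("parcellations live on different meshes")
    valid = (a > 0) & (b > 0)
    return int((a[valid] != b[valid]).sum())
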