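"""Areal indices, region statistics, and ground-truth registration errors."""

import numpy as np
import pytest

from spheredemons.deformation import identity_field, rotation_field
from spheredemons.metrics import (
    areal_asymmetry_index,
    areal_change_index,
    geodesic_error,
    label_error,
    one_sample_ttest,
    region_aggregate,
    two_sample_ttest,
)
from spheredemons.parcellation import ParcellationMap


class TestArealIndices:
    def test_equal_areas_give_zero(self, rng):
        a = rng.uniform(0.5, 2.0, size=100)
        np.testing.assert_allclose(areal_change_index(a, a), 0, atol=1e-15)

    def test_doubling_gives_one_third(self):
        a = np.full(10, 1.0)
        np.testing.assert_allclose(areal_change_index(a, 2 * a), 1 / 3, atol=1e-15)

    def test_ratio_three_gives_half(self):
        left = np.full(5, 3.0)
        right = np.full(5, 1.0)
        np.testing.assert_allclose(areal_asymmetry_index(left, right), 0.5, atol=1e-15)

    def test_antisymmetry_and_bounds(self, rng):
        a = rng.uniform(0.1, 5.0, size=200)
        b = rng.uniform(0.1, 5.0, size=200)
        aci = areal_change_index(a, b)
        np.testing.assert_allclose(aci, -areal_change_index(b, a), atol=1e-15)
        assert (np.abs(aci) < 1).all()
        aai = areal_asymmetry_index(a, b)
        np.testing.assert_allclose(aai, -areal_asymmetry_index(b, a), atol=1e-15)

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            areal_change_index(np.array([1.0, 0.0]), np.array([1.0, 1.0]))


class TestRegionAggregate:
    def test_constant_field(self, ico2, rng):
        parc = ParcellationMap(ico2, rng.integers(1, 6, size=ico2.n_vertices))
        out = region_aggregate(np.full(ico2.n_vertices, 4.2), parc)
        np.testing.assert_allclose(out.values, 4.2, atol=1e-12)

    def test_two_region_signs(self, ico2):
        labels = np.where(ico2.vertices[:, 2] > 0, 1, 2).astype(np.int64)
        parc = ParcellationMap(ico2, labels, {1: "north", 2: "south"})
        values = np.where(labels == 1, 1.0, -1.0)
        out = region_aggregate(values, parc)
        assert out["north"] == 1.0 and out["south"] == -1.0

    def test_matches_brute_force_group_by(self, ico2, rng):
        labels = rng.integers(0, 7, size=ico2.n_vertices)
        parc = ParcellationMap(ico2, labels)
        values = rng.normal(size=ico2.n_vertices)
        out = region_aggregate(values, parc)
        for r in parc.region_ids():
            assert out[parc.names[int(r)]] == pytest.approx(
                values[labels == r].mean(), abs=1e-12
            )
        assert parc.names.get(0) is None  # label 0 excluded


def oracle_one_sample_t(x):
    n = len(x)
    return x.mean() / (x.std(ddof=1) / np.sqrt(n))


def oracle_welch_t(a, b):
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / np.sqrt(va + vb)


class TestTTests:
    def test_symmetric_triple_gives_t0_p1(self):
        table = one_sample_ttest(np.array([[-1.0], [0.0], [1.0]]))
        assert table["t"].iloc[0] == pytest.approx(0.0, abs=1e-15)
        assert table["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_textbook_formula_on_given_moments(self, rng):
        # a 13-subject vector with mean -0.156 and sample std 0.055 must
        # give t = mean / (std / sqrt(13)) ~ -10.2
        x = rng.normal(size=13)
        x = (x - x.mean()) / x.std(ddof=1)
        x = -0.156 + 0.055 * x
        table = one_sample_ttest(x[:, None])
        expect = -0.156 / (0.055 / np.sqrt(13))
        assert table["t"].iloc[0] == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(-10.227, abs=0.01)

    def test_one_sample_matches_oracle_to_1e9(self, rng):
        x = rng.normal(size=(10, 5))
        table = one_sample_ttest(x)
        for k in range(5):
            assert table["t"].iloc[k] == pytest.approx(
                oracle_one_sample_t(x[:, k]), abs=1e-9
            )

    def test_all_zero_degenerate_guarded(self):
        with pytest.warns(UserWarning):
            table = one_sample_ttest(np.zeros((4, 1)))
        assert table["t"].iloc[0] == 0.0 and table["p"].iloc[0] == 1.0

    def test_zero_std_nonzero_mean_flagged(self):
        with pytest.warns(UserWarning):
            table = one_sample_ttest(np.full((4, 1), 2.0))
        assert np.isinf(table["t"].iloc[0]) and table["p"].iloc[0] == 0.0

    def test_identical_groups_two_sample(self, rng):
        x = rng.normal(size=(6, 3))
        table, signed = two_sample_ttest(x, x.copy())
        np.testing.assert_allclose(table["t"], 0, atol=1e-12)
        np.testing.assert_allclose(table["p"], 1, atol=1e-12)
        np.testing.assert_allclose(signed, 0, atol=1e-12)

    def test_separated_groups_direction(self, rng):
        a = np.zeros((4, 1)) + 1e-6 * rng.normal(size=(4, 1))
        b = np.ones((4, 1)) + 1e-6 * rng.normal(size=(4, 1))
        table, signed = two_sample_ttest(a, b)
        assert table["t"].iloc[0] < -100
        assert signed[0] < 0

    def test_welch_matches_oracle_to_1e9(self, rng):
        a = rng.normal(size=(8, 4))
        b = rng.normal(size=(11, 4)) * 2 + 0.3
        table, _ = two_sample_ttest(a, b)
        for k in range(4):
            assert table["t"].iloc[k] == pytest.approx(
                oracle_welch_t(a[:, k], b[:, k]), abs=1e-9
            )

    def test_absolute_mode_ignores_sign(self, rng):
        a = rng.normal(size=(7, 2))
        table_abs, _ = two_sample_ttest(a, -a.copy(), absolute=True)
        np.testing.assert_allclose(table_abs["t"], 0, atol=1e-12)

    def test_one_sample_consistent_with_pooled_two_sample_limit(self, rng):
        # against a zero-variance zero group of equal size, the pooled
        # variance halves and the two-sample t equals the one-sample t
        x = rng.normal(size=(2000, 1)) + 0.5
        zeros = np.zeros((2000, 1)) + 1e-9 * rng.normal(size=(2000, 1))
        t1 = one_sample_ttest(x)["t"].iloc[0]
        t2 = two_sample_ttest(x, zeros, equal_var=True)[0]["t"].iloc[0]
        assert t2 == pytest.approx(t1, rel=0.01)


class TestRegistrationErrors:
    def test_identical_fields_zero_error(self, ico2):
        f = rotation_field(ico2, [0, 0, 1], 0.2)
        assert geodesic_error(f, f) == 0.0

    def test_rotation_error_matches_closed_form(self, ico3):
        # a z-rotation by theta displaces a vertex at colatitude alpha by
        # 2 asin(sin(alpha) sin(theta/2)) exactly
        theta = 0.3
        f = rotation_field(ico3, [0, 0, 1], theta)
        alpha = np.arccos(np.clip(ico3.vertices[:, 2], -1, 1))
        expect = 2 * np.arcsin(np.sin(alpha) * np.sin(theta / 2))
        assert geodesic_error(identity_field(ico3), f) == pytest.approx(
            expect.sum(), abs=1e-9
        )
        # the small-angle form theta*sin(colatitude) agrees to first order
        assert expect.sum() == pytest.approx((theta * np.sin(alpha)).sum(), rel=0.01)

    def test_error_mask_restricts_sum(self, ico2):
        f = rotation_field(ico2, [0, 0, 1], 0.1)
        mask = np.zeros(ico2.n_vertices, dtype=bool)
        mask[:10] = True
        full = geodesic_error(identity_field(ico2), f)
        part = geodesic_error(identity_field(ico2), f, mask=mask)
        assert 0 < part < full

    def test_triangle_inequality_over_three_fields(self, ico2):
        a = identity_field(ico2)
        b = rotation_field(ico2, [0, 0, 1], 0.1)
        c = rotation_field(ico2, [0, 1, 0], 0.2)
        assert geodesic_error(a, c) <= geodesic_error(a, b) + geodesic_error(b, c) + 1e-9


class TestLabelError:
    def test_identical_maps_zero(self, ico2, rng):
        labels = rng.integers(1, 5, size=ico2.n_vertices)
        p = ParcellationMap(ico2, labels)
        assert label_error(p, ParcellationMap(ico2, labels.copy())) == 0

    def test_single_flip_counts_one(self, ico2, rng):
        labels = rng.integers(1, 5, size=ico2.n_vertices)
        flipped = labels.copy()
        flipped[3] = labels[3] % 4 + 1
        assert label_error(ParcellationMap(ico2, flipped), ParcellationMap(ico2, labels)) == 1

    def test_k_relabeled_vertices_count_k(self, ico2, rng):
        labels = rng.integers(1, 5, size=ico2.n_vertices)
        k = 17
        idx = rng.choice(ico2.n_vertices, size=k, replace=False)
        changed = labels.copy()
        changed[idx] = labels[idx] + 10  # guaranteed different, nonzero
        assert label_error(ParcellationMap(ico2, changed), ParcellationMap(ico2, labels)) == k

    def test_label_zero_excluded_both_sides(self, ico2, rng):
        labels = rng.integers(1, 5, size=ico2.n_vertices)
        a, b = labels.copy(), labels.copy()
        a[0], b[1] = 0, 0
        b[0], a[1] = 3 if labels[0] != 3 else 4, 3 if labels[1] != 3 else 4
        assert label_error(ParcellationMap(ico2, a), ParcellationMap(ico2, b)) == 0
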