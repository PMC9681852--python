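import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import ks_2samp

import serm
from serm.distribution import FittedDistribution
from serm.equalize import (
    _levels_of,
    equalization_transform,
    make_roi_grid,
    raw_transform,
    roi_cdf,
    roi_histogram,
)
from serm.errors import ContractError, ParameterError

FAMILIES = [
    FittedDistribution("exponential", 10.0, 0.0),
    FittedDistribution("rayleigh", 0.3, 0.0),
    FittedDistribution("gaussian", 0.3, 0.0),
]


class TestRoiGrid:
    def test_default_half_window_tiling(self):
        grid = make_roi_grid(100, 200)
        assert grid.n_rois == 4
        sizes = {(r1 - r0, c1 - c0) for r0, r1, c0, c1 in grid.roi_list}
        assert sizes == {(50, 100)}

    def test_explicit_grid_override(self):
        grid = make_roi_grid(2400, 100, grid_override=(24, 2))
        assert grid.n_rois == 48

    def test_remainder_absorbed_by_edge_rois(self):
        grid = make_roi_grid(101, 201)
        assert grid.n_rois == 4
        sizes = sorted((r1 - r0, c1 - c0) for r0, r1, c0, c1 in grid.roi_list)
        assert sizes == [(50, 100), (50, 101), (51, 100), (51, 101)]

    def test_oversized_window_degrades_to_single_roi(self):
        with pytest.warns(UserWarning):
            grid = make_roi_grid(10, 10, window_frac=2.0)
        assert grid.n_rois == 1
        assert grid.roi_list == [(0, 10, 0, 10)]

    def test_coverage_is_exact_partition(self):
        for q, m in [(7, 9), (100, 200), (101, 201), (37, 5)]:
            grid = make_roi_grid(q, m)
            hit = np.zeros((q, m), dtype=int)
            for r0, r1, c0, c1 in grid.roi_list:
                hit[r0:r1, c0:c1] += 1
            assert np.all(hit == 1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(q=st.integers(2, 60), m=st.integers(2, 60),
           frac=st.floats(0.2, 1.0), step=st.floats(0.05, 1.0))
    def test_sliding_grids_cover_every_element(self, q, m, frac, step):
        grid = make_roi_grid(q, m, window_frac=frac, step_frac=step)
        hit = np.zeros((q, m), dtype=int)
        for r0, r1, c0, c1 in grid.roi_list:
            assert r1 > r0 and c1 > c0
            hit[r0:r1, c0:c1] += 1
        assert hit.min() >= 1

    def test_too_small_matrix(self):
        with pytest.raises(ParameterError):
            make_roi_grid(1, 5)


class TestRoiHistogram:
    def test_all_zero_roi_concentrates_at_level_zero(self):
        hist = roi_histogram(np.zeros((3, 3)), 100, (0.0, 10.0))
        assert hist.p[0] == 1.0

    def test_extreme_corner_split(self):
        values = np.array([[0.0, 0.0], [5.0, 5.0]])
        hist = roi_histogram(values, 100, (0.0, 5.0))
        assert hist.p[0] == 0.5 and hist.p[99] == 0.5

    def test_normalization(self, rng):
        hist = roi_histogram(rng.gamma(1, 3, (20, 20)), 50, (0.0, 50.0))
        assert hist.p.sum() == pytest.approx(1.0)


class TestRoiCdf:
    def test_closed_forms(self):
        h2 = roi_histogram(np.array([[0.0, 1.0]]), 2, (0.0, 1.0))
        assert roi_cdf(h2).tolist() == [0.5, 1.0]
        h1 = roi_histogram(np.zeros((2, 2)), 1, (0.0, 0.0))
        assert roi_cdf(h1).tolist() == [1.0]

    def test_monotone_and_reaches_one(self, rng):
        hist = roi_histogram(rng.gamma(1, 3, (30, 30)), 100, (0.0, 60.0))
        F = roi_cdf(hist)
        assert np.all(np.diff(F) >= -1e-15)
        assert F[-1] == pytest.approx(1.0)

    def test_count_scaled_variant_caps_at_reciprocal_count(self, rng):
        hist = roi_histogram(rng.gamma(1, 3, (10, 10)), 20, (0.0, 60.0))
        F = roi_cdf(hist, scale_by_count=True)
        assert F[-1] == pytest.approx(1.0 / hist.total)


class TestRawTransform:
    def test_zero_cdf_maps_to_zero(self):
        target = FittedDistribution("exponential", 1.0, 0.0)
        t = raw_transform(np.array([0.0, 0.5]), target, n_elements=10**6)
        assert t[0] == 0

    def test_exponential_closed_form(self):
        # F = 1 - e^{-1}, lambda = 1: t = -floor(ln(e^{-1})) = 1
        target = FittedDistribution("exponential", 1.0, 0.0)
        t = raw_transform(np.array([1.0 - np.exp(-1.0)]), target, n_elements=10**6)
        assert t[0] == 1


class TestEqualizationTransform:
    def _uniform_cdf(self, L=100):
        return np.cumsum(np.full(L, 1.0 / L))

    @pytest.mark.parametrize("target", FAMILIES, ids=lambda t: t.family)
    def test_lut_matches_brute_force_inverse(self, target):
        """The lut equals a numerically inverted CDF, discretized, at all levels."""
        L = 100
        N = 10_000
        cdf = self._uniform_cdf(L)
        lut = equalization_transform(cdf, target, n_elements=N).lut
        eps = 1.0 / (2 * N)
        hi = 100.0
        while target.cdf(np.array([hi]))[0] < 1.0 - 1e-15:
            hi *= 2
        umax = brentq(lambda x: target.cdf(np.array([x]))[0] - (1 - eps), 0.0, hi)
        expected = []
        p = np.diff(cdf, prepend=0.0)
        for k in range(L):
            Fk = min(cdf[k] - p[k] / 2.0, 1 - eps)  # mass-midpoint convention
            u = brentq(lambda x: target.cdf(np.array([x]))[0] - Fk, 0.0, hi) if Fk > 0 else 0.0
            expected.append(min(int(np.floor(u / umax * (L - 1))), L - 1))
        assert lut.tolist() == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(0, 50), min_size=2, max_size=60).filter(lambda c: sum(c) > 0),
           fam=st.sampled_from(["exponential", "rayleigh", "gaussian"]))
    def test_lut_monotone_for_any_histogram(self, counts, fam):
        p = np.asarray(counts, dtype=float) / sum(counts)
        target = {"exponential": FAMILIES[0], "rayleigh": FAMILIES[1], "gaussian": FAMILIES[2]}[fam]
        lut = equalization_transform(np.cumsum(p), target, n_elements=sum(counts)).lut
        assert np.all(np.diff(lut) >= 0)
        assert lut.min() >= 0 and lut.max() <= len(p) - 1

    def test_invalid_cdf_rejected(self):
        with pytest.raises(ContractError):
            equalization_transform(np.array([0.5, 1.5]), FAMILIES[0])

    @pytest.mark.parametrize("target", FAMILIES, ids=lambda t: t.family)
    def test_transformed_levels_match_inverse_sampling_oracle(self, target):
        """Applying the lut to uniform levels reproduces independent
        inverse-transform sampling from the target distribution."""
        L = 100
        n = 10**6
        rng = np.random.default_rng(33)
        levels = rng.integers(0, L, n)
        counts = np.bincount(levels, minlength=L)
        cdf = np.cumsum(counts / n)
        lut = equalization_transform(cdf, target, n_elements=n).lut
        transformed = lut[levels]
        # oracle: uniformize, then push through the target's inverse CDF
        eps = 1.0 / (2 * n)
        u = rng.uniform(0, 1 - eps, n)
        z = target.inverse_cdf(u)
        umax = target.inverse_cdf(np.asarray(1 - eps))
        oracle = np.floor(np.clip(z / umax, 0, 1) * (L - 1))
        ks = ks_2samp(transformed, oracle).statistic
        assert ks < 0.01


class TestApplyTransform:
    def test_constant_roi_stays_constant(self):
        values = np.full((4, 4), 3.0)
        hist = roi_histogram(values, 50, (0.0, 10.0))
        tr = equalization_transform(roi_cdf(hist), FAMILIES[0], n_elements=16)
        out = serm.apply_transform(values, tr, (0.0, 10.0))
        assert len(np.unique(out)) == 1

    def test_order_preserved(self, rng):
        values = rng.gamma(1, 4, (10, 10))
        hist = roi_histogram(values, 100, (values.min(), values.max()))
        tr = equalization_transform(roi_cdf(hist), FAMILIES[0], n_elements=100)
        out = serm.apply_transform(values, tr, (values.min(), values.max()))
        flat_in, flat_out = values.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= -1e-12)

    def test_zeros_lifted_to_nonzero_value(self):
        # half zeros: F(0) = 0.5 -> exponential target lifts level 0 above 0
        values = np.zeros((10, 10))
        values[5:] = 10.0
        hist = roi_histogram(values, 100, (0.0, 10.0))
        tr = equalization_transform(roi_cdf(hist), FAMILIES[0], n_elements=100)
        out = serm.apply_transform(values, tr, (0.0, 10.0))
        assert tr.lut[0] > 0
        assert np.all(out[:5] > 0)


class TestEqualizeAll:
    def test_single_roi_equals_global_transform(self, rng):
        values = rng.gamma(1, 4, (12, 9))
        mat = serm.ExpressionMatrix(values, [f"c{i}" for i in range(12)], [f"g{j}" for j in range(9)])
        with pytest.warns(UserWarning):
            grid = make_roi_grid(12, 9, window_frac=1.0)
        out = serm.equalize_all(mat, grid, FAMILIES[0], levels=50)
        lo, hi = values.min(), values.max()
        hist = roi_histogram(values, 50, (lo, hi))
        tr = equalization_transform(roi_cdf(hist), FAMILIES[0], n_elements=values.size)
        expected = serm.apply_transform(values, tr, (lo, hi))
        assert np.allclose(out.values, expected)

    def test_quadrants_match_independent_equalization(self, rng):
        values = rng.gamma(1, 4, (20, 16))
        mat = serm.ExpressionMatrix(values, [f"c{i}" for i in range(20)], [f"g{j}" for j in range(16)])
        grid = make_roi_grid(20, 16)
        out = serm.equalize_all(mat, grid, FAMILIES[1], levels=40).values
        lo, hi = values.min(), values.max()
        for r0, r1, c0, c1 in grid.roi_list:
            sub = values[r0:r1, c0:c1]
            hist = roi_histogram(sub, 40, (lo, hi))
            tr = equalization_transform(roi_cdf(hist), FAMILIES[1], n_elements=sub.size)
            assert np.allclose(out[r0:r1, c0:c1], serm.apply_transform(sub, tr, (lo, hi)))

    def test_identical_quadrants_transform_identically(self, rng):
        block = rng.gamma(1, 4, (8, 6))
        values = np.block([[block, block], [block, block]])
        mat = serm.ExpressionMatrix(values, [f"c{i}" for i in range(16)], [f"g{j}" for j in range(12)])
        out = serm.equalize_all(mat, make_roi_grid(16, 12), FAMILIES[0], levels=30).values
        assert np.allclose(out[:8, :6], out[8:, 6:])
        assert np.allclose(out[:8, :6], out[:8, 6:])

    def test_self_consistency_reduces_cross_roi_divergence(self, small_dataset):
        """After equalization the four quadrants share a much more similar
        value distribution than in the dropout-affected input."""
        obs = small_dataset.observed
        grid = make_roi_grid(obs.n_cells, obs.n_genes)
        out = serm.equalize_all(obs, grid, FAMILIES[0], levels=100)

        def max_pairwise_ks(values):
            parts = [values[r0:r1, c0:c1].ravel() for r0, r1, c0, c1 in grid.roi_list]
            return max(
                ks_2samp(a, b).statistic
                for i, a in enumerate(parts) for b in parts[i + 1:]
            )

        # rows arrive in random group order, so quadrant mismatch is modest but real
        assert max_pairwise_ks(out.values) <= max_pairwise_ks(obs.values)


class TestEqualizeBlend:
    def test_identical_tiles_reduce_to_plain_equalization(self, rng):
        block = rng.gamma(1, 4, (8, 6))
        values = np.block([[block, block], [block, block]])
        mat = serm.ExpressionMatrix(values, [f"c{i}" for i in range(16)], [f"g{j}" for j in range(12)])
        grid = make_roi_grid(16, 12)
        hard = serm.equalize_all(mat, grid, FAMILIES[0], levels=30).values
        blended = serm.equalize_blend(mat, grid, FAMILIES[0], levels=30).values
        assert np.allclose(hard, blended)

    def test_blending_is_pointwise(self, rng):
        """Each element's output depends only on its own value (plus tile
        histograms), never on neighboring elements' values directly."""
        values = rng.gamma(1, 4, (12, 10))
        mat = serm.ExpressionMatrix(values, [f"c{i}" for i in range(12)], [f"g{j}" for j in range(10)])
        grid = make_roi_grid(12, 10)
        out = serm.equalize_blend(mat, grid, FAMILIES[0], levels=20).values
        # equal input values in the same matrix position row must map consistently:
        # a constant matrix maps to a constant
        const = serm.ExpressionMatrix(np.full((12, 10), 2.0), mat.cell_ids, mat.gene_ids)
        out_const = serm.equalize_blend(const, grid, FAMILIES[0], levels=20).values
        assert len(np.unique(out_const)) == 1
        assert out.shape == values.shape and np.all(out >= 0)

    def test_requires_non_overlapping_grid(self, rng):
        values = rng.gamma(1, 4, (12, 10))
        mat = serm.ExpressionMatrix(values, [f"c{i}" for i in range(12)], [f"g{j}" for j in range(10)])
        grid = make_roi_grid(12, 10, window_frac=0.5, step_frac=0.25)
        with pytest.raises(ParameterError):
            serm.equalize_blend(mat, grid, FAMILIES[0])


class TestBilinearResample:
    def test_interior_of_constant_matrix_preserved(self):
        out = serm.bilinear_resample(np.full((5, 5), 7.0))
        assert np.allclose(out[1:-1, 1:-1], 7.0)

    def test_two_by_two_ones(self):
        out = serm.bilinear_resample(np.ones((2, 2)))
        assert np.allclose(out, 0.25)

    def test_single_spike_spreads_to_diagonal_neighbors(self):
        A = np.zeros((5, 5))
        A[2, 2] = 8.0
        out = serm.bilinear_resample(A)
        expected = np.zeros((5, 5))
        for di in (-1, 1):
            for dj in (-1, 1):
                expected[2 + di, 2 + dj] = 2.0
        assert np.allclose(out, expected)


def test_integer_count_matrices_use_lossless_levels(rng):
    counts = rng.poisson(2.0, (20, 16)).astype(float)
    counts[0, 0] = 30.0
    mat = serm.ExpressionMatrix(counts, [f"c{i}" for i in range(20)], [f"g{j}" for j in range(16)])
    out = serm.equalize_all(mat, make_roi_grid(20, 16), FAMILIES[0], levels=100)
    # all outputs land on the integer value grid 0..30
    assert np.allclose(out.values, np.round(out.values))


def test_level_discretization_is_identity_on_integers():
    v = np.arange(0, 31, dtype=float)
    assert np.array_equal(_levels_of(v, 0.0, 30.0, 31), np.arange(31))
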