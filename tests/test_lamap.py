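"""The potential model: CSA sampling, ECDF similarity, combination, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamap.raster import GridRaster, SitePoint
from lamap.surface import (
    DegenerateClassificationError,
    EdgeSiteError,
    LamapParams,
    NoTrainingDataError,
    classify_quantiles,
    compute_surface,
    distance_weights,
    empirical_similarity,
    extract_csa,
    lamap_value,
    site_joint_probability,
)
from lamap.terrain import DerivativeStack
from conftest import random_stack
from oracles import csa_cell_count, mid_ecdf_similarity, surface_reference


def uniform_stack(n, cell_size=15.0, n_layers=2, fill=0.0):
    rng = np.random.default_rng(0)
    layers = {
        f"v{i}": GridRaster(
            values=np.full((n, n), fill) + rng.normal(size=(n, n)),
            origin_x=0.0, origin_y=n * cell_size, cell_size=cell_size,
        )
        for i in range(n_layers)
    }
    return DerivativeStack(layers=layers)


class TestExtractCSA:
    def test_one_km_csa_on_15m_grid_has_about_3500_cells(self):
        n = 80  # 1200 m square, site centred
        stack = uniform_stack(n)
        site = SitePoint("S1", 600.0, 600.0)
        csa = extract_csa(stack, site, diameter_m=1000.0)
        assert csa.coverage == 1.0
        assert abs(csa.n_cells - 3490) < 60  # pi * 500^2 / 15^2 = 3491

    def test_diameter_of_one_cell_is_single_cell(self):
        stack = uniform_stack(9)
        site = SitePoint("S1", 67.5, 67.5)  # a cell centre
        csa = extract_csa(stack, site, diameter_m=15.0)
        assert csa.n_cells == 1
        assert csa.samples["v0"].size == 1

    def test_edge_site_coverage_matches_bruteforce(self):
        n, cs = 40, 15.0
        stack = uniform_stack(n)
        geom = stack.geometry
        site = SitePoint("S1", 100.0, 300.0)  # 100 m from the west edge
        csa = extract_csa(stack, site, diameter_m=1000.0, min_coverage=0.1)
        expected = csa_cell_count(
            geom.origin_x, geom.origin_y, cs, n, n, site.x, site.y, 500.0
        )
        assert csa.n_cells == expected
        assert csa.coverage < 1.0

    def test_low_coverage_raises_edge_site_error(self):
        stack = uniform_stack(20)  # 300 m square, 1 km CSA mostly off-grid
        with pytest.raises(EdgeSiteError):
            extract_csa(stack, SitePoint("S1", 20.0, 20.0), diameter_m=1000.0)

    def test_site_outside_extent(self):
        with pytest.raises(ValueError, match="outside"):
            extract_csa(uniform_stack(10), SitePoint("S1", -5.0, 10.0))


class TestEmpiricalSimilarity:
    def test_median_of_distinct_sample_scores_one(self):
        sample = np.arange(1.0, 10.0)  # 9 points, median 5
        assert empirical_similarity(sample, 5.0) == 1.0

    def test_enumerated_counts(self):
        sample = np.arange(1.0, 11.0)
        # F(3) = (2 + 0.5) / 10 = 0.25 -> p = 0.5
        assert empirical_similarity(sample, 3.0) == pytest.approx(0.5)

    def test_below_minimum_hits_epsilon_floor(self):
        sample = np.array([2.0, 3.0, 4.0])
        assert empirical_similarity(sample, 1.0, epsilon=1e-6) == 1e-6

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            empirical_similarity(np.array([]), 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sample = np.sort(np.round(rng.normal(size=rng.integers(1, 40)), 1))
        xs = np.round(rng.normal(size=10), 1)
        for x in xs:
            assert empirical_similarity(sample, x) == pytest.approx(
                mid_ecdf_similarity(sample, x, 1e-6), abs=1e-14
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_monotone_toward_median(self, seed):
        """Moving a value from the tail toward the median never lowers similarity."""
        rng = np.random.default_rng(seed)
        sample = np.sort(rng.normal(size=25))
        med = np.median(sample)
        xs = np.linspace(sample[0] - 1, med, 30)
        ps = empirical_similarity(sample, xs)
        assert np.all(np.diff(ps) >= -1e-14)


class TestCombination:
    def test_joint_of_ones_is_one(self):
        csa = _csa_with({"a": np.arange(9.0), "b": np.arange(9.0)})
        assert site_joint_probability(csa, {"a": 4.0, "b": 4.0}) == pytest.approx(1.0)

    def test_joint_is_product(self):
        csa = _csa_with({"a": np.arange(1.0, 11.0), "b": np.arange(1.0, 11.0)})
        # each similarity is 0.5 at x = 3
        assert site_joint_probability(csa, {"a": 3.0, "b": 3.0}) == pytest.approx(0.25)

    def test_log_space_equals_direct_product(self, rng):
        sims = rng.uniform(0.01, 1.0, size=6)
        samples = {}
        targets = {}
        for i, p in enumerate(sims):
            # craft a sample/value pair whose similarity is exactly p via quantiles
            sample = np.arange(1.0, 101.0)
            k = p * 50.0  # F = p/2 at x below median
            samples[f"v{i}"] = sample
            targets[f"v{i}"] = np.floor(k) + 0.5  # strictly between sample values
        csa = _csa_with(samples)
        direct = 1.0
        for i in range(6):
            direct *= empirical_similarity(samples[f"v{i}"], targets[f"v{i}"])
        assert site_joint_probability(csa, targets) == pytest.approx(direct, rel=1e-12)

    def test_missing_variable_is_schema_error(self):
        csa = _csa_with({"a": np.arange(5.0)})
        with pytest.raises(KeyError):
            site_joint_probability(csa, {"b": 1.0})

    def test_single_site_weight(self):
        w = distance_weights((0.0, 0.0), [_csa_at(10.0, 10.0)], d_floor=15.0)
        np.testing.assert_allclose(w, [1.0])

    def test_equidistant_sites_split_evenly(self):
        w = distance_weights((0.0, 0.0), [_csa_at(100.0, 0.0), _csa_at(0.0, 100.0)],
                             d_floor=15.0)
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_inverse_distance_ratio(self):
        w = distance_weights((0.0, 0.0), [_csa_at(15.0, 0.0), _csa_at(45.0, 0.0)],
                             alpha=1.0, d_floor=15.0)
        np.testing.assert_allclose(w, [0.75, 0.25])

    def test_lamap_value_arithmetic_and_bounds(self, rng):
        assert lamap_value([0.2, 0.6], [0.75, 0.25]) == pytest.approx(0.3)
        assert lamap_value([0.4, 0.4, 0.4], [0.2, 0.3, 0.5]) == pytest.approx(0.4)
        probs = rng.uniform(size=5)
        w = rng.uniform(size=5)
        w /= w.sum()
        v = lamap_value(probs, w)
        assert probs.min() - 1e-12 <= v <= probs.max() + 1e-12
        with pytest.raises(ValueError):
            lamap_value([0.5], [0.6, 0.4])
        with pytest.raises(ValueError):
            lamap_value([0.5, 0.5], [0.6, 0.6])


def _csa_with(samples):
    from lamap.surface import CSASample

    return CSASample("X", 0.0, 0.0, {k: np.sort(v) for k, v in samples.items()},
                     n_cells=len(next(iter(samples.values()))), coverage=1.0)


def _csa_at(x, y):
    from lamap.surface import CSASample

    return CSASample("X", x, y, {"a": np.arange(5.0)}, n_cells=5, coverage=1.0)


class TestComputeSurface:
    def test_values_bounded_and_near_constant_on_homogeneous_landscape(self):
        n = 40
        rng = np.random.default_rng(5)
        # i.i.d. noise everywhere: every cell is equally typical of any CSA
        stack = DerivativeStack(layers={
            "v0": GridRaster(values=rng.normal(size=(n, n)) * 1e-3 + 7.0,
                             origin_x=0.0, origin_y=n * 15.0, cell_size=15.0),
        })
        site = SitePoint("S1", 300.0, 300.0)
        surf = compute_surface(stack, [site], LamapParams(diameter_m=400.0))
        v = surf.raster.values
        assert np.nanmin(v) >= 0.0 and np.nanmax(v) <= 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_nested_loop_reference(self, seed):
        n = 30
        rng = np.random.default_rng(seed)
        stack = random_stack(rng, n=n, n_layers=3)
        params = LamapParams(diameter_m=300.0, min_coverage=0.3, epsilon=1e-6, alpha=1.0)
        sites = [
            SitePoint(f"S{i}", float(rng.uniform(50, n * 15 - 50)),
                      float(rng.uniform(50, n * 15 - 50)))
            for i in range(4)
        ]
        surf = compute_surface(stack, sites, params)
        ref = surface_reference(stack, sites, 300.0, 0.3, 1e-6, 1.0, 15.0)
        np.testing.assert_allclose(surf.raster.values, ref, atol=1e-12)

    def test_translation_equivariance(self, rng):
        n = 25
        stack = random_stack(rng, n=n, n_layers=2)
        sites = [SitePoint("S1", 150.0, 200.0), SitePoint("S2", 250.0, 120.0)]
        params = LamapParams(diameter_m=200.0, min_coverage=0.3)
        surf1 = compute_surface(stack, sites, params)
        dx, dy = 5000.0, -3000.0
        shifted = DerivativeStack(layers={
            k: GridRaster(values=v.values.copy(), origin_x=v.origin_x + dx,
                          origin_y=v.origin_y + dy, cell_size=v.cell_size)
            for k, v in stack.layers.items()
        })
        moved = [SitePoint(s.site_id, s.x + dx, s.y + dy) for s in sites]
        surf2 = compute_surface(shifted, moved, params)
        np.testing.assert_allclose(surf2.raster.values, surf1.raster.values, atol=1e-12)

    def test_all_csas_rejected_raises(self):
        stack = uniform_stack(20)
        site = SitePoint("S1", 10.0, 10.0)  # corner, tiny coverage for 1 km CSA
        with pytest.raises(NoTrainingDataError):
            compute_surface(stack, [site], LamapParams())


class TestClassifyQuantiles:
    def _surface(self, values, cell_size=10.0):
        v = np.asarray(values, dtype=float)
        return GridRaster(values=v, origin_x=0.0, origin_y=v.shape[0] * cell_size,
                          cell_size=cell_size)

    def test_hundred_distinct_values_split_evenly(self, rng):
        vals = rng.permutation(100).reshape(10, 10).astype(float)
        pc = classify_quantiles(self._surface(vals), k=5)
        counts = np.bincount(pc.raster.values[~np.isnan(pc.raster.values)].astype(int))[1:]
        np.testing.assert_array_equal(counts, [20] * 5)

    def test_remainder_goes_to_lowest_classes(self, rng):
        vals = np.full(110, np.nan)
        vals[:103] = rng.permutation(103).astype(float)
        pc = classify_quantiles(self._surface(vals.reshape(10, 11)), k=5)
        c = pc.raster.values[~np.isnan(pc.raster.values)].astype(int)
        np.testing.assert_array_equal(np.bincount(c)[1:], [21, 21, 21, 20, 20])

    def test_ties_split_deterministically(self):
        vals = np.concatenate([np.zeros(30), np.linspace(1, 2, 70)])
        arr = vals.reshape(10, 10)
        pc1 = classify_quantiles(self._surface(arr), k=5)
        pc2 = classify_quantiles(self._surface(arr.copy()), k=5)
        np.testing.assert_array_equal(pc1.raster.values, pc2.raster.values)
        counts = np.bincount(pc1.raster.values.ravel().astype(int))[1:]
        np.testing.assert_array_equal(counts, [20] * 5)
        # the tie run (30 zeros) spans classes 1 and 2, broken row-major
        flat = pc1.raster.values.ravel()
        assert set(flat[:20]) == {1.0} and set(flat[20:30]) == {2.0}

    def test_class5_above_class1(self, rng):
        vals = rng.uniform(size=(20, 20))
        pc = classify_quantiles(self._surface(vals), k=5)
        c = pc.raster.values
        assert vals[c == 5].min() >= vals[c == 1].max()
        assert len(pc.class_edges) == 4

    def test_constant_surface_degenerate(self):
        with pytest.raises(DegenerateClassificationError):
            classify_quantiles(self._surface(np.full((5, 5), 0.3)), k=5)
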