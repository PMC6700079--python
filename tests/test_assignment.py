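import math

import numpy as np
import pytest

from swallowtrace import (
    GridSpec,
    binarize_odds,
    estimate_residual_covariance,
    likelihood_surface,
    population_surface,
    posterior_surface,
    threshold_origin,
)
from swallowtrace.assignment import (
    BinaryOriginMap,
    PopulationOriginSurface,
    PosteriorSurface,
    ResidualCovariance,
    assign_population,
)
from swallowtrace.prior import PriorSurface, VonMisesFit, build_prior_surface
from swallowtrace.synthetic import (
    FeatherSample,
    box_origin_sampler,
    generate_feather_samples,
    generate_isoscapes,
)


def make_posterior(grid, values, individual_id="x"):
    values = np.asarray(values, dtype=float)
    return PosteriorSurface(individual_id=individual_id, grid=grid, values=values)


@pytest.fixture()
def uniform_prior(small_grid):
    n = small_grid.n_rows * small_grid.n_cols
    return PriorSurface(
        grid=small_grid,
        values=np.full(small_grid.shape, 1.0 / n),
        breeding_centroid=(57.22, 9.97),
    )


class TestResidualCovariance:
    def test_complete_data_matches_closed_form_ml(self, small_isoscapes, feather_batch):
        est = estimate_residual_covariance(feather_batch, small_isoscapes)
        resid = np.array(
            [s.triplet() - small_isoscapes.values_at(*s.true_origin) for s in feather_batch]
        )
        centered = resid - resid.mean(axis=0)
        expected = centered.T @ centered / len(resid)  # n denominator
        assert est.method == "ML-complete"
        assert np.allclose(est.cov, expected, atol=1e-9)

    def test_duplicated_sample_degenerate_without_ridge(self, small_isoscapes, feather_batch):
        dup = [feather_batch[0]] * 50
        with pytest.raises(ValueError, match="singular"):
            estimate_residual_covariance(dup, small_isoscapes)
        est = estimate_residual_covariance(dup, small_isoscapes, ridge=1e-6)
        assert np.all(np.linalg.eigvalsh(est.cov) > 0)

    def test_em_recovers_covariance_with_missingness(self, small_grid, residual_cov):
        iso = generate_isoscapes(small_grid, seed=5)
        sampler = box_origin_sampler(-13, -7, 12, 18)
        samples = generate_feather_samples(
            n=1000, origin_sampler=sampler, isoscapes=iso,
            residual_cov=residual_cov, missing_rate=0.3, seed=6,
        )
        est = estimate_residual_covariance(samples, iso)
        assert est.method == "ML-EM-missing"
        rel = np.abs(est.cov - residual_cov) / np.abs(residual_cov)
        assert rel.max() < 0.25

    def test_needs_at_least_four_samples(self, small_isoscapes, feather_batch):
        with pytest.raises(ValueError):
            estimate_residual_covariance(feather_batch[:3], small_isoscapes)


class TestLikelihoodSurface:
    def test_univariate_mode_attains_normal_peak(self, small_grid):
        iso = generate_isoscapes(small_grid, seed=1)
        i, j = 4, 7
        lat = iso.grid.lat_centers()[i]
        lon = iso.grid.lon_centers()[j]
        sample = FeatherSample("a", d2H=iso.d2H[i, j], d13C=np.nan, d15N=np.nan)
        cov = ResidualCovariance(
            mean=np.zeros(3), cov=np.diag([64.0, 1.0, 1.0]), method="user-supplied"
        )
        dens = likelihood_surface(sample, iso, cov)
        assert dens.values[i, j] == pytest.approx(1.0 / (8.0 * math.sqrt(2 * math.pi)))
        assert dens.values.max() == dens.values[i, j]

    def test_diagonal_covariance_factorizes(self, small_isoscapes):
        sample = FeatherSample("a", d2H=-40.0, d13C=-15.0, d15N=10.0)
        diag = np.array([64.0, 2.25, 1.44])
        cov = ResidualCovariance(mean=np.zeros(3), cov=np.diag(diag), method="user-supplied")
        dens = likelihood_surface(sample, small_isoscapes, cov).values
        x = sample.triplet()
        prod = np.ones(small_isoscapes.grid.shape)
        for k, layer in enumerate(("d2H", "d13C", "d15N")):
            mu = small_isoscapes.layer(layer)
            sd = math.sqrt(diag[k])
            prod *= np.exp(-0.5 * ((x[k] - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        assert np.allclose(dens, prod, atol=1e-12)

    def test_full_covariance_matches_quadratic_form(self, toy_grid, residual_cov):
        iso = generate_isoscapes(toy_grid, seed=2)
        sample = FeatherSample("a", d2H=-50.0, d13C=-14.0, d15N=9.5)
        cov = ResidualCovariance(mean=np.zeros(3), cov=residual_cov, method="user-supplied")
        dens = likelihood_surface(sample, iso, cov).values
        Sinv = np.linalg.inv(residual_cov)
        det = np.linalg.det(residual_cov)
        for i in range(3):
            for j in range(3):
                d = sample.triplet() - iso.values_at(iso.grid.lat_centers()[i],
                                                     iso.grid.lon_centers()[j])
                expect = math.exp(-0.5 * d @ Sinv @ d) / math.sqrt((2 * math.pi) ** 3 * det)
                assert dens[i, j] == pytest.approx(expect, rel=1e-12)

    def test_no_observed_isotopes_rejected(self, small_isoscapes, residual_cov):
        cov = ResidualCovariance(mean=np.zeros(3), cov=residual_cov, method="user-supplied")
        sample = FeatherSample("a", d2H=np.nan, d13C=np.nan, d15N=np.nan)
        with pytest.raises(ValueError):
            likelihood_surface(sample, small_isoscapes, cov)


class TestPosterior:
    def test_flat_prior_returns_normalized_likelihood(self, small_isoscapes, uniform_prior,
                                                      residual_cov):
        from swallowtrace.grid import Raster

        sample = FeatherSample("a", d2H=-40.0, d13C=-15.0, d15N=10.0)
        cov = ResidualCovariance(mean=np.zeros(3), cov=residual_cov, method="user-supplied")
        lik = likelihood_surface(sample, small_isoscapes, cov)
        post = posterior_surface(lik, uniform_prior, "a")
        assert np.allclose(post.values, lik.values / lik.values.sum(), atol=1e-12)

    def test_point_mass_prior_pins_posterior(self, small_isoscapes, residual_cov, small_grid):
        from swallowtrace.grid import Raster

        prior_vals = np.zeros(small_grid.shape)
        prior_vals[3, 3] = 1.0
        prior = PriorSurface(grid=small_grid, values=prior_vals, breeding_centroid=(57, 10))
        sample = FeatherSample("a", d2H=-40.0, d13C=-15.0, d15N=10.0)
        cov = ResidualCovariance(mean=np.zeros(3), cov=residual_cov, method="user-supplied")
        post = posterior_surface(likelihood_surface(sample, small_isoscapes, cov), prior)
        expected = np.zeros(small_grid.shape)
        expected[3, 3] = 1.0
        assert np.array_equal(post.values, expected)

    def test_four_pixel_hand_product(self):
        from swallowtrace.grid import Raster

        grid = GridSpec(lon_min=0, lon_max=2, lat_min=0, lat_max=2, resolution=1.0)
        lik = Raster(grid=grid, values=np.array([[4.0, 3.0], [2.0, 1.0]]))
        prior = PriorSurface(
            grid=grid, values=np.array([[0.1, 0.2], [0.3, 0.4]]), breeding_centroid=(5, 1)
        )
        post = posterior_surface(lik, prior, "toy")
        assert np.allclose(post.values, np.array([[0.2, 0.3], [0.3, 0.2]]), atol=1e-12)

    def test_disjoint_support_raises_with_name(self, small_grid):
        from swallowtrace.grid import Raster

        lik_vals = np.zeros(small_grid.shape)
        lik_vals[0, 0] = 1.0
        prior_vals = np.zeros(small_grid.shape)
        prior_vals[5, 5] = 1.0
        lik = Raster(grid=small_grid, values=lik_vals)
        prior = PriorSurface(grid=small_grid, values=prior_vals, breeding_centroid=(57, 10))
        with pytest.raises(ValueError, match="bird_007"):
            posterior_surface(lik, prior, "bird_007")


class TestBinarize:
    def test_cumulative_mass_example(self):
        grid = GridSpec(lon_min=0, lon_max=2, lat_min=0, lat_max=2, resolution=1.0)
        post = make_posterior(grid, [[0.5, 0.3], [0.15, 0.05]])
        bom = binarize_odds(post, q=0.67)
        assert np.array_equal(bom.values, [[1, 1], [0, 0]])

    def test_q_near_one_includes_all_positive_pixels(self):
        grid = GridSpec(lon_min=0, lon_max=2, lat_min=0, lat_max=2, resolution=1.0)
        post = make_posterior(grid, [[0.5, 0.5], [0.0, 0.0]])
        bom = binarize_odds(post, q=0.999999)
        assert np.array_equal(bom.values, [[1, 1], [0, 0]])

    def test_uniform_posterior_takes_ceil_qn(self):
        grid = GridSpec(lon_min=0, lon_max=5, lat_min=0, lat_max=2, resolution=1.0)
        n = 10
        post = make_posterior(grid, np.full((2, 5), 1.0 / n))
        bom = binarize_odds(post, q=0.67)
        assert bom.values.sum() == math.ceil(0.67 * n)

    def test_included_mass_is_minimal_cover(self):
        rng = np.random.default_rng(12)
        grid = GridSpec(lon_min=0, lon_max=6, lat_min=0, lat_max=5, resolution=1.0)
        vals = rng.random((5, 6))
        vals /= vals.sum()
        post = make_posterior(grid, vals)
        q = 0.67
        bom = binarize_odds(post, q=q)
        inside = vals[bom.values == 1]
        assert inside.sum() >= q - 1e-12
        assert inside.sum() - inside.min() < q


class TestPopulationAndThreshold:
    def test_identical_maps_double_counts(self, toy_grid):
        m = BinaryOriginMap("a", toy_grid, np.eye(3, dtype=int), q=0.67)
        pop = population_surface([m, m])
        assert np.array_equal(pop.counts, 2 * np.eye(3, dtype=int))

    def test_disjoint_maps_max_one(self, toy_grid):
        a = BinaryOriginMap("a", toy_grid, np.diag([1, 1, 1]), q=0.67)
        b = BinaryOriginMap("b", toy_grid, 1 - np.diag([1, 1, 1]), q=0.67)
        pop = population_surface([a, b])
        assert pop.counts.max() == 1

    def test_random_maps_equal_elementwise_sum(self, toy_grid):
        rng = np.random.default_rng(8)
        maps = [
            BinaryOriginMap(f"i{k}", toy_grid, rng.integers(0, 2, (3, 3)), q=0.67)
            for k in range(5)
        ]
        pop = population_surface(maps)
        brute = np.zeros((3, 3), dtype=int)
        for m in maps:
            for i in range(3):
                for j in range(3):
                    brute[i, j] += m.values[i, j]
        assert np.array_equal(pop.counts, brute)

    def test_strict_inequality_at_threshold(self, toy_grid):
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 1] = 7
        pop = PopulationOriginSurface(grid=toy_grid, counts=counts, n_individuals=10)
        assert threshold_origin(pop, 0.6).mask[1, 1]
        assert not threshold_origin(pop, 0.7).mask[1, 1]

    def test_masks_are_nested_and_areas_decrease(self, small_grid):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 11, small_grid.shape)
        pop = PopulationOriginSurface(grid=small_grid, counts=counts, n_individuals=10)
        m50, m60, m70 = (threshold_origin(pop, p) for p in (0.5, 0.6, 0.7))
        assert np.all(m70.mask <= m60.mask) and np.all(m60.mask <= m50.mask)
        assert m50.area_km2 > m60.area_km2 > m70.area_km2


class TestEndToEndBruteForce:
    def test_pipeline_equals_enumeration_on_toy_grid(self, toy_grid):
        """Likelihood → posterior → binarize → sum → threshold, checked
        against an explicit per-pixel enumeration for two individuals."""
        iso = generate_isoscapes(
            toy_grid,
            gradient_spec={"d2H": (-30, -2, 1), "d13C": (-15, 0.5, -0.3), "d15N": (8, 0.2, 0.1)},
            noise_sd=0.0,
            seed=0,
        )
        cov_m = np.diag([25.0, 1.0, 0.5])
        cov = ResidualCovariance(mean=np.zeros(3), cov=cov_m, method="user-supplied")
        prior = build_prior_surface(VonMisesFit(mu=185.0, kappa=1.5, n=20), (10.0, 1.5), toy_grid)
        samples = [
            FeatherSample("s1", d2H=-32.0, d13C=-14.2, d15N=8.6),
            FeatherSample("s2", d2H=-28.0, d13C=np.nan, d15N=8.1),
        ]
        posteriors, pop, masks = assign_population(
            samples, iso, prior, cov, q=0.67, thresholds=(0.5,)
        )

        # --- independent brute force -----------------------------------
        def normal_pdf(x, mu, var):
            return math.exp(-0.5 * (x - mu) ** 2 / var) / math.sqrt(2 * math.pi * var)

        brute_maps = []
        for s in samples:
            post = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    mu = [iso.d2H[i, j], iso.d13C[i, j], iso.d15N[i, j]]
                    lik = 1.0
                    for k, x in enumerate(s.triplet()):
                        if not np.isnan(x):
                            lik *= normal_pdf(x, mu[k], cov_m[k, k])
                    post[i, j] = lik * prior.values[i, j]
            post /= post.sum()
            flat = sorted(
                [(post[i, j], (i, j)) for i in range(3) for j in range(3)], reverse=True
            )
            acc, chosen = 0.0, set()
            for val, idx in flat:
                if acc >= 0.67 - 1e-12:
                    break
                chosen.add(idx)
                acc += val
            binary = np.zeros((3, 3), dtype=int)
            for i, j in chosen:
                binary[i, j] = 1
            brute_maps.append(binary)
        brute_pop = brute_maps[0] + brute_maps[1]
        brute_mask = brute_pop / 2 > 0.5

        for post, s in zip(posteriors, samples):
            assert post.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.array_equal(pop.counts, brute_pop)
        assert np.array_equal(masks[0.5].mask, brute_mask)

    def test_true_origin_recovered_in_top_mask(self, small_grid):
        """With informative isoscapes and the true covariance, the >50% mask
        should contain the true-origin centroid in nearly all replicates."""
        iso = generate_isoscapes(small_grid, seed=3)
        cov_m = np.diag([16.0, 0.5, 0.3])
        cov = ResidualCovariance(mean=np.zeros(3), cov=cov_m, method="user-supplied")
        prior_vals = np.full(small_grid.shape, 1.0 / (small_grid.n_rows * small_grid.n_cols))
        prior = PriorSurface(grid=small_grid, values=prior_vals, breeding_centroid=(57, 10))
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            # a shared moult origin; 84 feathers as in one sampling season
            sampler = lambda rng: (-10.0, 15.0)  # noqa: E731
            samples = generate_feather_samples(
                n=84, origin_sampler=sampler, isoscapes=iso,
                residual_cov=cov_m, seed=1000 + rep,
            )
            _, pop, masks = assign_population(samples, iso, prior, cov, thresholds=(0.5,))
            i, j = small_grid.index_of(-10.0, 15.0)
            hits += bool(masks[0.5].mask[i, j])
        assert hits >= 90


class TestBinarizeProperties:
    """Invariants of the odds-based binarization over random posteriors."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _posterior_from(raw):
        grid = GridSpec(lon_min=0, lon_max=4, lat_min=0, lat_max=3, resolution=1.0)
        vals = np.array(raw, dtype=float).reshape(3, 4)
        vals /= vals.sum()
        return make_posterior(grid, vals)

    @given(
        raw=st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=12, max_size=12,
        ),
        q=st.floats(min_value=0.05, max_value=0.95),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_mass_cover_is_minimal(self, raw, q):
        post = self._posterior_from(raw)
        bom = binarize_odds(post, q=q)
        inside = post.values[bom.values == 1]
        assert inside.sum() >= q - 1e-9
        # dropping the smallest included pixel must fall below q
        assert inside.sum() - inside.min() < q

    @given(
        raw=st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=12, max_size=12,
        ),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_included_set_grows_with_q(self, raw):
        post = self._posterior_from(raw)
        small = binarize_odds(post, q=0.3).values
        large = binarize_odds(post, q=0.8).values
        assert np.all(small <= large)
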