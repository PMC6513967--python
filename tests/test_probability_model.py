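"""Priors, proportional-error likelihood, posterior and the dataset format."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from fasciclebayes import (
    FascicleClass,
    FascicleDataset,
    MaterialParams,
    PriorSpec,
    log_likelihood,
    log_posterior,
    log_prior,
    prior_sample,
    read_dataset,
    write_dataset,
)
from fasciclebayes.probability_model import (
    _proportional_loglik,
    make_log_likelihood_fn,
    make_log_prior_fn,
)


def make_params(e_f=1400.0, eta=42_000.0, e_m=0.4, r_inf=0.4, sigma=0.05):
    return MaterialParams(e_f, eta, e_m, r_inf, sigma)


def single_datum_dataset(value: float) -> FascicleDataset:
    """A dataset whose elastic block holds one replicate; the other blocks
    carry placeholder values and are excluded from the likelihood."""
    return FascicleDataset(
        dataset_id="unit",
        elastic_moduli=np.array([value]),
        poisson_value=1.0,
        times=np.array([0.0, 1.0]),
        ebar=np.array([1.0, 0.9]),
    )


class TestPrior:
    def test_mid_box_density_is_negative_log_volume(self, prior):
        params = MaterialParams.from_vector(0.5 * (prior.lower + prior.upper))
        expected = -np.sum(np.log(prior.upper - prior.lower))
        assert log_prior(params, prior) == pytest.approx(expected)

    def test_below_fiber_modulus_bound_is_minus_inf(self, prior):
        params = make_params(e_f=499.0)
        assert log_prior(params, prior) == -np.inf

    def test_boundary_is_inside_closed_box(self, prior):
        params = make_params(e_m=5.0)
        assert np.isfinite(log_prior(params, prior))

    def test_samples_all_have_finite_prior(self, prior):
        for params in prior_sample(prior, n=1000, seed=0):
            assert np.isfinite(log_prior(params, prior))

    def test_same_seed_reproduces_draws(self, prior):
        a = prior_sample(prior, n=50, seed=123)
        b = prior_sample(prior, n=50, seed=123)
        assert all(x == y for x, y in zip(a, b))

    def test_sample_mean_matches_box_midpoint(self, prior):
        n = 10_000
        draws = np.array([p.to_vector() for p in prior_sample(prior, n=n, seed=1)])
        width = prior.upper - prior.lower
        se = width / math.sqrt(12.0 * n)
        mid = 0.5 * (prior.lower + prior.upper)
        assert np.all(np.abs(draws.mean(axis=0) - mid) <= 3.0 * se)

    def test_density_normalizes_over_enclosing_box(self, prior):
        """MC integral of exp(log_prior) over a box 1.5x the prior -> 1."""
        rng = np.random.default_rng(2)
        width = prior.upper - prior.lower
        lo = prior.lower - 0.25 * width
        hi = prior.upper + 0.25 * width
        n = 200_000
        theta = rng.uniform(lo, hi, size=(n, 5))
        vals = np.exp(make_log_prior_fn(prior)(theta))
        volume = np.prod(hi - lo)
        est = volume * vals.mean()
        se = volume * vals.std() / math.sqrt(n)
        assert abs(est - 1.0) <= 3.0 * se


class TestLikelihood:
    def test_single_datum_at_prediction(self):
        # q1 = 0.5*199 + 0.5*1 = 100 exactly; sd = 0.05 * 100 = 5
        params = make_params(e_f=199.0, e_m=1.0, sigma=0.05)
        cls = FascicleClass(0.5, 70.0)
        value = log_likelihood(params, single_datum_dataset(100.0), cls,
                               observables=("elastic",))
        assert value == pytest.approx(-math.log(math.sqrt(2 * math.pi) * 5.0), abs=1e-9)
        assert value == pytest.approx(-2.5284, abs=1e-3)

    def test_two_sigma_residual_costs_two(self):
        params = make_params(e_f=199.0, e_m=1.0, sigma=0.05)
        cls = FascicleClass(0.5, 70.0)
        at_mean = log_likelihood(params, single_datum_dataset(100.0), cls,
                                 observables=("elastic",))
        off = log_likelihood(params, single_datum_dataset(110.0), cls,
                             observables=("elastic",))
        assert at_mean - off == pytest.approx(2.0, abs=1e-9)

    def test_scale_equivariance_of_proportional_error(self):
        # doubling datum and prediction changes the density only via -log F
        cls = FascicleClass(0.5, 70.0)
        small = log_likelihood(make_params(e_f=199.0, e_m=1.0),
                               single_datum_dataset(110.0), cls, observables=("elastic",))
        large = log_likelihood(make_params(e_f=398.0, e_m=2.0),
                               single_datum_dataset(220.0), cls, observables=("elastic",))
        assert small - large == pytest.approx(math.log(2.0), abs=1e-9)

    def test_factorizes_over_data(self, truth_params, base_class, noisy_dataset):
        total = log_likelihood(truth_params, noisy_dataset, base_class)
        parts = 0.0
        for modulus in noisy_dataset.elastic_moduli:
            one = FascicleDataset("part", [modulus], noisy_dataset.poisson_value,
                                  noisy_dataset.times, noisy_dataset.ebar)
            parts += log_likelihood(truth_params, one, base_class,
                                    observables=("elastic",))
        parts += log_likelihood(truth_params, noisy_dataset, base_class,
                                observables=("poisson",))
        parts += log_likelihood(truth_params, noisy_dataset, base_class,
                                observables=("relaxation",))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_nonpositive_prediction_gives_minus_inf(self):
        d = np.array([1.0, 2.0])
        f = np.array([[1.0, -0.5], [1.0, 2.0]])
        out = _proportional_loglik(d, f, np.array([0.05, 0.05]))
        assert out[0] == -np.inf and np.isfinite(out[1])

    def test_unknown_observable_block_rejected(self, truth_params, base_class,
                                               noisy_dataset):
        with pytest.raises(ValueError):
            log_likelihood(truth_params, noisy_dataset, base_class,
                           observables=("spectral",))

    def test_vectorized_matches_scalar(self, truth_params, base_class, noisy_dataset):
        fn = make_log_likelihood_fn(noisy_dataset, base_class)
        rng = np.random.default_rng(0)
        prior = PriorSpec()
        theta = rng.uniform(prior.lower, prior.upper, size=(20, 5))
        batch = fn(theta)
        for i in range(20):
            scalar = log_likelihood(MaterialParams.from_vector(theta[i]),
                                    noisy_dataset, base_class)
            assert batch[i] == pytest.approx(scalar, rel=1e-12)


class TestPosterior:
    def test_outside_prior_is_minus_inf(self, prior, base_class, noisy_dataset):
        params = make_params(e_f=3000.0)
        assert log_posterior(params, noisy_dataset, base_class, prior) == -np.inf

    def test_reduces_to_prior_for_flat_likelihood(self, prior):
        # with a constant likelihood, posterior differences equal prior
        # differences: check the additive structure directly
        inside = MaterialParams.from_vector(0.5 * (prior.lower + prior.upper))
        other = make_params(e_f=600.0, eta=10_000.0, e_m=1.0, r_inf=0.3, sigma=0.1)
        assert log_prior(inside, prior) == pytest.approx(log_prior(other, prior))

    def test_noise_free_truth_beats_coarse_grid(self, truth_params, base_class,
                                                noisefree_dataset, prior):
        """On noise-free data the posterior peaks at the generator truth with
        sigma_n at its lower bound, beating every point of a coarse 5-D grid."""
        truth_vec = truth_params.to_vector()
        truth_vec[4] = prior.lower[4]
        best = log_posterior(MaterialParams.from_vector(truth_vec),
                             noisefree_dataset, base_class, prior)
        axes = [np.linspace(lo, hi, 4) for lo, hi in zip(prior.lower, prior.upper)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 5)
        fn = make_log_likelihood_fn(noisefree_dataset, base_class)
        grid_best = np.max(fn(grid)) - prior.log_volume
        assert best > grid_best

    def test_profile_map_matches_elastic_mean(self, prior):
        """Elastic-only inference: the profile-posterior E_f equals
        mean(data)/f_r (matrix contribution removed), against a numeric
        2-D optimizer oracle over (E_f, sigma_n)."""
        data = FascicleDataset("prof", [640.0, 480.0, 550.0], 1.0,
                               np.array([0.0, 1.0]), np.array([1.0, 0.9]))
        cls = FascicleClass(0.35, 70.0)
        e_m = 0.01
        fn = make_log_likelihood_fn(data, cls, observables=("elastic",))

        def negloglik(x):
            e_f, sigma = x
            if e_f <= 0 or sigma <= 0:
                return np.inf
            return -float(fn(np.array([[e_f, 42.0, e_m, 0.4, sigma]]))[0])

        res = minimize(negloglik, x0=np.array([1500.0, 0.1]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        mean = np.mean(data.elastic_moduli)
        expected = (mean - (1 - 0.35) * e_m) / 0.35
        assert res.x[0] == pytest.approx(expected, rel=1e-5)
        assert res.x[0] == pytest.approx(mean / 0.35, rel=1e-2)


class TestDatasetFormat:
    def test_round_trip_is_exact(self, noisy_dataset, tmp_path):
        path = tmp_path / "d.csv"
        write_dataset(noisy_dataset, path)
        back = read_dataset(path)
        assert back.dataset_id == noisy_dataset.dataset_id
        assert back.provenance == "file"
        assert np.array_equal(back.elastic_moduli, noisy_dataset.elastic_moduli)
        assert back.poisson_value == noisy_dataset.poisson_value
        assert np.array_equal(back.times, noisy_dataset.times)
        assert np.array_equal(back.ebar, noisy_dataset.ebar)

    def test_reader_rejects_missing_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# dataset_id: X\ntime_s,Ebar\n0,1\n")
        with pytest.raises(ValueError, match="poisson_value"):
            read_dataset(path)

    @pytest.mark.parametrize("kwargs", [
        {"elastic_moduli": [-1.0]},
        {"poisson_value": 0.0},
        {"times": [0.0, 0.0], "ebar": [1.0, 0.9]},
        {"ebar": [1.0, 1.9]},
        {"ebar": [1.0, 0.0]},
    ])
    def test_invariant_violations_rejected(self, kwargs):
        base = dict(dataset_id="x", elastic_moduli=[640.0], poisson_value=1.0,
                    times=[0.0, 1.0], ebar=[1.0, 0.9])
        with pytest.raises(ValueError):
            FascicleDataset(**{**base, **kwargs})
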