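import math

import numpy as np
import pytest
from scipy.stats import norm

from gnrhsim.infotheory import (CellSample, PopulationSpec, estimate_mi,
                                hill_response_model, input_entropy,
                                samples_from_frame, samples_to_frame,
                                simulate_population)
from gnrhsim.infotheory import _mi_from_counts


def gaussian_samples(means, sd, n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for idx, mu in enumerate(means):
        for cell, value in enumerate(rng.normal(mu, sd, n)):
            out.append(CellSample(idx, float(mu), cell, float(value)))
    return out


class TestInputEntropy:
    def test_eight_uniform_levels_is_three_bits(self):
        assert input_entropy(8) == 3.0

    def test_two_uniform_levels_is_one_bit(self):
        assert input_entropy(2) == 1.0

    def test_single_level_is_zero_bits(self):
        assert input_entropy(1) == 0.0

    def test_nonuniform_probabilities(self):
        assert input_entropy(2, [0.5, 0.5]) == pytest.approx(1.0)
        assert input_entropy(2, [1.0, 0.0]) == pytest.approx(0.0)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            input_entropy(2, [0.7, 0.7])
        with pytest.raises(ValueError):
            input_entropy(3, [0.5, 0.5])


class TestEstimator:
    def test_noiseless_channel_attains_input_entropy(self):
        samples = [CellSample(i, float(i), c, float(i))
                   for i in range(8) for c in range(50)]
        est = estimate_mi(samples, n_boot=20)
        assert est.mi_bits == pytest.approx(3.0, abs=0.05)
        assert est.mi_bits_corrected == pytest.approx(3.0, abs=0.05)

    def test_independent_response_carries_no_information(self):
        rng = np.random.default_rng(7)
        samples = [CellSample(i, 1.0, c, float(rng.normal()))
                   for i in range(8) for c in range(1000)]
        est = estimate_mi(samples, n_boot=20)
        assert est.mi_bits_corrected == pytest.approx(0.0, abs=0.05)

    def test_gaussian_channel_matches_quadrature_oracle(self):
        # oracle: exact MI of the discretized channel, with per-level bin
        # probabilities obtained by integrating the Gaussian densities
        # over the estimator's own bin edges
        means, sd, n = np.arange(8.0), 1.0, 1000
        samples = gaussian_samples(means, sd, n, seed=2)
        est = estimate_mi(samples, n_boot=20)
        responses = np.array([s.response for s in samples])
        edges = np.unique(np.quantile(responses, np.linspace(0, 1, 17)))
        edges[0] -= 1e-12
        edges[-1] += 1e-12
        probs = np.array([np.diff(norm.cdf(edges, m, sd)) for m in means])
        oracle = _mi_from_counts(probs / probs.sum())
        assert est.mi_bits_corrected == pytest.approx(oracle, abs=0.05)

    def test_bounded_by_input_entropy_and_bin_count(self):
        samples = gaussian_samples(np.arange(4.0) * 10, 0.01, 200, seed=3)
        est = estimate_mi(samples, n_bins=2, n_boot=20)
        assert 0.0 <= est.mi_bits_corrected <= min(
            input_entropy(4), math.log2(est.n_bins)) + 1e-12

    def test_mi_degrades_monotonically_with_noise(self):
        mis = [estimate_mi(gaussian_samples(np.arange(4.0), sd, 400, seed=4),
                           n_boot=10).mi_bits_corrected
               for sd in (0.5, 1.0, 2.0)]
        assert mis[0] > mis[1] > mis[2]

    def test_data_processing_inequality(self):
        # stimulus -> upstream (noisy) -> downstream (more noise):
        # information can only be lost along the chain
        rng = np.random.default_rng(11)
        upstream, downstream = [], []
        for idx in range(6):
            up = idx + rng.normal(0, 0.7, 500)
            down = np.sqrt(np.maximum(up, 0)) + rng.normal(0, 0.3, 500)
            for cell, (u, d) in enumerate(zip(up, down)):
                upstream.append(CellSample(idx, float(idx), cell, float(u)))
                downstream.append(CellSample(idx, float(idx), cell, float(d)))
        mi_up = estimate_mi(upstream, n_boot=10).mi_bits_corrected
        mi_down = estimate_mi(downstream, n_boot=10).mi_bits_corrected
        assert mi_down <= mi_up + 0.05

    def test_consistency_on_noiseless_channel(self):
        errors = []
        for n in (50, 200, 1000):
            samples = [CellSample(i, float(i), c, float(i) + 1e-6 * c)
                       for i in range(8) for c in range(n)]
            est = estimate_mi(samples, n_boot=5)
            errors.append(abs(est.mi_bits_corrected - 3.0))
        assert errors[-1] <= errors[0] + 1e-9
        assert errors[-1] < 0.02

    def test_insufficient_cells_error_names_level(self):
        samples = ([CellSample(0, 1.0, c, float(c)) for c in range(20)]
                   + [CellSample(1, 2.0, c, float(c)) for c in range(5)])
        with pytest.raises(ValueError, match="level 1"):
            estimate_mi(samples)

    def test_single_level_rejected(self):
        samples = [CellSample(0, 1.0, c, float(c)) for c in range(20)]
        with pytest.raises(ValueError, match="two stimulus levels"):
            estimate_mi(samples)


class TestPopulation:
    LEVELS = tuple(10.0 ** e for e in np.linspace(-11, -6, 8))

    def _spec(self, **kwargs):
        defaults = dict(stimulus_levels=self.LEVELS, n_cells=300,
                        parameter_cvs={"gain": 0.3}, noise_sd=0.0, seed=1)
        defaults.update(kwargs)
        return PopulationSpec(**defaults)

    def test_zero_cv_zero_noise_gives_identical_cells(self):
        spec = self._spec(parameter_cvs={"gain": 0.0}, n_cells=12)
        samples = simulate_population(spec, response_model=hill_response_model())
        by_level = {}
        for s in samples:
            by_level.setdefault(s.stimulus_index, set()).add(round(s.response, 15))
        assert all(len(v) == 1 for v in by_level.values())

    def test_reproducible_from_seed(self):
        spec = self._spec(n_cells=20, noise_sd=0.05)
        a = simulate_population(spec, response_model=hill_response_model())
        b = simulate_population(spec, response_model=hill_response_model())
        assert [s.response for s in a] == [s.response for s in b]

    def test_higher_cell_variability_lowers_mi(self):
        # two populations with identical mean dose-response; the noisier
        # one transmits less information
        noisy = simulate_population(self._spec(parameter_cvs={"gain": 0.6}),
                                    response_model=hill_response_model())
        tight = simulate_population(self._spec(parameter_cvs={"gain": 0.15}),
                                    response_model=hill_response_model())
        mi_noisy = estimate_mi(noisy, n_boot=30).mi_bits_corrected
        mi_tight = estimate_mi(tight, n_boot=30).mi_bits_corrected
        assert mi_noisy < mi_tight

    def test_proportional_adaptation_preserves_mi_scale_only_reduces_it(self):
        # A -> A': responses and spread shrink together (pure rescaling):
        # MI unchanged.  B -> B': mean response shrinks but absolute
        # spread stays: distributions overlap more and MI drops.
        spec = self._spec(parameter_cvs={"gain": 0.4})
        baseline = simulate_population(spec, response_model=hill_response_model())
        scaled = simulate_population(
            spec, response_model=hill_response_model(top=0.25))
        est_base = estimate_mi(baseline, n_boot=50)
        est_scaled = estimate_mi(scaled, n_boot=50)
        # quantile bins make MI exactly invariant under common rescaling
        assert est_scaled.mi_bits_corrected == pytest.approx(
            est_base.mi_bits_corrected, abs=1e-9)
        assert est_base.ci_low <= est_scaled.mi_bits <= est_base.ci_high

        def shrunk_mean_fixed_spread(stimulus, factors):
            mean = 0.25 * hill_response_model()(stimulus, {"gain": 1.0})
            spread = factors.get("gain", 1.0) - 1.0  # lognormal around 0
            return mean + spread
        adapted = simulate_population(spec,
                                      response_model=shrunk_mean_fixed_spread)
        est_adapted = estimate_mi(adapted, n_boot=50)
        assert est_adapted.mi_bits_corrected < est_base.mi_bits_corrected

    def test_network_backed_population_runs(self):
        # tiny end-to-end run through the receptor-network model itself
        spec = PopulationSpec(stimulus_levels=(1e-9, 1e-7), n_cells=3,
                              parameter_cvs={"Rtot": 0.2}, seed=5)
        samples = simulate_population(spec, channel="ppERK_nuc",
                                      readout_time=30.0, rtol=1e-6, atol=1e-9)
        assert len(samples) == 6
        high = [s.response for s in samples if s.stimulus_index == 1]
        low = [s.response for s in samples if s.stimulus_index == 0]
        assert min(high) > max(low)
        assert len(set(high)) == 3  # heterogeneity visible

    def test_roundtrip_through_table(self):
        spec = self._spec(n_cells=15)
        samples = simulate_population(spec, response_model=hill_response_model())
        df = samples_to_frame(samples)
        back = samples_from_frame(df)
        assert back == samples
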