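"""Bayesian measurement model: sampler, diagnostics, posterior summaries."""

import numpy as np
import pytest

from hepatoclear import (
    DepletionDataset,
    SimulationTruth,
    bayes_clint,
    build_model,
    clint_to_k,
    concordance_report,
    estimate_clint,
    psrf,
    run_mcmc,
    simulate_depletion,
    summarize_posterior,
)
from hepatoclear.bayes import MCMCSamples, ModelError, PriorSpec
from hepatoclear.io import Measurement


FAST = dict(n_iter=2500, n_burn=500)


class TestModelStructure:
    def test_controls_share_abiotic_rate(self, strong_dataset):
        ds, _ = strong_dataset
        model = build_model(ds)
        one = np.ones(1)
        base = model.loglik(one * 0.0, one * 0.0, one * np.log(1e5), one * 0.1)
        moved = model.loglik(one * 0.0, one * 0.005, one * np.log(1e5), one * 0.1)
        assert moved[0] != base[0]  # abiotic rate acts on both conditions
        assert model.t_ctrl.size > 0 and model.t_cells.size > 0

    def test_no_internal_standard_widens_noise_prior(self, strong_dataset):
        ds, _ = strong_dataset
        narrow = build_model(ds)
        for m in ds.measurements:
            m.has_internal_standard = False
        wide = build_model(ds)
        assert wide.extra_noise and not narrow.extra_noise
        assert wide.sigma_scale > narrow.sigma_scale

    def test_slope_prior_bound_from_loq(self, strong_dataset):
        ds, _ = strong_dataset
        model = build_model(ds)
        expected = -np.log(ds.loq_uM / ds.c_test_uM) / ds.t_max
        assert model.k_max == pytest.approx(expected)

    def test_all_indicators_off_means_flat_mean_response(self, strong_dataset):
        ds, _ = strong_dataset
        model = build_model(ds)
        # with z=0 the likelihood is invariant to both rates
        one = np.ones(1)
        a = model.loglik(one * 0.0, one * 0.0, one * 11.0, one * 0.1)
        b = model.loglik(one * 0.0, one * 0.0, one * 11.0, one * 0.1)
        assert a[0] == b[0]

    def test_no_cells_rows_is_model_error(self):
        ds = DepletionDataset("E", [Measurement("E", 0.0, "no_cells", 1, 1.0)])
        with pytest.raises(ModelError, match="no cells-condition rows"):
            build_model(ds)


class TestSampler:
    def test_same_seed_identical_samples(self, strong_dataset):
        ds, _ = strong_dataset
        model = build_model(ds)
        a = run_mcmc(model, n_iter=600, n_burn=100, seed=42)
        b = run_mcmc(model, n_iter=600, n_burn=100, seed=42)
        np.testing.assert_array_equal(a.k_bio, b.k_bio)
        np.testing.assert_array_equal(a.z_bio, b.z_bio)
        c = run_mcmc(model, n_iter=600, n_burn=100, seed=43)
        assert not np.array_equal(a.k_bio, c.k_bio)

    def test_noiseless_decay_recovers_rate_within_two_percent(self):
        truth = SimulationTruth("NL", k_bio_true=0.01, noise_sd_true=0.0, seed=5)
        ds, _ = simulate_depletion(truth)
        post = bayes_clint(ds, n_iter=3000, n_burn=1000, seed=6)
        assert post.clint_median / 2000 == pytest.approx(0.01, rel=0.02)
        assert post.p_cleared > 0.99

    def test_flat_data_does_not_raise_clearance_probability(self, flat_dataset):
        ds, _ = flat_dataset
        post = bayes_clint(ds, seed=7, **FAST)
        assert post.p_cleared <= 0.5

    def test_scale_equivariance_of_biotic_rate_posterior(self, strong_dataset):
        ds, _ = strong_dataset
        scaled = DepletionDataset(
            ds.chemical_id,
            [
                Measurement(m.chemical_id, m.time_min, m.condition, m.replicate,
                            m.response * 1000.0, m.has_internal_standard,
                            m.nominal_conc_uM)
                for m in ds.measurements
            ],
            c_test_uM=ds.c_test_uM,
            cell_density_millions_per_mL=ds.cell_density_millions_per_mL,
            loq_uM=ds.loq_uM,
        )
        a = run_mcmc(build_model(ds), n_iter=800, n_burn=200, seed=9)
        b = run_mcmc(build_model(scaled), n_iter=800, n_burn=200, seed=9)
        np.testing.assert_allclose(a.k_bio, b.k_bio, rtol=1e-12)
        np.testing.assert_array_equal(a.z_bio, b.z_bio)

    def test_label_separation_when_controls_decay_like_cells(self):
        # all the loss is abiotic: cells and controls fall at the same rate
        truth = SimulationTruth("AB", k_bio_true=0.0, k_abio_true=0.004,
                                noise_sd_true=0.1, seed=7)
        ds, _ = simulate_depletion(truth)
        post = bayes_clint(ds, seed=9, **FAST)
        assert post.p_cleared < 0.5  # below the 0.5 prior
        assert post.p_abiotic_post > 0.9

    def test_prior_recovery_with_zero_observations(self):
        empty = DepletionDataset("PRIOR", [], loq_uM=0.01)
        model = build_model(empty, require_data=False)
        samples = run_mcmc(model, n_iter=6000, n_burn=1000, seed=4)
        post = summarize_posterior(samples)
        assert post.p_cleared == pytest.approx(0.5, abs=0.02)
        assert post.p_abiotic_post == pytest.approx(0.05, abs=0.02)


class TestPSRF:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((5, 5000))
        # the unclamped statistic can undershoot 1 by O(1/n) sampling noise
        assert 0.999 <= psrf(chains) <= 1.05

    def test_shifted_chains_exceed_threshold(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((5, 5000))
        chains += 5.0 * np.arange(5)[:, None]  # means 5 sd apart
        assert psrf(chains) > 1.1

    def test_constant_equal_chains_convention(self):
        assert psrf(np.full((5, 100), 3.14)) == 1.0

    def test_constant_different_chains_is_infinite(self):
        chains = np.tile(np.arange(5.0)[:, None], (1, 100))
        assert psrf(chains) == np.inf

    def test_convergence_gate_blocks_nonmixed_posteriors(self):
        rng = np.random.default_rng(2)
        n = 400
        stuck = rng.standard_normal((4, n)) * 1e-3 + np.array([[0.0], [0.004],
                                                               [0.008], [0.012]])
        samples = MCMCSamples(
            chemical_id="STUCK", density=0.5, n_chains=4, n_iter=n, n_burn=0,
            z_bio=np.ones((4, n)), z_abio=np.zeros((4, n)),
            k_bio=np.abs(stuck), k_abio=np.full((4, n), 1e-4),
            log_rf=rng.standard_normal((4, n)) * 0.01,
            log_sigma=rng.standard_normal((4, n)) * 0.01,
        )
        post = summarize_posterior(samples)
        assert post.psrf_max >= 1.1
        assert not post.converged


class TestConcordance:
    def test_identical_classifications_agree_fully(self, strong_dataset, flat_dataset):
        sds, _ = strong_dataset
        fds, _ = flat_dataset
        points = [estimate_clint(sds), estimate_clint(fds)]
        bayes = [bayes_clint(sds, seed=1, **FAST), bayes_clint(fds, seed=2, **FAST)]
        rep = concordance_report(points, bayes)
        assert rep.counts["both cleared"] == 1
        assert rep.counts["neither"] == 1
        assert rep.counts["point-only"] == rep.counts["bayes-only"] == 0

    def test_rank_correlation_on_strong_signals(self):
        clints = [2.0, 5.0, 10.0, 20.0, 35.0]
        points, bayes = [], []
        for i, c in enumerate(clints):
            truth = SimulationTruth(f"R{i}", k_bio_true=clint_to_k(c),
                                    noise_sd_true=0.1, seed=600 + i)
            ds, _ = simulate_depletion(truth)
            points.append(estimate_clint(ds))
            bayes.append(bayes_clint(ds, seed=700 + i, **FAST))
        rep = concordance_report(points, bayes)
        assert rep.rank_correlation > 0.9

    def test_mismatched_ids_error_lists_orphans(self, strong_dataset):
        ds, _ = strong_dataset
        pt = [estimate_clint(ds)]
        with pytest.raises(ValueError, match="CHEM-S"):
            concordance_report(pt, [])
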