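"""Tests of proportion-based and tract-based admixture dating, the
calibration loop, and the bootstrap."""

import numpy as np
import pytest

import admixtime as at
from admixtime.dating import (CalibrationResult, ProportionDataset,
                              PulseDatingMLE, bootstrap_ci,
                              calibrate_by_simulation, fit_pulse,
                              proportion_loglik, weighted_sd_statistic)
from admixtime.density import DiploidPulseDensity, PulseDensity


@pytest.fixture(scope="module")
def haploid_data():
    rng = np.random.default_rng(5)
    d = PulseDensity(0.4, 25, 1.0)
    x = d.sample(200, rng).reshape(50, 4)
    return ProportionDataset(x, np.full(4, 1.0), diploid=False)


class TestLoglik:
    def test_single_observation_at_the_atom(self):
        # haploid y = 1: contribution is log(q e^{-(1-q)h})
        q, t, L = 0.9, 2, 1.0
        data = ProportionDataset(np.array([[1.0]]), np.array([L]),
                                 diploid=False)
        ll = proportion_loglik(data, q, t)
        assert abs(ll - np.log(q * np.exp(-(1 - q) * t * L))) < 1e-12

    def test_invariant_to_individual_ordering(self, haploid_data):
        perm = np.random.default_rng(0).permutation(
            haploid_data.n_individuals)
        shuffled = haploid_data.subset(perm)
        a = proportion_loglik(haploid_data, 0.4, 25)
        b = proportion_loglik(shuffled, 0.4, 25)
        assert abs(a - b) < 1e-9

    def test_equals_per_observation_sum(self, haploid_data):
        """Direct-summation oracle via the raw density functions."""
        q, t = 0.45, 20
        expect = 0.0
        for j, L in enumerate(haploid_data.lengths_morgans):
            d = PulseDensity(q, t, float(L))
            for y in haploid_data.fractions[:, j]:
                if abs(y) < 1e-6:
                    expect += np.log(d.mass_at_0)
                elif abs(y - 1) < 1e-6:
                    expect += np.log(d.mass_at_1)
                else:
                    expect += float(d.log_pdf(y))
        assert abs(proportion_loglik(haploid_data, q, t) - expect) < 1e-8

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ProportionDataset(np.empty((0, 2)), np.ones(2)) \
                .fractions.sum() or proportion_loglik(
                    ProportionDataset(np.empty((0, 2)), np.ones(2)), 0.5, 10)


class TestFitPulse:
    def test_grid_of_one_point_returns_it(self, haploid_data):
        fit = fit_pulse(haploid_data, q_grid=[0.4], t_grid=[25])
        assert (fit.q_hat, fit.t_hat) == (0.4, 25)

    def test_recovers_parameters_from_exact_diploid_samples(self):
        """Sampling exactly from the diploid law at (q=0.3, t=20) with
        n = 1000 on one chromosome recovers the truth to about one grid
        step."""
        rng = np.random.default_rng(7)
        d = DiploidPulseDensity(0.3, 20, 1.5)
        y = d.sample(1000, rng)
        data = ProportionDataset(y[:, None], np.array([1.5]), diploid=True)
        mle = PulseDatingMLE(
            q_grid=np.round(np.arange(0.2, 0.41, 0.01), 3),
            t_grid=np.arange(12, 29)).fit(data)
        assert abs(mle.q_ - 0.3) <= 0.02
        assert abs(mle.t_ - 20) <= 2

    def test_degenerate_data_reported(self):
        data = ProportionDataset(np.ones((5, 3)), np.ones(3), diploid=False)
        with pytest.raises(ValueError, match="non-identifiable"):
            fit_pulse(data, q_grid=[0.5], t_grid=[10])

    def test_tie_break_prefers_smaller_t_then_q(self, monkeypatch):
        data = ProportionDataset(np.full((2, 1), 0.4), np.ones(1),
                                 diploid=False)
        monkeypatch.setattr("admixtime.dating._chrom_loglik",
                            lambda *a, **k: 0.0)
        fit = fit_pulse(data, q_grid=[0.3, 0.5], t_grid=[10, 20])
        assert (fit.t_hat, fit.q_hat) == (10, 0.3)


class TestTractDating:
    def test_worked_example(self):
        # mean ME tract 6.6 cM with q = 0.53 implies ~29 generations
        t = at.mean_tract_time(0.066, 0.53)
        assert abs(t - 28.59) < 0.01
        assert round(t) == 29

    def test_identity_point(self):
        assert at.mean_tract_time(1.0, 1.0) == 1.0

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            at.mean_tract_time(0.0, 0.5)
        with pytest.raises(ValueError):
            at.mean_tract_time(0.1, -1)

    def test_inverse_consistency_with_simulator(self, long_chromosome_map):
        """Feeding the simulated mean B-run length back through the relation
        recovers the simulated time within 2 SE."""
        q, t = 0.5, 30
        tracks = at.simulate_pulse_tracks(
            long_chromosome_map, at.PulseModel({"A": q, "B": 1 - q}, t), 40,
            seed=13)
        res = [tr.run_lengths("B", with_censoring=True) for tr in tracks]
        n_complete = int(np.concatenate([r[1] for r in res]).sum())
        mean_b = at.mean_run_length(tracks, "B") / 100.0
        t_hat = at.mean_tract_time(mean_b, q)
        se_t = t_hat / np.sqrt(n_complete)  # delta method
        assert abs(t_hat - t) < 2 * se_t


class TestWeightedSD:
    def test_identical_proportions_give_zero(self):
        data = ProportionDataset(np.full((4, 3), 0.4), np.ones(3))
        assert weighted_sd_statistic(data) == 0.0

    def test_single_chromosome_equals_its_sd(self):
        fr = np.array([[0.2], [0.4], [0.9]])
        data = ProportionDataset(fr, np.array([1.5]))
        assert abs(weighted_sd_statistic(data) - fr.std(ddof=1)) < 1e-12

    def test_matches_brute_force_weighting(self):
        rng = np.random.default_rng(2)
        fr = rng.random((6, 4))
        L = np.array([2.8, 1.5, 1.0, 0.6])
        data = ProportionDataset(fr, L)
        w = np.sqrt(100 * L)
        expect = sum(wi * fr[:, j].std(ddof=1)
                     for j, wi in enumerate(w)) / w.sum()
        assert abs(weighted_sd_statistic(data) - expect) < 1e-12

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            weighted_sd_statistic(ProportionDataset(np.array([[0.5]]),
                                                    np.ones(1)))


class TestCalibration:
    @staticmethod
    def _stat(t, seed):
        # mean minor-run length of a small simulated cohort
        gmap = at.GeneticMap(lengths_cm={"1": 2000.0})
        tracks = at.simulate_pulse_tracks(
            gmap, at.PulseModel({"A": 0.5, "B": 0.5}, t), 10, seed)
        return at.mean_run_length(tracks, "B")

    def test_closed_loop_recovery(self):
        observed = np.mean([self._stat(25.0, s) for s in (900, 901, 902)])
        res = calibrate_by_simulation(observed, self._stat,
                                      t_grid=np.arange(15, 36, 5),
                                      replicates=3, seed=1)
        assert isinstance(res, CalibrationResult)
        assert abs(res.t_star - 25.0) < 3.0

    def test_constant_curve_is_nonidentifiable(self):
        with pytest.raises(ValueError, match="constant"):
            calibrate_by_simulation(1.0, lambda t, s: 2.0, [10, 20, 30],
                                    replicates=2, seed=0)

    def test_extrapolation_reported(self):
        with pytest.raises(ValueError, match="outside"):
            calibrate_by_simulation(99.0, lambda t, s: t, [10, 20, 30],
                                    replicates=1, seed=0)


class TestBootstrap:
    def test_constant_estimator_zero_width(self, haploid_data):
        lo, hi = bootstrap_ci(lambda d: 1.23, haploid_data, B=50, seed=0)
        assert lo == hi == 1.23

    def test_single_replicate_degenerate_interval(self, haploid_data):
        lo, hi = bootstrap_ci(lambda d: float(d.fractions.mean()),
                              haploid_data, B=1, seed=0)
        assert lo == hi

    def test_too_many_failures_abort(self, haploid_data):
        def flaky(d):
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match="failed"):
            bootstrap_ci(flaky, haploid_data, B=20, seed=0)

    def test_coverage_of_a_known_mean(self):
        """~95% empirical coverage (within the 92-98% band) of the true
        mean over 200 outer replicates."""
        rng = np.random.default_rng(11)
        true_mean = 0.5  # Beta(5, 5)
        hits = 0
        for _ in range(200):
            fr = rng.beta(5, 5, size=(60, 1))
            data = ProportionDataset(fr, np.ones(1))
            lo, hi = bootstrap_ci(lambda d: float(d.fractions.mean()),
                                  data, B=200,
                                  seed=int(rng.integers(2 ** 31)))
            hits += lo <= true_mean <= hi
        assert 0.92 <= hits / 200 <= 0.98


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = PulseDatingMLE(fix_q=0.4, eps=1e-5)
        params = est.get_params()
        clone = PulseDatingMLE(**params)
        assert clone.get_params() == params

    def test_fix_q_mean_uses_sample_mean(self, haploid_data):
        mle = PulseDatingMLE(fix_q="mean", t_grid=[20, 25, 30]) \
            .fit(haploid_data)
        assert abs(mle.q_ - haploid_data.fractions.mean()) < 1e-12

    def test_rejects_non_dataset_input(self):
        with pytest.raises(TypeError):
            PulseDatingMLE().fit(np.ones((3, 2)))
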