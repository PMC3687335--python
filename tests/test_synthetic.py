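"""Tests of the synthetic-measurement generators and the stochastic oracle."""

import math

import numpy as np
import pytest

from transposim.analysis import fit_exp_decay, fit_power_law
from transposim.invasion_models import CellContext, KineticParameterSet
from transposim.synthetic import (
    gen_dose_response,
    gen_emsa_decay,
    gen_gel_timecourse,
    stochastic_oracle,
)


class TestDeterminism:
    def test_same_seed_reproduces_exactly(self):
        a = gen_emsa_decay(5.8e-4, np.linspace(0, 3600, 20), 0.1, seed=3)
        b = gen_emsa_decay(5.8e-4, np.linspace(0, 3600, 20), 0.1, seed=3)
        assert np.array_equal(a.observations, b.observations)
        c = gen_dose_response(100.0, -1.0, [1, 2, 4], 0.2, seed=9)
        d = gen_dose_response(100.0, -1.0, [1, 2, 4], 0.2, seed=9)
        assert np.array_equal(c.observations, d.observations)

    def test_different_seeds_differ(self):
        a = gen_emsa_decay(5.8e-4, [600.0, 1200.0], 0.1, seed=1)
        b = gen_emsa_decay(5.8e-4, [600.0, 1200.0], 0.1, seed=2)
        assert not np.array_equal(a.observations, b.observations)


class TestEmsaDecay:
    def test_noise_free_signal_is_exponential(self):
        ds = gen_emsa_decay(5.8e-4, [0.0, 1200.0], noise_cv=0.0)
        assert ds.observations[0] == pytest.approx(1.0)
        # the 20-minute point carries 50% of the complex
        assert ds.observations[1] == pytest.approx(0.5, rel=0.01)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            gen_emsa_decay(5.8e-4, [-1.0], 0.1, seed=0)

    def test_truth_recovered_from_one_noisy_course(self):
        ds = gen_emsa_decay(5.8e-4, np.linspace(0, 3600, 21)[1:], 0.10, seed=1)
        fit = fit_exp_decay(ds.design, np.clip(ds.observations, None, 1.0))
        assert fit.estimates["k"][0] == pytest.approx(5.8e-4, rel=0.15)


class TestDoseResponse:
    def test_inverse_law_halves_on_doubling(self):
        ds = gen_dose_response(1000.0, -1.0, [50.0, 100.0], noise_cv=0.0)
        assert ds.observations[0] / ds.observations[1] == pytest.approx(2.0)

    def test_zero_noise_is_exact_power_law(self):
        doses = np.geomspace(8, 1000, 8)
        ds = gen_dose_response(1000.0, -1.0, doses, noise_cv=0.0)
        assert np.allclose(ds.observations, 1000.0 / doses)

    def test_positive_doses_required(self):
        with pytest.raises(ValueError):
            gen_dose_response(10.0, -1.0, [0.0, 1.0])

    def test_poisson_counts_are_integers(self):
        ds = gen_dose_response(50.0, -1.0, [1.0, 2.0], 0.1, seed=0, poisson=True)
        assert np.all(ds.observations == np.round(ds.observations))


class TestGelTimecourse:
    def test_quarter_consumption_near_the_synapsis_halftime(self):
        """At k2 = 9.6e-5 /s a quarter of the substrate goes in roughly 2 hr
        (redistribution of occluding dimers makes it slightly faster)."""
        ds = gen_gel_timecourse(
            KineticParameterSet.in_vitro_allosteric(),
            np.linspace(0, 6 * 3600, 400),
            noise_cv=0.0,
        )
        rem = ds.observations
        i = int(np.where(rem <= 0.75)[0][0])
        t_quarter = float(np.interp(0.75, rem[[i, i - 1]], ds.design[[i, i - 1]]))
        assert 3600.0 < t_quarter < 3 * 3600.0

    def test_zero_transposase_is_flat(self):
        ds = gen_gel_timecourse(
            KineticParameterSet.in_vitro_allosteric(),
            np.linspace(0, 3600, 5),
            transposase_M=0.0,
            noise_cv=0.0,
        )
        assert np.allclose(ds.observations, 1.0)


class TestStochasticOracle:
    def test_zero_rate_network_is_constant(self):
        params = KineticParameterSet(
            k0=0, k_minus0=0, k1=0, k_minus1=0, k2=0, k_minus2=0, k3=0
        )
        ctx = CellContext(expression_per_copy=10.0, efficiency=1.0,
                          nonspecific_sites=0.0)
        ens = stochastic_oracle(params, ctx, [1.0, 10.0, 100.0], n_runs=5,
                                seed=0, n0=3)
        assert np.all(ens.trajectories == ens.trajectories[:, :1, :])

    def test_oversized_instance_refused_with_guidance(self):
        with pytest.raises(ValueError, match="ODE engine"):
            stochastic_oracle(
                KineticParameterSet(), CellContext(), [1.0], n_runs=1, n0=200
            )

    def test_single_transposon_occupancy_is_binomial(self):
        """Equilibrium occupancy histogram matches binomial(2, p) with
        p = [T] / ([T] + Kd)."""
        params = KineticParameterSet(k0=0.0, k_minus0=1.0, k2=0.0, k3=0.0)
        ctx = CellContext(nuclear_volume=500.0, expression_per_copy=200.0,
                          efficiency=1.0, nonspecific_sites=0.0)
        cps = np.linspace(2000.0, 4000.0, 6)  # past equilibration
        ens = stochastic_oracle(params, ctx, cps, n_runs=400, seed=7, n0=1)
        observed = ens.trajectories[:, :, 2:5].reshape(-1, 3).mean(axis=0)
        conc = ctx.count_to_molar(200.0)
        p = conc / (conc + params.specific_kd)
        expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        n_samples = 400 * 6
        sems = np.sqrt(expected * (1 - expected) / n_samples)
        # samples are correlated across checkpoints; allow a wide band
        assert np.all(np.abs(observed - expected) < 6 * sems + 0.01)

    def test_ensemble_error_shrinks_with_run_count(self):
        params = KineticParameterSet(k0=0.0, k_minus0=1.0, k2=0.05, k3=5e-3)
        ctx = CellContext(nuclear_volume=2000.0, expression_per_copy=50.0,
                          efficiency=1.0, nonspecific_sites=0.0)
        cps = np.linspace(100, 600, 4)
        small = stochastic_oracle(params, ctx, cps, n_runs=40, seed=1, n0=10)
        big = stochastic_oracle(params, ctx, cps, n_runs=160, seed=2, n0=10)
        ratio = big.sem.mean() / small.sem.mean()
        assert ratio == pytest.approx(0.5, rel=0.4)  # ~1/sqrt(4)


def test_recovery_round_trips_single_seed():
    """One-dataset spot checks; the 100-seed bias medians live in the
    acceptance suite."""
    doses = np.geomspace(8, 1000, 8)
    ds = gen_dose_response(1000.0, -1.0, doses, noise_cv=0.20, seed=7)
    b = fit_power_law(ds.design, ds.observations).estimates["b"][0]
    assert -1.15 <= b <= -0.85
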