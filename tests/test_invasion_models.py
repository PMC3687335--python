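"""Tests of the mechanism right-hand sides and their kinetic identities."""

import numpy as np
import pytest

import transposim as tp
from transposim.invasion_models import (
    CellContext,
    KineticParameterSet,
    allostery_override,
    apply_secondary_site,
    build_model,
    end_occupancy_fractions,
    simulate_invitro_reaction,
)
from transposim.simulation import ScenarioSpec, rate_at_copy_number


def test_parameter_validation():
    with pytest.raises(ValueError):
        KineticParameterSet(k1=-1.0)
    with pytest.raises(ValueError):
        KineticParameterSet(cis_fraction=1.5)
    with pytest.raises(ValueError):
        CellContext(efficiency=0.0)
    with pytest.raises(ValueError):
        apply_secondary_site(KineticParameterSet(), -1.0)


def test_no_transposase_means_no_binding_flux():
    model = build_model("snec", KineticParameterSet(), CellContext())
    y = model.initial_state(5.0)
    y[0] = 0.0  # remove all free transposase
    dy = model.rhs(0.0, y)
    assert np.allclose(dy, 0.0)


@pytest.mark.parametrize("name", ["snec_invitro", "spd_invitro", "deo_invitro"])
def test_transposase_conservation_along_trajectories(name):
    """Expressed transposase closes against expression_per_copy * N."""
    traj = tp.run_invasion(tp.get_scenario(name))
    assert traj.max_conservation_residual() < 1e-6


def test_transposon_pools_sum_to_copy_number(allosteric_invivo_traj):
    traj = allosteric_invivo_traj
    pools = traj.states[list(traj.model.transposon_pools), :].sum(axis=0)
    assert np.allclose(pools, traj.N)


def test_random_assortment_is_quarter_half_quarter():
    """One dimer per transposon, binding only: U:S:D -> 1/4 : 1/2 : 1/4."""
    params = KineticParameterSet(k0=0.0, k_minus0=1.0, k1=3.8e8, k_minus1=1.2e-4,
                                 k2=0.0, k3=0.0)
    ctx = CellContext(nuclear_volume=1.0, expression_per_copy=1.0,
                      efficiency=1.0, nonspecific_sites=0.0)
    spec = ScenarioSpec("assort", "snec", params, ctx, t_span=1e6, n0=1000.0)
    traj = tp.run_invasion(spec)
    fractions = traj.states[2:5, -1] / 1000.0
    assert fractions == pytest.approx([0.25, 0.5, 0.25], abs=0.02)


def test_peak_synapsis_precursor_at_kd():
    """The singly-occupied fraction peaks where free transposase equals Kd."""
    params = KineticParameterSet.in_vivo_ideal()
    kd = params.specific_kd
    grid = kd * np.logspace(-3, 3, 25)
    f_single = [end_occupancy_fractions(c, params)[1] for c in grid]
    c_peak = grid[int(np.argmax(f_single))]
    assert 0.5 * kd <= c_peak <= 2.0 * kd


class TestAllostery:
    def test_identity_override_leaves_trajectories_unchanged(self):
        spec = tp.get_scenario("snec_invitro").with_overrides(t_span=1e5)
        p_id = allostery_override(spec.params, spec.params.k2, spec.params.k_minus1)
        t1 = tp.run_invasion(spec)
        t2 = tp.run_invasion(spec.with_overrides(params=p_id))
        assert np.array_equal(t1.N, t2.N)

    def test_override_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            allostery_override(KineticParameterSet(), 0.0, 1.0)

    def test_crowding_scaled_allosteric_synapsis_rate(
        self, in_vitro_table, in_vivo_table
    ):
        """The in vivo allosteric k2 equals the in vitro estimate times the
        ideal-chain crowding penalty, consistent with the preset 3.4e-9."""
        scaled = 9.6e-5 * (in_vivo_table.k2 / in_vitro_table.k2)
        assert scaled == pytest.approx(3.4e-9, rel=0.10)

    def test_allosteric_estimates_flatten_the_accelerating_phase(self):
        """With experimental k2/k-1 the per-copy rate decays from the start
        while the total rate stays roughly constant."""
        traj = tp.run_invasion(tp.get_scenario("snec_invitro_allosteric"))
        sel = traj.N >= 2.0
        pcr = traj.per_copy_rate[sel]
        assert pcr[-1] < 0.5 * pcr[0]  # per-copy rate decays
        from transposim.simulation import steady_state_rate

        assert steady_state_rate(traj).steady  # total rate constant


class TestSecondarySite:
    def test_zero_multiplier_is_exactly_baseline(self):
        base = tp.get_scenario("snec_invivo").with_overrides(t_span=1e7)
        with_site = base.with_overrides(
            params=apply_secondary_site(base.params, 0.0)
        )
        assert np.array_equal(
            tp.run_invasion(base).N, tp.run_invasion(with_site).N
        )

    def test_occupied_site_reduces_rate_in_proportion_to_affinity(self):
        """At a fixed copy number the rate falls ~2x from 1x to 2x affinity."""
        s0 = tp.get_scenario("snec_invivo").with_overrides(t_span=1e10)
        s1 = tp.get_scenario("snec_invivo_secondary_1x").with_overrides(t_span=1e10)
        s2 = tp.get_scenario("snec_invivo_secondary_2x").with_overrides(t_span=1e10)
        q0, q1, q2 = (rate_at_copy_number(s, 5000.0) for s in (s0, s1, s2))
        assert q1 < q0
        assert q2 / q1 == pytest.approx(0.5, rel=0.15)

    def test_dynamics_stay_non_exponential(self):
        from transposim.analysis import classify_regime

        traj = tp.run_invasion(tp.get_scenario("snec_invivo_secondary_1x"))
        assert classify_regime(traj) == "linear_steady"


class TestSpdVariants:
    def test_cis_action_slows_but_stays_exponential(self, spd_baseline_traj):
        from transposim.analysis import classify_regime

        cis = tp.run_invasion(tp.get_scenario("spd_invitro_cis"))
        assert classify_regime(cis) == "exponential"

        def time_to(traj, n):
            idx = np.where(traj.N >= n)[0]
            return traj.times[idx[0]] if idx.size else np.inf

        assert time_to(cis, 1e5) > 2.0 * time_to(spd_baseline_traj, 1e5)

    def test_inhibitor_alone_stays_exponential(self):
        from transposim.analysis import classify_regime

        traj = tp.run_invasion(tp.get_scenario("spd_invitro_inhibitor"))
        assert classify_regime(traj) == "exponential"

    def test_combined_cis_and_inhibitor_nearly_flat(self):
        traj = tp.run_invasion(tp.get_scenario("spd_invitro_cis_inhibitor"))
        assert traj.N[-1] < 5.0  # barely grows over the simulated window

    def test_bigger_genome_and_volume_slow_the_spd_invasion(self):
        """Opposite response to the naked-end-capture mechanism."""
        base = tp.get_scenario("spd_invitro").with_overrides(t_span=2e4)
        n_base = tp.run_invasion(base).N[-1]
        n_genome = tp.run_invasion(
            base.with_overrides(ctx={"genome_size": 6e9})
        ).N[-1]
        assert n_genome < 0.5 * n_base


class TestDeo:
    def test_dampened_relative_to_unregulated_dimerization_assembly(self):
        from transposim.analysis import classify_regime

        traj = tp.run_invasion(tp.get_scenario("deo_invitro"))
        assert classify_regime(traj) == "linear_steady"

    def test_doubling_inhibitory_dimer_affinity_lowers_the_rate(self):
        base = tp.get_scenario("deo_invivo").with_overrides(t_span=1e10)
        stronger = base.with_overrides(
            params={"deo_dimer_end_affinity_multiplier": 2.0}
        )
        r1 = rate_at_copy_number(base, 1e5)
        r2 = rate_at_copy_number(stronger, 1e5)
        assert r2 < r1

    def test_steady_rate_independent_of_end_binding_rate(self):
        """Scaling monomer and dimer end association together (dimerization
        fixed) leaves the established steady rate unchanged."""
        base = tp.get_scenario("deo_invitro").with_overrides(
            params={"deo_dimerization_k": 3.8e8}
        )
        r1 = rate_at_copy_number(base, 2e5)
        r5 = rate_at_copy_number(
            base.with_overrides(params={"k1": 3.8e8 * 5}), 2e5
        )
        r02 = rate_at_copy_number(
            base.with_overrides(params={"k1": 3.8e8 / 5}), 2e5
        )
        assert r5 / r1 == pytest.approx(1.0, rel=0.10)
        assert r02 / r1 == pytest.approx(1.0, rel=0.10)


class TestInvitroReaction:
    def test_preequilibrated_optimal_ratio_starts_quarter_half_quarter(self):
        params = KineticParameterSet.in_vitro_allosteric()
        t, y = simulate_invitro_reaction(
            params, 6.7e-9, 6.7e-9, [0.0], binding_preequilibrated=True
        )
        pools = y[1:4, 0] / 6.7e-9
        assert pools == pytest.approx([0.25, 0.5, 0.25], abs=0.02)

    def test_fast_synapsis_consumes_the_reactive_half_immediately(self):
        params = KineticParameterSet(k2=50.0, k_minus1=5.8e-4)
        t, y = simulate_invitro_reaction(
            params, 6.7e-9, 6.7e-9, np.linspace(0, 60, 7),
            binding_preequilibrated=True,
        )
        consumed = (y[4] + y[5]) / 6.7e-9
        assert 0.45 < consumed[-1] < 0.65

    def test_zero_transposase_is_flat(self):
        params = KineticParameterSet.in_vitro_allosteric()
        _, y = simulate_invitro_reaction(params, 6.7e-9, 0.0, np.linspace(0, 3600, 5))
        assert np.allclose(y[1], 6.7e-9)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_invitro_reaction(
                KineticParameterSet(), 1e-9, 1e-9, [-1.0, 0.0]
            )
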