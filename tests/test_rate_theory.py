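"""Unit and property tests of the diffusion-limited rate-theory chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import transposim as tp
from transposim.rate_theory import (
    RateTheoryInputs,
    collins_kimball_compose,
    collins_kimball_kact,
    halflife_to_rate,
    k1_diff_bound,
    k1_diff_free,
    local_concentration_jM,
    molar_rate_to_volume_rate,
    rate_to_halflife,
    volume_rate_to_molar_rate,
)


def rel(a, b):
    return abs(a - b) / abs(b)


class TestUnitConversions:
    @pytest.mark.parametrize(
        "molar, volume, tol",
        [(3.8e8, 0.633, 0.01), (9.9e6, 0.0166, 0.02)],
    )
    def test_molar_to_per_nucleus_volume(self, molar, volume, tol):
        assert rel(molar_rate_to_volume_rate(molar), volume) < tol

    def test_zero_and_errors(self):
        assert molar_rate_to_volume_rate(0.0) == 0.0
        with pytest.raises(ValueError):
            molar_rate_to_volume_rate(-1.0)
        with pytest.raises(ValueError):
            volume_rate_to_molar_rate(-1.0)

    @given(st.floats(min_value=1e-6, max_value=1e12))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip(self, k):
        assert volume_rate_to_molar_rate(molar_rate_to_volume_rate(k)) == pytest.approx(
            k, rel=1e-14
        )


class TestHalflifeConversions:
    @pytest.mark.parametrize(
        "t_half, rate",
        [
            (1200.0, 5.8e-4),  # 20 min, 50% complex dissociation
            (7200.0, 9.6e-5),  # 2 hr quarter-consumption of nicked substrate
            (480.0, 1.4e-3),  # 8 min maturation of the excised transposon
        ],
    )
    def test_measured_halflives(self, t_half, rate):
        assert rel(halflife_to_rate(t_half), rate) < 0.05

    def test_identity_and_inverse(self):
        assert halflife_to_rate(math.log(2.0)) == pytest.approx(1.0)
        assert rate_to_halflife(halflife_to_rate(321.0)) == pytest.approx(321.0)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            halflife_to_rate(bad)
        with pytest.raises(ValueError):
            rate_to_halflife(bad)


class TestDiffusionLimits:
    def test_free_protein_limit_reduces_to_smoluchowski(self):
        """With no segmental DNA motion only the 4*pi*Dp*R term remains."""
        inputs = RateTheoryInputs(segmental_diffusion_Ds=1e-12)
        expected = volume_rate_to_molar_rate(4 * math.pi * 61.0 * 2.5e-3)
        assert rel(k1_diff_free(inputs), expected) < 1e-6
        assert rel(expected, 1.15e9) < 0.01  # hand computation

    def test_bound_protein_limit_linear_in_segmental_diffusion(self):
        vitro = k1_diff_bound(tp.preset_inputs("in_vitro"))
        vivo = k1_diff_bound(tp.preset_inputs("in_vivo"))
        assert vitro / vivo == pytest.approx(27.0 / 5e-4, rel=1e-9)

    def test_input_invariants(self):
        with pytest.raises(ValueError):
            RateTheoryInputs(reaction_radius_R=60.0)  # R >= a
        with pytest.raises(ValueError):
            RateTheoryInputs(segmental_diffusion_Ds=-1.0)


class TestCollinsKimball:
    def test_half_diffusion_limit_symmetry(self):
        assert collins_kimball_kact(0.5e9, 1.0e9) == pytest.approx(1.0e9)

    def test_no_activation_barrier_limit(self):
        assert collins_kimball_compose(4.2e8, math.inf) == pytest.approx(4.2e8)

    def test_observed_faster_than_diffusion_is_an_error(self):
        with pytest.raises(ValueError):
            collins_kimball_kact(2.0e9, 1.5e9)

    @given(
        st.floats(min_value=1e2, max_value=1e12),
        st.floats(min_value=1e2, max_value=1e12),
    )
    @settings(derandomize=True, max_examples=100)
    def test_compose_then_extract_round_trip(self, k_diff, k_act):
        composed = collins_kimball_compose(k_diff, k_act)
        assert collins_kimball_kact(composed, k_diff) == pytest.approx(
            k_act, rel=1e-10
        )
        # harmonic bound
        assert composed <= min(k_diff, k_act) * (1 + 1e-12)


class TestLocalConcentration:
    def test_third_factor_is_unity_at_reference_persistence_length(self):
        assert 1.25e5 / 50.0**3 == pytest.approx(1.0)

    def test_gaussian_chain_limit(self):
        """Independent oracle: ideal-chain looping concentration.

        For separations far above the persistence length the stiffness
        exponential approaches 1 and the empirical formula must agree with
        the Gaussian-chain local concentration
        j = (3 / (2 pi <R^2>))^(3/2) / N_A with <R^2> = 2 a L.
        """
        a_nm = 50.0
        for b in (2000.0, 5000.0, 2e4, 1e5):
            L_nm = 0.34 * b
            r2 = 2.0 * a_nm * L_nm  # nm^2
            j_per_nm3 = (3.0 / (2.0 * math.pi * r2)) ** 1.5
            j_gauss = j_per_nm3 * 1e24 / tp.AVOGADRO  # nm^-3 -> mol/L
            assert rel(local_concentration_jM(a_nm, b), j_gauss) < 0.15

    def test_monotone_decreasing_beyond_maximum(self):
        bs = np.geomspace(500, 1e5, 60)
        js = [local_concentration_jM(50.0, b) for b in bs]
        i_max = int(np.argmax(js))
        assert all(x > y for x, y in zip(js[i_max:], js[i_max + 1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            local_concentration_jM(-50.0, 1287.0)


class TestParameterTables:
    @pytest.mark.parametrize(
        "field, expected",
        [
            ("k1_diff", 1.5e9),
            ("k_act", 5.2e8),
            ("k1_diff_prime", 4.2e8),
            ("k1_prime", 2.3e8),
            ("local_conc_B", 5.5e-8),
            ("k2", 12.7),
        ],
    )
    def test_dilute_solution_chain(self, in_vitro_table, two_sf, field, expected):
        assert rel(getattr(in_vitro_table, field), expected) < two_sf

    @pytest.mark.parametrize(
        "field, expected",
        [
            ("k1_diff", 2.9e8),
            ("k1_effective", 1.9e8),
            ("k1_diff_prime", 7.8e3),
            ("k1_prime", 7.8e3),
            ("local_conc_B", 5.5e-8),
            ("k2", 4.3e-4),
        ],
    )
    def test_crowded_nucleus_chain(self, in_vivo_table, two_sf, field, expected):
        assert rel(getattr(in_vivo_table, field), expected) < two_sf

    def test_recomposed_first_end_rate_recovers_measurement(self, in_vitro_table):
        assert in_vitro_table.k1_effective == pytest.approx(3.8e8, rel=1e-9)

    def test_crowding_penalty_on_synapsis_is_four_orders(
        self, in_vitro_table, in_vivo_table
    ):
        penalty = in_vitro_table.k2 / in_vivo_table.k2
        assert 1e4 < penalty < 1e5  # order of magnitude only

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            tp.preset_inputs("in_silico")
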