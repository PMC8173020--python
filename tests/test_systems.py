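import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import translocation_step_oracle, two_locus_step_oracle
from underdrive import (
    DriveSystemSpec,
    Fate,
    PopulationState,
    System,
    carrier_frequency,
    iterate,
    release_state,
    step_extreme_ud,
    step_translocation,
    step_two_locus,
)

COSTS = st.floats(min_value=0.0, max_value=0.95)
FRACTIONS = st.floats(min_value=0.0, max_value=1.0)


def simplex(n):
    """Strategy for a normalized frequency vector of length n."""
    return st.lists(
        st.floats(min_value=1e-3, max_value=1.0), min_size=n, max_size=n
    ).map(lambda v: np.array(v) / np.sum(v))


class TestExtremeUnderdominance:
    @pytest.mark.parametrize(
        "p, s, expected",
        [
            (0.5, 0.0, 0.5),  # symmetric unstable fixed point at zero cost
            (1.0, 0.3, 1.0),  # fixation is absorbing
            (0.0, 0.3, 0.0),  # loss is absorbing
            (0.6, 0.1, 0.36 * 0.9 / (0.36 * 0.9 + 0.16)),
        ],
    )
    def test_step_examples(self, p, s, expected):
        assert step_extreme_ud(p, s) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("s", [0.0, 0.05, 0.1, 0.3484, 0.8])
    def test_fixed_points_are_loss_threshold_fixation(self, s):
        for p_star in (0.0, 1.0 / (2.0 - s), 1.0):
            assert abs(step_extreme_ud(p_star, s) - p_star) < 1e-12

    @settings(derandomize=True, max_examples=200)
    @given(p=FRACTIONS)
    def test_zero_cost_symmetry(self, p):
        assert step_extreme_ud(1.0 - p, 0.0) == pytest.approx(
            1.0 - step_extreme_ud(p, 0.0), abs=1e-12
        )

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_rejects_frequency_outside_unit_interval(self, bad):
        with pytest.raises(ValueError):
            step_extreme_ud(bad, 0.1)

    def test_rejects_lethal_cost_of_one(self):
        with pytest.raises(ValueError):
            step_extreme_ud(0.5, 1.0)
        with pytest.raises(ValueError):
            DriveSystemSpec(System.EXTREME_UD, 1.0)


class TestTranslocation:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)),  # stock breeds true
            ((0.5, 0.0, 0.5), (0.25, 0.5, 0.25)),  # Hardy-Weinberg at T=0.5
            # heterozygotes: balanced gametes are 1/4 T, 1/4 t; conditioning
            # on viable zygotes restores T-gamete frequency 0.5
            ((0.0, 1.0, 0.0), (0.25, 0.5, 0.25)),
        ],
    )
    def test_zero_cost_examples(self, state, expected):
        out = step_translocation(
            PopulationState(System.TRANSLOCATION, state), 0.0
        )
        np.testing.assert_allclose(out.frequencies, expected, atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(freqs=simplex(3), s=COSTS)
    def test_matches_mating_table_oracle(self, freqs, s):
        ours = step_translocation(
            PopulationState(System.TRANSLOCATION, freqs), s
        ).frequencies
        np.testing.assert_allclose(
            ours, translocation_step_oracle(freqs, s), atol=1e-12
        )


class TestTwoLocus:
    def test_released_double_homozygote_breeds_true(self):
        state = release_state(System.TWO_LOCUS_UD, 1.0)
        out = step_two_locus(state, 0.0)
        assert out.frequency("AABB") == pytest.approx(1.0, abs=1e-12)

    def test_half_release_gives_three_viable_classes(self):
        out = step_two_locus(release_state(System.TWO_LOCUS_UD, 0.5), 0.0)
        assert out.frequency("AABB") == pytest.approx(0.25, abs=1e-12)
        assert out.frequency("AaBb") == pytest.approx(0.5, abs=1e-12)
        assert out.frequency("aabb") == pytest.approx(0.25, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(freqs=simplex(9), s=COSTS)
    def test_unbalanced_carriers_are_always_killed(self, freqs, s):
        out = step_two_locus(PopulationState(System.TWO_LOCUS_UD, freqs), s)
        for genotype in ("AAbb", "Aabb", "aaBB", "aaBb"):
            assert out.frequency(genotype) == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(freqs=simplex(9), s=COSTS)
    def test_matches_mating_table_oracle(self, freqs, s):
        ours = step_two_locus(
            PopulationState(System.TWO_LOCUS_UD, freqs), s
        ).frequencies
        np.testing.assert_allclose(
            ours, two_locus_step_oracle(freqs, s), atol=1e-12
        )


class TestStateInvariants:
    @settings(derandomize=True, max_examples=60)
    @given(freqs=simplex(3), s=COSTS)
    def test_translocation_step_stays_on_simplex(self, freqs, s):
        out = step_translocation(PopulationState(System.TRANSLOCATION, freqs), s)
        assert np.all(out.frequencies >= 0)
        assert out.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(freqs=simplex(9), s=COSTS)
    def test_two_locus_step_stays_on_simplex(self, freqs, s):
        out = step_two_locus(PopulationState(System.TWO_LOCUS_UD, freqs), s)
        assert np.all(out.frequencies >= 0)
        assert out.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_normalized_state_rejected(self):
        with pytest.raises(ValueError):
            PopulationState(System.TRANSLOCATION, [0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            PopulationState(System.EXTREME_UD, [0.7, 0.2])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            PopulationState(System.EXTREME_UD, [0.2, 0.3, 0.5])


class TestCarrierFrequency:
    def test_extreme_ud_has_no_heterozygote_class(self):
        state = PopulationState(System.EXTREME_UD, [0.7, 0.3])
        assert carrier_frequency(state) == pytest.approx(0.7)

    def test_translocation_counts_heterozygotes(self):
        state = PopulationState(System.TRANSLOCATION, [0.25, 0.5, 0.25])
        assert carrier_frequency(state) == pytest.approx(0.75)

    def test_two_locus_counts_every_construct_bearing_class(self):
        freqs = np.zeros(9)
        freqs[[0, 4, 8]] = (0.25, 0.5, 0.25)
        state = PopulationState(System.TWO_LOCUS_UD, freqs)
        assert carrier_frequency(state) == pytest.approx(0.75)


class TestIterate:
    def test_unstable_equilibrium_is_constant(self):
        spec = DriveSystemSpec(System.EXTREME_UD, 0.0)
        traj = iterate(spec, release_state(System.EXTREME_UD, 0.5), 10)
        assert len(traj) == 11
        assert all(
            st.frequencies[0] == pytest.approx(0.5, abs=1e-12) for st in traj.states
        )
        assert traj.fate is Fate.PERSISTING

    def test_release_above_threshold_fixes(self):
        spec = DriveSystemSpec(System.EXTREME_UD, 0.1)  # threshold 0.5263
        traj = iterate(spec, release_state(System.EXTREME_UD, 0.9), 200)
        assert traj.fate is Fate.FIXED

    def test_release_below_threshold_is_lost(self):
        spec = DriveSystemSpec(System.EXTREME_UD, 0.1)
        traj = iterate(spec, release_state(System.EXTREME_UD, 0.5), 200)
        assert traj.fate is Fate.LOST

    def test_fate_is_a_step_function_of_release(self):
        # single switch point between the loss and fixation basins
        spec = DriveSystemSpec(System.EXTREME_UD, 0.1)
        fates = [
            iterate(spec, release_state(System.EXTREME_UD, f), 300).fate
            for f in np.linspace(0.01, 0.99, 50)
        ]
        switches = sum(
            fates[i] != fates[i + 1] for i in range(len(fates) - 1)
        )
        assert switches == 1
        assert fates[0] is Fate.LOST and fates[-1] is Fate.FIXED

    def test_negative_generations_rejected(self):
        spec = DriveSystemSpec(System.EXTREME_UD, 0.0)
        with pytest.raises(ValueError):
            iterate(spec, release_state(System.EXTREME_UD, 0.5), -1)
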