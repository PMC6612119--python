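"""Population-doubling arithmetic, composition dynamics, stress and invasion
normalization, tumor volume."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonetrace as ct

positive_counts = st.floats(min_value=1.0, max_value=1e9)


class TestCpd:
    @pytest.mark.parametrize(
        "seed,final,expected",
        [(500_000, 1_000_000, 1.0), (500_000, 4_000_000, 3.0), (123_456, 123_456, 0.0)],
    )
    def test_doubling_counts(self, seed, final, expected):
        assert ct.cpd(seed, final) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            ct.cpd(0, 100)
        with pytest.raises(ValueError):
            ct.cpd(100, 0)

    @given(a=positive_counts, b=positive_counts, c=positive_counts)
    @settings(max_examples=200, derandomize=True)
    def test_additive_over_serial_passages(self, a, b, c):
        assert ct.cpd(a, b) + ct.cpd(b, c) == pytest.approx(ct.cpd(a, c), abs=1e-9)

    @pytest.mark.parametrize(
        "doublings,interval,expected", [(7, 7, 1.0), (3, 7, 3 / 7), (0, 10, 0.0)]
    )
    def test_rate(self, doublings, interval, expected):
        assert ct.cpd_rate(doublings, interval) == pytest.approx(expected)

    def test_rate_rejects_zero_interval(self):
        with pytest.raises(ValueError):
            ct.cpd_rate(1.0, 0)


class TestExpectedComposition:
    def test_equal_rates_leave_fractions_unchanged(self):
        start = {"a": 0.2, "b": 0.8}
        state = ct.expected_composition({"a": 0.7, "b": 0.7}, start, t=13)
        assert state.fractions["a"] == pytest.approx(0.2, abs=1e-12)

    def test_closed_form_two_thirds(self):
        state = ct.expected_composition({"f": 1.0, "s": 0.0}, {"f": 0.5, "s": 0.5}, t=1)
        assert state.fractions["f"] == pytest.approx(2 / 3, abs=1e-12)
        assert state.fractions["s"] == pytest.approx(1 / 3, abs=1e-12)

    def test_single_clone_stays_at_one(self):
        for t in (0, 5, 30):
            assert ct.expected_composition({"a": 0.9}, {"a": 1.0}, t).fractions["a"] == 1.0

    @given(
        r1=st.floats(-2, 2), r2=st.floats(-2, 2),
        f=st.floats(0.01, 0.99), t=st.floats(0, 30),
    )
    @settings(max_examples=200, derandomize=True)
    def test_fractions_sum_to_one(self, r1, r2, f, t):
        state = ct.expected_composition({"a": r1, "b": r2}, {"a": f, "b": 1 - f}, t)
        assert sum(state.fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestParameterRecovery:
    """simulate_growth -> cpd/cpd_rate recovers the input rates; compounding
    them reproduces the simulated co-culture fractions."""

    RATES = {"MDA-MB-231": 1.00, "GFP C3": 0.95, "mKO E10": 0.60, "Sapphire D7": 0.70}

    def test_rates_and_fractions_recovered(self):
        seeds = dict.fromkeys(self.RATES, 125_000.0)
        growth = ct.simulate_growth(self.RATES, seeds, days=28,
                                    passage_every=7, total_reseed=500_000)
        cpds = ct.cpds_from_growth(growth, passage_every=7)
        for row in cpds.itertuples():
            assert row.rate == pytest.approx(self.RATES[row.clone], abs=1e-9)
        start = {c: 0.25 for c in self.RATES}
        for day in (0, 7, 14, 21, 28):
            expected = ct.expected_composition(self.RATES, start, day)
            observed = growth[growth.day == day].set_index("clone")["fraction"]
            for clone in self.RATES:
                assert observed[clone] == pytest.approx(
                    expected.fractions[clone], abs=1e-9
                )


class TestCompareExpectedObserved:
    def test_zero_deviation_when_equal(self):
        state = ct.CompositionState(7, {"a": 0.4, "b": 0.6})
        table = ct.compare_expected_observed(state, state)
        assert np.allclose(table["deviation_points"], 0.0)
        assert np.allclose(table["ratio"], 1.0)

    def test_reported_shortfall_in_points(self):
        expected = ct.CompositionState(28, {"GFP C3": 0.3994, "rest": 0.6006})
        observed = ct.CompositionState(28, {"GFP C3": 0.1472, "rest": 0.8528})
        table = ct.compare_expected_observed(expected, observed).set_index("clone")
        assert table.loc["GFP C3", "deviation_points"] == pytest.approx(-25.22)

    def test_infinite_ratio_flagged_not_raised(self):
        expected = ct.CompositionState(1, {"a": 0.0, "b": 1.0})
        observed = ct.CompositionState(1, {"a": 0.1, "b": 0.9})
        table = ct.compare_expected_observed(expected, observed).set_index("clone")
        assert math.isinf(table.loc["a", "ratio"])

    def test_clone_mismatch_raises(self):
        with pytest.raises(ValueError):
            ct.compare_expected_observed(
                ct.CompositionState(1, {"a": 1.0}), ct.CompositionState(1, {"b": 1.0})
            )


class TestApplyStress:
    def test_full_survival_is_identity(self):
        state = ct.CompositionState(1, {"a": 0.3, "b": 0.7})
        out = ct.apply_stress(state, {"a": 1.0, "b": 1.0})
        assert out.fractions == pytest.approx(state.fractions)

    def test_differential_survival_renormalizes(self):
        state = ct.CompositionState(1, {"a": 0.5, "b": 0.5})
        out = ct.apply_stress(state, {"a": 1.0, "b": 0.5})
        assert out.fractions["a"] == pytest.approx(2 / 3)

    def test_extinction(self):
        state = ct.CompositionState(1, {"a": 0.5, "b": 0.5})
        out = ct.apply_stress(state, {"a": 1.0, "b": 0.0})
        assert out.fractions == {"a": 1.0, "b": 0.0}

    def test_all_dead_raises(self):
        state = ct.CompositionState(1, {"a": 0.5, "b": 0.5})
        with pytest.raises(ValueError):
            ct.apply_stress(state, {"a": 0.0, "b": 0.0})

    @given(
        f=st.floats(0.01, 0.99),
        s1=st.floats(0.01, 1), s2=st.floats(0.01, 1),
        t1=st.floats(0.01, 1), t2=st.floats(0.01, 1),
    )
    @settings(max_examples=200, derandomize=True)
    def test_two_pulses_compose_multiplicatively(self, f, s1, s2, t1, t2):
        state = ct.CompositionState(1, {"a": f, "b": 1 - f})
        stepwise = ct.apply_stress(ct.apply_stress(state, {"a": s1, "b": s2}),
                                   {"a": t1, "b": t2})
        joint = ct.apply_stress(state, {"a": s1 * t1, "b": s2 * t2})
        assert stepwise.fractions["a"] == pytest.approx(joint.fractions["a"], abs=1e-9)


class TestMixInvasionRatio:
    def _cond(self, clone, seeded, invading, tag):
        return ct.InvasionCondition(clone, seeded, invading, tag)

    def test_half_seed_equal_invaders_doubles(self):
        alone = self._cond("GFP C3", 30_000, 300, "alone")
        mix = self._cond("GFP C3", 15_000, 300, "mix")
        assert ct.mix_invasion_ratio(alone, mix) == pytest.approx(2.0)

    def test_identical_per_cell_rates_give_one(self):
        alone = self._cond("c", 30_000, 600, "alone")
        mix = self._cond("c", 15_000, 300, "mix")
        assert ct.mix_invasion_ratio(alone, mix) == pytest.approx(1.0)

    def test_no_mix_invaders_gives_zero(self):
        alone = self._cond("c", 30_000, 600, "alone")
        mix = self._cond("c", 15_000, 0, "mix")
        assert ct.mix_invasion_ratio(alone, mix) == 0.0

    def test_no_alone_invaders_is_undefined(self):
        alone = self._cond("c", 30_000, 0, "alone")
        mix = self._cond("c", 15_000, 10, "mix")
        assert math.isnan(ct.mix_invasion_ratio(alone, mix))


class TestTumorVolume:
    @pytest.mark.parametrize("D,d,expected", [(10, 5, 125.0), (2, 1, 1.0), (3, 3, 13.5)])
    def test_formula(self, D, d, expected):
        assert ct.tumor_volume(D, d) == pytest.approx(expected)

    def test_sphere_limit(self):
        assert ct.tumor_volume(4.0, 4.0) == pytest.approx(4.0**3 / 2)

    def test_rejects_d_larger_than_D(self):
        with pytest.raises(ValueError):
            ct.tumor_volume(2.0, 3.0)
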