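"""Concordance rates and the ascertainment / shared-environment adjustments."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinrisk.concordance import (
    AdjustmentFactors,
    EpidemiologicalObservables,
    TwinPairCounts,
    adjust_concordance,
    calibrate_ascertainment,
    iu_adjustment_factor,
    pairwise_concordance,
    probandwise_concordance,
    renormalize_subgroups,
    round_half_up,
)


@pytest.mark.parametrize(
    "c, d, expected",
    [(9, 31, 0.225), (0, 10, 0.0), (22, 66, 0.25)],
)
def test_pairwise_concordance(c, d, expected):
    assert pairwise_concordance(TwinPairCounts(c, d)) == pytest.approx(expected)


def test_pairwise_needs_pairs():
    with pytest.raises(ValueError):
        pairwise_concordance(TwinPairCounts(0, 0))


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        TwinPairCounts(-1, 5)


class TestAscertainmentCalibration:
    def test_registry_example(self):
        """Solving f*20/(f*20+73) = 0.297 gives f ~ 1.542 and round-trips."""
        counts = TwinPairCounts(20, 73)
        factors = calibrate_ascertainment(counts, 0.297)
        assert factors.ascertainment_inflation == pytest.approx(1.542, abs=5e-4)
        assert probandwise_concordance(counts, factors) == pytest.approx(
            0.297, abs=1e-12
        )

    def test_full_double_ascertainment_gives_f2(self):
        counts = TwinPairCounts(24, 109)
        rate = 2 * 24 / (2 * 24 + 109)
        f = calibrate_ascertainment(counts, rate).ascertainment_inflation
        assert f == pytest.approx(2.0, abs=1e-12)

    def test_no_double_ascertainment_gives_f1(self):
        counts = TwinPairCounts(13, 37)
        f = calibrate_ascertainment(counts, 13 / 50).ascertainment_inflation
        assert f == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_rate_raises(self):
        with pytest.raises(ValueError, match="outside"):
            calibrate_ascertainment(TwinPairCounts(10, 90), 0.5)

    def test_zero_concordant_uncalibratable(self):
        with pytest.raises(ValueError):
            calibrate_ascertainment(TwinPairCounts(0, 50), 0.1)

    @given(
        c=st.integers(1, 500),
        d=st.integers(1, 500),
        pi=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_roundtrip_property(self, c, d, pi):
        counts = TwinPairCounts(c, d)
        rate = probandwise_concordance(counts, 1.0 + pi)
        recovered = calibrate_ascertainment(counts, rate)
        assert probandwise_concordance(counts, recovered) == pytest.approx(
            rate, abs=1e-12
        )

    @given(c=st.integers(1, 500), d=st.integers(1, 500), pi=st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_probandwise_exceeds_pairwise(self, c, d, pi):
        counts = TwinPairCounts(c, d)
        assert probandwise_concordance(counts, 1.0 + pi) > pairwise_concordance(counts)
        assert probandwise_concordance(counts, 1.0) == pytest.approx(
            pairwise_concordance(counts)
        )


@pytest.mark.parametrize(
    "c, d, f, expected",
    [
        (9, 31, 1.542, 0.309),
        (11, 42, 1.542, 0.2877),  # registry's own factor places this at 0.287
        (20, 73, 1.542, 0.297),
    ],
)
def test_probandwise_examples(c, d, f, expected):
    assert probandwise_concordance(TwinPairCounts(c, d), f) == pytest.approx(
        expected, abs=5e-4
    )


class TestIUAdjustment:
    def test_sibling_dz_ratio(self, simple_observables):
        factors = iu_adjustment_factor(simple_observables)
        assert factors.iu_ch_factor == pytest.approx(0.029 / 0.054)

    def test_reproduces_all_published_adjusted_rates(self, simple_observables):
        """One pooled factor maps every raw rate onto its published adjusted value."""
        fac = iu_adjustment_factor(simple_observables)
        for raw, printed in [(0.25, 0.134), (0.34, 0.183), (0.067, 0.036), (0.309, 0.166)]:
            assert round_half_up(adjust_concordance(raw, fac), 3) == pytest.approx(
                printed
            )

    def test_pooled_factor_used_even_with_per_gender_rates(self):
        """Per-gender sib/DZ ratios exist but the pooled ratio is the correction."""
        obs = EpidemiologicalObservables(
            prevalence=0.0015,
            mz_raw=0.25,
            dz_raw=0.054,
            sib_raw=0.029,
            per_gender={
                "F": {"dz_raw": 0.051, "sib_raw": 0.039},
                "M": {"dz_raw": 0.057, "sib_raw": 0.019},
            },
        )
        assert iu_adjustment_factor(obs).iu_ch_factor == pytest.approx(0.029 / 0.054)

    def test_no_excess_no_adjustment(self):
        obs = EpidemiologicalObservables(
            prevalence=0.001, mz_raw=0.2, dz_raw=0.04, sib_raw=0.04
        )
        assert iu_adjustment_factor(obs).iu_ch_factor == 1.0

    def test_zero_dz_rejected(self):
        obs = EpidemiologicalObservables(
            prevalence=0.001, mz_raw=0.2, dz_raw=0.0, sib_raw=0.0
        )
        with pytest.raises(ValueError):
            iu_adjustment_factor(obs)

    def test_mode_none_disables(self):
        factors = AdjustmentFactors(iu_ch_factor=0.5, mode="none")
        assert adjust_concordance(0.4, factors) == 0.4

    @given(
        t=st.floats(0.01, 0.9),
        s=st.floats(0.01, 0.9),
        fac=st.floats(0.1, 1.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_order_preservation(self, t, s, fac):
        factors = AdjustmentFactors(iu_ch_factor=fac)
        ta, sa = adjust_concordance(t, factors), adjust_concordance(s, factors)
        assert (t > s) == (ta > sa) or t == s


class TestRenormalization:
    def test_pooled_anchor_reproduces_published_values(self):
        """Carrier subgroup rates rescaled against the pooled adjusted rate."""
        iu = 0.029 / 0.054
        pen = renormalize_subgroups(
            0.309 * iu, 0.287 * iu, b_target=0.134, b_subgroup=0.297 * iu
        )
        assert round_half_up(pen.t, 3) == pytest.approx(0.139)
        assert round_half_up(pen.s, 3) == pytest.approx(0.129)

    def test_identity_when_consistent(self):
        pen = renormalize_subgroups(0.2, 0.1, b_target=0.16, weight_plus=0.6)
        assert pen.t == pytest.approx(0.2)
        assert pen.s == pytest.approx(0.1)

    def test_gender_table_nearly_consistent(self):
        """The gender table's 0.68-weighted mixture sits within rounding of b."""
        mixture = 0.68 * 0.183 + 0.32 * 0.036
        assert mixture == pytest.approx(0.136, abs=5e-4)
        pen = renormalize_subgroups(0.183, 0.036, b_target=0.134, weight_plus=0.68)
        assert 0.134 / mixture == pytest.approx(0.985, abs=1e-3)
        assert pen.t == pytest.approx(0.183 * 0.134 / mixture)

    @given(
        t=st.floats(0.01, 0.5),
        s=st.floats(0.01, 0.5),
        w=st.floats(0.0, 1.0),
        b=st.floats(0.01, 0.5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_mixture_consistency_property(self, t, s, w, b):
        try:
            pen = renormalize_subgroups(t, s, b_target=b, weight_plus=w)
        except ValueError:
            return  # scale pushed a rate outside [0, 1]: rejected, not silently clamped
        assert w * pen.t + (1 - w) * pen.s == pytest.approx(b, abs=1e-12)
        assert (t > s) == (pen.t > pen.s) or t == s

    def test_zero_mixture_rejected(self):
        with pytest.raises(ValueError):
            renormalize_subgroups(0.0, 0.0, b_target=0.1, weight_plus=0.5)


def test_susceptible_only_analogues():
    """b' = b/g and the subgroup analogues divide by the subgroup fractions."""
    from twinrisk.concordance import AdjustedPenetrances, with_susceptible_only

    pen = AdjustedPenetrances(b=0.134, t=0.139, s=0.129)
    filled = with_susceptible_only(pen, g=0.944, g1=0.976, g2=0.908)
    assert filled.b_prime == pytest.approx(0.134 / 0.944)
    assert filled.t_prime == pytest.approx(0.139 / 0.976)
    assert filled.s_prime == pytest.approx(0.129 / 0.908)
    # the carrier partition's susceptible-only ratio sits at ~1: the marker
    # leaves penetrance untouched once susceptibility is conditioned on
    assert filled.s_prime / filled.b_prime == pytest.approx(1.0, abs=0.01)
    with pytest.raises(ValueError):
        with_susceptible_only(pen, g=0.0)


def test_observables_warn_on_ordering_violation():
    with pytest.warns(UserWarning):
        EpidemiologicalObservables(
            prevalence=0.001, mz_raw=0.05, dz_raw=0.1, sib_raw=0.02
        )


def test_round_half_up_ties():
    assert round_half_up(0.1595, 3) == 0.160
    assert round_half_up(0.2875, 3) == 0.288
    assert math.isclose(round_half_up(-0.0445, 3), -0.045)
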