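"""Susceptible-fraction bounds, partition-based g estimation, penetrance ranges."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinrisk.concordance import EpidemiologicalObservables, round_half_up
from twinrisk.partition import PartitionObservables
from twinrisk.susceptibility import (
    SusceptibilityEstimates,
    estimate_g,
    partition_admissible_interval,
    penetrance_range,
    prob_g_lower,
    prob_g_upper,
    purely_genetic_bound,
    region_table,
    sensitivity_sweep,
)


class TestBounds:
    @pytest.mark.parametrize(
        "prevalence, b, expected",
        [
            (0.0015, 0.134, 0.0224),
            (0.00152, 0.1192, 0.0255),
            (0.004, 1.0, 0.008),
        ],
    )
    def test_upper(self, prevalence, b, expected):
        assert prob_g_upper(prevalence, b) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "prevalence, g, z_upper, expected",
        [
            (0.00144, 0.94, 0.1192, 0.0114),
            (0.00052, 0.94, 0.2481, 0.0020),
            (0.01, 0.0, 0.2, 0.0),
        ],
    )
    def test_lower(self, prevalence, g, z_upper, expected):
        assert prob_g_lower(prevalence, g, z_upper) == pytest.approx(expected, abs=5e-5)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            prob_g_upper(0.001, 0.0)
        with pytest.raises(ValueError):
            prob_g_lower(0.001, 0.9, 0.0)

    @given(
        prevalence=st.floats(1e-5, 0.05),
        b=st.floats(0.01, 1.0),
        g=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_bound_ordering(self, prevalence, b, g):
        assert prob_g_lower(prevalence, g, b) <= prob_g_upper(prevalence, b) + 1e-15

    @given(
        p1=st.floats(1e-4, 0.01),
        p2=st.floats(1e-4, 0.01),
        b1=st.floats(0.05, 0.9),
        b2=st.floats(0.05, 0.9),
        g1=st.floats(0.1, 1.0),
        g2=st.floats(0.1, 1.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotonicity(self, p1, p2, b1, b2, g1, g2):
        if p1 <= p2:
            assert prob_g_upper(p1, b1) <= prob_g_upper(p2, b1) + 1e-15
        if b1 <= b2:
            assert prob_g_upper(p1, b1) >= prob_g_upper(p1, b2) - 1e-15
        if g1 <= g2:
            assert prob_g_lower(p1, g1, b1) <= prob_g_lower(p1, g2, b1) + 1e-15


GENDER = PartitionObservables(A=0.68, A0=0.50, t=0.183, s=0.036, b=0.134, label="gender")
CARRIER = PartitionObservables(
    A=0.55, A0=0.24, t=0.139, s=0.129, b=0.134, label="carrier"
)


def _closed_form_lower(p: PartitionObservables) -> float:
    """Independent oracle: the ordering constraint t*g2 >= s*g1 is linear in
    u = 1 - g, so the boundary solves t - s = u*(t*(1-A0)/(1-A) - s*A0/A)."""
    slope = p.t * (1 - p.A0) / (1 - p.A) - p.s * p.A0 / p.A
    u_order = (p.t - p.s) / slope if slope > 0 else math.inf
    u_t = (1 - p.t) * p.A / p.A0 if p.A0 > 0 else math.inf
    u_s = (1 - p.s) * (1 - p.A) / (1 - p.A0)
    return 1.0 - min(u_order, u_t, u_s)


class TestEstimateG:
    def test_published_partitions_give_94_percent(self):
        est = estimate_g([GENDER, CARRIER])
        assert est.g_lower >= 0.94
        assert est.g_lower == pytest.approx(0.944, abs=3e-3)

    def test_carrier_partition_is_the_binding_one(self):
        lo_g, _ = partition_admissible_interval(GENDER)
        lo_c, _ = partition_admissible_interval(CARRIER)
        assert lo_c > lo_g
        assert lo_g == pytest.approx(0.433, abs=2e-3)

    @pytest.mark.parametrize("part", [GENDER, CARRIER], ids=["gender", "carrier"])
    def test_grid_search_matches_closed_form(self, part):
        lo, hi = partition_admissible_interval(part)
        assert hi == 1.0
        assert lo == pytest.approx(_closed_form_lower(part), abs=1e-8)

    def test_uninformative_partition(self):
        """A partition with no case enrichment and equal subgroup rates
        constrains g only through t' <= 1, i.e. essentially not at all."""
        flat = PartitionObservables(A=0.5, A0=0.5, t=0.01, s=0.01, b=0.01, label="flat")
        lo, hi = partition_admissible_interval(flat)
        assert (lo, hi) == pytest.approx((0.01, 1.0), abs=1e-6)
        est = estimate_g([flat])
        assert est.g_lower <= 0.011

    def test_simulated_truth_contained(self):
        """A cohort generated with every case genetic admits g = 1."""
        from twinrisk.simulate import (
            PenetranceDistribution,
            SimulationConfig,
            cohort_partition,
            simulate_cohort,
        )

        cohort = simulate_cohort(
            SimulationConfig(
                n_pairs=100_000,
                p_g=0.05,
                maf=0.2,
                susceptibility_multiplier=4.0,
                ascertainment_pi=1.0,
                penetrance_distribution=PenetranceDistribution.two_point(0.2, 0.6),
                seed=11,
            )
        )
        part = cohort_partition(cohort)
        lo, hi = partition_admissible_interval(part, grid_step=1e-3)
        assert lo <= 1.0 <= hi
        assert cohort.truth["g"] == 1.0

    def test_empty_partition_list_rejected(self):
        with pytest.raises(ValueError):
            estimate_g([])

    def test_estimates_attached_to_observables(self, simple_observables):
        est = estimate_g([GENDER, CARRIER], simple_observables)
        assert est.p_g_upper == pytest.approx(2 * 0.0015 / 0.134)
        assert est.p_g_lower == pytest.approx(est.g_lower * 0.0015 / 0.134)
        assert "admissible_intervals" in est.provenance


class TestPenetranceRange:
    def _estimates(self, g=0.944, prevalence=0.0015, b=0.134):
        return SusceptibilityEstimates(
            p_g_lower=prob_g_lower(prevalence, g, b),
            p_g_upper=prob_g_upper(prevalence, b),
            g=g,
            g_lower=g,
        )

    def test_conservation_identity(self, simple_observables):
        est = self._estimates()
        lo, hi = penetrance_range(simple_observables, est, b=0.134)
        for d in (lo, hi):
            assert d.z * d.p_g == pytest.approx(est.g * 0.0015, abs=1e-12)

    def test_coherence_raises_lower_boundary_to_half_b_prime(self, simple_observables):
        est = self._estimates()
        lo, _ = penetrance_range(simple_observables, est, b=0.134)
        b_prime = 0.134 / est.g
        raw_lower = est.g * 0.0015 / est.p_g_upper
        assert raw_lower < b_prime / 2  # raw bound is the incoherent one
        assert lo.z == pytest.approx(b_prime / 2)
        assert lo.y >= 0.0

    def test_zero_variance_limit(self):
        obs = EpidemiologicalObservables(
            prevalence=0.003, mz_raw=0.3, dz_raw=0.03, sib_raw=0.029
        )
        est = SusceptibilityEstimates(
            p_g_lower=0.01, p_g_upper=0.01, g=1.0, g_lower=1.0
        )
        lo, hi = penetrance_range(obs, est, b=0.3)
        assert hi.z == pytest.approx(0.3)
        assert hi.sigma2 == pytest.approx(0.0, abs=1e-12)
        assert hi.x == pytest.approx(hi.y) == pytest.approx(hi.z)

    def test_two_point_moments(self):
        """sigma2 recovered from b' = E[z^2]/E[z] for the {0.1, 0.5} mixture."""
        z, b_prime = 0.3, (0.5 * 0.01 + 0.5 * 0.25) / 0.3
        assert b_prime == pytest.approx(13 / 30)
        sigma2 = z * (b_prime - z)
        assert sigma2 == pytest.approx(0.04)

    def test_incoherent_inputs_rejected(self, simple_observables):
        est = SusceptibilityEstimates(
            p_g_lower=0.5, p_g_upper=0.6, g=1.0, g_lower=1.0
        )
        with pytest.raises(ValueError):
            penetrance_range(simple_observables, est, b=0.134)


def _brute_force_bound(z, s2, tau, step=0.01, var_tol=2e-3):
    """Exhaustive search over discretized two-point penetrance distributions."""
    best = 0.0
    his = np.arange(math.ceil(tau / step) * step, 1.0 + step / 2, step)
    los = np.arange(0.0, tau, step)
    for hi in his:
        for lo in los[los < hi]:
            p = (z - lo) / (hi - lo)
            if not 0.0 <= p <= 1.0:
                continue
            if abs(p * (1 - p) * (hi - lo) ** 2 - s2) <= var_tol:
                best = max(best, p)
    return best


class TestPurelyGeneticBound:
    def test_all_mass_at_one(self):
        d = _decomp(z=1.0, sigma2=0.0)
        assert purely_genetic_bound(d, 1.0) == 1.0

    def test_small_mean_small_variance_tiny_bound(self):
        d = _decomp(z=0.07, sigma2=0.005)
        assert purely_genetic_bound(d, 0.99) < 0.01

    def test_ms_range_stays_below_a_tenth(self):
        """Across the whole admissible (z, sigma2) range the near-unity mass is tiny."""
        for z in np.linspace(0.071, 0.134, 10):
            d = _decomp(z=z, sigma2=z * (0.142 - z))
            assert purely_genetic_bound(d, 0.9) < 0.1

    def test_decreasing_in_threshold_gap(self):
        d = _decomp(z=0.1, sigma2=0.008)
        assert purely_genetic_bound(d, 0.95) < purely_genetic_bound(d, 0.8)

    def test_matches_brute_force_on_random_moments(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            z = rng.uniform(0.05, 0.5)
            s2 = rng.uniform(0.1, 0.9) * min(z * z, z * (1 - z)) * 0.9
            impl = purely_genetic_bound(_decomp(z, s2), 0.9)
            brute = _brute_force_bound(z, s2, 0.9)
            # the oracle matches variance within +-2e-3, so compare against
            # the bound at the top of that tolerance band
            impl_hi = purely_genetic_bound(_decomp(z, s2 + 2e-3), 0.9)
            assert brute <= impl_hi + 1e-9
            assert impl - brute <= 0.06  # grid resolution of the oracle


def _decomp(z, sigma2):
    from twinrisk.susceptibility import PenetranceDecomposition

    sigma = math.sqrt(max(sigma2, 0.0))
    return PenetranceDecomposition(
        z=z,
        x=min(1.0, z + sigma),
        y=max(0.0, z - sigma),
        p=0.5,
        a=min(1.0, 2 * z),
        a_prime=min(1.0, 2 * z),
        sigma2=sigma2,
        z_max=min(1.0, z + sigma2 / z if z > 0 else 1.0),
        p_g=0.02,
        penetrance_nonsusceptible=0.0,
    )


class TestSensitivitySweep:
    def test_no_overrides_matches_base(self, simple_observables):
        df = sensitivity_sweep(simple_observables, {})
        assert len(df) == 1
        assert df.iloc[0].p_g_upper == pytest.approx(2 * 0.0015 / (0.25 * 0.029 / 0.054))

    def test_doubled_prevalence_scenario(self, simple_observables):
        df = sensitivity_sweep(simple_observables, {"prevalence": [0.003]})
        assert df.iloc[0].p_g_upper == pytest.approx(0.0448, abs=5e-4)

    def test_sibling_scenario(self, simple_observables):
        df = sensitivity_sweep(simple_observables, {"sib_raw": [0.035]})
        assert df.iloc[0].b == pytest.approx(0.162, abs=5e-4)
        assert df.iloc[0].p_g_upper == pytest.approx(0.0185, abs=5e-4)

    def test_grid_is_cartesian(self, simple_observables):
        df = sensitivity_sweep(
            simple_observables,
            {"prevalence": [0.0015, 0.003], "mz_raw": [0.25, 0.35]},
        )
        assert len(df) == 4

    def test_unknown_field_rejected(self, simple_observables):
        with pytest.raises(ValueError, match="cannot sweep"):
            sensitivity_sweep(simple_observables, {"nope": [1.0]})


class TestRegionTable:
    def test_sardinia_row(self):
        df = region_table(
            pd.DataFrame(
                {
                    "region": ["Sardinia"],
                    "prevalence_low": [144],
                    "prevalence_high": [152],
                    "probandwise_mz": [0.222],
                }
            ),
            mode="iu_adjusted",
            g=0.94,
            iu_ch_factor=0.029 / 0.054,
        )
        row = df.iloc[0]
        assert round_half_up(100 * row.susceptible_lower, 1) == pytest.approx(1.1)
        assert round_half_up(100 * row.susceptible_upper, 1) == pytest.approx(2.5)

    def test_lupus_row_unadjusted(self):
        df = region_table(
            pd.DataFrame(
                {
                    "region": ["SLE"],
                    "prevalence_low": [0.00025],
                    "prevalence_high": [0.00025],
                    "probandwise_mz": [0.39],
                }
            ),
            mode="unadjusted",
            prevalence_scale=1.0,
        )
        assert round_half_up(100 * df.iloc[0].susceptible_upper, 2) == pytest.approx(0.13)

    def test_degenerate_prevalence_keeps_bound_order(self):
        df = region_table(
            pd.DataFrame(
                {
                    "region": ["X"],
                    "prevalence_low": [100],
                    "prevalence_high": [100],
                    "probandwise_mz": [0.3],
                }
            ),
            mode="iu_adjusted",
            g=0.94,
            iu_ch_factor=0.54,
        )
        assert df.iloc[0].susceptible_lower <= df.iloc[0].susceptible_upper

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            region_table(pd.DataFrame({"region": ["X"]}), mode="unadjusted")
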