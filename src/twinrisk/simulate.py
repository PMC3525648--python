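"""Forward simulation of twin cohorts with known susceptibility structure.

The generator draws a population in which a fraction ``p_g`` of genotypes is
susceptible, each susceptible genotype carries its own penetrance ``z_i``
drawn from a configurable distribution, and an optional diallelic marker
(allele frequency ``maf``) is tied to susceptibility through one of two
mechanisms:

* ``susceptibility_multiplier`` — carriers are more likely to be susceptible
  (allele-frequency mechanism); penetrance is untouched.
* ``penetrance_multiplier`` — susceptible carriers have their penetrance
  multiplied (penetrance mechanism); susceptibility prevalence is untouched.

MZ co-twins share the genotype exactly.  DZ co-twins and siblings share the
*susceptibility status* of the index twin with probability
``sib_share_susceptibility`` (their penetrance class is their own draw) —
the estimators consume concordance rates only, so a single sharing
probability stands in for explicit multilocus genetics.  Co-gestated pairs
(MZ and DZ, not sibling pairs) get the co-twin's penetrance multiplied by
``iu_effect`` when the index twin is affected, emulating the shared
intra-uterine environment excess that the sibling/DZ ratio is designed to
remove.  Concordant pairs are doubly ascertained with probability
``ascertainment_pi``.

Every cohort carries an immutable record of the generating truth
(``p_g``, ``g``, ``z``, ``sigma2``, the size-biased penetrance
``b' = E[z**2]/E[z]``) so estimator output can be asserted against it.
Draws consume one stream per zygosity block in a fixed order (carrier,
susceptibility, penetrance, disease, ascertainment), so identical seeds
yield identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .concordance import TwinPairCounts
from .partition import PartitionObservables
from .susceptibility import (
    SusceptibilityEstimates,
    estimate_g,
    prob_g_lower,
    prob_g_upper,
)

__all__ = [
    "PenetranceDistribution",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "recover_parameters",
]

ZYGOSITIES = ("MZ", "DZ", "sibling")


@dataclass(frozen=True)
class PenetranceDistribution:
    """Distribution of genotype penetrances within the susceptible set.

    ``point(z0)`` — every susceptible genotype has penetrance ``z0``;
    ``two_point(lo, hi, w_hi)`` — mass ``w_hi`` at ``hi``, rest at ``lo``;
    ``beta(a, b)`` — Beta(a, b) on [0, 1].
    """

    kind: Literal["point", "two_point", "beta"]
    params: tuple[float, ...]

    @classmethod
    def point(cls, z0: float) -> "PenetranceDistribution":
        return cls("point", (z0,))

    @classmethod
    def two_point(cls, lo: float, hi: float, w_hi: float = 0.5) -> "PenetranceDistribution":
        return cls("two_point", (lo, hi, w_hi))

    @classmethod
    def beta(cls, a: float, b: float) -> "PenetranceDistribution":
        return cls("beta", (a, b))

    def __post_init__(self) -> None:
        if self.kind == "point":
            (z0,) = self.params
            if not 0.0 <= z0 <= 1.0:
                raise ValueError("point penetrance must lie in [0, 1]")
        elif self.kind == "two_point":
            lo, hi, w = self.params
            if not (0.0 <= lo <= hi <= 1.0 and 0.0 <= w <= 1.0):
                raise ValueError("two-point support must lie in [0, 1] with weight in [0, 1]")
        elif self.kind == "beta":
            a, b = self.params
            if a <= 0 or b <= 0:
                raise ValueError("beta shape parameters must be positive")
        else:
            raise ValueError(f"unknown penetrance distribution {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, self.params[0])
        if self.kind == "two_point":
            lo, hi, w = self.params
            return np.where(rng.random(size) < w, hi, lo)
        a, b = self.params
        return rng.beta(a, b, size)

    def mean(self) -> float:
        if self.kind == "point":
            return self.params[0]
        if self.kind == "two_point":
            lo, hi, w = self.params
            return w * hi + (1 - w) * lo
        a, b = self.params
        return a / (a + b)

    def second_moment(self) -> float:
        if self.kind == "point":
            return self.params[0] ** 2
        if self.kind == "two_point":
            lo, hi, w = self.params
            return w * hi**2 + (1 - w) * lo**2
        a, b = self.params
        return a * (a + 1) / ((a + b) * (a + b + 1))

    def variance(self) -> float:
        return self.second_moment() - self.mean() ** 2

    def size_biased_mean(self) -> float:
        """E[z**2]/E[z]: the expected proband-wise concordance among genetic probands."""
        m = self.mean()
        return self.second_moment() / m if m > 0 else 0.0


@dataclass(frozen=True)
class SimulationConfig:
    n_pairs: int = 5000
    p_g: float = 0.02
    penetrance_distribution: PenetranceDistribution = field(
        default_factory=lambda: PenetranceDistribution.two_point(0.1, 0.5)
    )
    penetrance_nonsusceptible: float = 0.0
    maf: float = 0.0
    susceptibility_multiplier: float | None = None
    penetrance_multiplier: float | None = None
    sib_share_susceptibility: float = 0.5
    iu_effect: float = 1.0
    ascertainment_pi: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("need at least one twin pair")
        for name in ("p_g", "penetrance_nonsusceptible", "maf",
                     "sib_share_susceptibility", "ascertainment_pi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.iu_effect < 0.0:
            raise ValueError("iu_effect must be non-negative")
        if self.susceptibility_multiplier is not None and self.penetrance_multiplier is not None:
            raise ValueError(
                "choose one carrier mechanism: susceptibility_multiplier or "
                "penetrance_multiplier"
            )

    @property
    def carrier_freq(self) -> float:
        return 1.0 - (1.0 - self.maf) ** 2

    def susceptibility_by_carrier(self) -> tuple[float, float]:
        """P(G|carrier), P(G|non-carrier) with the marginal fixed at p_g."""
        c0 = self.carrier_freq
        m = self.susceptibility_multiplier
        if m is None or c0 == 0.0:
            return self.p_g, self.p_g
        norm = c0 * m + (1.0 - c0)
        return min(1.0, self.p_g * m / norm), min(1.0, self.p_g / norm)

    def truth(self) -> dict[str, float]:
        dist = self.penetrance_distribution
        z = dist.mean()
        z_neg = self.penetrance_nonsusceptible
        p_case = self.p_g * z + (1.0 - self.p_g) * z_neg
        g = self.p_g * z / p_case if p_case > 0 else 1.0
        return {
            "p_g": self.p_g,
            "g": g,
            "z": z,
            "sigma2": dist.variance(),
            "b_prime": dist.size_biased_mean(),
            "prevalence": p_case,
        }


@dataclass(frozen=True)
class SimulatedCohort:
    config: SimulationConfig
    counts: dict[str, TwinPairCounts]
    observed_probandwise: dict[str, float]
    subgroup_counts: dict[tuple[str, str], TwinPairCounts]
    subgroup_probandwise: dict[tuple[str, str], float]
    prevalence_estimate: float
    case_carrier_fraction: float | None
    population_carrier_fraction: float | None
    truth: dict[str, float]

    def to_table(self) -> pd.DataFrame:
        """Twin tables in the concordance-module ingest schema."""
        rows = [
            {
                "zygosity": z,
                "subgroup": "all",
                "concordant": c.concordant,
                "discordant": c.discordant,
            }
            for z, c in self.counts.items()
        ]
        rows += [
            {
                "zygosity": z,
                "subgroup": sub,
                "concordant": c.concordant,
                "discordant": c.discordant,
            }
            for (z, sub), c in self.subgroup_counts.items()
        ]
        return pd.DataFrame(rows, columns=["zygosity", "subgroup", "concordant", "discordant"])


def _apply_mechanism2(cfg: SimulationConfig, z: np.ndarray, carrier: np.ndarray,
                      susceptible: np.ndarray) -> np.ndarray:
    if cfg.penetrance_multiplier is None:
        return z
    boosted = np.minimum(1.0, z * cfg.penetrance_multiplier)
    return np.where(carrier & susceptible, boosted, z)


def _simulate_block(
    cfg: SimulationConfig, rng: np.random.Generator, zygosity: str
) -> dict:
    n = cfg.n_pairs
    c0 = cfg.carrier_freq
    pg_c, pg_n = cfg.susceptibility_by_carrier()
    dist = cfg.penetrance_distribution

    carrier1 = rng.random(n) < c0
    susc1 = rng.random(n) < np.where(carrier1, pg_c, pg_n)
    z1 = np.where(susc1, dist.sample(rng, n), cfg.penetrance_nonsusceptible)

    if zygosity == "MZ":
        carrier2, susc2, z2 = carrier1, susc1, z1
    else:
        carrier2 = rng.random(n) < c0
        shared = rng.random(n) < cfg.sib_share_susceptibility
        own = rng.random(n) < np.where(carrier2, pg_c, pg_n)
        susc2 = np.where(shared, susc1, own)
        z2 = np.where(susc2, dist.sample(rng, n), cfg.penetrance_nonsusceptible)

    z1 = _apply_mechanism2(cfg, z1, carrier1, susc1)
    z2 = _apply_mechanism2(cfg, z2, carrier2, susc2)

    iu = cfg.iu_effect if zygosity in ("MZ", "DZ") else 1.0
    d1 = rng.random(n) < z1
    z2_eff = np.where(d1, np.minimum(1.0, z2 * iu), z2)
    d2 = rng.random(n) < z2_eff

    concordant = d1 & d2
    discordant = d1 ^ d2
    doubly = concordant & (rng.random(n) < cfg.ascertainment_pi)

    def tally(mask: np.ndarray) -> tuple[TwinPairCounts, float]:
        c = int((concordant & mask).sum())
        d = int((discordant & mask).sum())
        probands_c = c + int((doubly & mask).sum())
        rate = probands_c / (probands_c + d) if probands_c + d > 0 else float("nan")
        return TwinPairCounts(c, d, zygosity=zygosity), rate  # type: ignore[arg-type]

    every = np.ones(n, dtype=bool)
    counts, rate = tally(every)
    out = {
        "counts": counts,
        "rate": rate,
        "affected": int(d1.sum() + d2.sum()),
        "individuals": 2 * n,
        "case_carriers": int((d1 & carrier1).sum() + (d2 & carrier2).sum()),
        "carriers": int(carrier1.sum() + carrier2.sum()),
        "subgroups": {},
    }
    if cfg.maf > 0 and zygosity == "MZ":
        for label, mask in (("carrier", carrier1), ("non-carrier", ~carrier1)):
            sub_counts, sub_rate = tally(mask)
            out["subgroups"][label] = (
                TwinPairCounts(
                    sub_counts.concordant,
                    sub_counts.discordant,
                    zygosity="MZ",
                    subgroup=label,
                ),
                sub_rate,
            )
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one twin cohort (MZ, DZ and sibling blocks) under the config."""
    rng = np.random.default_rng(config.seed)
    counts: dict[str, TwinPairCounts] = {}
    rates: dict[str, float] = {}
    sub_counts: dict[tuple[str, str], TwinPairCounts] = {}
    sub_rates: dict[tuple[str, str], float] = {}
    affected = individuals = case_carriers = carriers = 0
    for zyg in ZYGOSITIES:
        block = _simulate_block(config, rng, zyg)
        counts[zyg] = block["counts"]
        rates[zyg] = block["rate"]
        affected += block["affected"]
        individuals += block["individuals"]
        case_carriers += block["case_carriers"]
        carriers += block["carriers"]
        for label, (tc, tr) in block["subgroups"].items():
            sub_counts[(zyg, label)] = tc
            sub_rates[(zyg, label)] = tr
    return SimulatedCohort(
        config=config,
        counts=counts,
        observed_probandwise=rates,
        subgroup_counts=sub_counts,
        subgroup_probandwise=sub_rates,
        prevalence_estimate=affected / individuals,
        case_carrier_fraction=case_carriers / affected if config.maf > 0 and affected else None,
        population_carrier_fraction=carriers / individuals if config.maf > 0 else None,
        truth=config.truth(),
    )


def cohort_partition(cohort: SimulatedCohort) -> PartitionObservables | None:
    """Carrier-status partition observables recovered from a simulated cohort."""
    key_c, key_n = ("MZ", "carrier"), ("MZ", "non-carrier")
    if key_c not in cohort.subgroup_probandwise:
        return None
    factor = _iu_factor(cohort)
    t_raw = cohort.subgroup_probandwise[key_c]
    s_raw = cohort.subgroup_probandwise[key_n]
    pooled_raw = cohort.observed_probandwise["MZ"]
    if not (np.isfinite(t_raw) and np.isfinite(s_raw) and np.isfinite(pooled_raw)):
        return None
    b = pooled_raw * factor
    if b <= 0:
        return None
    # pooled anchoring: subgroup rates share the IU factor, so the pooled
    # adjusted rate is b and no further rescaling is needed
    return PartitionObservables(
        A=cohort.case_carrier_fraction or 0.0,
        A0=cohort.population_carrier_fraction or 0.0,
        t=min(1.0, t_raw * factor),
        s=min(1.0, s_raw * factor),
        b=b,
        label="simulated carrier partition",
    )


def _iu_factor(cohort: SimulatedCohort) -> float:
    dz = cohort.observed_probandwise["DZ"]
    sib = cohort.observed_probandwise["sibling"]
    if not (np.isfinite(dz) and np.isfinite(sib)) or dz <= 0:
        return 1.0
    return min(1.0, sib / dz)


def recover_parameters(
    cohort: SimulatedCohort,
    g: float | None = None,
    apply_iu_correction: bool = True,
) -> SusceptibilityEstimates:
    """Run the concordance -> susceptibility chain on simulated observables.

    The adjusted concordance is the observed MZ proband-wise rate times the
    simulated sibling/DZ ratio (the same correction the real pipeline
    applies).  ``g`` defaults to the carrier-partition estimate when the
    cohort was simulated with a marker, and to 1 otherwise.
    """
    mz = cohort.observed_probandwise["MZ"]
    if not np.isfinite(mz) or mz <= 0:
        raise ValueError("cohort has no affected MZ pairs; cannot recover parameters")
    factor = _iu_factor(cohort) if apply_iu_correction else 1.0
    b = mz * factor
    prev = cohort.prevalence_estimate
    provenance: dict = {"b": b, "iu_ch_factor": factor, "prevalence": prev}
    if g is None:
        part = cohort_partition(cohort)
        if part is not None:
            try:
                est = estimate_g([part], grid_step=1e-3)
                g = est.g_lower
                provenance["g_source"] = "carrier partition"
            except ValueError:
                g = 1.0
                provenance["g_source"] = "partition infeasible; defaulted to 1"
        else:
            g = 1.0
            provenance["g_source"] = "no partition; defaulted to 1"
    upper = prob_g_upper(prev, b)
    lower = min(prob_g_lower(prev, g, b), upper)
    return SusceptibilityEstimates(
        p_g_lower=lower,
        p_g_upper=upper,
        g=g,
        g_lower=g,
        provenance={**provenance, "truth": cohort.truth},
    )
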