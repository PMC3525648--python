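"""Twin-pair concordance rates and their ascertainment / environment adjustments.

Raw twin registries report pairs in which both members are affected
(concordant, ``C``) or exactly one is (discordant, ``D``).  Three layers of
processing turn these tallies into the genotype-sharing penetrance ``b``
used by the susceptibility model:

1. *Proband-wise conversion.*  Concordant pairs can enter a registry twice
   (once per proband).  If a fraction ``pi`` of concordant pairs was doubly
   ascertained, each concordant pair contributes ``f = 1 + pi`` probands and
   the proband-wise concordance is ``f*C / (f*C + D)``.  Registries usually
   print the proband-wise rate but not ``pi``, so ``calibrate_ascertainment``
   solves for ``f`` from the printed rate.
2. *Shared-gestation (IU/CH) correction.*  MZ co-twins share an intra-uterine
   environment in addition to their genotype.  The excess of the DZ-twin
   concordance over the sibling concordance measures that shared-environment
   effect (DZ twins and siblings share genes to the same degree but only DZ
   twins share a gestation), so multiplying an MZ rate by
   ``sib_raw / dz_raw`` strips it, leaving the pure genotype-sharing effect.
3. *Subgroup renormalization.*  When a twin table is split by a marker
   (carrier status, gender), the subgroup-adjusted rates ``t`` and ``s`` are
   rescaled so that their combination reproduces the whole-cohort ``b``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "TwinPairCounts",
    "EpidemiologicalObservables",
    "AdjustmentFactors",
    "AdjustedPenetrances",
    "pairwise_concordance",
    "calibrate_ascertainment",
    "probandwise_concordance",
    "iu_adjustment_factor",
    "adjust_concordance",
    "renormalize_subgroups",
    "with_susceptible_only",
]

Zygosity = Literal["MZ", "DZ", "sibling"]


class CalibrationError(ValueError):
    """No ascertainment inflation factor in [1, 2] matches the observed rate."""


@dataclass(frozen=True)
class TwinPairCounts:
    """Concordant/discordant pair tallies for one zygosity (and optional subgroup).

    Parameters
    ----------
    concordant
        Number of doubly-affected pairs (``C``).
    discordant
        Number of singly-affected pairs (``D``).
    zygosity
        ``"MZ"``, ``"DZ"`` or ``"sibling"``.
    subgroup
        Optional categorical tag of the proband (e.g. ``"carrier"``, ``"F"``).
    """

    concordant: int
    discordant: int
    zygosity: Zygosity = "MZ"
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.concordant < 0 or self.discordant < 0:
            raise ValueError("pair counts must be non-negative")

    @property
    def total(self) -> int:
        return self.concordant + self.discordant


@dataclass(frozen=True)
class EpidemiologicalObservables:
    """Directly observable inputs of the model (all probabilities in [0, 1]).

    ``carrier_fraction_cases`` is the marker frequency among cases
    (``A = P(Gx+|MS)``) and ``carrier_fraction_population`` the population
    frequency (``A0 = P(Gx+)``).
    """

    prevalence: float
    mz_raw: float
    dz_raw: float
    sib_raw: float
    female_fraction_cases: float | None = None
    carrier_fraction_cases: float | None = None
    carrier_fraction_population: float | None = None
    per_gender: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("prevalence", "mz_raw", "dz_raw", "sib_raw"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "female_fraction_cases",
            "carrier_fraction_cases",
            "carrier_fraction_population",
        ):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.mz_raw >= self.dz_raw >= self.sib_raw:
            warnings.warn(
                "expected mz_raw >= dz_raw >= sib_raw; proceeding anyway",
                stacklevel=3,
            )


@dataclass(frozen=True)
class AdjustmentFactors:
    """Multiplicative corrections applied to raw concordance rates.

    ``ascertainment_inflation`` is ``f = 1 + pi`` where ``pi`` is the
    probability that a concordant pair was ascertained twice.
    ``iu_ch_factor`` is the shared intra-uterine/childhood environment
    correction (``sib_raw / dz_raw`` by default); ``mode="none"`` disables it
    (used e.g. for diseases where gestational sharing is assumed inert).
    """

    ascertainment_inflation: float = 1.0
    iu_ch_factor: float = 1.0
    mode: Literal["apply_iu_adjustment", "none"] = "apply_iu_adjustment"

    def __post_init__(self) -> None:
        if not 1.0 <= self.ascertainment_inflation <= 2.0:
            raise ValueError("ascertainment_inflation must lie in [1, 2]")
        if not 0.0 < self.iu_ch_factor <= 1.0:
            raise ValueError("iu_ch_factor must lie in (0, 1]")

    @property
    def effective_iu_factor(self) -> float:
        return self.iu_ch_factor if self.mode == "apply_iu_adjustment" else 1.0


@dataclass(frozen=True)
class AdjustedPenetrances:
    """Adjusted concordance rates: whole-cohort ``b`` and subgroup ``t``, ``s``.

    ``*_prime`` values are the susceptible-only analogues (``b' = b/g`` etc.)
    and are populated once the susceptible-case fraction ``g`` is known.
    """

    b: float
    t: float | None = None
    s: float | None = None
    b_prime: float | None = None
    t_prime: float | None = None
    s_prime: float | None = None

    def __post_init__(self) -> None:
        for name in ("b", "t", "s", "b_prime", "t_prime", "s_prime"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def pairwise_concordance(counts: TwinPairCounts) -> float:
    """Fraction of ascertained pairs in which both twins are affected: C/(C+D)."""
    if counts.total < 1:
        raise ValueError("need at least one twin pair to compute a rate")
    return counts.concordant / counts.total


def calibrate_ascertainment(
    counts: TwinPairCounts, observed_probandwise: float
) -> AdjustmentFactors:
    """Solve ``f*C / (f*C + D) = observed_probandwise`` for the inflation ``f``.

    ``f = 1 + pi`` where ``pi`` is the double-ascertainment probability of
    concordant pairs; a registry that counted every concordant pair once has
    ``f = 1`` and one that counted every such pair twice has ``f = 2``.
    """
    if not 0.0 < observed_probandwise < 1.0:
        raise ValueError("observed proband-wise rate must lie strictly in (0, 1)")
    if counts.concordant == 0:
        raise CalibrationError(
            "cannot calibrate with zero concordant pairs: the proband-wise "
            "rate is 0 for every inflation factor"
        )
    r = observed_probandwise
    f = r * counts.discordant / (counts.concordant * (1.0 - r))
    if not 1.0 - 1e-12 <= f <= 2.0 + 1e-12:
        raise CalibrationError(
            f"inflation factor {f:.4f} outside [1, 2]: the observed rate "
            f"{r} is inconsistent with counts C={counts.concordant}, "
            f"D={counts.discordant} under double ascertainment"
        )
    return AdjustmentFactors(ascertainment_inflation=min(2.0, max(1.0, f)))


def probandwise_concordance(
    counts: TwinPairCounts, factors: AdjustmentFactors | float
) -> float:
    """Proband-wise concordance ``f*C / (f*C + D)``.

    Concordant pairs contribute ``f`` probands each (``1 <= f <= 2``); at
    ``f = 1`` this reduces to the pairwise rate.
    """
    if counts.total < 1:
        raise ValueError("need at least one twin pair to compute a rate")
    f = (
        factors.ascertainment_inflation
        if isinstance(factors, AdjustmentFactors)
        else float(factors)
    )
    fc = f * counts.concordant
    return fc / (fc + counts.discordant)


def iu_adjustment_factor(obs: EpidemiologicalObservables) -> AdjustmentFactors:
    """Shared intra-uterine environment correction ``sib_raw / dz_raw``.

    DZ twins and siblings share genes to the same extent; the DZ excess over
    siblings is attributed to co-gestation, so the ratio is the multiplicative
    factor that removes it from an MZ rate.  The pooled (not per-gender)
    sibling and DZ rates are used: the same factor is applied uniformly to
    every subgroup, which is what reproduces the published adjusted rates.
    """
    if obs.dz_raw <= 0.0:
        raise ValueError("dz_raw must be positive to form the sibling/DZ ratio")
    factor = obs.sib_raw / obs.dz_raw
    if factor > 1.0:
        warnings.warn(
            "sibling concordance exceeds DZ concordance; no gestational excess "
            "to remove, clamping factor to 1",
            stacklevel=2,
        )
        factor = 1.0
    return AdjustmentFactors(iu_ch_factor=factor)


def adjust_concordance(
    raw_probandwise: float, factors: AdjustmentFactors
) -> float:
    """Apply the IU/CH correction to a proband-wise rate (no-op in mode='none')."""
    if not 0.0 <= raw_probandwise <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    return raw_probandwise * factors.effective_iu_factor


def renormalize_subgroups(
    t: float,
    s: float,
    *,
    b_target: float,
    weight_plus: float | None = None,
    b_subgroup: float | None = None,
) -> AdjustedPenetrances:
    """Jointly rescale subgroup rates so their combination equals ``b_target``.

    The common scale factor is ``b_target / b_subgroup`` where ``b_subgroup``
    is the subgroup-table's own estimate of the whole-cohort adjusted rate:
    either supplied explicitly (e.g. the adjusted pooled proband-wise rate of
    the same table, which is how the published subgroup tables are anchored)
    or formed as the case-weighted mixture ``w*t + (1-w)*s``.  Rescaling both
    subgroups by one factor preserves their ratio, so subgroup ordering and
    the mechanism diagnostics are unaffected.
    """
    if b_subgroup is None:
        if weight_plus is None:
            raise ValueError("provide either weight_plus or b_subgroup")
        if not 0.0 <= weight_plus <= 1.0:
            raise ValueError("weight_plus must be in [0, 1]")
        b_subgroup = weight_plus * t + (1.0 - weight_plus) * s
    if b_subgroup <= 0.0:
        raise ValueError("subgroup mixture rate is zero; cannot renormalize")
    scale = b_target / b_subgroup
    t_new, s_new = t * scale, s * scale
    if not (0.0 <= t_new <= 1.0 and 0.0 <= s_new <= 1.0):
        raise ValueError(
            f"renormalization pushes a rate outside [0, 1] (scale={scale:.4f})"
        )
    return AdjustedPenetrances(b=b_target, t=t_new, s=s_new)


def with_susceptible_only(
    pen: AdjustedPenetrances, g: float, g1: float | None = None, g2: float | None = None
) -> AdjustedPenetrances:
    """Fill in the susceptible-only analogues ``b' = b/g``, ``t' = t/g1``, ``s' = s/g2``."""
    if not 0.0 < g <= 1.0:
        raise ValueError("g must lie in (0, 1]")

    def _div(x: float | None, d: float | None) -> float | None:
        if x is None or d is None or d <= 0.0:
            return None
        return min(1.0, x / d)

    return replace(
        pen,
        b_prime=_div(pen.b, g),
        t_prime=_div(pen.t, g1),
        s_prime=_div(pen.s, g2),
    )


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching how the printed tables round.

    A 1e-9 nudge absorbs floating-point representations sitting a hair below
    an exact tie (e.g. 0.1375 stored as 0.13749999...).
    """
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5 + 1e-9) / scale * (1 if x >= 0 else -1)
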