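"""Two-way genetic partitions of cases and population.

A *partition* splits the population by a dichotomous genetic characteristic
``Gx`` — carrying at least one copy of a risk allele, or gender — and asks how
the ``Gx+`` subgroup is enriched among cases.  Two mechanisms can produce
enrichment:

* **Mechanism 1 (allele frequency):** carriers are more likely to be
  genetically susceptible at all, but susceptible carriers are no more
  penetrant than susceptible non-carriers.
* **Mechanism 2 (penetrance):** susceptible carriers are more likely to
  develop disease than susceptible non-carriers.

The ratio of the non-carrier subgroup rate to the whole-cohort rate
(``s/b``, standing in for the susceptible-only ``s'/b'`` when nearly all
cases are genetic) discriminates the two: a ratio near 1 means carrier
status leaves penetrance untouched (Mechanism 1 only).

The module also handles genotype-dose structure at a diallelic locus:
Hardy-Weinberg expectations, per-dose odds ratios, and the geometric /
dominant / recessive classification of the dose-response in selection
weights (1, w, w**2) vs (1, w, w) vs (1, 1, w).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "PartitionObservables",
    "PartitionAnalysis",
    "GenotypeFrequencyTable",
    "SelectionWeights",
    "enrichment_mechanism",
    "hwe_expected",
    "genotype_odds_ratios",
    "geometric_selection_test",
    "carrier_susceptibility",
    "allele_contribution_fraction",
    "max_susceptible_carriers",
    "continued_enrichment_check",
]

Mechanism = Literal["allele_frequency_only", "penetrance_only", "both"]


@dataclass(frozen=True)
class PartitionObservables:
    """Observable inputs of one partition.

    ``A0 = P(Gx+)`` in the population, ``A = P(Gx+|cases)``, and the adjusted
    subgroup concordances ``t`` (Gx+ probands) and ``s`` (Gx- probands),
    renormalized to the whole-cohort ``b``.
    """

    A: float
    A0: float
    t: float
    s: float
    b: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("A", "A0", "t", "s", "b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class PartitionAnalysis:
    """Derived quantities of one partition at a given susceptible-case fraction g."""

    observables: PartitionObservables
    g: float
    g1: float            # P(G | Gx+, cases)
    g2: float            # P(G | Gx-, cases)
    t_prime: float       # P(disease | G, Gx+, co-twin of case)
    s_prime: float
    b_prime: float
    B: float             # g1 / g2, the partition's susceptibility imbalance
    mechanism: Mechanism
    mechanism_ratio: float
    admissible_g: tuple[float, float] | None = None


@dataclass(frozen=True)
class GenotypeFrequencyTable:
    """Genotype-dose frequencies (2 copies, 1 copy, 0 copies) for one cohort."""

    freq_2copy: float
    freq_1copy: float
    freq_0copy: float
    source_label: str = ""

    def __post_init__(self) -> None:
        for v in (self.freq_2copy, self.freq_1copy, self.freq_0copy):
            if v < 0.0:
                raise ValueError("genotype frequencies must be non-negative")
        total = self.freq_2copy + self.freq_1copy + self.freq_0copy
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies must sum to 1, got {total}")

    @property
    def carrier_freq(self) -> float:
        return self.freq_2copy + self.freq_1copy


@dataclass(frozen=True)
class SelectionWeights:
    """Normalized per-dose selection pressures and their dose-independence test."""

    w: float
    w2: float
    geometric_deviation: float
    classification: Literal["geometric", "dominant", "recessive"]
    deviations: dict[str, float] = field(default_factory=dict)


def enrichment_mechanism(
    s_adj: float, b_adj: float, tolerance: float = 0.10
) -> tuple[float, Mechanism]:
    """Classify the enrichment mechanism from the ratio ``s/b``.

    Returns ``(ratio, label)``.  A ratio within ``tolerance`` of 1 means the
    non-carrier subgroup is as penetrant as the cohort overall, so the case
    enrichment of carriers can only come from a higher prevalence of
    susceptibility among them (Mechanism 1).  A ratio below ``1 - tolerance``
    means susceptible carriers are the more penetrant group and both
    mechanisms operate; a ratio above ``1 + tolerance`` flags a pure
    penetrance effect in the opposite direction.
    """
    if b_adj <= 0.0:
        raise ValueError("b must be positive")
    ratio = s_adj / b_adj
    if abs(ratio - 1.0) <= tolerance:
        label: Mechanism = "allele_frequency_only"
    elif ratio < 1.0:
        label = "both"
    else:
        label = "penetrance_only"
    return ratio, label


def hwe_expected(
    anchor_value: float,
    anchor: Literal["two_copy_freq", "carrier_freq", "zero_copy_freq"] = "two_copy_freq",
    source_label: str = "HWE",
) -> GenotypeFrequencyTable:
    """Hardy-Weinberg genotype frequencies anchored on one observed frequency.

    The allele frequency ``q`` is recovered from the anchor
    (``q = sqrt(freq2)``, ``1 - q = sqrt(freq0)`` or
    ``1 - (1-q)**2 = carrier_freq``) and the full triple
    ``(q**2, 2q(1-q), (1-q)**2)`` is returned.  Anchors of 0 or 1 yield the
    degenerate fixed triples (0, 0, 1) / (1, 0, 0).
    """
    if not 0.0 <= anchor_value <= 1.0:
        raise ValueError("anchor frequency must lie in [0, 1]")
    if anchor == "two_copy_freq":
        q = math.sqrt(anchor_value)
    elif anchor == "zero_copy_freq":
        q = 1.0 - math.sqrt(anchor_value)
    elif anchor == "carrier_freq":
        q = 1.0 - math.sqrt(1.0 - anchor_value)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return GenotypeFrequencyTable(
        freq_2copy=q * q,
        freq_1copy=2.0 * q * (1.0 - q),
        freq_0copy=(1.0 - q) ** 2,
        source_label=source_label,
    )


def genotype_odds_ratios(
    cases: GenotypeFrequencyTable, controls: GenotypeFrequencyTable
) -> dict[str, float]:
    """Per-genotype odds ratios against the zero-copy reference class.

    ``or_kcopy = (case_k / case_0) / (control_k / control_0)``; ``or_carrier``
    pools the one- and two-copy classes.
    """
    if cases.freq_0copy <= 0.0 or controls.freq_0copy <= 0.0:
        raise ValueError("zero-copy reference frequency must be positive in both cohorts")
    ctrl_ref = controls.freq_0copy

    def _or(case_f: float, ctrl_f: float) -> float:
        return (case_f / cases.freq_0copy) / (ctrl_f / ctrl_ref)

    return {
        "or_2copy": _or(cases.freq_2copy, controls.freq_2copy)
        if controls.freq_2copy > 0
        else math.inf,
        "or_1copy": _or(cases.freq_1copy, controls.freq_1copy)
        if controls.freq_1copy > 0
        else math.inf,
        "or_carrier": _or(cases.carrier_freq, controls.carrier_freq)
        if controls.carrier_freq > 0
        else math.inf,
    }


def geometric_selection_test(
    or_1copy: float, or_2copy: float, tolerance: float = 0.25
) -> SelectionWeights:
    """Test whether two risk alleles act independently (weights 1, w, w**2).

    Under independent selection the two-copy odds ratio should equal the
    square of the one-copy odds ratio.  The observed pair is scored against
    the geometric (1, w, w**2), dominant (1, w, w) and recessive (1, 1, w)
    weighting schemes by relative deviation; the minimum wins, with ties
    broken toward geometric.
    """
    if or_1copy <= 0.0 or or_2copy <= 0.0:
        raise ValueError("odds ratios must be positive")
    deviations = {
        "geometric": abs(or_2copy - or_1copy**2) / or_1copy**2,
        "dominant": abs(or_2copy - or_1copy) / or_1copy,
        "recessive": abs(or_1copy - 1.0),
    }
    best = min(deviations, key=lambda k: (deviations[k], k != "geometric"))
    geo_dev = deviations["geometric"]
    if best != "geometric" and math.isclose(
        deviations[best], geo_dev, rel_tol=1e-9, abs_tol=1e-12
    ):
        warnings.warn(
            "selection-weight schemes tie; classifying as geometric", stacklevel=2
        )
        best = "geometric"
    if best == "geometric" and geo_dev > tolerance:
        warnings.warn(
            f"geometric scheme fits best but deviation {geo_dev:.2f} exceeds "
            f"tolerance {tolerance}",
            stacklevel=2,
        )
    return SelectionWeights(
        w=or_1copy,
        w2=or_2copy,
        geometric_deviation=geo_dev,
        classification=best,  # type: ignore[arg-type]
        deviations=deviations,
    )


def carrier_susceptibility(A: float, A0: float, p_g: float) -> float:
    """Fraction of carriers who are genetically susceptible, ``P(G|Gx+) = A*P(G)/A0``.

    Valid for a Mechanism-1 partition, where the carrier frequency among
    susceptibles equals the carrier frequency among cases (``A``), so Bayes
    gives ``P(G|Gx+) = P(Gx+|G) P(G) / P(Gx+) = A * p_g / A0``.
    """
    if A0 <= 0.0:
        raise ValueError("population carrier frequency must be positive")
    return A * p_g / A0


def allele_contribution_fraction(A: float, A0: float) -> float:
    """Fraction of susceptible cases whose susceptibility depends on the allele.

    Splits susceptible cases into a fraction ``x`` that requires the allele
    (all carriers) and a remainder carrying it at the population frequency:
    ``x + (1-x)*A0 = A`` gives ``x = (A - A0) / (1 - A0)``.
    """
    if A0 >= 1.0:
        raise ValueError("population carrier frequency must be below 1")
    if A < A0:
        warnings.warn(
            "cases are depleted of the allele (A < A0); protective direction "
            "is outside the model, returning 0",
            stacklevel=2,
        )
        return 0.0
    return (A - A0) / (1.0 - A0)


def max_susceptible_carriers(
    p_g_upper: float, maf: float, mode: Literal["carrier", "homozygote"] = "carrier"
) -> float:
    """Ceiling on the susceptible fraction of risk-allele carriers.

    Even if every susceptible person carried the allele, at most
    ``P(G)_upper / P(carrier)`` of carriers could be susceptible; in
    ``homozygote`` mode the denominator is the homozygote frequency
    ``maf**2`` instead of the carrier frequency ``1 - (1-maf)**2``.
    """
    if not 0.0 < maf <= 1.0:
        raise ValueError("maf must lie in (0, 1]")
    denom = 1.0 - (1.0 - maf) ** 2 if mode == "carrier" else maf**2
    if denom <= 0.0:
        raise ValueError("carrier frequency is zero")
    return p_g_upper / denom


def continued_enrichment_check(
    freq_population: float,
    freq_cases: float,
    freq_concordant_cases: float,
    tolerance: float = 0.10,
) -> dict[str, float | bool | str]:
    """Track subgroup enrichment across population -> cases -> concordant cases.

    Mechanism 1 predicts a single enrichment step (population to cases) and a
    flat second step (cases to co-twin cases of affected probands), because
    conditioning on being a case twice adds nothing once susceptibility is
    accounted for.  Continued enrichment at the second step signals a
    penetrance effect (Mechanism 2).
    """
    for v in (freq_population, freq_cases, freq_concordant_cases):
        if not 0.0 <= v <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    step1 = freq_cases / freq_population if freq_population > 0 else math.inf
    step2 = freq_concordant_cases / freq_cases if freq_cases > 0 else math.inf
    second_flat = abs(step2 - 1.0) <= tolerance
    return {
        "first_step_ratio": step1,
        "second_step_ratio": step2,
        "second_step_flat": second_flat,
        "interpretation": "allele_frequency_only" if second_flat else "penetrance_effect",
    }
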