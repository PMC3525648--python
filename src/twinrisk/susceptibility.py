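"""Bounds on the genetically susceptible fraction of a population.

The central quantities are ``P(G)``, the fraction of the population carrying
a genotype capable of producing the disease, and ``g = P(G|cases)``, the
fraction of cases occurring in such individuals.  Neither is observable, but
the adjusted MZ-twin concordance ``b`` pins both:

* **Upper bound on P(G).**  The co-twin of a case proband shares the
  proband's genotype, so the adjusted concordance ``b`` is a size-biased
  penetrance average and cannot fall below half the mean penetrance of the
  susceptible set while the prevalence accounting ``z * P(G) = g * P(MS)``
  holds.  Combining the constraints yields ``P(G) <= 2 * P(MS) / b``.
* **Lower bound on P(G).**  ``P(G) = g * P(MS) / z >= g * P(MS) / z_max``
  for any admissible ceiling ``z_max`` on the susceptible-set penetrance.
* **Lower bound on g.**  Each two-way partition of the population (carrier
  status, gender) constrains ``g`` through the joint feasibility of the
  subgroup susceptible-case fractions ``g1``, ``g2`` and susceptible-only
  penetrances ``t'``, ``s'``; intersecting the admissible intervals of
  several partitions sharpens the bound (see :func:`estimate_g`).

Penetrance decompositions (``z``, ``x``, ``y``, ``sigma2``) and the ceiling
on "purely genetic" disease follow from the first two moments of the
genotype-penetrance distribution via the size-biased identity
``b' = z + sigma2 / z``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .concordance import EpidemiologicalObservables
from .partition import (
    Mechanism,
    PartitionAnalysis,
    PartitionObservables,
    enrichment_mechanism,
)

__all__ = [
    "SusceptibilityEstimates",
    "PenetranceDecomposition",
    "prob_g_upper",
    "prob_g_lower",
    "partition_admissible_interval",
    "analyze_partition",
    "estimate_g",
    "penetrance_range",
    "purely_genetic_bound",
    "sensitivity_sweep",
    "region_table",
]


class InfeasibilityError(ValueError):
    """The supplied partitions admit no common susceptible-case fraction."""


@dataclass(frozen=True)
class SusceptibilityEstimates:
    """Bounds on P(G) and g, with a provenance record of inputs and formulas."""

    p_g_lower: float
    p_g_upper: float
    g: float
    g_lower: float
    p_g3_given_g_upper: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_g_lower <= self.p_g_upper <= 1.0:
            raise ValueError(
                f"bounds must satisfy 0 <= lower <= upper <= 1, got "
                f"[{self.p_g_lower}, {self.p_g_upper}]"
            )
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("g must be in [0, 1]")


@dataclass(frozen=True)
class PenetranceDecomposition:
    """First-two-moment decomposition of the susceptible-set penetrances.

    ``z`` is the expected penetrance of the susceptible set, split into a
    high-penetrance subset (expectation ``x``, weight ``p``) and a
    low-penetrance subset (expectation ``y``); ``sigma2`` is the penetrance
    variance within the set.  ``a = z/p`` and ``a_prime = z/(1-p)`` are the
    disease mass per subset member.
    """

    z: float
    x: float
    y: float
    p: float
    a: float
    a_prime: float
    sigma2: float
    z_max: float
    p_g: float
    penetrance_nonsusceptible: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.y <= self.z <= self.x <= 1.0):
            raise ValueError(f"need 0 <= y <= z <= x <= 1, got y={self.y}, z={self.z}, x={self.x}")
        if self.sigma2 < -1e-15:
            raise ValueError("variance must be non-negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


def prob_g_upper(prevalence: float, b: float) -> float:
    """Upper bound ``2 * P(MS) / b`` on the susceptible population fraction."""
    if b <= 0.0:
        raise ValueError("adjusted concordance b must be positive")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    return min(1.0, 2.0 * prevalence / b)


def prob_g_lower(prevalence: float, g: float, z_upper: float) -> float:
    """Lower bound ``g * P(MS) / z_upper`` on the susceptible population fraction.

    ``z_upper`` is the ceiling used for the susceptible-set penetrance; the
    regional-table convention uses the region's own adjusted concordance
    ``b``, a user-supplied tighter ``z_max`` is also accepted.
    """
    if z_upper <= 0.0:
        raise ValueError("penetrance ceiling must be positive")
    if not 0.0 <= g <= 1.0:
        raise ValueError("g must be in [0, 1]")
    return min(1.0, g * prevalence / z_upper)


# ---------------------------------------------------------------------------
# Partition-based estimation of g
# ---------------------------------------------------------------------------

def _oriented(obs: PartitionObservables) -> tuple[PartitionObservables, bool]:
    """Relabel so the case-enriched subgroup is Gx+ (A >= A0)."""
    if obs.A >= obs.A0:
        return obs, False
    flipped = PartitionObservables(
        A=1.0 - obs.A,
        A0=1.0 - obs.A0,
        t=obs.s,
        s=obs.t,
        b=obs.b,
        label=obs.label + " (flipped)",
    )
    return flipped, True


def _subgroup_fractions(obs: PartitionObservables, g: float) -> tuple[float, float]:
    """Subgroup susceptible-case fractions (g1, g2) implied by carrier balance.

    Non-genetic cases carry the marker at the population frequency ``A0``, so
    ``A * (1 - g1) = (1 - g) * A0`` and the complementary relation for the
    Gx- subgroup.  Both reduce to ``g1 = g2 = g`` for an uninformative
    partition (A = A0).
    """
    u = 1.0 - g
    g1 = 1.0 - u * obs.A0 / obs.A if obs.A > 0 else 0.0
    g2 = (
        1.0 - u * (1.0 - obs.A0) / (1.0 - obs.A)
        if obs.A < 1.0
        else 1.0 - u
    )
    return g1, g2


def _feasible(obs: PartitionObservables, g: float, enforce_ordering: bool) -> bool:
    """Joint feasibility of (g1, g2, t', s') at a candidate g for one partition."""
    g1, g2 = _subgroup_fractions(obs, g)
    if g1 < obs.t - 1e-12 or g2 < obs.s - 1e-12:  # t' <= 1 and s' <= 1
        return False
    if g1 < 0.0 or g2 < 0.0:
        return False
    if enforce_ordering:
        # penetrance ordering t' >= s' for the case-enriched subgroup
        if obs.t * g2 < obs.s * g1 - 1e-12:
            return False
    return True


def partition_admissible_interval(
    obs: PartitionObservables,
    grid_step: float = 1e-4,
    refine_tol: float = 1e-10,
) -> tuple[float, float]:
    """Admissible interval of the susceptible-case fraction g for one partition.

    Scans g over a uniform grid for joint feasibility of the per-partition
    relations, then refines the boundary by bisection.  All constraints relax
    monotonically as g -> 1, so the admissible set is an interval ``[lo, 1]``.
    The penetrance-ordering constraint (``t' >= s'`` for the enriched
    subgroup) is enforced when the observed subgroup ordering is consistent
    with it and dropped (with a warning) otherwise.
    """
    oriented, _ = _oriented(obs)
    enforce_ordering = oriented.t >= oriented.s
    if not enforce_ordering:
        warnings.warn(
            f"partition {obs.label!r}: enriched subgroup has the lower adjusted "
            "concordance; penetrance-ordering constraint dropped",
            stacklevel=2,
        )
    n = int(round(1.0 / grid_step)) + 1
    feasible = [
        _feasible(oriented, i * grid_step, enforce_ordering) for i in range(n)
    ]
    if not any(feasible):
        raise InfeasibilityError(
            f"partition {obs.label!r} admits no susceptible-case fraction in [0, 1]"
        )
    first = feasible.index(True)
    if first == 0:
        return 0.0, 1.0
    lo, hi = (first - 1) * grid_step, first * grid_step
    while hi - lo > refine_tol:
        mid = 0.5 * (lo + hi)
        if _feasible(oriented, mid, enforce_ordering):
            hi = mid
        else:
            lo = mid
    return hi, 1.0


def analyze_partition(
    obs: PartitionObservables,
    g: float,
    mechanism_tolerance: float = 0.10,
) -> PartitionAnalysis:
    """Derive subgroup quantities (g1, g2, t', s', B, mechanism) at a given g."""
    oriented, flipped = _oriented(obs)
    g1o, g2o = _subgroup_fractions(oriented, g)
    g1o, g2o = min(1.0, max(0.0, g1o)), min(1.0, max(0.0, g2o))
    g1, g2 = (g2o, g1o) if flipped else (g1o, g2o)
    t_prime = min(1.0, obs.t / g1) if g1 > 0 else math.nan
    s_prime = min(1.0, obs.s / g2) if g2 > 0 else math.nan
    b_prime = min(1.0, obs.b / g) if g > 0 else math.nan
    ratio, label = enrichment_mechanism(obs.s, obs.b, mechanism_tolerance)
    return PartitionAnalysis(
        observables=obs,
        g=g,
        g1=g1,
        g2=g2,
        t_prime=t_prime,
        s_prime=s_prime,
        b_prime=b_prime,
        B=g1 / g2 if g2 > 0 else math.inf,
        mechanism=label,
        mechanism_ratio=ratio,
    )


def estimate_g(
    partitions: Sequence[PartitionObservables],
    obs: EpidemiologicalObservables | None = None,
    grid_step: float = 1e-4,
) -> SusceptibilityEstimates:
    """Lower bound on g jointly feasible for all supplied partitions.

    Each partition contributes an admissible interval of g; the estimate is
    the intersection's lower endpoint.  With the published gender and
    carrier-status partitions the result is g >= 0.94.  If an
    ``EpidemiologicalObservables`` is supplied, the companion P(G) bounds are
    filled in from its prevalence and the whole-cohort adjusted concordance.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    intervals: dict[str, tuple[float, float]] = {}
    lo, hi = 0.0, 1.0
    for i, part in enumerate(partitions):
        interval = partition_admissible_interval(part, grid_step=grid_step)
        intervals[part.label or f"partition_{i}"] = interval
        lo, hi = max(lo, interval[0]), min(hi, interval[1])
    if lo > hi:
        raise InfeasibilityError(
            "partitions are mutually infeasible; per-partition admissible "
            f"intervals: {intervals}"
        )
    g_lower = lo
    provenance: dict = {
        "method": "joint feasibility grid search over g",
        "grid_step": grid_step,
        "admissible_intervals": intervals,
    }
    if obs is not None:
        b = partitions[0].b
        p_up = prob_g_upper(obs.prevalence, b)
        p_lo = prob_g_lower(obs.prevalence, g_lower, b)
        provenance.update({"prevalence": obs.prevalence, "b": b})
    else:
        p_up, p_lo = 1.0, 0.0
    return SusceptibilityEstimates(
        p_g_lower=p_lo,
        p_g_upper=p_up,
        g=g_lower,
        g_lower=g_lower,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Penetrance decomposition
# ---------------------------------------------------------------------------

def _decomposition_at(
    z: float,
    b_prime: float,
    g: float,
    prevalence: float,
    p_high: float,
) -> PenetranceDecomposition:
    sigma2 = max(0.0, z * (b_prime - z))
    sigma = math.sqrt(sigma2)
    p = p_high
    x = min(1.0, z + sigma * math.sqrt((1.0 - p) / p))
    y = max(0.0, z - sigma * math.sqrt(p / (1.0 - p)))
    p_g = min(1.0, g * prevalence / z) if z > 0 else 1.0
    pen_nonsusc = (
        (1.0 - g) * prevalence / (1.0 - p_g) if p_g < 1.0 else 0.0
    )
    return PenetranceDecomposition(
        z=z,
        x=x,
        y=y,
        p=p,
        a=min(1.0, z / p),
        a_prime=min(1.0, z / (1.0 - p)),
        sigma2=sigma2,
        z_max=b_prime,
        p_g=p_g,
        penetrance_nonsusceptible=pen_nonsusc,
    )


def penetrance_range(
    obs: EpidemiologicalObservables,
    est: SusceptibilityEstimates,
    b: float,
    p_high: float = 0.5,
) -> tuple[PenetranceDecomposition, PenetranceDecomposition]:
    """Range of penetrance decompositions consistent with the P(G) bounds.

    For each P(G) bound the conservation identity ``z * P(G) = g * P(MS)``
    fixes ``z``; the size-biased identity ``b' = z + sigma2/z`` then yields
    the within-set variance.  The raw lower boundary ``g*P(MS)/P(G)_upper``
    is raised, minimally, to ``b'/2`` whenever the two constraint sets would
    otherwise be incoherent (below ``b'/2`` the implied variance exceeds
    ``z**2`` and the low-penetrance subset would need a negative
    expectation).  Returns the (low-z, high-z) endpoint decompositions.
    """
    if not 0.0 < est.g <= 1.0:
        raise ValueError("estimates must carry g in (0, 1]")
    b_prime = b / est.g
    if b_prime > 1.0:
        raise ValueError("b/g exceeds 1; inputs incoherent")
    z_lo_raw = (
        est.g * obs.prevalence / est.p_g_upper if est.p_g_upper > 0 else b_prime
    )
    z_lo = max(z_lo_raw, b_prime / 2.0)
    z_hi = b_prime
    if est.p_g_lower > 0.0:
        z_hi = min(z_hi, est.g * obs.prevalence / est.p_g_lower)
    if z_lo > z_hi + 1e-12:
        raise ValueError(
            f"incoherent penetrance constraints: lower {z_lo:.4g} exceeds "
            f"upper {z_hi:.4g}"
        )
    z_hi = max(z_lo, z_hi)
    return (
        _decomposition_at(z_lo, b_prime, est.g, obs.prevalence, p_high),
        _decomposition_at(z_hi, b_prime, est.g, obs.prevalence, p_high),
    )


def purely_genetic_bound(
    decomp: PenetranceDecomposition, near_unity_threshold: float = 0.9
) -> float:
    """Ceiling on the mass of near-deterministic ("purely genetic") genotypes.

    Maximizes ``P(penetrance >= threshold)`` over all distributions on
    [0, 1] with the decomposition's mean ``z`` and variance ``sigma2``.  The
    extremal distribution is two-point: mass at the threshold with the rest
    at a floor ``>= 0`` (a Cantelli-type bound ``sigma2/(sigma2 + (tau-z)**2)``)
    or, when the variance is large relative to ``z*(tau-z)``, mass at
    ``(sigma2 + z**2)/z`` with the rest at zero (bound ``z**2/(z**2+sigma2)``).
    """
    tau = near_unity_threshold
    if not 0.5 < tau <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    z, s2 = decomp.z, decomp.sigma2
    if z >= tau:
        # mean already at/above the threshold; all mass can sit >= tau iff the
        # variance fits in the remaining interval
        if s2 <= (z - tau) * (1.0 - z) + 1e-15:
            return 1.0
        return max(
            z * z / (z * z + s2),
            s2 / (s2 + (tau - z) ** 2) if tau != z else 1.0,
        )
    if s2 <= 0.0:
        return 0.0
    if s2 <= z * (tau - z):
        return s2 / (s2 + (tau - z) ** 2)
    return z * z / (z * z + s2)


# ---------------------------------------------------------------------------
# Sensitivity sweep and regional tables
# ---------------------------------------------------------------------------

_SWEEPABLE = ("prevalence", "mz_raw", "sib_raw", "dz_raw")


def sensitivity_sweep(
    base: EpidemiologicalObservables,
    overrides: dict[str, Iterable[float]],
    g: float = 0.94,
) -> pd.DataFrame:
    """Recompute the susceptibility bounds over a grid of input overrides.

    ``overrides`` maps observable field names (prevalence, mz_raw, sib_raw,
    dz_raw) to candidate values; every combination (plus the base value of
    any field not overridden) is evaluated.  Named headline scenarios —
    prevalence doubled to 0.003, MZ proband-wise concordance 0.35, sibling
    concordance 0.035 — are just particular rows of this grid.
    """
    for name in overrides:
        if name not in _SWEEPABLE:
            raise ValueError(
                f"cannot sweep {name!r}; valid fields: {_SWEEPABLE}"
            )
    grids = {
        name: list(overrides.get(name, [getattr(base, name)])) for name in _SWEEPABLE
    }
    rows = []
    for combo in itertools.product(*grids.values()):
        vals = dict(zip(grids.keys(), combo))
        factor = vals["sib_raw"] / vals["dz_raw"]
        b = vals["mz_raw"] * factor
        rows.append(
            {
                **vals,
                "iu_ch_factor": factor,
                "b": b,
                "p_g_upper": prob_g_upper(vals["prevalence"], b),
                "p_g_lower": prob_g_lower(vals["prevalence"], g, b),
            }
        )
    return pd.DataFrame(rows)


def region_table(
    registry: pd.DataFrame,
    mode: Literal["iu_adjusted", "unadjusted"] = "iu_adjusted",
    g: float = 0.94,
    iu_ch_factor: float | None = None,
    prevalence_scale: float = 1e-5,
) -> pd.DataFrame:
    """Susceptible-fraction bounds per region (or per disease).

    Expects columns ``region``, ``prevalence_low``, ``prevalence_high``
    (multiplied by ``prevalence_scale``; pass 1.0 for decimals) and
    ``probandwise_mz`` (decimal).  In ``iu_adjusted`` mode each region's
    concordance is multiplied by the shared-gestation factor and the lower
    bound is ``g * prevalence_low / b``; in ``unadjusted`` mode (cross-disease
    tables where gestational sharing is assumed inert) the factor is 1 and
    both ends use the upper-bound formula ``2 * prevalence / b``.
    """
    required = {"region", "prevalence_low", "prevalence_high", "probandwise_mz"}
    missing = required - set(registry.columns)
    if missing:
        raise ValueError(f"region registry is missing columns: {sorted(missing)}")
    if mode == "iu_adjusted" and iu_ch_factor is None:
        raise ValueError("iu_adjusted mode needs an iu_ch_factor")
    factor = iu_ch_factor if mode == "iu_adjusted" else 1.0
    rows = []
    for rec in registry.to_dict("records"):
        p_lo = float(rec["prevalence_low"]) * prevalence_scale
        p_hi = float(rec["prevalence_high"]) * prevalence_scale
        b = float(rec["probandwise_mz"]) * factor
        lower = (
            prob_g_lower(p_lo, g, b)
            if mode == "iu_adjusted"
            else prob_g_upper(p_lo, b)
        )
        upper = prob_g_upper(p_hi, b)
        rows.append(
            {
                "region": rec["region"],
                "prevalence_low": p_lo,
                "prevalence_high": p_hi,
                "b": b,
                "susceptible_lower": lower,
                "susceptible_upper": upper,
            }
        )
    return pd.DataFrame(rows)
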