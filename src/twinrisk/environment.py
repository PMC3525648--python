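"""Gender-specific response curves of disease risk versus environmental exposure.

Susceptible individuals develop disease only after a sufficient environmental
exposure ``E``.  The probability ``P(disease, E | G)`` is modelled as a
saturating response in a dimensionless exposure coordinate ``x`` (monotone in
the population likelihood of sufficient exposure, not a time axis): zero
below a gender-specific threshold, then a constant-hazard rise

    response(x) = plateau * (1 - exp(-hazard * (x - threshold)))

towards a gender-specific plateau.  The plateau exists because only part of
the susceptible set responds to any particular mix of exposures — raising
exposure indefinitely does not push risk past roughly 28% in women and 6% in
men.  A proportional-hazard assumption ties the two genders: the female
hazard is ``r`` times the male hazard, so observed gender differences in
current-epoch risk must come from a threshold offset ``lambda``, a hazard
ratio ``r != 1``, or both.

The exponential saturation is the minimal constant-hazard form consistent
with the proportional-hazard assumption; the curve function is pluggable via
:class:`ResponseCurveParams` so an alternative parametric form can be
substituted without touching the fitting interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "ResponseCurveParams",
    "GenderCurves",
    "ExposureSummary",
    "response_curve",
    "fit_gender_curves",
    "exposure_sufficiency",
    "prevalence_increase_stub",
    "population_exposure_bound_stub",
]


@dataclass(frozen=True)
class ResponseCurveParams:
    """One gender's response curve: plateau, hazard and exposure threshold."""

    plateau_c: float
    hazard_scale: float = 1.0
    hazard_ratio: float = 1.0
    lambda_threshold: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_c <= 1.0:
            raise ValueError("plateau must lie in [0, 1]")
        if self.hazard_scale <= 0.0 or self.hazard_ratio <= 0.0:
            raise ValueError("hazard scale and ratio must be positive")
        if not math.isfinite(self.lambda_threshold):
            raise ValueError("threshold must be finite")

    @property
    def hazard(self) -> float:
        return self.hazard_scale * self.hazard_ratio


@dataclass(frozen=True)
class GenderCurves:
    """Fitted female/male curve pair with the calibration exposure."""

    female: ResponseCurveParams
    male: ResponseCurveParams
    x_calibration: float
    r: float                       # women:men proportional-hazard ratio
    lambda_offset: float           # lambda_male - lambda_female
    degenerate: bool = False


@dataclass(frozen=True)
class ExposureSummary:
    """Exposure-sufficiency summary: saturation fraction and event count floor."""

    p_e_lower: float
    n_events_min: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_e_lower <= 1.0:
            raise ValueError("p_e_lower must lie in [0, 1]")
        if self.n_events_min < 1:
            raise ValueError("n_events_min must be a positive integer")


def response_curve(x: float, params: ResponseCurveParams) -> float:
    """Disease probability at exposure ``x``: 0 below threshold, else
    ``plateau * (1 - exp(-hazard * (x - threshold)))``."""
    if x <= params.lambda_threshold:
        return 0.0
    return params.plateau_c * (
        1.0 - math.exp(-params.hazard * (x - params.lambda_threshold))
    )


def _log_gap(z: float, plateau: float) -> float:
    """Cumulative hazard needed to reach response z on a curve with this plateau."""
    if z < 0.0 or z > plateau:
        raise ValueError(f"target response {z} outside [0, plateau={plateau}]")
    if z == plateau:
        return math.inf
    return -math.log(1.0 - z / plateau)


def fit_gender_curves(
    z_f: float,
    z_m: float,
    plateau_f: float = 0.28,
    plateau_m: float = 0.06,
    constraint_mode: Literal["threshold", "hazard", "both"] = "threshold",
    hazard_scale: float = 1.0,
) -> GenderCurves:
    """Fit a proportional-hazard curve pair to current-epoch responses.

    The female curve is the reference (threshold 0, hazard ``hazard_scale``);
    the calibration exposure ``x_cal`` is where it reaches ``z_f``.  The male
    curve is then solved to reach ``z_m`` at the same exposure under the
    chosen constraint: ``threshold`` fixes r = 1 and moves the male
    threshold; ``hazard`` keeps thresholds equal and solves the hazard ratio;
    ``both`` splits the gap geometrically between the two.  When the male
    saturation fraction exceeds the female one, the fit necessarily yields a
    lower male threshold, a greater male hazard, or both.
    """
    if z_f == plateau_f and z_m == plateau_m:
        # both genders saturated: any threshold/hazard pair fits
        return GenderCurves(
            female=ResponseCurveParams(plateau_f, hazard_scale, 1.0, 0.0, "F"),
            male=ResponseCurveParams(plateau_m, hazard_scale, 1.0, 0.0, "M"),
            x_calibration=math.inf,
            r=1.0,
            lambda_offset=0.0,
            degenerate=True,
        )
    gap_f = _log_gap(z_f, plateau_f)
    gap_m = _log_gap(z_m, plateau_m)
    if not (math.isfinite(gap_f) and math.isfinite(gap_m)):
        raise ValueError(
            "one gender is exactly at its plateau; the joint fit is infeasible "
            "unless both are (degenerate case)"
        )
    x_cal = gap_f / hazard_scale
    # with male hazard = hazard_scale / r, the male curve reaches z_m at x_cal
    # when (x_cal - lam_m) / r = gap_m / hazard_scale
    if constraint_mode == "threshold":
        r = 1.0
        lam_m = (gap_f - gap_m) / hazard_scale
    elif constraint_mode == "hazard":
        lam_m = 0.0
        r = gap_f / gap_m
    elif constraint_mode == "both":
        r = math.sqrt(gap_f / gap_m)
        lam_m = (gap_f - r * gap_m) / hazard_scale
    else:
        raise ValueError(f"unknown constraint mode {constraint_mode!r}")
    # female curve is the unit-hazard reference; the male hazard is 1/r of it
    female = ResponseCurveParams(
        plateau_c=plateau_f,
        hazard_scale=hazard_scale,
        hazard_ratio=1.0,
        lambda_threshold=0.0,
        label="F",
    )
    male = ResponseCurveParams(
        plateau_c=plateau_m,
        hazard_scale=hazard_scale,
        hazard_ratio=1.0 / r,
        lambda_threshold=lam_m,
        label="M",
    )
    if z_m / plateau_m > z_f / plateau_f:
        assert lam_m <= 1e-12 or r < 1.0, (
            "male saturation exceeds female: fit must give men a lower "
            "threshold or a greater hazard"
        )
    return GenderCurves(
        female=female,
        male=male,
        x_calibration=x_cal,
        r=r,
        lambda_offset=lam_m,
    )


def exposure_sufficiency(
    z_gender: float, plateau_gender: float, n_events_min: int = 3
) -> ExposureSummary:
    """Lower bound on the probability of sufficient exposure from the saturation fraction.

    Under the monotone response contract, the current response cannot exceed
    ``plateau * P(E|G)``, so ``z / plateau`` bounds ``P(E|G)`` from below.
    ``n_events_min`` carries the configured minimum number of distinct
    environmental events required (default 3, from prior sequential-exposure
    work; not derived here).
    """
    if plateau_gender <= 0.0:
        raise ValueError("plateau must be positive")
    if z_gender < 0.0 or z_gender > plateau_gender + 1e-12:
        raise ValueError("response must lie in [0, plateau]")
    return ExposureSummary(
        p_e_lower=min(1.0, z_gender / plateau_gender), n_events_min=n_events_min
    )


def prevalence_increase_stub(
    gender_ratio_early: float, gender_ratio_late: float, male_saturation: float
) -> float:
    """Prevalence increase implied by a rising gender ratio (stub).

    Requires an external gender-ratio trajectory.  If the male response is
    effectively saturated (``male_saturation`` near 1), male prevalence is
    static and the prevalence ratio between epochs follows from the gender
    ratios alone:  with case gender ratio ``R = F:M``, total prevalence is
    proportional to ``1 + R``, so the fractional increase is
    ``(1 + R_late) / (1 + R_early) - 1``.  Documented as a stub because the
    trajectory data are an external input, not part of the bundled tables.
    """
    if gender_ratio_early <= 0.0 or gender_ratio_late <= 0.0:
        raise ValueError("gender ratios must be positive")
    if not 0.0 < male_saturation <= 1.0:
        raise ValueError("male saturation must lie in (0, 1]")
    return (1.0 + gender_ratio_late) / (1.0 + gender_ratio_early) / male_saturation - 1.0


def population_exposure_bound_stub(
    p_e_given_g_lower: float, susceptible_exposure_enrichment: float = 1.0
) -> float:
    """Population-level sufficient-exposure bound (stub).

    Converts a lower bound on ``P(E|G)`` to one on ``P(E)`` given a
    user-supplied enrichment factor ``P(E|G)/P(E)``.  Two readings exist —
    the bound may refer to ``P(E)`` in the whole population or to ``P(E|G)``
    — and with no exposure-susceptibility association (factor 1) they
    coincide, which is the default.
    """
    if susceptible_exposure_enrichment <= 0.0:
        raise ValueError("enrichment factor must be positive")
    return min(1.0, p_e_given_g_lower / susceptible_exposure_enrichment)
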