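"""Likelihood/severity scoring, band rating and danger-level classification.

    likelihood = (cluster + flight-height + activity coefficients) x 100 / 3
    severity   = (comparative number + comparative weight)          x 100 / 2

Both land on a 0-100 scale and are rated into five ordinal bands
(likelihood thresholds 15/30/50/70; severity 4/7/14/40). A 5x5 matrix maps
the band pair to a danger level in {1, 2, 3}; two rules can then each raise
the level by one (capped at 3): the species is a raptor, or it was seen
crossing or overflying the runway at least ``crossing_threshold`` times.
"""

from __future__ import annotations

import math

from .config import RiskModelConfig
from .models import Band, RiskFactors, RiskScore, SpeciesProfile
from .risk_factors import ACTIVITY_COEFFS, CLUSTER_COEFFS, FLIGHT_HEIGHT_COEFFS

RAPTOR_RULE = "raptor"
CROSSING_RULE = "runway_crossing"

_BANDS = list(Band)


def _check_in_set(value: float, allowed: tuple[float, ...], name: str) -> None:
    if not any(math.isclose(value, a, abs_tol=1e-9) for a in allowed):
        raise ValueError(f"{name} {value!r} not in allowed set {allowed}")


def likelihood(
    cluster_coeff: float, flight_height_coeff: float, activity_coeff: float
) -> float:
    """Strike likelihood on the 0-100 scale from the three coefficients."""
    _check_in_set(cluster_coeff, CLUSTER_COEFFS, "cluster coefficient")
    _check_in_set(flight_height_coeff, FLIGHT_HEIGHT_COEFFS, "flight-height coefficient")
    _check_in_set(
        activity_coeff, tuple(ACTIVITY_COEFFS.values()), "activity coefficient"
    )
    return (cluster_coeff + flight_height_coeff + activity_coeff) * 100.0 / 3.0


def severity(comparative_number: float, comparative_weight: float) -> float:
    """Strike severity on the 0-100 scale from the two normalized factors."""
    for name, value in (
        ("comparative number", comparative_number),
        ("comparative weight", comparative_weight),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    return (comparative_number + comparative_weight) * 100.0 / 2.0


def band(score: float, bounds: tuple[float, ...]) -> Band:
    """Rate a 0-100 score into its ordinal band.

    Bands are half-open ``[lo, hi)`` with the top band closed at 100, so
    every real score in [0, 100] is assigned (the published integer ranges
    would leave non-integer scores such as 14.5 unrated).
    """
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score must be in [0, 100], got {score}")
    for i, bound in enumerate(bounds):
        if score < bound:
            return _BANDS[i]
    return _BANDS[len(bounds)]


def classify(
    likelihood_band: Band, severity_band: Band, config: RiskModelConfig | None = None
) -> int:
    """Look up the danger level for a (likelihood, severity) band pair."""
    config = config or RiskModelConfig()
    return config.matrix[likelihood_band.ordinal - 1][severity_band.ordinal - 1]


def adjust(
    base_level: int, profile: SpeciesProfile, config: RiskModelConfig | None = None
) -> tuple[int, list[str]]:
    """Apply the raptor and runway-crossing adjustment rules.

    Each applicable rule adds one level; rules stack and the result is
    capped at level 3. Returns the adjusted level and the names of the
    rules applied.
    """
    config = config or RiskModelConfig()
    if base_level not in (1, 2, 3):
        raise ValueError(f"base_level must be in {{1,2,3}}, got {base_level}")
    level = base_level
    applied: list[str] = []
    if config.raptor_bump and profile.is_raptor:
        level += 1
        applied.append(RAPTOR_RULE)
    if profile.runway_crossings >= config.crossing_threshold:
        level += 1
        applied.append(CROSSING_RULE)
    return min(level, config.level_cap), applied


def score_species(
    factors: RiskFactors,
    profile: SpeciesProfile,
    config: RiskModelConfig | None = None,
) -> RiskScore:
    """Compute the full risk score of one species from its factors."""
    config = config or RiskModelConfig()
    lik = likelihood(
        factors.cluster_coeff, factors.flight_height_coeff, factors.activity_coeff
    )
    sev = severity(factors.comparative_number, factors.comparative_weight)
    l_band = band(lik, config.likelihood_bounds)
    s_band = band(sev, config.severity_bounds)
    base = classify(l_band, s_band, config)
    adjusted, applied = adjust(base, profile, config)
    return RiskScore(
        likelihood=lik,
        severity=sev,
        likelihood_band=l_band,
        severity_band=s_band,
        base_level=base,
        adjusted_level=adjusted,
        adjustments_applied=applied,
    )


def score_community(
    profiles: list[SpeciesProfile], config: RiskModelConfig | None = None
) -> tuple[dict[str, RiskFactors], dict[str, RiskScore]]:
    """Assign factors and scores for every species in a community."""
    from .risk_factors import assign_factors

    config = config or RiskModelConfig()
    factors = assign_factors(profiles, weight_basis=config.weight_basis)
    scores = {
        p.species_name: score_species(factors[p.species_name], p, config)
        for p in profiles
    }
    return factors, scores
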