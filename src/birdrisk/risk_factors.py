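"""Assignment of the five per-species risk factors.

Two continuous factors compare a species against the rest of the surveyed
community:

* comparative number  = total individuals / community maximum,
* comparative weight  = total biomass / community maximum biomass,

both kept as fractions in [0, 1] (the x100 scaling happens once, inside
the severity formula, so severity lands on the 0-100 rating scale).

Three step-function coefficients come from published lookup tables:

* flight height H (m):   H > 100 -> 0.1; 100 >= H > 50 -> 0.5;
                         50 >= H > 30 -> 1; 30 >= H > 5 -> 0.5; H <= 5 -> 0.1
  (40 m is treated as the critical aircraft take-off/landing height, so
  risk peaks in the 30-50 m band and falls off symmetrically);
* cluster size N:        N >= 100 -> 1; 100 > N >= 20 -> 0.5;
                         20 > N >= 3 -> 0.2; 3 > N >= 1 -> 0;
* activity zone:         A -> 0.9, B -> 0.6, C -> 0.3.

The published cluster table leaves N = 100 unassigned ("N > 100" vs
"100 > N >= 20"); the gap is closed risk-conservatively with N >= 100 -> 1.
"""

from __future__ import annotations

from .models import RiskFactors, SpeciesProfile, Zone

ACTIVITY_COEFFS: dict[Zone, float] = {Zone.A: 0.9, Zone.B: 0.6, Zone.C: 0.3}

FLIGHT_HEIGHT_COEFFS = (0.1, 0.5, 1.0)
CLUSTER_COEFFS = (0.0, 0.2, 0.5, 1.0)


class EmptyCommunityError(ValueError):
    """No individuals (or biomass) observed in any species."""


def comparative_number(profiles: list[SpeciesProfile]) -> dict[str, float]:
    """Normalized abundance: each species' total count over the community
    maximum. The most abundant species scores 1 (ties share the maximum)."""
    if not profiles:
        raise EmptyCommunityError("no species profiles supplied")
    top = max(p.total_count for p in profiles)
    if top <= 0:
        raise EmptyCommunityError("all species counts are zero")
    return {p.species_name: p.total_count / top for p in profiles}


def comparative_weight(
    profiles: list[SpeciesProfile], basis: str = "total_biomass"
) -> dict[str, float]:
    """Normalized biomass: species total biomass (count x mean individual
    mass) over the community maximum; ``basis="individual_mass"`` compares
    mean individual masses instead."""
    if not profiles:
        raise EmptyCommunityError("no species profiles supplied")
    if basis == "individual_mass":
        weights = {
            p.species_name: (
                p.total_biomass_g / p.total_count if p.total_count else 0.0
            )
            for p in profiles
        }
    elif basis == "total_biomass":
        weights = {p.species_name: p.total_biomass_g for p in profiles}
    else:
        raise ValueError(f"unknown comparative-weight basis {basis!r}")
    top = max(weights.values())
    if top <= 0:
        raise EmptyCommunityError("all species biomass totals are zero")
    return {name: w / top for name, w in weights.items()}


def flight_height_coeff(height_m: float) -> float:
    """Step-function flight-height risk coefficient (upper-inclusive bands)."""
    if height_m < 0:
        raise ValueError(f"flight height must be non-negative, got {height_m}")
    if height_m > 100:
        return 0.1
    if height_m > 50:
        return 0.5
    if height_m > 30:
        return 1.0
    if height_m > 5:
        return 0.5
    return 0.1


def cluster_coeff(n: int) -> float:
    """Step-function clustering risk coefficient for a group of ``n`` birds."""
    if n < 1:
        raise ValueError(f"cluster size must be >= 1, got {n}")
    if n >= 100:  # table gap at exactly 100 closed conservatively
        return 1.0
    if n >= 20:
        return 0.5
    if n >= 3:
        return 0.2
    return 0.0


def activity_coeff(zone: Zone | str) -> float:
    """Activity-range risk coefficient of the zone nearest the flight area."""
    try:
        return ACTIVITY_COEFFS[Zone(zone)]
    except (ValueError, KeyError):
        raise ValueError(f"unknown zone {zone!r}") from None


def assign_factors(
    profiles: list[SpeciesProfile], weight_basis: str = "total_biomass"
) -> dict[str, RiskFactors]:
    """Assign all five risk factors to every species in the community."""
    numbers = comparative_number(profiles)
    weights = comparative_weight(profiles, basis=weight_basis)
    return {
        p.species_name: RiskFactors(
            comparative_number=numbers[p.species_name],
            comparative_weight=weights[p.species_name],
            flight_height_coeff=flight_height_coeff(p.representative_flight_height_m),
            cluster_coeff=cluster_coeff(p.max_cluster_size),
            activity_coeff=activity_coeff(p.nearest_zone),
        )
        for p in profiles
    }
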