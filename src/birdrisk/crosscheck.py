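"""Cross-check a risk classification against historical strike records.

High-danger (level 3) species are compared with a list of species/families
drawn from an aviation strike-record database. A species matches at species
level on its normalized name (case-folded, whitespace-collapsed, optionally
mapped through a synonym table); species without a name match can still
match at family level. The two match sets are disjoint by construction and
the reported fractions are taken over the high-danger list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .models import SpeciesProfile


@dataclass(frozen=True)
class StrikeRecord:
    family: str
    species_name: str | None = None

    def __post_init__(self) -> None:
        if not self.family or not self.family.strip():
            raise ValueError("a strike record needs at least a family")


@dataclass
class StrikeRecordList:
    entries: list[StrikeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class OverlapResult:
    species_matches: list[str]
    family_matches: list[str]
    species_fraction: float
    family_fraction: float


def normalize_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Case-fold, trim and collapse whitespace; then apply the synonym map."""
    norm = " ".join(name.casefold().split())
    if synonyms:
        norm = synonyms.get(norm, norm)
    return norm


def read_strikes(path: str | Path) -> StrikeRecordList:
    """Read a strike-record CSV with columns ``species,family`` (species may
    be blank)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("species", "family"):
        if col not in df.columns:
            raise ValueError(f"strike-record CSV {path} missing column {col!r}")
    entries = []
    for _, row in df.iterrows():
        species = row["species"].strip() or None
        entries.append(StrikeRecord(family=row["family"].strip(), species_name=species))
    return StrikeRecordList(entries=entries)


def overlap(
    high_danger: list[SpeciesProfile],
    strikes: StrikeRecordList,
    synonyms: dict[str, str] | None = None,
) -> OverlapResult:
    """Fraction of high-danger species confirmed by the strike records.

    Returns the species-level matches, the additional family-level matches
    (among species not already matched by name), and both fractions over
    the high-danger list; ``species_fraction + family_fraction <= 1``.
    """
    if not high_danger:
        raise ValueError("high-danger species list is empty")
    if synonyms:
        synonyms = {normalize_name(k): normalize_name(v) for k, v in synonyms.items()}
    if not strikes.entries:
        warnings.warn("strike-record list is empty; no overlap possible")
        return OverlapResult([], [], 0.0, 0.0)

    strike_species = {
        normalize_name(e.species_name, synonyms)
        for e in strikes.entries
        if e.species_name
    }
    strike_families = {normalize_name(e.family) for e in strikes.entries}

    species_matches: list[str] = []
    family_matches: list[str] = []
    for profile in high_danger:
        if normalize_name(profile.species_name, synonyms) in strike_species:
            species_matches.append(profile.species_name)
        elif normalize_name(profile.family) in strike_families:
            family_matches.append(profile.species_name)
    n = len(high_danger)
    return OverlapResult(
        species_matches=species_matches,
        family_matches=family_matches,
        species_fraction=len(species_matches) / n,
        family_fraction=len(family_matches) / n,
    )
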