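"""Risk reports: per-species tables, level shares, seasonal level counts,
and CSV/JSON serialization (JSON embeds the configuration used).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .config import RiskModelConfig
from .models import Band, RiskFactors, RiskScore, Season, SpeciesProfile

CSV_COLUMNS = [
    "species", "family", "order", "cn", "cw", "height_coeff", "cluster_coeff",
    "activity_coeff", "likelihood", "severity", "l_band", "s_band",
    "base_level", "adjusted_level", "adjustments",
]


@dataclass
class SpeciesRow:
    species: str
    family: str
    order: str
    factors: RiskFactors
    score: RiskScore
    seasons_present: frozenset[Season]


@dataclass
class RiskReport:
    species_rows: list[SpeciesRow]
    level_counts: dict[int, int]
    level_percentages: dict[int, float]
    seasonal_counts: dict[tuple[Season, int], int]
    config: dict = field(default_factory=dict)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (so 16.95 -> 17.0, not banker's 16.9...)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def level_percentages(counts: dict[int, int]) -> dict[int, float]:
    """Share of species at each danger level, in percent to one decimal.

    E.g. 32 of 118 species -> 27.1, 66 of 118 -> 55.9.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no species counted; cannot compute percentages")
    return {
        level: round_half_up(100.0 * n / total, 1) for level, n in counts.items()
    }


def seasonal_summary(
    profiles: list[SpeciesProfile], scores: dict[str, RiskScore]
) -> dict[tuple[Season, int], int]:
    """Number of species present in each season, broken down by danger level.

    A species present year-round contributes to all four seasons, so the
    sum over seasons may exceed the number of species.
    """
    table = {(season, level): 0 for season in Season for level in (1, 2, 3)}
    for profile in profiles:
        score = scores[profile.species_name]
        for season in profile.seasons_present:
            table[(season, score.adjusted_level)] += 1
    return table


def build_report(
    profiles: list[SpeciesProfile],
    factors: dict[str, RiskFactors],
    scores: dict[str, RiskScore],
    config: RiskModelConfig | None = None,
) -> RiskReport:
    """Assemble the full report for a scored community."""
    config = config or RiskModelConfig()
    rows = [
        SpeciesRow(
            species=p.species_name,
            family=p.family,
            order=p.order,
            factors=factors[p.species_name],
            score=scores[p.species_name],
            seasons_present=p.seasons_present,
        )
        for p in profiles
    ]
    counts = {level: 0 for level in (1, 2, 3)}
    for row in rows:
        counts[row.score.adjusted_level] += 1
    percentages = level_percentages(counts) if rows else {1: 0.0, 2: 0.0, 3: 0.0}
    return RiskReport(
        species_rows=rows,
        level_counts=counts,
        level_percentages=percentages,
        seasonal_counts=seasonal_summary(profiles, scores),
        config=config.to_dict(),
    )


def report_frame(report: RiskReport) -> pd.DataFrame:
    """Per-species report as a pandas DataFrame (one row per species)."""
    data = []
    for row in report.species_rows:
        data.append(
            {
                "species": row.species,
                "family": row.family,
                "order": row.order,
                "cn": row.factors.comparative_number,
                "cw": row.factors.comparative_weight,
                "height_coeff": row.factors.flight_height_coeff,
                "cluster_coeff": row.factors.cluster_coeff,
                "activity_coeff": row.factors.activity_coeff,
                "likelihood": row.score.likelihood,
                "severity": row.score.severity,
                "l_band": row.score.likelihood_band.value,
                "s_band": row.score.severity_band.value,
                "base_level": row.score.base_level,
                "adjusted_level": row.score.adjusted_level,
                "adjustments": ";".join(row.score.adjustments_applied),
            }
        )
    return pd.DataFrame(data, columns=CSV_COLUMNS)


def _report_to_dict(report: RiskReport) -> dict:
    return {
        "species": [
            {
                "species": r.species,
                "family": r.family,
                "order": r.order,
                "factors": {
                    "comparative_number": r.factors.comparative_number,
                    "comparative_weight": r.factors.comparative_weight,
                    "flight_height_coeff": r.factors.flight_height_coeff,
                    "cluster_coeff": r.factors.cluster_coeff,
                    "activity_coeff": r.factors.activity_coeff,
                },
                "score": {
                    "likelihood": r.score.likelihood,
                    "severity": r.score.severity,
                    "likelihood_band": r.score.likelihood_band.value,
                    "severity_band": r.score.severity_band.value,
                    "base_level": r.score.base_level,
                    "adjusted_level": r.score.adjusted_level,
                    "adjustments_applied": list(r.score.adjustments_applied),
                },
                "seasons_present": sorted(s.value for s in r.seasons_present),
            }
            for r in report.species_rows
        ],
        "level_counts": {str(k): v for k, v in report.level_counts.items()},
        "level_percentages": {str(k): v for k, v in report.level_percentages.items()},
        "seasonal_counts": {
            season.value: {
                str(level): report.seasonal_counts[(season, level)]
                for level in (1, 2, 3)
            }
            for season in Season
        },
        "config": report.config,
        "generated": _dt.date.today().isoformat(),
    }


def write_report(
    report: RiskReport, path: str | Path, format: str = "json"
) -> None:
    """Serialize a report to ``csv`` (per-species table) or ``json`` (full
    report including the configuration used, for provenance)."""
    path = Path(path)
    if format == "csv":
        report_frame(report).to_csv(path, index=False)
    elif format == "json":
        path.write_text(
            json.dumps(_report_to_dict(report), indent=2) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> RiskReport:
    """Load a JSON report written by :func:`write_report` back into memory."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    rows = []
    for entry in data["species"]:
        f = entry["factors"]
        s = entry["score"]
        rows.append(
            SpeciesRow(
                species=entry["species"],
                family=entry["family"],
                order=entry["order"],
                factors=RiskFactors(
                    comparative_number=f["comparative_number"],
                    comparative_weight=f["comparative_weight"],
                    flight_height_coeff=f["flight_height_coeff"],
                    cluster_coeff=f["cluster_coeff"],
                    activity_coeff=f["activity_coeff"],
                ),
                score=RiskScore(
                    likelihood=s["likelihood"],
                    severity=s["severity"],
                    likelihood_band=Band(s["likelihood_band"]),
                    severity_band=Band(s["severity_band"]),
                    base_level=s["base_level"],
                    adjusted_level=s["adjusted_level"],
                    adjustments_applied=list(s["adjustments_applied"]),
                ),
                seasons_present=frozenset(
                    Season(x) for x in entry["seasons_present"]
                ),
            )
        )
    return RiskReport(
        species_rows=rows,
        level_counts={int(k): v for k, v in data["level_counts"].items()},
        level_percentages={
            int(k): v for k, v in data["level_percentages"].items()
        },
        seasonal_counts={
            (Season(season), int(level)): n
            for season, by_level in data["seasonal_counts"].items()
            for level, n in by_level.items()
        },
        config=data.get("config", {}),
    )
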