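"""Model configuration: rating bands, the 5x5 risk matrix, adjustment rules
and aggregation choices.

Defaults reproduce the published coefficient tables and band thresholds.
The 5x5 matrix itself is a reconstruction (the original is only available
as a figure): the shipped default maps the sum of the two band ordinals
(1..5 each) to a level, 3 when the sum is >= 8, 2 for 5..7, 1 otherwise.
Both extreme corners then land on the extreme levels and the matrix is
monotone along both axes. Any user-supplied matrix is validated for the
same monotonicity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .models import Band, Season

#: Table-1 band thresholds (lower edges of bands 2..5) on the 0-100 scale.
DEFAULT_LIKELIHOOD_BOUNDS: tuple[float, ...] = (15.0, 30.0, 50.0, 70.0)
DEFAULT_SEVERITY_BOUNDS: tuple[float, ...] = (4.0, 7.0, 14.0, 40.0)

#: Calendar-quarter season scheme: Mar-May spring, Jun-Aug summer,
#: Sep-Nov autumn, Dec-Feb winter.
DEFAULT_SEASON_OF_MONTH: dict[int, Season] = {
    3: Season.spring, 4: Season.spring, 5: Season.spring,
    6: Season.summer, 7: Season.summer, 8: Season.summer,
    9: Season.autumn, 10: Season.autumn, 11: Season.autumn,
    12: Season.winter, 1: Season.winter, 2: Season.winter,
}


def default_matrix() -> tuple[tuple[int, ...], ...]:
    """Ordinal-sum reconstruction of the 5x5 risk matrix.

    Rows are likelihood bands (very_low..very_high), columns severity bands.
    """
    rows = []
    for l_ord in range(1, 6):
        row = []
        for s_ord in range(1, 6):
            total = l_ord + s_ord
            row.append(3 if total >= 8 else 2 if total >= 5 else 1)
        rows.append(tuple(row))
    return tuple(rows)


class ConfigError(ValueError):
    """Raised when a risk-model configuration fails validation."""


@dataclass
class RiskModelConfig:
    """All tunable parameters of the scoring pipeline.

    Parameters
    ----------
    likelihood_bounds, severity_bounds
        Lower edges of bands 2..5; scores live on [0, 100] and bands are
        half-open, the top band closed at 100.
    matrix
        5x5 grid (likelihood band x severity band) of levels in {1, 2, 3},
        monotone non-decreasing along both axes.
    raptor_bump
        Whether birds of prey get +1 level.
    crossing_threshold
        Number of observed runway crossings/overflights at which the
        crossing rule triggers (+1 level).
    height_statistic
        How the representative flight height is aggregated from sightings:
        ``"median"`` (count-weighted median, default) or ``"mean"``.
    cluster_statistic
        ``"max"`` (default) or a quantile in (0, 1) of observed group sizes.
    weight_basis
        ``"total_biomass"`` (count x mean mass, default) or
        ``"individual_mass"`` for the comparative-weight numerator.
    """

    likelihood_bounds: tuple[float, ...] = DEFAULT_LIKELIHOOD_BOUNDS
    severity_bounds: tuple[float, ...] = DEFAULT_SEVERITY_BOUNDS
    matrix: tuple[tuple[int, ...], ...] = field(default_factory=default_matrix)
    raptor_bump: bool = True
    crossing_threshold: int = 3
    level_cap: int = 3
    height_statistic: str = "median"
    cluster_statistic: Any = "max"
    weight_basis: str = "total_biomass"
    season_of_month: dict[int, Season] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_OF_MONTH)
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for name, bounds in (
            ("likelihood_bounds", self.likelihood_bounds),
            ("severity_bounds", self.severity_bounds),
        ):
            bounds = tuple(float(b) for b in bounds)
            if len(bounds) != 4:
                raise ConfigError(f"{name} must have 4 thresholds, got {len(bounds)}")
            if not all(b1 < b2 for b1, b2 in zip(bounds, bounds[1:])):
                raise ConfigError(f"{name} must be strictly increasing: {bounds}")
            if not (0 < bounds[0] and bounds[-1] < 100):
                raise ConfigError(f"{name} must lie strictly inside (0, 100)")
            setattr(self, name, bounds)

        matrix = tuple(tuple(int(c) for c in row) for row in self.matrix)
        if len(matrix) != 5 or any(len(row) != 5 for row in matrix):
            raise ConfigError("matrix must be 5x5")
        for row in matrix:
            for cell in row:
                if cell not in (1, 2, 3):
                    raise ConfigError(f"matrix cells must be in {{1,2,3}}, got {cell}")
        for i in range(5):
            for j in range(4):
                if matrix[i][j + 1] < matrix[i][j]:
                    raise ConfigError(
                        "matrix must be monotone non-decreasing in severity"
                    )
                if matrix[j + 1][i] < matrix[j][i]:
                    raise ConfigError(
                        "matrix must be monotone non-decreasing in likelihood"
                    )
        self.matrix = matrix

        if self.crossing_threshold < 1:
            raise ConfigError("crossing_threshold must be a positive integer")
        if self.level_cap != 3:
            raise ConfigError("level_cap must be 3 for the three-level scheme")
        if self.height_statistic not in ("median", "mean"):
            raise ConfigError(
                f"height_statistic must be 'median' or 'mean', got {self.height_statistic!r}"
            )
        if self.cluster_statistic != "max":
            q = float(self.cluster_statistic)
            if not 0 < q <= 1:
                raise ConfigError("cluster_statistic quantile must be in (0, 1]")
            self.cluster_statistic = q
        if self.weight_basis not in ("total_biomass", "individual_mass"):
            raise ConfigError(
                f"weight_basis must be 'total_biomass' or 'individual_mass', "
                f"got {self.weight_basis!r}"
            )
        months = {int(m) for m in self.season_of_month}
        if months != set(range(1, 13)):
            raise ConfigError("season_of_month must cover months 1..12")
        self.season_of_month = {
            int(m): Season(s) for m, s in self.season_of_month.items()
        }

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["matrix"] = [list(row) for row in self.matrix]
        d["likelihood_bounds"] = list(self.likelihood_bounds)
        d["severity_bounds"] = list(self.severity_bounds)
        d["season_of_month"] = {
            str(m): s.value for m, s in self.season_of_month.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RiskModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = dict(data)
        if "matrix" in kwargs:
            kwargs["matrix"] = tuple(tuple(row) for row in kwargs["matrix"])
        for key in ("likelihood_bounds", "severity_bounds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "season_of_month" in kwargs:
            kwargs["season_of_month"] = {
                int(m): Season(s) for m, s in kwargs["season_of_month"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RiskModelConfig":
        """Load a config from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
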