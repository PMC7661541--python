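import itertools

import pytest
import yaml
from hypothesis import given, strategies as st

from birdrisk import (
    Band,
    ConfigError,
    RiskFactors,
    RiskModelConfig,
    adjust,
    band,
    classify,
    default_matrix,
    likelihood,
    score_species,
    severity,
)

from conftest import make_profile

LIKELIHOOD_BOUNDS = (15.0, 30.0, 50.0, 70.0)
SEVERITY_BOUNDS = (4.0, 7.0, 14.0, 40.0)


def band_oracle(score, bounds):
    """Linear scan over band intervals, independent of the implementation."""
    labels = list(Band)
    edges = [0.0, *bounds, 100.0]
    for i in range(5):
        lo, hi = edges[i], edges[i + 1]
        if (lo <= score < hi) or (i == 4 and score == 100.0):
            return labels[i]
    raise AssertionError(f"unbanded score {score}")


class TestFormulas:
    @pytest.mark.parametrize(
        "coeffs,expected",
        [((1.0, 1.0, 0.9), 96.667), ((0.0, 0.1, 0.3), 13.333), ((0.5, 1.0, 0.9), 80.0)],
    )
    def test_likelihood_direct_substitution(self, coeffs, expected):
        assert likelihood(*coeffs) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "args,expected", [((1.0, 1.0), 100.0), ((0.25, 0.05), 15.0), ((0.0, 0.0), 0.0)]
    )
    def test_severity_direct_substitution(self, args, expected):
        assert severity(*args) == pytest.approx(expected)

    def test_out_of_set_coefficient_rejected(self):
        with pytest.raises(ValueError):
            likelihood(0.3, 0.1, 0.3)  # 0.3 is not a cluster coefficient
        with pytest.raises(ValueError):
            likelihood(0.0, 0.2, 0.3)  # 0.2 is not a height coefficient

    def test_severity_arguments_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            severity(1.2, 0.5)
        with pytest.raises(ValueError):
            severity(0.5, -0.1)

    def test_likelihood_attainable_range(self):
        values = [
            likelihood(c, f, a)
            for c in (0.0, 0.2, 0.5, 1.0)
            for f in (0.1, 0.5, 1.0)
            for a in (0.3, 0.6, 0.9)
        ]
        assert min(values) == pytest.approx(100 * 0.4 / 3)
        assert max(values) == pytest.approx(100 * 2.9 / 3)


class TestBanding:
    @pytest.mark.parametrize(
        "score,bounds,expected",
        [
            (70.0, LIKELIHOOD_BOUNDS, Band.very_high),
            (0.0, LIKELIHOOD_BOUNDS, Band.very_low),
            (14.999, LIKELIHOOD_BOUNDS, Band.very_low),
            (15.0, LIKELIHOOD_BOUNDS, Band.low),
            (100.0, LIKELIHOOD_BOUNDS, Band.very_high),
            (14.0, SEVERITY_BOUNDS, Band.high),
            (3.999, SEVERITY_BOUNDS, Band.very_low),
            (4.0, SEVERITY_BOUNDS, Band.low),
            (40.0, SEVERITY_BOUNDS, Band.very_high),
        ],
    )
    def test_threshold_placement(self, score, bounds, expected):
        assert band(score, bounds) is expected

    def test_score_outside_range_rejected(self):
        for bad in (-0.1, 100.1):
            with pytest.raises(ValueError):
                band(bad, LIKELIHOOD_BOUNDS)

    def test_bruteforce_scan_agreement(self):
        for bounds in (LIKELIHOOD_BOUNDS, SEVERITY_BOUNDS):
            for i in range(10_001):
                score = i / 100.0
                assert band(score, bounds) is band_oracle(score, bounds)


class TestClassify:
    def test_extreme_corners(self):
        assert classify(Band.very_high, Band.very_high) == 3
        assert classify(Band.very_low, Band.very_low) == 1

    def test_high_high_is_level_3_under_default_matrix(self):
        assert classify(Band.high, Band.high) == 3

    def test_monotone_over_all_cell_pairs(self):
        bands = list(Band)
        for l1, s1 in itertools.product(bands, repeat=2):
            for l2, s2 in itertools.product(bands, repeat=2):
                if l2.ordinal >= l1.ordinal and s2.ordinal >= s1.ordinal:
                    assert classify(l2, s2) >= classify(l1, s1)

    def test_non_monotone_matrix_rejected(self):
        matrix = [list(row) for row in default_matrix()]
        matrix[4][4], matrix[0][0] = 1, 3
        with pytest.raises(ConfigError, match="monotone"):
            RiskModelConfig(matrix=tuple(tuple(r) for r in matrix))

    def test_matrix_cells_restricted_to_levels(self):
        matrix = [list(row) for row in default_matrix()]
        matrix[2][2] = 4
        with pytest.raises(ConfigError):
            RiskModelConfig(matrix=tuple(tuple(r) for r in matrix))


class TestAdjust:
    def test_raptor_bump(self):
        level, applied = adjust(2, make_profile(is_raptor=True))
        assert level == 3 and applied == ["raptor"]

    def test_cap_at_three(self):
        level, applied = adjust(
            3, make_profile(is_raptor=True, runway_crossings=10)
        )
        assert level == 3 and set(applied) == {"raptor", "runway_crossing"}

    def test_two_bumps_compose(self):
        level, applied = adjust(1, make_profile(is_raptor=True, runway_crossings=5))
        assert level == 3 and len(applied) == 2

    @pytest.mark.parametrize("crossings,expected", [(2, 1), (3, 2), (4, 2)])
    def test_crossing_threshold_default_three(self, crossings, expected):
        level, _ = adjust(1, make_profile(runway_crossings=crossings))
        assert level == expected

    def test_raptor_bump_can_be_disabled(self):
        config = RiskModelConfig(raptor_bump=False)
        level, applied = adjust(1, make_profile(is_raptor=True), config)
        assert level == 1 and applied == []

    @given(
        base=st.integers(min_value=1, max_value=3),
        raptor=st.booleans(),
        crossings=st.integers(min_value=0, max_value=10),
    )
    def test_idempotent_on_cap(self, base, raptor, crossings):
        profile = make_profile(is_raptor=raptor, runway_crossings=crossings)
        once, _ = adjust(base, profile)
        twice, _ = adjust(once, profile)
        assert twice >= once and twice <= 3
        # re-applying from an already-capped level never exceeds the cap
        assert adjust(3, profile)[0] == 3


class TestScoreSpecies:
    def test_maximal_factor_combination(self):
        factors = RiskFactors(1.0, 1.0, 1.0, 1.0, 0.9)
        score = score_species(factors, make_profile())
        assert score.likelihood == pytest.approx(96.667, abs=5e-4)
        assert score.severity == 100.0
        assert score.likelihood_band is Band.very_high
        assert score.severity_band is Band.very_high
        assert score.base_level == 3

    def test_minimal_factor_combination(self):
        factors = RiskFactors(0.01, 0.01, 0.1, 0.0, 0.3)
        score = score_species(factors, make_profile())
        assert score.likelihood == pytest.approx(13.333, abs=5e-4)
        assert score.severity == pytest.approx(1.0)
        assert score.likelihood_band is Band.very_low
        assert score.severity_band is Band.very_low
        assert score.base_level == 1
        assert score.adjusted_level == 1

    def test_raptor_always_at_least_one_above_base(self):
        factors = RiskFactors(0.01, 0.01, 0.1, 0.0, 0.3)
        score = score_species(factors, make_profile(is_raptor=True))
        assert score.adjusted_level == min(3, score.base_level + 1)

    def test_end_to_end_monotone_in_count(self):
        # raising one species' count (others fixed) never lowers its level
        from birdrisk import Zone, assign_factors

        def level_for(count):
            target = make_profile(species_name="target", total_count=count,
                                  total_biomass_g=count * 20.0,
                                  max_cluster_size=25)
            other = make_profile(species_name="other", total_count=500,
                                 total_biomass_g=500 * 100.0,
                                 nearest_zone=Zone.B)
            factors = assign_factors([target, other])
            return score_species(factors["target"], target).adjusted_level

        levels = [level_for(c) for c in (1, 10, 100, 400, 1000, 5000)]
        assert levels == sorted(levels)


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        config = RiskModelConfig(crossing_threshold=5, raptor_bump=False)
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(config.to_dict()), encoding="utf-8")
        loaded = RiskModelConfig.from_file(path)
        assert loaded == config

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("nonsense_key: 1\n", encoding="utf-8")
        with pytest.raises(ConfigError, match="nonsense_key"):
            RiskModelConfig.from_file(path)

    def test_bounds_must_increase(self):
        with pytest.raises(ConfigError):
            RiskModelConfig(likelihood_bounds=(15, 30, 30, 70))
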