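"""Estimator arithmetic: published spot values, conventions, invariants."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fgmc.cohort_classifier import COUNT_COLUMNS, GroupCounts
from fgmc.country_profiles import CountryProfile, ProfileSet
from fgmc.extrapolation import (ScenarioConfig, estimate_all, estimate_risk,
                                estimate_undergone, format_percent,
                                national_summary, potentially_at_risk,
                                round_count, split_risk_types,
                                split_undergone_types)


def _counts(rows):
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "country"
    return GroupCounts(frame)


@pytest.fixture(scope="module")
def published_estimates(profiles, published_counts):
    return estimate_all(published_counts, profiles)


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (8686.667, 8687), (283.631, 284), (2149.641, 2150), (0.5, 1), (2.5, 3),
    ])
    def test_half_away_from_zero(self, value, expected):
        assert round_count(value, "half-away") == expected

    def test_half_even_differs_only_on_ties(self):
        assert round_count(2.5, "half-even") == 2
        assert round_count(2149.641, "half-even") == 2150

    def test_negative_estimates_are_rejected(self):
        with pytest.raises(ValueError):
            round_count(-1.0)


class TestUndergone:
    @pytest.mark.parametrize("country,expected_unrounded,expected", [
        ("Somalia", 8686.667, 8687),     # 8873 x 0.979
        ("Eritrea", 3998.596, 3999),     # 4508 x 0.887
    ])
    def test_spot_values(self, published_estimates, country, expected_unrounded, expected):
        row = published_estimates.loc[country]
        assert row["undergone_unrounded"] == pytest.approx(expected_unrounded, abs=5e-4)
        assert row["undergone"] == expected

    def test_zero_prevalence_gives_zero(self):
        profiles = ProfileSet([CountryProfile(
            country="X", prev_15_49=0.0, prev_15_19=0.0, cut_age_min=0, cut_age_max=5)])
        counts = _counts({"X": {"1a": 100, "1b": 1, "1c": 1, "1x": 0, "2a": 1, "2b": 0}})
        assert estimate_undergone(counts, profiles)["undergone"].item() == 0

    def test_missing_profile_is_a_hard_error(self, profiles):
        counts = _counts({"Atlantis": {c: 1 for c in COUNT_COLUMNS}})
        with pytest.raises(KeyError, match="Atlantis"):
            estimate_undergone(counts, profiles)


class TestUndergoneTypeSplit:
    @pytest.mark.parametrize("country,type3,other", [
        ("Eritrea", 1543, 2456),   # 3998.596 x 0.386 -> 1543; other = 3999 - 1543
        ("Somalia", 6889, 1798),
        ("Iraq", 0, 590),          # assumed-zero typology
    ])
    def test_spot_values(self, published_estimates, country, type3, other):
        row = published_estimates.loc[country]
        assert (row["undergone_type3"], row["undergone_other"]) == (type3, other)

    def test_complement_convention_sums_exactly(self, published_estimates):
        total = (published_estimates["undergone_type3"]
                 + published_estimates["undergone_other"])
        assert (total == published_estimates["undergone"]).all()


class TestPotentiallyAtRisk:
    def test_is_plain_head_count_of_1b_1c_2a(self, published_counts):
        par = potentially_at_risk(published_counts)
        assert par["Eritrea"] == 218 + 10 + 606 == 834
        assert par.sum() == 4763 + 1456 + 9324 == 15543

    def test_all_zero_counts(self):
        counts = _counts({"Somalia": {c: 0 for c in COUNT_COLUMNS}})
        assert potentially_at_risk(counts).sum() == 0


class TestRisk:
    @pytest.mark.parametrize("country,low,high", [
        ("Somalia", 2150, 5683),  # (1630+593)x0.967 / (1630+593+3654)x0.967
        ("Iraq", 116, 284),
    ])
    def test_scenario_spot_values(self, published_estimates, country, low, high):
        row = published_estimates.loc[country]
        assert (row["risk_low"], row["risk_high"]) == (low, high)

    def test_factor_cancels_without_second_generation(self, profiles):
        counts = _counts({"Somalia": {"1a": 0, "1b": 10, "1c": 5, "1x": 0,
                                      "2a": 0, "2b": 3}})
        risk = estimate_risk(counts, profiles)
        assert risk["risk_low"].item() == risk["risk_high"].item()

    def test_continuous_factor_interpolates(self, profiles, published_counts):
        cfg = ScenarioConfig(scenarios={"mid": 0.5})
        mid = estimate_risk(published_counts, profiles, cfg)["risk_mid"]
        both = estimate_risk(published_counts, profiles)
        assert ((both["risk_low"] <= mid) & (mid <= both["risk_high"])).all()

    def test_factor_outside_unit_interval_is_rejected(self, profiles, published_counts):
        with pytest.raises(ValueError):
            estimate_risk(published_counts, profiles, factor=1.5)
        with pytest.raises(ValueError):
            ScenarioConfig(scenarios={"bad": -0.1})


class TestRiskTypeSplit:
    @pytest.mark.parametrize("country,low3,lowo,high3,higho", [
        ("Eritrea", 60, 118, 221, 433),
        ("Somalia", 1634, 516, 4319, 1364),
    ])
    def test_spot_values(self, published_estimates, country, low3, lowo, high3, higho):
        row = published_estimates.loc[country]
        assert (row["risk_low_type3"], row["risk_low_other"],
                row["risk_high_type3"], row["risk_high_other"]) == (low3, lowo, high3, higho)

    def test_independent_rounding_may_drift_from_total_by_one(self, published_estimates):
        # Eritrea low scenario: 60 + 118 = 178 vs rounded total 179.
        row = published_estimates.loc["Eritrea"]
        assert row["risk_low_type3"] + row["risk_low_other"] == 178
        assert row["risk_low"] == 179
        drift = (published_estimates["risk_low_type3"]
                 + published_estimates["risk_low_other"]
                 - published_estimates["risk_low"]).abs()
        assert (drift <= 1).all()

    def test_zero_share_puts_everything_in_other(self, published_estimates):
        row = published_estimates.loc["Iraq"]
        assert row["risk_high_type3"] == 0
        assert row["risk_high_other"] == row["risk_high"]


class TestInvariants:
    def test_low_never_exceeds_high(self, published_estimates):
        assert (published_estimates["risk_low"] <= published_estimates["risk_high"]).all()

    def test_estimates_bounded_by_group_counts(self, published_estimates):
        assert (published_estimates["undergone"] <= published_estimates["1a"]).all()
        assert (published_estimates["risk_high"]
                <= published_estimates["potentially_at_risk"]).all()

    def test_unit_prevalence_limit(self, published_counts, profiles):
        """With every prevalence at 1, undergone = N1a and high risk = PAR."""
        from dataclasses import replace
        saturated = ProfileSet([
            replace(p, prev_15_49=1.0, prev_15_19=1.0) for p in profiles.values()])
        est = estimate_all(published_counts, saturated)
        assert (est["undergone"] == est["1a"]).all()
        assert (est["risk_high"] == est["potentially_at_risk"]).all()

    @given(n1a=st.integers(0, 10000), prev=st.floats(0, 1),
           bump=st.floats(0.0, 0.5), extra=st.integers(0, 50))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_prevalence_and_counts(self, n1a, prev, bump, extra):
        def undergone(n, p):
            profiles = ProfileSet([CountryProfile(
                country="X", prev_15_49=p, prev_15_19=p, cut_age_min=0, cut_age_max=5)])
            counts = _counts({"X": {"1a": n, "1b": 0, "1c": 0, "1x": 0, "2a": 0, "2b": 0}})
            return estimate_undergone(counts, profiles)["undergone"].item()
        base = undergone(n1a, prev)
        assert undergone(n1a + extra, prev) >= base
        assert undergone(n1a, min(1.0, prev + bump)) >= base


class TestNationalSummary:
    def test_headline_shares_render_as_published(self, published_estimates,
                                                 published_counts):
        summary = national_summary(published_estimates, published_counts)
        assert format_percent(summary.undergone_share) == "38.9 %"
        assert format_percent(summary.type3_share_of_undergone) == "52.8 %"
        assert summary.potentially_at_risk_total == 15543

    def test_zero_undergone_gives_zero_share(self, profiles):
        counts = _counts({"Somalia": {c: 0 for c in COUNT_COLUMNS}})
        est = estimate_all(counts, profiles)
        summary = national_summary(est, counts)
        assert summary.undergone_share == 0.0
        assert summary.type3_share_of_undergone == 0.0
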