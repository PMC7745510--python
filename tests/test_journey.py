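"""Simulator behaviour: roster composition, true-event draws, journey
propagation semantics, register-row generation and dataset round-trips."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from hmisdq.journey import (
    DEFAULT_ROSTER,
    Dataset,
    DistrictSpec,
    JourneyParams,
    RosterConfig,
    SERVICE_AREAS,
    SOURCES,
    DatasetError,
    counts_to_long,
    counts_to_wide,
    default_indicators,
    indicators_frame,
    propagate_journey,
    read_dataset,
    roster_frame,
    simulate_register_rows,
    simulate_roster,
    simulate_true_events,
    write_dataset,
)

from tests.conftest import SMALL_ROSTER


class TestRoster:
    def test_default_composition_counts(self):
        roster = simulate_roster(DEFAULT_ROSTER, seed=3)
        levels = pd.Series([p.level for p in roster]).value_counts()
        assert len(roster) == 115
        assert levels["dispensary"] == 67
        assert levels["health_centre"] == 36
        assert levels["hospital"] == 12
        districts = pd.Series([p.district for p in roster]).value_counts()
        assert districts["Kinondoni"] == 18 and districts["Mbulu"] == 8

    def test_empty_config_gives_empty_roster(self):
        cfg = RosterConfig(
            districts=(), level_counts={}, ownership_counts={}, offer_rates={}
        )
        assert simulate_roster(cfg, seed=0) == []

    def test_same_seed_reproduces_roster_exactly(self):
        a = simulate_roster(DEFAULT_ROSTER, seed=5)
        b = simulate_roster(DEFAULT_ROSTER, seed=5)
        assert a == b

    def test_invalid_enum_rejected(self):
        with pytest.raises(ValueError):
            RosterConfig(
                districts=(DistrictSpec("X", "urban", 1),),
                level_counts={"clinic": 1},
                ownership_counts={"government": 1},
                offer_rates={},
            )

    def test_every_facility_offers_something(self):
        roster = simulate_roster(DEFAULT_ROSTER, seed=2)
        assert all(p.offered_service_areas for p in roster)


class TestTrueEvents:
    def test_zero_volume_means_zero_counts(self, small_roster, indicators):
        params = JourneyParams(mean_monthly_volume=0.0)
        truth = simulate_true_events(small_roster, indicators, ("2015-01", "2015-03"), params)
        assert (truth["true_count"] == 0).all()

    def test_cardinality_one_facility_one_indicator(self, small_roster, indicators):
        ind = [d for d in indicators if d.indicator_id == "OPD-1"]
        truth = simulate_true_events(small_roster[:1], ind, ("2015-01", "2015-12"), JourneyParams())
        assert len(truth) == 12

    def test_unoffered_service_area_emits_no_rows(self, indicators):
        cfg = RosterConfig(
            districts=(DistrictSpec("Solo", "rural", 1),),
            level_counts={"dispensary": 1},
            ownership_counts={"government": 1},
            offer_rates={"OPD": 1.0},
        )
        roster = simulate_roster(cfg, seed=0)
        truth = simulate_true_events(roster, indicators, ("2015-01", "2015-02"), JourneyParams())
        assert set(truth["service_area"]) == {"OPD"}

    def test_monte_carlo_mean_matches_configured(self, small_roster, indicators):
        # >10k indicator-months at mean 50: sample mean within 3 SE
        params = JourneyParams(mean_monthly_volume=50.0, seed=3)
        truth = simulate_true_events(small_roster, indicators, ("2014-01", "2017-09"), params)
        n = len(truth)
        assert n > 9000
        se = np.sqrt(50.0 / n)
        assert abs(truth["true_count"].mean() - 50.0) < 3 * se

    def test_facility_draws_invariant_to_roster_growth(self, indicators):
        period = ("2015-01", "2015-06")
        one = simulate_true_events(
            simulate_roster(SMALL_ROSTER, seed=7)[:1], indicators, period, JourneyParams(seed=1)
        )
        many = simulate_true_events(
            simulate_roster(SMALL_ROSTER, seed=7), indicators, period, JourneyParams(seed=1)
        )
        fid = one["facility_id"].iloc[0]
        sub = many[many["facility_id"] == fid].reset_index(drop=True)
        pdt.assert_frame_equal(one, sub)


class TestPropagation:
    def test_lossless_journey_all_sources_identical(self, lossless_counts):
        for src in SOURCES:
            assert lossless_counts[f"{src}_present"].all()
            assert (lossless_counts[src] == lossless_counts["register"]).all()

    def test_forced_transmission_loss_hides_district_and_dhis2(self, small_roster, indicators):
        params = JourneyParams(p_transmission_loss=1.0, seed=5)
        truth = simulate_true_events(small_roster, indicators, ("2015-01", "2015-03"), params)
        counts = propagate_journey(truth, params)
        assert not counts["district_report_present"].any()
        assert not counts["dhis2_present"].any()
        assert counts["district_report"].isna().all()
        assert counts["facility_report_present"].all()

    def test_absent_facility_report_suppresses_downstream(self, small_roster, indicators):
        params = JourneyParams(p_facility_report_absent=0.5, seed=5)
        truth = simulate_true_events(small_roster, indicators, ("2015-01", "2015-06"), params)
        counts = propagate_journey(truth, params)
        absent = ~counts["facility_report_present"]
        assert absent.any() and (~absent).any()
        assert not counts.loc[absent, "district_report_present"].any()
        assert not counts.loc[absent, "dhis2_present"].any()

    def test_absent_register_leaves_report_present(self, small_roster, indicators):
        params = JourneyParams(p_register_absent=1.0, seed=5)
        truth = simulate_true_events(small_roster, indicators, ("2015-01", "2015-03"), params)
        counts = propagate_journey(truth, params)
        assert not counts["register_present"].any()
        assert counts["facility_report_present"].all()

    def test_binomial_thinning_pooled_ratio(self, thinned_counts):
        counts, params = thinned_counts
        reg = counts["register"].sum()
        tally = counts["tally"].sum()
        r = 1.0 - params.p_register_miss
        se = np.sqrt(params.p_register_miss / (r**3 * tally))
        assert abs(tally / reg - 1.0 / r) < 3 * se

    def test_counts_nonnegative_integers(self, small_roster, indicators):
        from hmisdq.journey import preset_typical

        params = preset_typical(seed=9)
        truth = simulate_true_events(small_roster, indicators, ("2015-01", "2015-06"), params)
        counts = propagate_journey(truth, params)
        for src in SOURCES:
            vals = counts[src].dropna()
            assert (vals >= 0).all()
            assert (vals.astype(float) % 1 == 0).all()

    def test_deterministic_given_seed(self, small_roster, indicators):
        from hmisdq.journey import preset_typical

        params = preset_typical(seed=4)
        truth = simulate_true_events(small_roster, indicators, ("2015-01", "2015-06"), params)
        a = propagate_journey(truth, params)
        b = propagate_journey(truth, params)
        pdt.assert_frame_equal(a, b)


class TestRegisterRows:
    def test_zero_blank_rate_emits_no_blanks(self, small_roster):
        rows = simulate_register_rows(small_roster[:2], ("2015-01", "2015-03"), seed=1)
        for col in ("sex", "age", "weight", "height", "diagnosis", "yes_no_code"):
            assert (rows[col] != "").all()

    def test_forced_invalid_yes_no_codes(self, small_roster):
        rows = simulate_register_rows(
            small_roster[:2],
            ("2015-01", "2015-02"),
            error_rates={"yes_no_code": {"invalid": 1.0}},
            seed=1,
        )
        assert not rows["yes_no_code"].isin(["N", "H"]).any()

    def test_blank_rate_recovered_within_3se(self, small_roster):
        p = 0.3
        rows = simulate_register_rows(
            small_roster, ("2014-01", "2016-12"), error_rates={"weight": {"blank": p}}, seed=2
        )
        n = len(rows)
        assert n > 10000
        frac = (rows["weight"] == "").mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_unknown_field_rejected(self, small_roster):
        with pytest.raises(ValueError, match="unknown fields"):
            simulate_register_rows(
                small_roster[:1], ("2015-01", "2015-01"), error_rates={"bmi": {"blank": 0.1}}
            )


class TestDatasetIO:
    def test_round_trip_identity(self, tmp_path, lossless_counts, small_roster, indicators):
        rows = simulate_register_rows(
            small_roster[:2], ("2015-01", "2015-02"),
            error_rates={"weight": {"blank": 0.3}}, seed=3,
        )
        ds = Dataset(
            counts=lossless_counts,
            roster=roster_frame(small_roster),
            indicators=indicators_frame(indicators),
            register_rows=rows,
        )
        write_dataset(ds, tmp_path)
        back = read_dataset(tmp_path)
        pdt.assert_frame_equal(
            counts_to_long(ds.counts), counts_to_long(back.counts)
        )
        pdt.assert_frame_equal(ds.roster, back.roster)
        key = ["facility_id", "service_area", "month", "row_id"]
        a = rows.sort_values(key, kind="mergesort").reset_index(drop=True)
        b = back.register_rows.sort_values(key, kind="mergesort").reset_index(drop=True)
        pdt.assert_frame_equal(a, b[a.columns])

    def test_unknown_source_label_rejected_with_row(self, tmp_path, lossless_counts, small_roster, indicators):
        ds = Dataset(lossless_counts, roster_frame(small_roster), indicators_frame(indicators))
        write_dataset(ds, tmp_path)
        counts = pd.read_csv(tmp_path / "counts.csv")
        counts.loc[3, "source"] = "registry"
        counts.to_csv(tmp_path / "counts.csv", index=False)
        with pytest.raises(DatasetError, match="row 3.*registry"):
            read_dataset(tmp_path)

    def test_negative_value_rejected(self, tmp_path, lossless_counts, small_roster, indicators):
        ds = Dataset(lossless_counts, roster_frame(small_roster), indicators_frame(indicators))
        write_dataset(ds, tmp_path)
        counts = pd.read_csv(tmp_path / "counts.csv")
        counts.loc[5, "value"] = -3
        counts.to_csv(tmp_path / "counts.csv", index=False)
        with pytest.raises(DatasetError, match="row 5"):
            read_dataset(tmp_path)

    def test_long_wide_conversion_is_inverse(self, lossless_counts):
        wide = counts_to_wide(counts_to_long(lossless_counts))
        canon = lossless_counts.sort_values(
            ["facility_id", "service_area", "indicator_id", "month"], kind="mergesort"
        ).reset_index(drop=True)
        pdt.assert_frame_equal(wide, canon[wide.columns])
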