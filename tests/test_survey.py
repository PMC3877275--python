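"""Survey preparation: CPUE, diets, regressions, profiles, temperatures."""

import numpy as np
import pandas as pd
import pytest

from growthscape import survey
from growthscape.survey import (
    EDRegression,
    FishObservation,
    build_vertical_profiles,
    compute_cpue,
    fit_ed_lipid_regression,
    mean_individual_biomass,
    predict_ed_from_lipid,
    prep_temperature,
    select_main_prey,
    station_prey_energy,
    weighted_diet_composition,
)


class TestCPUE:
    def test_direct_evaluation(self):
        obs = FishObservation("A", 50, 1000.0, 50.0)
        assert compute_cpue(obs) == pytest.approx(0.001)

    def test_zero_catch_and_proportionality(self):
        assert compute_cpue(FishObservation("A", 0, 500.0, 50.0)) == 0.0
        c1 = compute_cpue(FishObservation("A", 40, 1000.0, 50.0))
        c2 = compute_cpue(FishObservation("A", 40, 2000.0, 50.0))
        assert c1 == pytest.approx(2 * c2)

    def test_midwater_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="midwater"):
            out = compute_cpue(FishObservation("A", 10, 1000.0, 50.0, tow_type="midwater"))
        assert np.isnan(out)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            compute_cpue(FishObservation("A", 10, 0.0, 50.0))


class TestWeightedDiet:
    @staticmethod
    def _frames(pcts_by_station, cpues):
        diets = pd.DataFrame(
            [
                {"station_id": sid, "taxon": t, "percent_volume": p}
                for sid, comp in pcts_by_station.items()
                for t, p in comp.items()
            ]
        )
        cp = pd.DataFrame(
            {"station_id": list(cpues), "cpue": list(cpues.values())}
        )
        return diets, cp

    def test_single_station_passthrough(self):
        diets, cp = self._frames({"A": {"x": 60.0, "y": 40.0}}, {"A": 0.02})
        mean = weighted_diet_composition(diets, cp)
        assert mean["x"] == pytest.approx(60.0)
        assert mean["y"] == pytest.approx(40.0)

    def test_three_to_one_blend_matches_hand_computation(self):
        diets, cp = self._frames(
            {"A": {"x": 80.0, "y": 20.0}, "B": {"x": 20.0, "y": 80.0}},
            {"A": 0.03, "B": 0.01},
        )
        mean = weighted_diet_composition(diets, cp)
        assert mean["x"] == pytest.approx(0.75 * 80 + 0.25 * 20)
        assert mean["y"] == pytest.approx(0.75 * 20 + 0.25 * 80)

    def test_all_zero_cpue_falls_back_to_unweighted(self):
        diets, cp = self._frames(
            {"A": {"x": 100.0}, "B": {"x": 50.0, "y": 50.0}},
            {"A": 0.0, "B": 0.0},
        )
        with pytest.warns(UserWarning):
            mean = weighted_diet_composition(diets, cp)
        assert mean["x"] == pytest.approx(75.0)


class TestMainPreySelection:
    def test_warm_year_cumulative_column(self, table1_warm):
        out = select_main_prey(table1_warm)
        assert list(out["taxon"]) == list(table1_warm.index)
        assert out["cumulative_pct"].iloc[-1] == 91.4
        assert out.loc[out["taxon"] == "Acartia clausi", "cumulative_pct"].item() == 89.7

    def test_cold_year_cumulative_column(self, table1_cold):
        out = select_main_prey(table1_cold)
        assert out["cumulative_pct"].iloc[-1] == 93.4
        assert (
            out.loc[out["taxon"] == "Neocalanus plumchrus", "cumulative_pct"].item()
            == 90.5
        )

    def test_single_dominant_taxon(self):
        out = select_main_prey(pd.Series({"only": 100.0}))
        assert len(out) == 1
        assert np.isnan(out["cumulative_pct"].iloc[0])  # first row left blank

    def test_stops_below_two_percent_once_target_met(self):
        comp = pd.Series({"a": 60.0, "b": 35.0, "c": 1.9, "d": 1.5})
        out = select_main_prey(comp)
        assert list(out["taxon"]) == ["a", "b"]

    def test_continues_past_floor_until_target(self):
        comp = pd.Series({"a": 60.0, "b": 28.0, "c": 1.9, "d": 1.5})
        out = select_main_prey(comp)
        assert list(out["taxon"]) == ["a", "b", "c", "d"]

    def test_empty_composition(self):
        assert select_main_prey(pd.Series(dtype=float)).empty


class TestEDRegression:
    def test_collinear_pairs_give_r2_one(self):
        pairs = [(l, 19.3 + 0.41 * l) for l in (5.0, 10.0, 20.0, 30.0)]
        reg = fit_ed_lipid_regression(pairs)
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(19.3)
        assert reg.slope == pytest.approx(0.41)

    def test_parameter_recovery_under_noise(self):
        rng = np.random.default_rng(42)
        lipid = rng.uniform(5, 40, 40)
        ed = 19.3 + 0.41 * lipid + rng.normal(0, 0.05, 40)
        reg = fit_ed_lipid_regression(list(zip(lipid, ed)))
        assert reg.intercept == pytest.approx(19.3, abs=0.1)
        assert reg.slope == pytest.approx(0.41, abs=0.01)
        assert reg.r_squared > 0.99

    def test_prediction_is_linear(self):
        reg = EDRegression(19.3, 0.41, 0.98, 0.1)
        assert predict_ed_from_lipid(0.0, reg) == pytest.approx(19.3)
        assert predict_ed_from_lipid(10.0, reg) == pytest.approx(23.4)
        d = predict_ed_from_lipid(20.0, reg) - predict_ed_from_lipid(10.0, reg)
        assert d == pytest.approx(0.41 * 10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_ed_lipid_regression([(5.0, 20.0), (10.0, 22.0)])
        with pytest.raises(ValueError):
            fit_ed_lipid_regression([(5.0, 20.0)] * 4)


class TestStationPreyEnergy:
    def test_single_and_equal_mixtures(self):
        assert station_prey_energy({"a": 1.0}, {"a": 4.2}).prey_ed == pytest.approx(4.2)
        pe = station_prey_energy({"a": 1.0, "b": 1.0}, {"a": 2.0, "b": 4.0})
        assert pe.prey_ed == pytest.approx(3.0)

    def test_matches_brute_force_dot_product(self):
        rng = np.random.default_rng(3)
        biom = {f"t{i}": float(b) for i, b in enumerate(rng.uniform(0, 2, 8))}
        eds = {f"t{i}": float(e) for i, e in enumerate(rng.uniform(2, 6, 8))}
        pe = station_prey_energy(biom, eds)
        total = sum(biom.values())
        expect = sum(biom[t] / total * eds[t] for t in biom)
        assert pe.prey_ed == pytest.approx(expect, rel=1e-12)
        assert min(eds.values()) <= pe.prey_ed <= max(eds.values())
        assert sum(pe.biomass_shares.values()) == pytest.approx(1.0)

    def test_zero_biomass_station_flagged(self):
        with pytest.raises(ValueError, match="zero total"):
            station_prey_energy({"a": 0.0}, {"a": 4.0}, station_id="S1")


class TestMeanIndividualBiomass:
    def test_division_and_order_invariance(self):
        w = [0.004, 0.006, 0.01, 0.03]
        assert mean_individual_biomass(w, 10) == pytest.approx(0.005)
        assert mean_individual_biomass(w[::-1], 10) == pytest.approx(0.005)
        assert mean_individual_biomass([0.02], 1) == pytest.approx(0.02)
        with pytest.raises(ValueError):
            mean_individual_biomass(w, 0)


class TestVerticalProfiles:
    @staticmethod
    def _tow(tow_id, taxon, period, strata):
        return pd.DataFrame(
            [
                {"tow_id": tow_id, "taxon": taxon, "period": period,
                 "depth_top_m": a, "depth_bottom_m": b, "abundance": n}
                for a, b, n in strata
            ]
        )

    def test_uniform_within_stratum(self):
        tows = self._tow(1, "cope", "day", [(0, 20, 10.0), (20, 100, 0.0)])
        tows = pd.concat([tows, self._tow(1, "cope", "night", [(0, 100, 1.0)])])
        out = build_vertical_profiles(tows, column_depth_m=100)
        day = out[(out["taxon"] == "cope") & (out["period"] == "day")]
        assert day["fraction"].iloc[:20].unique() == pytest.approx([0.05])
        assert (day["fraction"].iloc[20:] == 0).all()
        assert day["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_average_across_tows(self):
        t1 = self._tow(1, "x", "day", [(0, 50, 2.0)])
        t2 = self._tow(2, "x", "day", [(50, 100, 2.0)])
        night = self._tow(1, "x", "night", [(0, 100, 1.0)])
        out = build_vertical_profiles(pd.concat([t1, t2, night]), column_depth_m=100)
        day = out[(out["taxon"] == "x") & (out["period"] == "day")]
        assert day["fraction"].unique() == pytest.approx([0.01])

    def test_missing_taxon_gets_uniform_with_warning(self):
        tows = self._tow(1, "x", "day", [(0, 0, 0.0)])
        with pytest.warns(UserWarning, match="uniform"):
            out = build_vertical_profiles(tows, column_depth_m=50)
        assert out["fraction"].iloc[:50].unique() == pytest.approx([0.02])

    def test_genus_average_fallback(self):
        a = self._tow(1, "Thysanoessa raschii", "day", [(0, 50, 4.0)])
        b = self._tow(2, "Thysanoessa inermis", "day", [(50, 100, 4.0)])
        rare = self._tow(3, "Thysanoessa inspinata", "day", [(0, 100, 0.0)])
        night = pd.concat(
            [self._tow(4, t, "night", [(0, 100, 1.0)])
             for t in ("Thysanoessa raschii", "Thysanoessa inermis",
                       "Thysanoessa inspinata")]
        )
        out = build_vertical_profiles(
            pd.concat([a, b, rare, night]),
            column_depth_m=100,
            genus_average={"Thysanoessa inspinata": "Thysanoessa"},
        )
        insp = out[(out["taxon"] == "Thysanoessa inspinata") & (out["period"] == "day")]
        # genus mean of a shallow and a deep member: flat at 1/100
        assert insp["fraction"].to_numpy() == pytest.approx(np.full(100, 0.01))


class TestTemperaturePrep:
    @staticmethod
    def _profile(sid, depths, temps):
        return pd.DataFrame({"station_id": sid, "depth_m": depths, "temp_C": temps})

    @staticmethod
    def _stations(rows):
        return pd.DataFrame(rows, columns=["station_id", "lon", "lat", "bottom_depth"])

    def test_constant_and_linear_profiles(self):
        temps = pd.concat([
            self._profile("A", np.arange(40), np.full(40, 8.0)),
            self._profile("B", [0, 30], [10.0, 4.0]),
        ])
        stations = self._stations([("A", -165, 57, 40), ("B", -166, 57, 40)])
        summary, bins = prep_temperature(temps, stations)
        s = summary.set_index("station_id")["upper30_mean_C"]
        assert s["A"] == pytest.approx(8.0)
        # linear 10 -> 4 over 0-30 m sampled at 1-m bins 0..29
        assert s["B"] == pytest.approx(np.mean(10 + (4 - 10) * np.arange(30) / 30))

    def test_gap_interpolation(self):
        temps = self._profile("A", [0, 10], [6.0, 4.0])
        stations = self._stations([("A", -165, 57, 20)])
        _, bins = prep_temperature(temps, stations)
        b = bins.set_index("depth_m")["temp_C"]
        assert b[5] == pytest.approx(5.0)

    def test_missing_station_filled_from_nearest_similar_depth(self):
        temps = pd.concat([
            self._profile("A", np.arange(50), np.full(50, 6.0)),
            self._profile("B", np.arange(50), np.full(50, 9.0)),
        ])
        stations = self._stations(
            [("A", -165.0, 57.0, 50), ("B", -170.0, 60.0, 50), ("C", -165.2, 57.1, 52)]
        )
        summary, _ = prep_temperature(temps, stations)
        s = summary.set_index("station_id")["upper30_mean_C"]
        assert s["C"] == pytest.approx(6.0)  # nearest donor is A

    def test_no_donor_excluded_with_warning(self):
        temps = self._profile("A", np.arange(30), np.full(30, 6.0))
        stations = self._stations([("A", -165, 57, 30), ("D", -166, 57, 150)])
        with pytest.warns(UserWarning, match="no donor"):
            summary, _ = prep_temperature(temps, stations)
        assert list(summary["station_id"]) == ["A"]

    def test_idempotent_on_own_output(self, warm_bundle):
        s1, bins = prep_temperature(warm_bundle.temperature_profiles, warm_bundle.stations)
        s2, bins2 = prep_temperature(bins, warm_bundle.stations)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(
            bins.reset_index(drop=True), bins2.reset_index(drop=True)
        )


class TestFishEnergySummary:
    def test_weighted_mean_matches_brute_force(self):
        obs = [
            FishObservation("A", 100, 1000.0, 50.0, fish_ed=(4.0, 4.2)),
            FishObservation("B", 300, 1000.0, 50.0, fish_ed=(5.0,)),
        ]
        vbar, _ = survey.fish_energy_summary(obs)
        w_a = (100 / 50000) * 2
        w_b = (300 / 50000) * 1
        assert vbar == pytest.approx((w_a * 4.1 + w_b * 5.0) / (w_a + w_b))

    def test_equal_weights_midpoint(self):
        obs = [
            FishObservation("A", 100, 1000.0, 50.0, fish_ed=(4.0,)),
            FishObservation("B", 100, 1000.0, 50.0, fish_ed=(5.0,)),
        ]
        assert survey.fish_energy_summary(obs)[0] == pytest.approx(4.5)

    def test_no_processed_fish_rejected(self):
        with pytest.raises(ValueError):
            survey.fish_energy_summary([FishObservation("A", 10, 1000.0, 50.0)])
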