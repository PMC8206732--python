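import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wheatclim as wc
from wheatclim.crop import (
    grain_set_factor,
    soil_water_update,
    vernalization_effectiveness,
)


class TestThermalTime:
    @pytest.mark.parametrize(
        "tmin,tmax,base,expected",
        [(2, 10, 0, 6.0), (-5, -1, 0, 0.0), (-2, 6, 0, 2.0), (5, 15, 4, 6.0)],
    )
    def test_mean_above_base_floored(self, tmin, tmax, base, expected):
        assert wc.thermal_time_increment(tmin, tmax, base) == expected

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            wc.thermal_time_increment(10, 2, 0)


class TestCo2RueFactor:
    def test_baseline_identity(self):
        assert wc.co2_rue_factor(364.0) == 1.0

    def test_doubling_gives_thirty_percent(self):
        assert wc.co2_rue_factor(728.0) == pytest.approx(1.30)

    def test_rcp85_concentration(self):
        # Linear rule: 1 + 0.3 * 177/364.
        assert wc.co2_rue_factor(541.0) == pytest.approx(1.0 + 0.3 * 177.0 / 364.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            wc.co2_rue_factor(0.0)


class TestWaterStressFactor:
    @pytest.mark.parametrize("ftsw,expected", [(1.0, 1.0), (0.0, 0.0), (0.25, 0.5), (0.5, 1.0)])
    def test_piecewise_linear_choking(self, ftsw, expected):
        assert wc.water_stress_factor(ftsw, threshold=0.5) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0, max_value=1),
        b=st.floats(min_value=0, max_value=1),
    )
    def test_monotone_non_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert wc.water_stress_factor(lo) <= wc.water_stress_factor(hi)


class TestPotentialEt:
    def test_no_energy_no_et(self):
        assert wc.potential_et(0.0, 15.0) == 0.0

    def test_reference_value(self):
        # Hand evaluation: s(15 C) = 0.10978 kPa/C, s/(s+gamma) = 0.6245,
        # 1.26 * 0.6245 * (0.6*20)/2.45 = 3.85 mm.
        assert wc.potential_et(20.0, 15.0) == pytest.approx(3.85, abs=0.05)

    def test_linear_in_radiation(self):
        assert wc.potential_et(40.0, 15.0) == pytest.approx(2 * wc.potential_et(20.0, 15.0))

    def test_increases_with_temperature(self):
        assert wc.potential_et(20.0, 25.0) > wc.potential_et(20.0, 5.0)


class TestVernalization:
    def test_full_effectiveness_on_plateau(self, cultivar):
        for t in (0.0, 5.0, 12.0):
            assert vernalization_effectiveness(t, cultivar) == 1.0

    def test_no_effect_when_hot(self, cultivar):
        assert vernalization_effectiveness(30.0, cultivar) == 0.0

    def test_edges_fractional(self, cultivar):
        assert 0 < vernalization_effectiveness(-2.0, cultivar) < 1
        assert 0 < vernalization_effectiveness(14.0, cultivar) < 1

    def test_saturation_after_vern_full_days(self, cultivar):
        # vern_full days at optimum accumulate exactly to 1.
        progress = sum(
            vernalization_effectiveness(5.0, cultivar) / cultivar.vern_full
            for _ in range(int(cultivar.vern_full))
        )
        assert progress == pytest.approx(1.0)


class TestGrainSetFactor:
    def test_tolerant_cultivar_unaffected(self, cultivar):
        assert grain_set_factor(0.9, 50.0, cultivar) == 1.0

    def test_heat_sensitive_no_exposure(self, cultivar):
        heat = dataclasses.replace(cultivar, heat_sensitive=True)
        assert grain_set_factor(0.5, 0.0, heat) == 1.0

    def test_drought_linear_response(self, cultivar):
        drought = dataclasses.replace(cultivar, drought_sensitive=True)
        # Mean daily choking factor 0.8 -> mean stress 0.2 -> 1 - 1.0*0.2.
        assert grain_set_factor(0.2, 0.0, drought) == pytest.approx(0.8)

    def test_floor(self, cultivar):
        drought = dataclasses.replace(cultivar, drought_sensitive=True)
        assert grain_set_factor(1.0, 0.0, drought) == cultivar.grain_set_floor


class TestSoilWaterUpdate:
    def test_no_flux_no_change(self, soil):
        sw = np.full(soil.n_layers, soil.layer_capacity)
        before = sw.copy()
        evap, transp, drainage = soil_water_update(
            sw, soil.layer_capacity, 0.0, 0.0, 0.0, 2, soil.n_layers
        )
        assert (evap, transp, drainage) == (0.0, 0.0, 0.0)
        assert np.array_equal(sw, before)

    def test_saturated_profile_overflows(self, soil):
        sw = np.full(soil.n_layers, soil.layer_capacity)
        _, _, drainage = soil_water_update(
            sw, soil.layer_capacity, 10.0, 0.0, 0.0, 2, soil.n_layers
        )
        assert drainage == pytest.approx(10.0)

    def test_empty_profile_caps_extraction(self, soil):
        sw = np.zeros(soil.n_layers)
        evap, transp, _ = soil_water_update(
            sw, soil.layer_capacity, 0.0, 2.0, 5.0, 2, soil.n_layers
        )
        assert evap == 0.0 and transp == 0.0
        assert np.all(sw == 0.0)

    def test_infiltration_fills_top_down(self, soil):
        sw = np.zeros(soil.n_layers)
        cap = soil.layer_capacity
        soil_water_update(sw, cap, 1.5 * cap, 0.0, 0.0, 2, soil.n_layers)
        assert sw[0] == pytest.approx(cap)
        assert sw[1] == pytest.approx(0.5 * cap)
        assert np.all(sw[2:] == 0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        rain=st.floats(min_value=0, max_value=50),
        evap=st.floats(min_value=0, max_value=8),
        transp=st.floats(min_value=0, max_value=8),
        fill=st.floats(min_value=0, max_value=1),
    )
    def test_daily_closure_and_bounds(self, rain, evap, transp, fill):
        cap = 5.9
        sw = np.full(10, fill * cap)
        before = sw.sum()
        e, t, d = soil_water_update(sw, cap, rain, evap, transp, 2, 8)
        assert rain - (sw.sum() - before) - e - t - d == pytest.approx(0.0, abs=1e-9)
        assert np.all(sw >= 0) and np.all(sw <= cap + 1e-12)


class TestRunSeason:
    def test_deterministic(self, dry_weather, cultivar, soil, dry_site):
        r1 = wc.run_season(dry_weather[0], cultivar, soil, 363.8, latitude=dry_site.latitude)
        r2 = wc.run_season(dry_weather[0], cultivar, soil, 363.8, latitude=dry_site.latitude)
        assert r1 == r2

    def test_water_limitation_only_removes_yield(self, dry_weather, cultivar, soil, dry_site):
        for s in dry_weather:
            pot = wc.run_season(s, cultivar, soil, 363.8, water_limited=False,
                                latitude=dry_site.latitude)
            lim = wc.run_season(s, cultivar, soil, 363.8, water_limited=True,
                                latitude=dry_site.latitude)
            assert lim.yield_t_ha <= pot.yield_t_ha

    def test_huge_full_soil_recovers_potential(self, dry_weather, cultivar, dry_site):
        big = wc.SoilProfile(awc_total=5000.0, n_layers=30)
        for s in dry_weather[:4]:
            pot = wc.run_season(s, cultivar, big, 363.8, water_limited=False,
                                latitude=dry_site.latitude)
            lim = wc.run_season(s, cultivar, big, 363.8, water_limited=True,
                                latitude=dry_site.latitude)
            assert lim.yield_t_ha == pytest.approx(pot.yield_t_ha, rel=1e-9)

    def test_warming_advances_anthesis(self, dry_site, cultivar, soil):
        scen = wc.ClimateScenario("w2", 363.8, delta_tmean=2.0)
        base = wc.generate_weather(dry_site, 3, seed=31)
        warm = wc.generate_weather(wc.apply_scenario(dry_site, scen), 3, seed=31)
        for b, w in zip(base, warm):
            rb = wc.run_season(b, cultivar, soil, 363.8, latitude=dry_site.latitude)
            rw = wc.run_season(w, cultivar, soil, 363.8, latitude=dry_site.latitude)
            assert rw.anthesis_doy < rb.anthesis_doy

    def test_interception_bounded_by_incident(self, dry_weather, cultivar, soil, dry_site):
        for s in dry_weather:
            r = wc.run_season(s, cultivar, soil, 363.8, latitude=dry_site.latitude)
            assert r.intercepted_rad <= 0.5 * s.srad.sum()

    def test_water_balance_closure(self, dry_weather, cultivar, soil, dry_site):
        for s in dry_weather:
            r = wc.run_season(s, cultivar, soil, 363.8, latitude=dry_site.latitude)
            assert r.water_balance_error <= 1e-9

    def test_diagnostics_ranges(self, dry_weather, cultivar, soil, dry_site):
        r = wc.run_season(dry_weather[0], cultivar, soil, 363.8, latitude=dry_site.latitude)
        assert not r.failed
        assert 0 <= r.swd_anthesis <= soil.awc_total
        assert r.yield_t_ha >= 0
        assert r.season_et > 0

    def test_failed_season_flagged(self, dry_site, cultivar, soil):
        # Chop the series right after sowing: anthesis cannot be reached.
        s = wc.generate_weather(dry_site, 1, seed=5)[0]
        short = wc.WeatherSeries(
            s.site_id, s.harvest_year, s.doy[:40], s.tmin[:40], s.tmax[:40],
            s.rain[:40], s.srad[:40],
        )
        r = wc.run_season(short, cultivar, soil, 363.8, latitude=dry_site.latitude)
        assert r.failed and "anthesis" in r.failure_reason

    def test_missing_sowing_day_rejected(self, dry_weather, cultivar, soil):
        with pytest.raises(ValueError, match="sowing"):
            wc.run_season(dry_weather[0], cultivar, soil, 363.8, sowing_doy=250)


class TestRunCultivarSet:
    def test_stress_ordering(self, dry_weather, wet_weather, cultivar, soil, dry_site, wet_site):
        for series, site in [(s, dry_site) for s in dry_weather] + [
            (s, wet_site) for s in wet_weather
        ]:
            r = wc.run_cultivar_set(series, cultivar, soil, 363.8, latitude=site.latitude)
            assert r.yw <= r.yp
            assert r.ywd <= r.yw
            assert r.ywh <= r.yw

    def test_cool_wet_season_heat_yield_equals_tolerant(self, wet_weather, cultivar, soil, wet_site):
        # The wet demo site essentially never crosses the 27 C damage
        # threshold around flowering, so the heat-sensitive yield is exact.
        r = wc.run_cultivar_set(wet_weather[0], cultivar, soil, 363.8, latitude=wet_site.latitude)
        assert r.ywh == r.yw

    def test_co2_monotone_yield(self, dry_weather, cultivar, soil, dry_site):
        for s in dry_weather[:5]:
            yields = [
                wc.run_cultivar_set(s, cultivar, soil, co2, latitude=dry_site.latitude).yw
                for co2 in (363.8, 487.0, 541.0)
            ]
            assert yields[0] <= yields[1] <= yields[2]
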