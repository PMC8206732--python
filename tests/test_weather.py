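import dataclasses

import numpy as np
import pytest

import wheatclim as wc
from wheatclim.weather import (
    BASELINE_CO2_PPM,
    ScenarioSpread,
    markov_stationary_wet_fraction,
    month_of_doy,
)


def series_equal(a: wc.WeatherSeries, b: wc.WeatherSeries) -> bool:
    return (
        np.array_equal(a.doy, b.doy)
        and np.array_equal(a.tmin, b.tmin)
        and np.array_equal(a.tmax, b.tmax)
        and np.array_equal(a.rain, b.rain)
        and np.array_equal(a.srad, b.srad)
    )


class TestApplyScenario:
    def test_baseline_is_identity(self, dry_site):
        out = wc.apply_scenario(dry_site, wc.ClimateScenario.baseline())
        assert np.array_equal(out.monthly_tmean, dry_site.monthly_tmean)
        assert np.array_equal(out.gamma_mean_wet, dry_site.gamma_mean_wet)
        assert np.array_equal(out.monthly_srad_factor, dry_site.monthly_srad_factor)

    def test_uniform_warming_is_exactly_additive(self, dry_site):
        scen = wc.ClimateScenario("w2", 487.0, delta_tmean=2.0)
        out = wc.apply_scenario(dry_site, scen)
        assert np.array_equal(out.monthly_tmean, dry_site.monthly_tmean + 2.0)

    def test_input_not_modified(self, dry_site):
        before = dry_site.monthly_tmean.copy()
        wc.apply_scenario(dry_site, wc.ClimateScenario("w", 487.0, delta_tmean=3.0))
        assert np.array_equal(dry_site.monthly_tmean, before)

    def test_zero_precip_factor_annihilates_rain(self, dry_site):
        scen = wc.ClimateScenario("dryout", 487.0, precip_factor=0.0)
        out = wc.apply_scenario(dry_site, scen)
        series = wc.generate_weather(out, 2, seed=5)
        assert all(s.rain.sum() == 0.0 for s in series)

    def test_negative_precip_factor_rejected(self):
        with pytest.raises(ValueError):
            wc.ClimateScenario("bad", 487.0, precip_factor=-0.1)


class TestGenerateWeather:
    def test_seeded_determinism_bitwise(self, dry_site):
        a = wc.generate_weather(dry_site, 3, seed=9)
        b = wc.generate_weather(dry_site, 3, seed=9)
        assert all(series_equal(x, y) for x, y in zip(a, b))

    def test_different_years_differ(self, dry_site):
        a, b = wc.generate_weather(dry_site, 2, seed=9)
        assert not series_equal(a, b)

    def test_physical_invariants(self, dry_weather):
        for s in dry_weather:
            assert np.all(s.tmin <= s.tmax)
            assert np.all(s.rain >= 0)
            assert np.all(s.srad >= 0)
            assert len(s) == 335  # 1 Oct through 31 Aug, non-leap

    def test_degenerate_chain_every_day_dry(self, dry_site):
        climate = dataclasses.replace(
            dry_site, p_wet_given_dry=np.zeros(12), p_wet_given_wet=np.zeros(12)
        )
        for s in wc.generate_weather(climate, 3, seed=1):
            assert s.rain.sum() == 0.0

    def test_stationary_wet_fraction_formula(self):
        # Stationary distribution of the 2-state chain: p_wd/(1 + p_wd - p_ww).
        assert markov_stationary_wet_fraction(0.3, 0.6) == pytest.approx(0.3 / 0.7)

    def test_long_run_wet_frequency_matches_stationary(self, dry_site):
        climate = dataclasses.replace(
            dry_site,
            p_wet_given_dry=np.full(12, 0.3),
            p_wet_given_wet=np.full(12, 0.6),
        )
        series = wc.generate_weather(climate, 300, seed=7)
        wet = np.concatenate([s.rain > 0 for s in series])
        assert wet.mean() == pytest.approx(0.3 / 0.7, abs=0.02)

    def test_monthly_tmean_reproduced(self, dry_site):
        # Use a zero wet-day offset so (tmin+tmax)/2 estimates tmean cleanly.
        climate = dataclasses.replace(dry_site, wet_day_temp_offset=0.0)
        series = wc.generate_weather(climate, 250, seed=13)
        months = np.concatenate([month_of_doy(s.doy) for s in series])
        tmean = np.concatenate([s.tmean for s in series])
        for m in range(12):
            sample = tmean[months == m]
            if len(sample) == 0:  # September is outside the season window
                continue
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            # AR(1) correlation inflates the standard error by ~sqrt((1+rho)/(1-rho)).
            se *= np.sqrt((1 + climate.temp_ar1) / (1 - climate.temp_ar1))
            assert abs(sample.mean() - climate.monthly_tmean[m]) < 3 * se

    def test_wet_day_amounts_match_configured_mean(self, dry_site):
        climate = dataclasses.replace(dry_site, gamma_mean_wet=np.full(12, 5.0))
        series = wc.generate_weather(climate, 250, seed=17)
        amounts = np.concatenate([s.rain[s.rain > 0] for s in series])
        se = amounts.std(ddof=1) / np.sqrt(len(amounts))
        assert abs(amounts.mean() - 5.0) < 3 * se

    def test_scenario_shift_propagates_exactly(self, dry_site):
        scen = wc.ClimateScenario("w2", 487.0, delta_tmean=2.0)
        base = wc.generate_weather(dry_site, 2, seed=21)
        warm = wc.generate_weather(wc.apply_scenario(dry_site, scen), 2, seed=21)
        for b, w in zip(base, warm):
            assert np.allclose(w.tmean, b.tmean + 2.0)

    def test_wet_day_radiation_reduced(self, dry_weather):
        s = dry_weather[0]
        # Compare wet vs dry days within one month to isolate the wet factor.
        from wheatclim.weather import month_of_doy as mod

        months = mod(s.doy)
        m = months[20]
        sel = months == m
        wet, dry = s.rain[sel] > 0, s.rain[sel] == 0
        if wet.any() and dry.any():
            assert s.srad[sel][wet].mean() < s.srad[sel][dry].mean()

    def test_rejects_zero_years(self, dry_site):
        with pytest.raises(ValueError):
            wc.generate_weather(dry_site, 0, seed=1)


class TestWeatherSeriesValidation:
    def test_gap_rejected(self, dry_weather):
        s = dry_weather[0]
        with pytest.raises(ValueError, match="non-consecutive"):
            wc.WeatherSeries(
                "x", 2001, s.doy[[0, 2, 3]], s.tmin[:3], s.tmax[:3], s.rain[:3], s.srad[:3]
            )

    def test_tmin_above_tmax_rejected(self):
        with pytest.raises(ValueError, match="tmin"):
            wc.WeatherSeries("x", 2001, [1, 2], [5.0, 9.0], [8.0, 4.0], [0, 0], [5, 5])


class TestGcmEnsemble:
    def test_members_share_rcp_co2(self):
        members = wc.make_gcm_ensemble(19, "RCP8.5", seed=3)
        assert len(members) == 19
        assert all(m.co2_ppm == 541.0 for m in members)
        members45 = wc.make_gcm_ensemble(19, "RCP4.5", seed=3)
        assert all(m.co2_ppm == 487.0 for m in members45)

    def test_zero_spread_gives_ensemble_mean(self):
        spread = ScenarioSpread(
            dtemp_winter=(1.5, 0.0), dtemp_summer=(2.5, 0.0),
            precip_winter=(1.1, 0.0), precip_summer=(0.8, 0.0),
        )
        (m,) = wc.make_gcm_ensemble(1, "RCP4.5", seed=0, spread_spec=spread)
        assert m.delta_tmean[0] == pytest.approx(1.5)   # January anchor
        assert m.delta_tmean[6] == pytest.approx(2.5)   # July anchor
        assert m.precip_factor[0] == pytest.approx(1.1)
        assert m.precip_factor[6] == pytest.approx(0.8)

    def test_seeded_determinism(self):
        a = wc.make_gcm_ensemble(5, "RCP4.5", seed=11)
        b = wc.make_gcm_ensemble(5, "RCP4.5", seed=11)
        for x, y in zip(a, b):
            assert np.array_equal(x.delta_tmean, y.delta_tmean)
            assert np.array_equal(x.precip_factor, y.precip_factor)

    def test_members_spread(self):
        members = wc.make_gcm_ensemble(10, "RCP4.5", seed=2)
        julys = [m.delta_tmean[6] for m in members]
        assert np.std(julys) > 0

    def test_unknown_rcp_rejected(self):
        with pytest.raises(ValueError, match="RCP"):
            wc.make_gcm_ensemble(3, "RCP6.0", seed=1)

    def test_baseline_constants(self):
        b = wc.ClimateScenario.baseline()
        assert b.co2_ppm == BASELINE_CO2_PPM == 363.8
        assert np.all(b.delta_tmean == 0) and np.all(b.precip_factor == 1)
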