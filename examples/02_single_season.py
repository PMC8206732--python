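"""Simulate one winter-wheat season and read its diagnostics.

Runs the same season twice — with and without water limitation — to show
the seasonal water-stress pathway: the water-limited yield can only fall
short of the potential yield, and the gap is the water stress index WSI.
"""

import wheatclim as wc
from wheatclim.config import demo_dry_site

site = demo_dry_site()
weather = wc.generate_weather(site, n_years=1, seed=11)[0]
cultivar = wc.CultivarParams()
soil = wc.SoilProfile()  # AWC = 177 mm, full at sowing

pot = wc.run_season(weather, cultivar, soil, co2_ppm=363.8,
                    water_limited=False, latitude=site.latitude)
lim = wc.run_season(weather, cultivar, soil, co2_ppm=363.8,
                    water_limited=True, latitude=site.latitude)

print(f"potential yield    Yp = {pot.yield_t_ha:5.2f} t/ha")
print(f"water-limited      Yw = {lim.yield_t_ha:5.2f} t/ha")
print(f"WSI = 1 - Yw/Yp       = {1 - lim.yield_t_ha / pot.yield_t_ha:5.3f}")
print(f"anthesis doy {lim.anthesis_doy}, maturity doy {lim.maturity_doy}")
print(f"seasonal ET {lim.season_et:.0f} mm, "
      f"soil water deficit at anthesis {lim.swd_anthesis:.0f} mm")
print(f"temperature sum {lim.temp_sum:.0f} C d, rain {lim.rain_total:.0f} mm, "
      f"intercepted PAR {lim.intercepted_rad:.0f} MJ/m2")

# WSI is this season's proportional yield loss to water limitation; the
# deficit at anthesis and seasonal ET explain how much of the demand the
# soil could meet.
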