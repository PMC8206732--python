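"""Generate synthetic daily weather for a GB-like site and inspect it.

Builds the dry southeast demo climatology, draws five seasons of daily
weather, and prints seasonal totals. Re-running with the same seed
reproduces the numbers exactly.
"""

import numpy as np

import wheatclim as wc
from wheatclim.config import demo_dry_site

site = demo_dry_site()
series = wc.generate_weather(site, n_years=5, seed=1)

print(f"site {site.site_id} (lat {site.latitude} N), "
      f"{len(series)} seasons of {len(series[0])} days (1 Oct - 31 Aug)")
for s in series:
    print(
        f"  harvest {s.harvest_year}: rain {s.rain.sum():6.1f} mm, "
        f"wet days {int((s.rain > 0).sum()):3d}, "
        f"mean T {s.tmean.mean():5.2f} C, "
        f"radiation {s.srad.sum():6.0f} MJ/m2"
    )

# The rain totals vary year to year (interannual variability); the mean
# temperature hovers around the climatological season mean; radiation is
# set by latitude, clearness and the wet-day reduction.
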