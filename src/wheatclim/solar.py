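"""Solar geometry: declination, astronomical daylength and extraterrestrial radiation.

All functions use a 365-day (non-leap) calendar and accept scalar or array
day-of-year arguments.
"""

from __future__ import annotations

import numpy as np

#: Solar constant expressed per minute (MJ m-2 min-1), FAO-56 convention.
SOLAR_CONSTANT = 0.0820

#: Highest absolute latitude (degrees) accepted; beyond it the sunrise
#: equation degenerates (polar day/night) and the daylength model is invalid.
MAX_LATITUDE = 66.5


def solar_declination(doy):
    """Solar declination (radians) for a day of year on a 365-day calendar."""
    doy = np.asarray(doy, dtype=float)
    return 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)


def daylength(latitude: float, doy):
    """Astronomical daylength in hours from the sunrise equation.

    Parameters
    ----------
    latitude : float
        Site latitude in decimal degrees; must satisfy ``|latitude| < 66.5``.
    doy : int or array-like
        Day of year, 1-365.

    Returns
    -------
    float or ndarray
        Hours of daylight, strictly inside (0, 24).
    """
    if abs(latitude) >= MAX_LATITUDE:
        raise ValueError(
            f"latitude {latitude} outside supported range (|lat| < {MAX_LATITUDE})"
        )
    phi = np.deg2rad(latitude)
    delta = solar_declination(doy)
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    out = 24.0 / np.pi * ws
    return float(out) if np.isscalar(doy) else out


def extraterrestrial_radiation(latitude: float, doy):
    """Daily top-of-atmosphere solar radiation (MJ m-2 d-1), FAO-56 form.

    Multiplied by an atmospheric clearness fraction this gives global
    radiation at the surface.
    """
    if abs(latitude) >= MAX_LATITUDE:
        raise ValueError(
            f"latitude {latitude} outside supported range (|lat| < {MAX_LATITUDE})"
        )
    phi = np.deg2rad(latitude)
    d = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * d / 365.0)
    delta = solar_declination(d)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (
        24.0 * 60.0 / np.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    ra = np.maximum(ra, 0.0)
    return float(ra) if np.isscalar(doy) else ra
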