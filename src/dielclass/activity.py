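"""Photographic-frequency computation and circular kernel density activity curves.

Two views of diel activity are produced from the same filtered events:

* **Daily photographic frequencies** -- for each calendar day, species and
  diel period, detections per hour of that period per 100 trap-days:

      f(d, s, p) = count(s, p, d) / hours(p, d) / cameras_active(d) * 100

  pooled over the cameras active on day ``d`` and normalized by that day's
  actual period durations (day and night lengths change through the year;
  twilight is always 4 h).  These daily values are the sampling unit of the
  downstream ANOVA / Steel--Dwass classification.

* **Circular kernel density estimates** -- the time of day of each event,
  mapped to the circle (24 h = 2 pi), smoothed with a von Mises kernel:

      g(theta) = (1/n) sum_i exp(kappa * cos(theta - t_i)) / (2 pi I0(kappa))

  Larger concentration ``kappa`` means less smoothing.  When no kappa is
  given, a deterministic plug-in rule fits a single von Mises to the data and
  scales its concentration by the sample size (Taylor's circular analogue of
  the normal-reference bandwidth).
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import i0e, i1, iv

from .records import DetectionEvent, EffortLedger
from .solar import PERIODS, SolarCalendar, season_of

__all__ = [
    "DailyFrequency",
    "ActivityDensity",
    "daily_frequencies",
    "circular_kde",
    "select_concentration",
    "times_to_radians",
    "KAPPA_FLOOR",
]

logger = logging.getLogger(__name__)

#: concentration floor returned for (near-)uniform data, where the resultant
#: length carries no information
KAPPA_FLOOR = 0.5

#: resultant length below which the data are treated as uniform
_RBAR_UNIFORM = 1e-3


@dataclass(frozen=True)
class ActivityDensity:
    """A circular density of activity over the 24 h cycle.

    ``grid`` holds equally spaced angles in radians on [0, 2 pi); ``density``
    is per radian and integrates to 1 around the circle.
    """

    species: str
    scope: str  # 'annual' or a season name
    grid: np.ndarray
    density: np.ndarray
    kappa: float

    @property
    def grid_hours(self) -> np.ndarray:
        return self.grid * 24.0 / (2.0 * np.pi)

    def integral(self) -> float:
        """Trapezoidal integral around the circle (should be 1)."""
        theta = np.append(self.grid, self.grid[0] + 2 * np.pi)
        dens = np.append(self.density, self.density[0])
        return float(np.trapezoid(dens, theta))


#: alias kept for symmetry with the frequency table's row meaning
DailyFrequency = pd.DataFrame


def times_to_radians(timestamps) -> np.ndarray:
    """Map clock times of day to radians on [0, 2 pi) (24 h = full circle)."""
    out = []
    for ts in timestamps:
        t = ts.time() if isinstance(ts, dt.datetime) else ts
        hours = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
        out.append(hours / 24.0 * 2.0 * np.pi)
    return np.asarray(out, dtype=float)


def daily_frequencies(
    events: list[DetectionEvent],
    effort: EffortLedger,
    calendar: SolarCalendar,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Per-day, per-period, per-species photographic frequencies.

    Events must already be filtered for independence and fall within effort.
    Returns one row per (date, species, period) for every date with at least
    one active camera, zeros included, with columns ``date, season, period,
    species, frequency``.  Dates with zero active cameras are excluded (a
    warning is logged if they carry events).
    """
    if species is None:
        species = sorted({e.species for e in events})
    dates = effort.active_dates()
    date_set = set(dates)

    counts: dict[tuple[dt.date, str, str], int] = {}
    dropped = 0
    for ev in events:
        d = ev.timestamp.date()
        if d not in date_set:
            dropped += 1
            continue
        p = calendar.period_of(ev.timestamp)
        counts[(d, ev.species, p)] = counts.get((d, ev.species, p), 0) + 1
    if dropped:
        logger.warning("%d events on dates with zero active cameras excluded", dropped)

    rows = []
    for d in dates:
        hours = calendar.diel_periods(d).hours
        n_cam = effort.cameras_active(d)
        seas = season_of(d)
        for s in species:
            for p in PERIODS:
                c = counts.get((d, s, p), 0)
                rows.append((d, seas, p, s, c / hours[p] / n_cam * 100.0))
    frame = pd.DataFrame(rows, columns=["date", "season", "period", "species", "frequency"])
    logger.info("daily frequencies: %d dates x %d species", len(dates), len(species))
    return frame


def circular_kde(
    event_times: np.ndarray,
    kappa: float | None = None,
    grid_size: int = 256,
    species: str = "",
    scope: str = "annual",
) -> ActivityDensity:
    """Von Mises kernel density of event times on the 24 h circle.

    ``event_times`` are radians on [0, 2 pi).  With ``kappa=None`` the
    concentration comes from :func:`select_concentration`.
    """
    t = np.asarray(event_times, dtype=float)
    if t.size < 2:
        raise ValueError("circular_kde needs at least 2 events; a density from fewer is meaningless")
    if kappa is None:
        kappa = select_concentration(t)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if grid_size < 16:
        raise ValueError("grid_size too small")
    grid = np.linspace(0.0, 2.0 * np.pi, grid_size, endpoint=False)
    # mixture of von Mises kernels, one per event; exponentially scaled
    # Bessel form stays finite at any kappa
    diff = np.subtract.outer(grid, t)
    dens = np.exp(kappa * (np.cos(diff) - 1.0)).mean(axis=1) / (2.0 * np.pi * i0e(kappa))
    return ActivityDensity(species=species, scope=scope, grid=grid,
                           density=dens, kappa=float(kappa))


def _kappa_mle(rbar: float) -> float:
    """Concentration of a von Mises fit from mean resultant length (Fisher's approximation)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def select_concentration(event_times: np.ndarray) -> float:
    """Plug-in smoothing concentration for the von Mises KDE.

    Fits a single von Mises by the mean resultant length, then applies
    Taylor's rule-of-thumb

        kappa_kde = [ 3 n kappa^2 I2(2 kappa) / (4 sqrt(pi) I1(kappa)^2) ]^(2/5)

    which plays the role 1/h^2 plays for a normal-reference linear bandwidth:
    more data or tighter clustering gives a more concentrated kernel.  For
    (near-)uniform data the resultant length carries no signal and the floor
    ``KAPPA_FLOOR`` is returned.  Deterministic.
    """
    t = np.asarray(event_times, dtype=float)
    if t.size < 10:
        raise ValueError("select_concentration needs at least 10 events")
    c, s = np.cos(t).mean(), np.sin(t).mean()
    rbar = math.hypot(c, s)
    if rbar < _RBAR_UNIFORM:
        return KAPPA_FLOOR
    kap = _kappa_mle(rbar)
    if kap <= 0:
        return KAPPA_FLOOR
    n = t.size
    num = 3.0 * n * kap**2 * iv(2, 2.0 * kap)
    den = 4.0 * math.sqrt(math.pi) * i1(kap) ** 2
    if den <= 0 or num <= 0:
        return KAPPA_FLOOR
    return max(float((num / den) ** 0.4), KAPPA_FLOOR)
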