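"""Growth physiology: rates, OD-to-dry-weight conversion, yields, carbon fate.

Growth rates come from the balanced (exponential) growth model: ln OD is
linear in time over the user-chosen exponential window, with slope mu.
Specific exchange rates use the standard exponential-phase estimator: a
compound whose concentration changes linearly with biomass at slope s
(mmol per gCDW) is exchanged at q = mu * |s| mmol gCDW^-1 h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import GluconeofluxError

R2_WARN_THRESHOLD_GROWTH = 0.95
R2_WARN_THRESHOLD_CDW = 0.750


@dataclass
class GrowthPhenotype:
    mu: float                    # h^-1
    mu_se: float
    r_squared: float
    exp_window: tuple[float, float]
    lag: float = 0.0
    od_to_cdw: float | None = None   # gCDW per liter per OD unit
    od_to_cdw_r2: float | None = None
    flags: tuple[str, ...] = ()


@dataclass
class ExchangeRate:
    compound: str
    q: float                     # mmol gCDW^-1 h^-1, magnitude
    role: str                    # "uptake" | "secretion" | "none"
    r_squared: float
    slope: float                 # mmol per gCDW


@dataclass
class ExchangeRates:
    rates: dict[str, ExchangeRate]
    yield_x_s: float | None = None   # gCDW per mmol substrate

    def q(self, compound: str) -> float:
        return self.rates[compound].q


def fit_growth(times, ods, window: tuple[float, float] | None = None,
               lag: float = 0.0) -> GrowthPhenotype:
    """Exponential growth rate from ln(OD) regression on the window."""
    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, od = t[mask], od[mask]
    else:
        window = (float(t.min()), float(t.max()))
    if len(t) < 3:
        raise GluconeofluxError("need >= 3 points in the growth window")
    if np.any(od <= 0):
        raise GluconeofluxError("OD values must be > 0 for log-linear fit")
    res = stats.linregress(t, np.log(od))
    r2 = float(res.rvalue ** 2)
    flags = []
    if r2 < R2_WARN_THRESHOLD_GROWTH:
        flags.append("low_r_squared")
    if res.slope <= 0:
        flags.append("non_growing")
    return GrowthPhenotype(mu=float(res.slope), mu_se=float(res.stderr),
                           r_squared=r2, exp_window=window, lag=lag,
                           flags=tuple(flags))


def od_to_cdw_fit(ods, cdws) -> tuple[float, float, tuple[str, ...]]:
    """Linear OD vs gCDW fit; returns (slope, R^2, flags)."""
    od = np.asarray(ods, dtype=float)
    cdw = np.asarray(cdws, dtype=float)
    if len(od) < 3:
        raise GluconeofluxError("need >= 3 OD/CDW pairs")
    res = stats.linregress(od, cdw)
    r2 = float(res.rvalue ** 2)
    flags = ("low_r_squared",) if r2 <= R2_WARN_THRESHOLD_CDW else ()
    return float(res.slope), r2, flags


def exchange_rates(conc_series: dict[str, tuple], biomass_series,
                   growth: GrowthPhenotype, substrate: str | None = None
                   ) -> ExchangeRates:
    """Specific exchange rates from concentration-vs-biomass regressions.

    ``conc_series`` maps compound -> (times, concentrations in mM);
    ``biomass_series`` is (times, gCDW per liter) on the same window.
    Uptake is reported with positive q and role "uptake".
    """
    tb, xb = (np.asarray(a, dtype=float) for a in biomass_series)
    if len(tb) < 2 or xb[-1] <= xb[0]:
        raise GluconeofluxError("biomass must increase over the window")
    rates: dict[str, ExchangeRate] = {}
    yield_x_s = None
    for compound, (tc, conc) in conc_series.items():
        tc = np.asarray(tc, dtype=float)
        conc = np.asarray(conc, dtype=float)
        x = np.interp(tc, tb, xb)
        res = stats.linregress(x, conc)
        slope = float(res.slope)  # mmol/L per gCDW/L = mmol per gCDW
        r2 = float(res.rvalue ** 2)
        if abs(slope) < 1e-12:
            role, q = "none", 0.0
        elif slope < 0:
            role, q = "uptake", growth.mu * -slope
        else:
            role, q = "secretion", growth.mu * slope
        rates[compound] = ExchangeRate(compound, q, role, r2, slope)
        if compound == substrate and slope < 0:
            yield_x_s = 1.0 / -slope  # gCDW per mmol substrate
    return ExchangeRates(rates, yield_x_s)


def carbon_partition(uptake_q: float, uptake_carbons: int,
                     secretions: dict[str, tuple[float, int]],
                     biomass_c_efflux: float) -> dict[str, float]:
    """Fate of carbon uptake: {biomass, secretion, other} fractions.

    ``secretions`` maps compound -> (q, carbon count); ``biomass_c_efflux``
    is the total biosynthetic carbon drain in mmol C gCDW^-1 h^-1;
    "other" is the residual (CO2 and unaccounted).
    """
    uptake_c = uptake_q * uptake_carbons
    if uptake_c <= 0:
        raise GluconeofluxError("carbon uptake must be > 0")
    secreted_c = sum(q * c for q, c in secretions.values())
    if secreted_c > uptake_c * (1 + 1e-9):
        raise GluconeofluxError(
            f"secreted carbon ({secreted_c:.3g}) exceeds uptake ({uptake_c:.3g})")
    f_bio = biomass_c_efflux / uptake_c
    f_sec = secreted_c / uptake_c
    if f_bio + f_sec > 1 + 1e-9:
        raise GluconeofluxError("biomass + secretion carbon exceeds uptake")
    return {"biomass": f_bio, "secretion": f_sec,
            "other": max(0.0, 1.0 - f_bio - f_sec)}
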