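"""Per-field land-use history metrics and landscape-level summaries.

From each field's ordered clear-cut chronology derive: the number of
swidden-fallow cycles, the fallow period between consecutive cuts (interval
minus the cropping period), the current secondary-forest age at the census
date, annual cultivated and deforested areas, their linear trends, and
cumulative age/intensity distributions.  Fields with no detected cut are not
part of the active shifting-cultivation landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class FieldHistory:
    field_id: int
    area_ha: float
    cover_1984: int
    clearcut_dates: np.ndarray
    n_cycles: int
    fallow_periods: list
    current_age: float
    cropping_flag: bool


def fallow_periods(clearcuts, cropping_yr: float = 2.0) -> list[float]:
    """Fallow length between consecutive cuts: max(0, interval - cropping).

    An interval not exceeding the cropping period would mean re-cutting a
    still-cropped field; it is clamped to zero and flagged with a warning.
    """
    dates = np.asarray(clearcuts, dtype=float)
    if len(dates) < 2:
        return []
    gaps = np.diff(dates)
    if np.any(gaps <= cropping_yr):
        warnings.warn("clear-cut interval not exceeding the cropping period; "
                      "fallow clamped to 0", stacklevel=2)
    return [float(max(0.0, g - cropping_yr)) for g in gaps]


def build_field_history(clearcuts, cover_1984: int, census: float,
                        cropping_yr: float = 2.0, field_id: int = 0,
                        area_ha: float = np.nan) -> FieldHistory:
    """Derive one field's cycle metrics from its cut chronology.

    ``current_age`` is measured from the last clear-cut; a field is at the
    cropping phase while within ``cropping_yr`` of its last cut.
    """
    dates = np.sort(np.asarray(clearcuts, dtype=float))
    if len(dates) and census < dates[-1]:
        raise ValueError("census date precedes the last clear-cut")
    n = len(dates)
    return FieldHistory(
        field_id=field_id,
        area_ha=area_ha,
        cover_1984=cover_1984,
        clearcut_dates=dates,
        n_cycles=n,
        fallow_periods=fallow_periods(dates, cropping_yr),
        current_age=float(census - dates[-1]) if n else 0.0,
        cropping_flag=bool(n and census - dates[-1] <= cropping_yr),
    )


def annual_area_series(histories: list, old_growth_code: int = 1) -> pd.DataFrame:
    """Per-calendar-year cultivated area, deforested area, and the percentage
    of the cultivated area that was deforestation.

    cultivated(y): total area of fields with >= 1 cut dated in year y (a field
    counts once per year).  deforested(y): area of fields whose FIRST cut falls
    in year y and which were old-growth at the reference date.
    """
    if not histories:
        raise ValueError("no field histories")
    cult: dict[int, float] = {}
    defo: dict[int, float] = {}
    for h in histories:
        years = np.unique(np.floor(h.clearcut_dates).astype(int))
        for y in years:
            cult[y] = cult.get(y, 0.0) + h.area_ha
        if h.n_cycles and h.cover_1984 == old_growth_code:
            y0 = int(np.floor(h.clearcut_dates[0]))
            defo[y0] = defo.get(y0, 0.0) + h.area_ha
    if not cult:
        return pd.DataFrame(columns=["year", "cultivated_ha", "deforested_ha",
                                     "pct_deforested"])
    years = np.arange(min(cult), max(cult) + 1)
    df = pd.DataFrame({
        "year": years,
        "cultivated_ha": [cult.get(int(y), 0.0) for y in years],
        "deforested_ha": [defo.get(int(y), 0.0) for y in years],
    })
    df["pct_deforested"] = np.where(df["cultivated_ha"] > 0,
                                    100.0 * df["deforested_ha"] / df["cultivated_ha"],
                                    np.nan)
    return df


def trend_regression(years, values) -> dict:
    """OLS trend of an annual series: slope per year, adjusted R^2, two-sided
    p-value of the slope, df = n - 2."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    years, values = years[ok], values[ok]
    if len(years) < 3:
        raise ValueError("need at least 3 points")
    if len(np.unique(years)) < 2:
        raise ValueError("all years identical")
    with np.errstate(divide="ignore"):  # adj R^2 of an exactly constant series
        res = sm.OLS(values, sm.add_constant(years)).fit()
    return {
        "slope": float(res.params[1]),
        "adj_r2": float(res.rsquared_adj),
        "p_value": float(res.pvalues[1]),
        "df": int(res.df_resid),
    }


def cumulative_distributions(histories: list) -> dict:
    """Area-weighted cumulative curves of fallow age and cycle count, with the
    ages/counts at which each curve crosses 50 % and 80 % of the active area."""
    if not histories:
        raise ValueError("no field histories")
    active = [h for h in histories if h.n_cycles > 0]
    total = sum(h.area_ha for h in active)

    def curve(values: np.ndarray, areas: np.ndarray) -> pd.DataFrame:
        order = np.argsort(values, kind="stable")
        v = values[order]
        a = np.cumsum(areas[order])
        xs, idx = np.unique(v, return_index=True)
        # cumulative area at each distinct value = last cumsum within that value
        last = np.append(idx[1:], len(v)) - 1
        cum = a[last]
        return pd.DataFrame({"x": xs, "cum_area_ha": cum,
                             "cum_pct": 100.0 * cum / total})

    def crossing(df: pd.DataFrame, pct: float) -> float:
        hit = df[df["cum_pct"] >= pct]
        return float(hit["x"].iloc[0]) if len(hit) else np.nan

    ages = np.array([h.current_age for h in active])
    cycles = np.array([h.n_cycles for h in active], dtype=float)
    areas = np.array([h.area_ha for h in active])
    age_cdf = curve(ages, areas)
    cyc_cdf = curve(cycles, areas)
    return {
        "age_cdf": age_cdf, "cycles_cdf": cyc_cdf,
        "age_p50": crossing(age_cdf, 50.0), "age_p80": crossing(age_cdf, 80.0),
        "cycles_p50": crossing(cyc_cdf, 50.0), "cycles_p80": crossing(cyc_cdf, 80.0),
        "total_active_area_ha": total,
    }
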