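"""Store-level inventory preprocessing.

Turns a raw 10-minute stock trace into the average number of customers a
store serves per day, in four steps: (1) aggregate the stock level to one
value per clock hour (last observation in the hour) and take consecutive
hourly differences; (2) per calendar day, sum the absolute values of the
negative differences to get that day's sales; (3) average the daily sales
over the observed days; (4) divide by the rationing quota (nine masks per
person per two weeks) to convert masks sold into customers served.

Restocking jumps show up as positive hourly differences and are ignored by
the sales sum; a restock and sales landing in the same hour partially
cancel (the net change is used), a known small bias of the procedure that
is deliberately not corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_QUOTA = 9


@dataclass
class StoreSupply:
    """Per-store supply summary."""

    store_id: str
    location: tuple  # (x, y) planar meters
    daily_sales: pd.Series  # masks sold per calendar day, indexed by date
    avg_daily_sales: float
    avg_daily_customers: float


def _as_series(series: pd.DataFrame | pd.Series) -> pd.Series:
    """Normalize input to a stock Series indexed by timestamp."""
    if isinstance(series, pd.DataFrame):
        if series.empty:
            raise ValueError("empty inventory series")
        s = series.set_index(pd.DatetimeIndex(series["timestamp"]))["stock"]
    else:
        s = series.copy()
        s.index = pd.DatetimeIndex(s.index)
    if s.empty:
        raise ValueError("empty inventory series")
    if not s.index.is_monotonic_increasing:
        s = s.sort_index()
    return s.astype(float)


def hourly_stock(series: pd.DataFrame | pd.Series) -> pd.Series:
    """Stock level per clock hour: last 10-minute observation in each hour.

    Hours with no observation are simply absent; differences are then taken
    between consecutive *observed* hours.
    """
    s = _as_series(series)
    return s.groupby(s.index.floor("h")).last()


def hourly_decrements(series: pd.DataFrame | pd.Series) -> pd.Series:
    """Consecutive differences of the hourly stock levels.

    Negative values are sales (stock decrements), positive values are
    restocks. Each difference is labeled by the *later* of the two hours it
    spans. A single observation yields an empty vector.
    """
    hs = hourly_stock(series)
    return hs.diff().dropna()


def daily_sales(series: pd.DataFrame | pd.Series) -> pd.Series:
    """Masks sold per calendar day: sum of |negative hourly differences|.

    Days spanned by the trace but containing only restocks (or nothing)
    report zero sales.
    """
    diffs = hourly_decrements(series)
    s = _as_series(series)
    days = pd.Index(s.index.normalize().unique().date, name="date")
    if diffs.empty:
        return pd.Series(0.0, index=days, name="sales")
    neg = (-diffs.clip(upper=0)).groupby(diffs.index.date).sum()
    out = pd.Series(0.0, index=days, name="sales")
    out.loc[neg.index] = neg.to_numpy(dtype=float)
    return out


def store_supply(
    series: pd.DataFrame | pd.Series,
    location: tuple = (np.nan, np.nan),
    quota: int = DEFAULT_QUOTA,
    store_id: str = "",
) -> StoreSupply:
    """Average daily sales and customers served for one store.

    The averaging denominator T is the number of calendar days with at
    least one observation, so a store whose feed starts late is not
    diluted by empty days.
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    ds = daily_sales(series)
    avg = float(ds.mean())
    return StoreSupply(
        store_id=store_id,
        location=tuple(location),
        daily_sales=ds,
        avg_daily_sales=avg,
        avg_daily_customers=avg / quota,
    )


def preprocess_inventory(
    inventory: pd.DataFrame,
    stores: pd.DataFrame,
    quota: int = DEFAULT_QUOTA,
) -> pd.DataFrame:
    """Per-store supply table from a long inventory table.

    ``inventory`` has columns (store_id, timestamp, stock); ``stores`` has
    (store_id, x, y). Returns one row per store with avg_daily_sales and
    avg_daily_customers; stores without any inventory rows are dropped.
    """
    loc = stores.set_index("store_id")
    rows = []
    for sid, grp in inventory.groupby("store_id", sort=True):
        if sid not in loc.index:
            raise KeyError(f"store {sid!r} missing from stores table")
        sup = store_supply(
            grp, (loc.at[sid, "x"], loc.at[sid, "y"]), quota, store_id=str(sid)
        )
        rows.append(
            {
                "store_id": sid,
                "x": sup.location[0],
                "y": sup.location[1],
                "avg_daily_sales": sup.avg_daily_sales,
                "avg_daily_customers": sup.avg_daily_customers,
            }
        )
    return pd.DataFrame(rows)
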