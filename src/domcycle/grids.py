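"""Monthly-grid construction for entity time-series.

Marine time-series stations sample on an irregular (roughly bimonthly)
calendar.  Wavelet analysis requires a uniform grid, so observations are
collapsed to one value per calendar month (replicates averaged) and interior
gaps are filled by linear interpolation.  The resulting :class:`EntitySeries`
is the unit of analysis for every downstream seasonality computation: one
entity (a DOM molecule feature or an ASV) at one sampling depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EntitySeries",
    "collapse_replicates",
    "to_monthly_grid",
    "series_rsd",
]


@dataclass
class EntitySeries:
    """One entity's values on a uniform monthly grid at one depth.

    Parameters
    ----------
    entity_id : str
        Feature or ASV identifier.
    entity_kind : str
        ``"DOM"`` or ``"ASV"``.
    depth : str
        Depth label (e.g. ``"1m"``).
    months : pd.PeriodIndex
        Strictly increasing monthly grid (freq ``"M"``, step one month).
    values : np.ndarray
        Non-negative intensities (DOM, arbitrary units) or relative
        abundances (ASV).
    observed_mask : np.ndarray
        True where the grid month was directly observed rather than
        interpolated.
    """

    entity_id: str
    entity_kind: str
    depth: str
    months: pd.PeriodIndex
    values: np.ndarray
    observed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.months = pd.PeriodIndex(self.months, freq="M")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.months) != len(self.values):
            raise ValueError("months and values must have equal length")
        if len(self.months) > 1:
            steps = np.diff(self.months.asi8)
            if not np.all(steps == 1):
                raise ValueError("months must increase with step 1 month")
        if self.observed_mask is None:
            self.observed_mask = np.ones(len(self.values), dtype=bool)
        else:
            self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
            if len(self.observed_mask) != len(self.values):
                raise ValueError("observed_mask length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def calendar_months(self) -> np.ndarray:
        """Calendar month (1-12) of each grid point."""
        return self.months.month.to_numpy()


def collapse_replicates(
    observations: list[tuple[object, float]],
) -> list[tuple[pd.Period, float]]:
    """Average replicate observations to one value per calendar month.

    Months with multiple samples (e.g. diel campaigns) are represented by
    the arithmetic mean of their observations.  Dates are mapped to months
    by calendar month regardless of day.

    Parameters
    ----------
    observations : list of (date-like, value)
        Each date-like is anything ``pd.Period(..., "M")`` accepts
        (timestamp, date string, or Period).

    Returns
    -------
    list of (pd.Period, float), sorted by month.
    """
    if len(observations) == 0:
        raise ValueError("need at least one observation")
    buckets: dict[pd.Period, list[float]] = {}
    for date, value in observations:
        month = pd.Period(pd.Timestamp(date), freq="M") if not isinstance(
            date, pd.Period
        ) else date.asfreq("M")
        buckets.setdefault(month, []).append(float(value))
    return [(m, float(np.mean(v))) for m, v in sorted(buckets.items())]


def to_monthly_grid(
    monthly_obs: list[tuple[object, float]],
    start: object | None = None,
    end: object | None = None,
    *,
    entity_id: str = "",
    entity_kind: str = "DOM",
    depth: str = "",
) -> EntitySeries:
    """Linearly interpolate monthly observations onto a uniform grid.

    Observed months keep their exact values; interior gaps are filled by
    linear interpolation between the adjacent observed months.  Leading and
    trailing unobserved months are never extrapolated: the grid is trimmed
    to the observed span even if ``start``/``end`` extend beyond it.
    """
    obs = [
        (
            p.asfreq("M")
            if isinstance(p, pd.Period)
            else pd.Period(pd.Timestamp(p), freq="M"),
            float(v),
        )
        for p, v in monthly_obs
    ]
    obs.sort(key=lambda t: t[0])
    if len(obs) < 2:
        raise ValueError("need at least two observed months to interpolate")
    first, last = obs[0][0], obs[-1][0]
    if start is not None:
        start_p = pd.Period(start, freq="M")
        if start_p > first:
            raise ValueError("start must be <= first observed month")
    if end is not None:
        end_p = pd.Period(end, freq="M")
        if end_p < last:
            raise ValueError("end must be >= last observed month")

    grid = pd.period_range(first, last, freq="M")
    obs_idx = np.array([(m - first).n for m, _ in obs])
    if len(np.unique(obs_idx)) != len(obs_idx):
        raise ValueError("duplicate observed months; collapse replicates first")
    obs_val = np.array([v for _, v in obs])
    values = np.interp(np.arange(len(grid)), obs_idx, obs_val)
    mask = np.zeros(len(grid), dtype=bool)
    mask[obs_idx] = True
    # interpolation knots are exact by construction of np.interp
    return EntitySeries(
        entity_id=entity_id,
        entity_kind=entity_kind,
        depth=depth,
        months=grid,
        values=values,
        observed_mask=mask,
    )


def series_rsd(series: EntitySeries | np.ndarray) -> float:
    """Relative standard deviation (percent) of the gridded values.

    RSD = 100 * sd / mean with the sample (n-1) standard deviation.  Used
    as the variability gate separating environmental signal from analytical
    noise (default threshold 25%).

    Raises
    ------
    ValueError
        If the mean is not strictly positive (RSD undefined).
    """
    values = series.values if isinstance(series, EntitySeries) else np.asarray(
        series, dtype=float
    )
    mean = values.mean()
    if mean <= 0:
        raise ValueError("RSD undefined for non-positive mean")
    return float(100.0 * values.std(ddof=1) / mean)


def series_from_long_table(
    table: pd.DataFrame,
    *,
    entity_col: str = "entity_id",
    kind_col: str = "entity_kind",
    depth_col: str = "depth",
    date_col: str = "date",
    value_col: str = "value",
) -> list[EntitySeries]:
    """Build gridded series from a long-format (entity, depth, date, value) table."""
    out: list[EntitySeries] = []
    for (entity, depth), grp in table.groupby([entity_col, depth_col], sort=True):
        kind = str(grp[kind_col].iloc[0]) if kind_col in grp else "DOM"
        monthly = collapse_replicates(list(zip(grp[date_col], grp[value_col])))
        out.append(
            to_monthly_grid(
                monthly, entity_id=str(entity), entity_kind=kind, depth=str(depth)
            )
        )
    return out
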