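"""Cohort-level summaries of seasonality calls.

Aggregates per-entity seasonality classifications across depths and entity
kinds: exact depth-set intersection (upset) tables, peak-season tallies, and
Kolmogorov-Smirnov comparison of median-power distributions between cohorts
(e.g. DOM molecules vs prokaryoplankton ASVs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .wavelets import SeasonalityCall

__all__ = [
    "DistributionComparison",
    "depth_intersections",
    "peak_season_tally",
    "compare_median_power",
]


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls.copy()
    return pd.DataFrame([vars(c) if isinstance(c, SeasonalityCall) else c
                         for c in calls])


def depth_intersections(calls, depths: list[str] | None = None) -> pd.DataFrame:
    """Exact depth-set membership counts of seasonal entities (upset table).

    Each seasonal entity is assigned to the row matching its *exact* set of
    depths with a seasonal call (an entity seasonal at all four depths counts
    only in the four-way row).  Returns one row per non-empty subset of
    ``depths`` (15 rows for four depths) with counts per entity kind, plus
    per-depth totals in the attribute ``.attrs["depth_totals"]``.
    """
    df = _calls_frame(calls)
    if df.duplicated(subset=["entity_id", "depth"]).any():
        dups = df[df.duplicated(subset=["entity_id", "depth"], keep=False)]
        raise ValueError(
            f"duplicate (entity, depth) calls: "
            f"{sorted(set(map(tuple, dups[['entity_id', 'depth']].values)))}"
        )
    if depths is None:
        depths = list(pd.unique(df["depth"]))
    kinds = sorted(pd.unique(df["entity_kind"])) or ["DOM"]

    seasonal = df[df["is_seasonal"].astype(bool)]
    depth_sets = (
        seasonal.groupby(["entity_kind", "entity_id"])["depth"]
        .apply(frozenset)
        .reset_index(name="depth_set")
    )

    rows = []
    for r in range(1, len(depths) + 1):
        for subset in combinations(depths, r):
            fs = frozenset(subset)
            row = {"depths": "+".join(subset), "n_depths": r}
            for kind in kinds:
                row[kind] = int(
                    (
                        (depth_sets["entity_kind"] == kind)
                        & (depth_sets["depth_set"] == fs)
                    ).sum()
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    totals = {
        d: {
            kind: int(
                (
                    (seasonal["depth"] == d)
                    & (seasonal["entity_kind"] == kind)
                ).sum()
            )
            for kind in kinds
        }
        for d in depths
    }
    table.attrs["depth_totals"] = totals
    return table


def peak_season_tally(calls) -> pd.DataFrame:
    """Counts and within-(depth, kind) percentages of peak seasons."""
    df = _calls_frame(calls)
    if df.empty:
        return pd.DataFrame(
            columns=["depth", "entity_kind", "season", "count", "percent"]
        )
    seasonal = df[df["is_seasonal"].astype(bool)]
    if seasonal.empty:
        return pd.DataFrame(
            columns=["depth", "entity_kind", "season", "count", "percent"]
        )
    counts = (
        seasonal.groupby(["depth", "entity_kind", "season"], dropna=False)
        .size()
        .reset_index(name="count")
    )
    totals = counts.groupby(["depth", "entity_kind"])["count"].transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    return counts


@dataclass
class DistributionComparison:
    """Two-sample KS comparison of median-power distributions."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    ecdf_a: tuple[np.ndarray, np.ndarray]
    ecdf_b: tuple[np.ndarray, np.ndarray]


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(x)
    return xs, np.arange(1, len(xs) + 1) / len(xs)


def compare_median_power(
    powers_a, powers_b, *, exact_below: int = 30
) -> DistributionComparison:
    """Two-sample Kolmogorov-Smirnov test on median-power samples.

    D is the supremum distance between the two empirical CDFs.  The
    asymptotic p-value is used for cohort-scale samples; the exact
    distribution is used when the smaller sample is below ``exact_below``.
    """
    a = np.asarray(powers_a, dtype=float)
    b = np.asarray(powers_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 values per cohort")
    method = "exact" if min(len(a), len(b)) < exact_below else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return DistributionComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        ecdf_a=_ecdf(a),
        ecdf_b=_ecdf(b),
    )
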