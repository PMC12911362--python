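"""Post-peak-picking QC filters for untargeted LC-MS feature tables.

A *feature* is a unique (m/z, retention time) pair, the proxy for one
dissolved molecule.  The cascade removes upstream annotation artifacts
(isotopologues, adducts), poorly shaped or drifting peaks, features that are
indistinguishable from process blanks, rarely detected features, and features
that are irreproducible across pooled-QC injections.  The table is assumed to
be batch-corrected upstream; an optional per-batch median-centering utility is
provided but is not part of the default cascade.

Filter cascade order: annotation -> width -> blank -> RT consistency ->
detection -> pool RSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FeatureTable",
    "FilterReport",
    "gaussian_shape_screen",
    "width_filter",
    "annotation_filter",
    "blank_filter",
    "detection_filter",
    "rt_consistency_filter",
    "pool_rsd_filter",
    "run_qc",
    "median_center_batches",
    "write_feature_table",
    "read_feature_table",
]

INJECTION_KINDS = ("sample", "process_blank", "pool")

FEATURE_COLUMNS = [
    "feature_id",
    "mz",
    "rt",
    "peak_width",
    "median_rt_range",
    "isotope_flag",
    "adduct_flag",
]
INJECTION_COLUMNS = ["injection_id", "kind", "batch", "depth", "event_time"]


@dataclass
class FeatureTable:
    """Feature x injection intensity matrix with metadata.

    Attributes
    ----------
    features : pd.DataFrame
        One row per feature; columns ``feature_id, mz, rt, peak_width,
        median_rt_range, isotope_flag, adduct_flag``.
    injections : pd.DataFrame
        One row per injection; columns ``injection_id, kind, batch, depth,
        event_time``; ``kind`` is one of sample | process_blank | pool.
    intensities : pd.DataFrame
        Non-negative matrix indexed by feature_id with injection_id columns;
        0 means not detected.  Intensities are unitless integrated ion counts.
    """

    features: pd.DataFrame
    injections: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.features = self.features.reset_index(drop=True)
        self.injections = self.injections.reset_index(drop=True)
        if not self.intensities.index.equals(
            pd.Index(self.features["feature_id"])
        ):
            self.intensities = self.intensities.loc[self.features["feature_id"]]
        if list(self.intensities.columns) != list(self.injections["injection_id"]):
            self.intensities = self.intensities[
                list(self.injections["injection_id"])
            ]
        bad_kinds = set(self.injections["kind"]) - set(INJECTION_KINDS)
        if bad_kinds:
            raise ValueError(f"unknown injection kinds: {sorted(bad_kinds)}")
        if (self.injections["batch"].astype(str).str.len() == 0).any():
            raise ValueError("batch labels must be non-empty")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def injection_ids(self, kind: str) -> list[str]:
        mask = self.injections["kind"] == kind
        return list(self.injections.loc[mask, "injection_id"])

    def subset(self, keep_ids: pd.Index | list) -> "FeatureTable":
        keep = self.features["feature_id"].isin(set(keep_ids))
        return FeatureTable(
            features=self.features.loc[keep].copy(),
            injections=self.injections.copy(),
            intensities=self.intensities.loc[
                self.features.loc[keep, "feature_id"]
            ].copy(),
        )


@dataclass
class FilterReport:
    """Per-stage record of which features were kept or removed and why."""

    stage: str
    n_in: int
    n_out: int
    decisions: dict[str, tuple[bool, str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"feature_id": fid, "kept": kept, "reason": reason}
                for fid, (kept, reason) in self.decisions.items()
            ]
        )


def _finalize(table: FeatureTable, stage: str, keep: pd.Series,
              reasons: pd.Series, warn: list[str] | None = None):
    ids = table.features["feature_id"]
    report = FilterReport(
        stage=stage,
        n_in=len(ids),
        n_out=int(keep.sum()),
        decisions={
            fid: (bool(k), str(r)) for fid, k, r in zip(ids, keep, reasons)
        },
        warnings=list(warn or []),
    )
    return table.subset(ids[keep.to_numpy()]), report


# ---------------------------------------------------------------------------
# Peak-shape screen (applied upstream of the table-level cascade)
# ---------------------------------------------------------------------------

def _gaussian(t, mu, sigma, height, offset):
    return offset + height * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def gaussian_shape_screen(
    profile, *, min_correlation: float = 0.6, max_p: float = 0.075
):
    """Screen a chromatographic peak profile for Gaussian shape.

    Fits a four-parameter Gaussian (location, scale, height, offset) by
    nonlinear least squares and scores the fit with the Pearson correlation
    between fitted and observed intensities.  A peak passes when the
    correlation exceeds ``min_correlation`` (default 0.6) and the
    correlation-test p-value is below ``max_p`` (default 0.075).

    Parameters
    ----------
    profile : sequence of (time_s, intensity)

    Returns
    -------
    (passed, correlation, p_value)
        ``correlation`` and ``p_value`` are NaN when undefined (flat profile
        or failed fit), in which case ``passed`` is False.
    """
    arr = np.asarray(profile, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 5:
        raise ValueError("profile must be >= 5 (time, intensity) points")
    t, y = arr[:, 0], arr[:, 1]
    if (y < 0).any():
        raise ValueError("intensities must be non-negative")
    if np.ptp(y) == 0:
        return False, float("nan"), float("nan")

    span = max(np.ptp(t), 1e-9)
    starts = []
    for mu0 in (t[np.argmax(y)], np.median(t)):
        for sig0 in (span / 6, span / 3):
            starts.append((mu0, sig0, np.ptp(y), y.min()))
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _gaussian, t, y, p0=p0,
                bounds=([t.min() - span, 1e-9 * span, 0, 0],
                        [t.max() + span, 10 * span, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        fitted = _gaussian(t, *popt)
        sse = float(np.sum((y - fitted) ** 2))
        if best is None or sse < best[0]:
            best = (sse, fitted)
    if best is None:
        return False, float("nan"), float("nan")
    fitted = best[1]
    if np.ptp(fitted) == 0:
        return False, float("nan"), float("nan")
    r, p = stats.pearsonr(fitted, y)
    return bool(r > min_correlation and p < max_p), float(r), float(p)


# ---------------------------------------------------------------------------
# Table-level cascade
# ---------------------------------------------------------------------------

def annotation_filter(table: FeatureTable):
    """Remove features flagged upstream as isotopologues or adducts."""
    flagged = table.features["isotope_flag"].astype(bool) | table.features[
        "adduct_flag"
    ].astype(bool)
    keep = ~flagged
    reasons = pd.Series(
        np.where(keep, "kept", "isotopologue/adduct"), index=keep.index
    )
    return _finalize(table, "annotation", keep, reasons)


def width_filter(table: FeatureTable, max_width: float = 15.0):
    """Keep features with peak width strictly below ``max_width`` seconds."""
    widths = pd.to_numeric(table.features["peak_width"], errors="coerce")
    if widths.isna().any():
        missing = list(table.features.loc[widths.isna(), "feature_id"])
        raise ValueError(f"missing peak widths for features: {missing}")
    keep = widths < max_width
    reasons = pd.Series(
        np.where(keep, "kept", f"peak_width >= {max_width} s"), index=keep.index
    )
    return _finalize(table, "width", keep, reasons)


def rt_consistency_filter(table: FeatureTable, max_range: float = 5.0):
    """Keep features whose grouped-peak median-RT range is below ``max_range`` s."""
    rng = pd.to_numeric(table.features["median_rt_range"], errors="coerce")
    if rng.isna().any():
        missing = list(table.features.loc[rng.isna(), "feature_id"])
        raise ValueError(f"missing median RT ranges for features: {missing}")
    keep = rng < max_range
    reasons = pd.Series(
        np.where(keep, "kept", f"median RT range >= {max_range} s"),
        index=keep.index,
    )
    return _finalize(table, "rt_consistency", keep, reasons)


def blank_filter(
    table: FeatureTable,
    quantile_cuts: tuple[float, ...] = (20, 40, 60, 80),
    threshold_quartile: float = 25,
    pseudocount: float = 1.0,
):
    """Data-adaptive process-blank filter.

    For every feature the mean log10(intensity + pseudocount) over samples
    (``d_s``) and over blanks (``d_b``) gives a blank contrast
    ``d = d_s - d_b``.  Features are binned by the 20/40/60/80th quantiles of
    their mean log abundance over samples + blanks; per bin the threshold T is
    the 25th percentile of the negative contrasts, and a feature is kept only
    when ``d > |T|``.  Bins with no negative contrast use T = 0 (keep d > 0).

    Bins are left-closed: a feature exactly at a quantile cut falls in the
    upper bin.  Decisions are invariant to rescaling all intensities by a
    common positive constant only in the large-intensity regime (the
    pseudocount breaks exact invariance at zero).
    """
    sample_ids = table.injection_ids("sample")
    blank_ids = table.injection_ids("process_blank")
    if not sample_ids or not blank_ids:
        raise ValueError("blank_filter needs >=1 sample and >=1 blank injection")

    logs = np.log10(table.intensities + pseudocount)
    d = logs[sample_ids].mean(axis=1) - logs[blank_ids].mean(axis=1)
    m_all = logs[sample_ids + blank_ids].mean(axis=1)

    cuts = np.percentile(m_all.to_numpy(), list(quantile_cuts))
    bins = np.searchsorted(cuts, m_all.to_numpy(), side="right")

    keep = np.zeros(len(d), dtype=bool)
    reasons = np.empty(len(d), dtype=object)
    for b in range(len(quantile_cuts) + 1):
        in_bin = bins == b
        if not in_bin.any():
            continue
        neg = d.to_numpy()[in_bin]
        neg = neg[neg < 0]
        thr = abs(float(np.percentile(neg, threshold_quartile))) if len(neg) else 0.0
        ok = d.to_numpy()[in_bin] > thr
        keep[in_bin] = ok
        reasons[in_bin] = np.where(
            ok, "kept", f"blank contrast <= bin-{b} threshold {thr:.4g}"
        )
    keep_s = pd.Series(keep, index=d.index)
    reasons_s = pd.Series(reasons, index=d.index)
    keep_s.index = reasons_s.index = table.features.index
    return _finalize(table, "blank", keep_s, reasons_s)


def detection_filter(table: FeatureTable, min_fraction: float = 0.5):
    """Keep features detected (> 0) in strictly more than ``min_fraction`` of samples.

    Blanks and pools are excluded from the denominator.
    """
    sample_ids = table.injection_ids("sample")
    if not sample_ids:
        raise ValueError("detection_filter needs >=1 sample injection")
    frac = (table.intensities[sample_ids] > 0).mean(axis=1)
    keep = pd.Series(frac.to_numpy() > min_fraction, index=table.features.index)
    reasons = pd.Series(
        np.where(keep, "kept", f"detected in <= {min_fraction:.0%} of samples"),
        index=keep.index,
    )
    return _finalize(table, "detection", keep, reasons)


def pool_rsd_filter(table: FeatureTable, max_rsd: float = 20.0):
    """Pooled-QC reproducibility filter.

    The metric uses the first pool injection of each batch (injection order
    is run order).  For features detected in any of those pools, the relative
    standard deviation (sample sd / mean, percent) across them must be below
    ``max_rsd``; features absent from all of them pass unconditionally.

    With fewer than two batches carrying a pool injection the stage is
    skipped with a warning in the report.
    """
    inj = table.injections
    pool_rows = inj[inj["kind"] == "pool"]
    first_per_batch = pool_rows.groupby("batch", sort=False).head(1)
    selected = list(first_per_batch["injection_id"])
    keep = pd.Series(True, index=table.features.index)
    if len(selected) < 2:
        msg = (
            "pool RSD stage skipped: fewer than 2 batches with pool injections"
        )
        warnings.warn(msg, stacklevel=2)
        reasons = pd.Series("kept (stage skipped)", index=keep.index)
        return _finalize(table, "pool_rsd", keep, reasons, warn=[msg])

    pools = table.intensities[selected]
    detected = (pools > 0).any(axis=1).to_numpy()
    mean = pools.mean(axis=1).to_numpy()
    sd = pools.std(axis=1, ddof=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    keep = pd.Series(~detected | (rsd < max_rsd), index=table.features.index)
    reasons = pd.Series(
        np.where(
            keep,
            np.where(detected, "kept", "kept (absent from pools)"),
            f"pool RSD >= {max_rsd}%",
        ),
        index=keep.index,
    )
    return _finalize(table, "pool_rsd", keep, reasons)


def run_qc(
    table: FeatureTable,
    *,
    max_width: float = 15.0,
    max_rt_range: float = 5.0,
    min_detect_fraction: float = 0.5,
    max_pool_rsd: float = 20.0,
    quantile_cuts: tuple[float, ...] = (20, 40, 60, 80),
    threshold_quartile: float = 25,
) -> tuple[FeatureTable, list[FilterReport]]:
    """Run the full filter cascade with the study's default thresholds."""
    reports: list[FilterReport] = []
    table, rep = annotation_filter(table)
    reports.append(rep)
    table, rep = width_filter(table, max_width)
    reports.append(rep)
    table, rep = blank_filter(table, quantile_cuts, threshold_quartile)
    reports.append(rep)
    table, rep = rt_consistency_filter(table, max_rt_range)
    reports.append(rep)
    table, rep = detection_filter(table, min_detect_fraction)
    reports.append(rep)
    table, rep = pool_rsd_filter(table, max_pool_rsd)
    reports.append(rep)
    return table, reports


def median_center_batches(table: FeatureTable) -> FeatureTable:
    """Optional per-batch median centering of sample intensities.

    Divides every sample injection by its batch's median total intensity
    relative to the global median.  Off by default; the cascade assumes the
    table is already batch-corrected upstream.
    """
    intens = table.intensities.copy()
    sample_ids = table.injection_ids("sample")
    totals = intens[sample_ids].sum(axis=0)
    batches = table.injections.set_index("injection_id").loc[sample_ids, "batch"]
    global_med = float(totals.median())
    for batch, ids in batches.groupby(batches).groups.items():
        factor = float(totals[list(ids)].median()) / global_med
        if factor > 0:
            intens[list(ids)] = intens[list(ids)] / factor
    return FeatureTable(table.features.copy(), table.injections.copy(), intens)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.features.to_csv(out / "features.tsv", sep="\t", index=False)
    table.injections.to_csv(out / "injections.tsv", sep="\t", index=False)
    table.intensities.to_csv(out / "intensities.tsv", sep="\t")


def read_feature_table(in_dir: str | Path) -> FeatureTable:
    src = Path(in_dir)
    features = pd.read_csv(src / "features.tsv", sep="\t")
    injections = pd.read_csv(src / "injections.tsv", sep="\t")
    intensities = pd.read_csv(src / "intensities.tsv", sep="\t", index_col=0)
    injections["batch"] = injections["batch"].astype(str)
    return FeatureTable(features, injections, intensities)
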