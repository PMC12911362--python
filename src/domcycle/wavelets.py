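"""Morlet continuous-wavelet seasonality detection for monthly series.

The seasonality classifier decomposes each standardized monthly series with
the Morlet continuous wavelet transform (Torrence & Compo normalisation),
assigns a dominant period as the period of highest median power over time,
tests it against a white-noise null by permutation (simulated Gaussian
white-noise series), gates on the raw series' relative standard deviation,
and — for seasonal (12-month-dominant) series — reconstructs the 12-month
band to assign the calendar month and hydrographic season of the seasonal
maximum.

A series is *seasonal* when its dominant period is the 12-month band, the
median permutation p-value at that period is <= alpha (default 0.01), and the
raw-series RSD exceeds the variability gate (default 25%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EntitySeries, series_rsd

__all__ = [
    "WaveletParams",
    "WaveletDecomposition",
    "SeasonalityCall",
    "DEFAULT_SEASON_MAP",
    "cwt",
    "permutation_significance",
    "classify",
    "classify_many",
    "reconstruct_and_peak",
    "season_of_month",
]

# Morlet reconstruction constants (omega0 = 6)
C_DELTA = 0.776
PSI0 = np.pi ** -0.25

#: BATS hydrographic seasons by calendar month: deep convective mixing
#: Jan-Mar, spring transition in April, stratified May-Oct, fall transition
#: Nov-Dec.
DEFAULT_SEASON_MAP: dict[int, str] = {
    1: "winter_mixed", 2: "winter_mixed", 3: "winter_mixed",
    4: "spring_transition",
    5: "summer_stratified", 6: "summer_stratified", 7: "summer_stratified",
    8: "summer_stratified", 9: "summer_stratified", 10: "summer_stratified",
    11: "fall_transition", 12: "fall_transition",
}


@dataclass
class WaveletParams:
    """Tunable parameters of the seasonality classifier.

    ``lower_period``/``upper_period`` bound the analysed periods in months
    (2-12 by default); ``suboctaves`` sets the number of voices per octave of
    the geometric period grid; ``omega0`` is the Morlet angular frequency;
    ``n_permutations`` white-noise simulations drive the significance test at
    level ``alpha`` on the median p-value; ``rsd_threshold`` (percent) is the
    variability gate applied to the raw series.
    """

    lower_period: float = 2.0
    upper_period: float = 12.0
    suboctaves: int = 20
    omega0: float = 6.0
    dt: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.01
    rsd_threshold: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.lower_period < self.upper_period:
            raise ValueError("need 2 <= lower_period < upper_period")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.suboctaves < 1:
            raise ValueError("suboctaves must be >= 1")

    @property
    def fourier_factor(self) -> float:
        """Period / scale ratio of the Morlet wavelet (~1.033 for omega0=6)."""
        return 4 * np.pi / (self.omega0 + np.sqrt(2 + self.omega0**2))

    def period_grid(self) -> np.ndarray:
        """Geometric period grid anchored so upper_period is an exact point."""
        n = int(np.floor(self.suboctaves * np.log2(self.upper_period / self.lower_period)))
        j = np.arange(n, -1, -1)
        return self.upper_period * 2.0 ** (-j / self.suboctaves)

    def band_indices(self, periods: np.ndarray, center: float) -> np.ndarray:
        """Indices of period bins within half a suboctave step of ``center``."""
        half_step = 0.5 / self.suboctaves
        return np.flatnonzero(np.abs(np.log2(periods / center)) <= half_step)


@dataclass
class WaveletDecomposition:
    """Period x time wavelet power with optional significance fields."""

    periods: np.ndarray
    scales: np.ndarray
    months: pd.PeriodIndex
    coefficients: np.ndarray  # complex W(s, t)
    power: np.ndarray  # |W|^2
    params: WaveletParams
    pvalues: np.ndarray | None = None
    reconstruction_12mo: np.ndarray | None = None

    @property
    def median_power(self) -> np.ndarray:
        """Per-period median of power over time (the goodness-of-fit metric)."""
        return np.median(self.power, axis=1)

    @property
    def median_p(self) -> np.ndarray:
        if self.pvalues is None:
            raise ValueError("p-values not computed; run permutation_significance")
        return np.median(self.pvalues, axis=1)


@dataclass
class SeasonalityCall:
    """Classification record for one entity at one depth."""

    entity_id: str
    depth: str
    entity_kind: str = "DOM"
    passed_rsd: bool = False
    rsd: float = float("nan")
    significant: bool = False
    dominant_period: float = float("nan")
    dominant_median_power: float = float("nan")
    median_p: float = float("nan")
    peak_month: int | None = None
    season: str | None = None
    is_seasonal: bool = False


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series: zero variance, cannot standardize")
    return (x - x.mean()) / sd


def _wavelet_filters(n_pad: int, scales: np.ndarray, omega0: float, dt: float) -> np.ndarray:
    """Frequency-domain Morlet daughters, Torrence & Compo normalisation."""
    # angular frequencies with the Nyquist bin positive (k <= N/2)
    k = np.arange(n_pad)
    omega = np.where(k <= n_pad // 2, k, k - n_pad) * 2 * np.pi / (n_pad * dt)
    s_omega = scales[:, None] * omega[None, :]
    psi = PSI0 * np.exp(-0.5 * (s_omega - omega0) ** 2)
    psi *= np.sqrt(2 * np.pi * scales[:, None] / dt)
    psi[:, omega <= 0] = 0.0
    return psi


def _cwt_batch(x: np.ndarray, psi_hat: np.ndarray, n_keep: int) -> np.ndarray:
    """Wavelet coefficients for one series or a batch of series.

    x : (n,) or (B, n) standardized series, zero-padded internally to the
    filter length; returns (scales, n_keep) or (B, scales, n_keep) complex.
    """
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    n_pad = psi_hat.shape[1]
    xhat = np.fft.fft(xb, n=n_pad, axis=1)
    w = np.fft.ifft(xhat[:, None, :] * psi_hat[None, :, :], axis=2)[:, :, :n_keep]
    return w[0] if single else w


def cwt(series: EntitySeries | np.ndarray, params: WaveletParams | None = None) -> WaveletDecomposition:
    """Morlet continuous wavelet transform of a monthly series.

    The series is standardized to zero mean, unit variance; the transform is
    computed in the frequency domain with zero padding to the next power of
    two.  Edge effects are retained (no cone-of-influence masking), matching
    the median-over-time statistics used downstream.
    """
    params = params or WaveletParams()
    if isinstance(series, EntitySeries):
        values = series.values
        months = series.months
    else:
        values = np.asarray(series, dtype=float)
        months = pd.period_range("2016-07", periods=len(values), freq="M")
    n = len(values)
    if n < 2 * params.upper_period:
        warnings.warn(
            f"series length {n} below 2 x upper period "
            f"({2 * params.upper_period:.0f}); edge effects dominate",
            stacklevel=2,
        )
    x = _standardize(values)
    periods = params.period_grid()
    scales = periods / params.fourier_factor
    n_pad = int(2 ** np.ceil(np.log2(n)))
    psi_hat = _wavelet_filters(n_pad, scales, params.omega0, params.dt)
    w = _cwt_batch(x, psi_hat, n)
    return WaveletDecomposition(
        periods=periods,
        scales=scales,
        months=months,
        coefficients=w,
        power=np.abs(w) ** 2,
        params=params,
    )


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def permutation_significance(
    series: EntitySeries | np.ndarray,
    params: WaveletParams | None = None,
    decomp: WaveletDecomposition | None = None,
    *,
    chunk: int = 250,
) -> np.ndarray:
    """White-noise permutation p-values for every (period, time) cell.

    Simulates ``n_permutations`` standardized Gaussian white-noise series of
    the same length, computes their wavelet power, and returns
    ``p = (1 + #{null power >= observed}) / (1 + n_permutations)`` — the
    add-one correction keeps p strictly positive.  The p-value matrix is also
    attached to ``decomp.pvalues`` when a decomposition is supplied.
    """
    params = params or WaveletParams()
    if decomp is None:
        decomp = cwt(series, params)
    n = decomp.power.shape[1]
    n_pad = int(2 ** np.ceil(np.log2(n)))
    psi_hat = _wavelet_filters(n_pad, decomp.scales, params.omega0, params.dt)
    rng = np.random.default_rng(params.seed)
    counts = np.zeros_like(decomp.power)
    done = 0
    while done < params.n_permutations:
        b = min(chunk, params.n_permutations - done)
        noise = rng.standard_normal((b, n))
        noise -= noise.mean(axis=1, keepdims=True)
        noise /= noise.std(axis=1, ddof=1, keepdims=True)
        w = _cwt_batch(noise, psi_hat, n)
        counts += (np.abs(w) ** 2 >= decomp.power[None]).sum(axis=0)
        done += b
    pvals = (1.0 + counts) / (1.0 + params.n_permutations)
    decomp.pvalues = pvals
    return pvals


# ---------------------------------------------------------------------------
# Reconstruction and classification
# ---------------------------------------------------------------------------

def reconstruct_and_peak(
    decomp: WaveletDecomposition,
    band: float = 12.0,
    *,
    peak_mode: str = "climatology",
) -> tuple[np.ndarray, int]:
    """Inverse transform restricted to one period band, plus its peak month.

    Uses the Torrence & Compo reconstruction (C_delta = 0.776,
    psi0(0) = pi^(-1/4)) summed over the period bins within half a suboctave
    step of ``band``.  The peak month is the calendar month maximizing the
    climatological mean (average over years) of the reconstruction;
    ``peak_mode="global_max"`` instead takes the month of the single global
    maximum.
    """
    params = decomp.params
    idx = params.band_indices(decomp.periods, band)
    if len(idx) == 0:
        raise ValueError(f"band {band} months outside the period grid")
    dj = 1.0 / params.suboctaves
    factor = dj * np.sqrt(params.dt) / (C_DELTA * PSI0)
    recon = factor * np.sum(
        np.real(decomp.coefficients[idx]) / np.sqrt(decomp.scales[idx, None]),
        axis=0,
    )
    cal = decomp.months.month.to_numpy()
    if peak_mode == "climatology":
        clim = {m: recon[cal == m].mean() for m in np.unique(cal)}
        peak_month = int(max(clim, key=clim.get))
    elif peak_mode == "global_max":
        peak_month = int(cal[int(np.argmax(recon))])
    else:
        raise ValueError(f"unknown peak_mode {peak_mode!r}")
    decomp.reconstruction_12mo = recon
    return recon, peak_month


def season_of_month(month: int, season_map: dict[int, str] | None = None) -> str:
    """Map a calendar month to its BATS hydrographic season label."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month {month} out of range 1-12")
    return (season_map or DEFAULT_SEASON_MAP)[int(month)]


def classify(
    series: EntitySeries,
    params: WaveletParams | None = None,
    *,
    season_map: dict[int, str] | None = None,
    decomp: WaveletDecomposition | None = None,
) -> SeasonalityCall:
    """Full seasonality classification of one gridded series.

    The dominant period maximizes the per-period median power; significance
    requires the median permutation p-value at that period <= alpha AND the
    raw-series RSD above the variability gate; a significant series whose
    dominant period falls in the 12-month band is classified seasonal and
    assigned a peak month and season from the band reconstruction.
    """
    params = params or WaveletParams()
    try:
        rsd = series_rsd(series)
        passed_rsd = rsd > params.rsd_threshold
    except ValueError:
        rsd, passed_rsd = float("nan"), False

    if decomp is None:
        decomp = cwt(series, params)
    if decomp.pvalues is None:
        permutation_significance(series, params, decomp)

    med_power = decomp.median_power
    dom_idx = int(np.argmax(med_power))
    dom_period = float(decomp.periods[dom_idx])
    med_p = float(decomp.median_p[dom_idx])

    significant = (med_p <= params.alpha) and passed_rsd
    in_band = dom_idx in params.band_indices(decomp.periods, params.upper_period)
    is_seasonal = significant and in_band

    peak_month: int | None = None
    season: str | None = None
    if is_seasonal:
        _, peak_month = reconstruct_and_peak(decomp, params.upper_period)
        season = season_of_month(peak_month, season_map)

    return SeasonalityCall(
        entity_id=series.entity_id,
        depth=series.depth,
        entity_kind=series.entity_kind,
        passed_rsd=passed_rsd,
        rsd=rsd,
        significant=significant,
        dominant_period=dom_period,
        dominant_median_power=float(med_power[dom_idx]),
        median_p=med_p,
        peak_month=peak_month,
        season=season,
        is_seasonal=is_seasonal,
    )


def classify_many(
    series_list: list[EntitySeries], params: WaveletParams | None = None
) -> pd.DataFrame:
    """Classify a cohort of series; returns one row per entity x depth."""
    calls = [classify(s, params) for s in series_list]
    return pd.DataFrame([vars(c) for c in calls])
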