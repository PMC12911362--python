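"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the sampled design of a multi-depth ocean time-series station:
bimonthly sampling at fixed depths (1, 40, 120, 200 m) on a July 2016 -
July 2019 monthly grid (37 points), with seasonal sinusoidal, partial-year,
and white-noise entities; LC-MS feature tables with process-blank, pooled-QC
and batch structure; and contig-level metagenome KO tables with controllable
contribution evenness and per-sample season labels.

Every generator is seeded and bit-reproducible, and returns a ground-truth
sidecar that downstream tests recompute independently.  Noise is Gaussian
white noise (the classifier's null hypothesis); Student-t noise is available
as an option, off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import EntitySeries
from .qc import FeatureTable

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCommunitySpec",
    "DEFAULT_SCMG_IDS",
    "generate_series",
    "generate_feature_table",
    "generate_ko_table",
    "write_table_with_truth",
]

#: Universal single-copy marker gene KOs used for richness estimation.
DEFAULT_SCMG_IDS = (
    "K01409", "K01869", "K01873", "K01875", "K01883",
    "K01887", "K01889", "K03106", "K03110", "K06942",
)

DEFAULT_DEPTHS = ("1m", "40m", "120m", "200m")


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass
class SyntheticCohortSpec:
    """Ground-truth description of a synthetic entity cohort.

    ``fraction_seasonal`` of the entities carry a sinusoid of
    ``period_months`` peaking in calendar ``peak_month``; the rest are white
    noise around ``baseline``.  Entities flagged in ``partial_year_flags``
    carry the sinusoid only within one 12-month window of the grid.
    """

    n_entities: int = 50
    depths: tuple[str, ...] = DEFAULT_DEPTHS
    start_month: str = "2016-07"
    end_month: str = "2019-07"
    fraction_seasonal: float = 0.5
    period_months: float = 12.0
    peak_month: int = 7
    amplitude: float = 10.0
    baseline: float = 100.0
    noise_sd: float = 2.0
    partial_year_flags: tuple[bool, ...] | None = None
    noise_kind: str = "gaussian"  # or "student_t"
    noise_df: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_entities >= 1, "n_entities", "must be >= 1")
        _require(0 <= self.fraction_seasonal <= 1, "fraction_seasonal",
                 "must be in [0, 1]")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(2 <= self.period_months <= 12, "period_months",
                 "must be in [2, 12]")
        _require(1 <= self.peak_month <= 12, "peak_month", "must be in 1-12")
        _require(len(self.depths) >= 1, "depths", "must be non-empty")
        _require(self.noise_kind in ("gaussian", "student_t"), "noise_kind",
                 "must be gaussian or student_t")
        if self.partial_year_flags is not None:
            _require(len(self.partial_year_flags) == self.n_entities,
                     "partial_year_flags", "length must equal n_entities")

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, self.end_month, freq="M")

    @property
    def n_seasonal(self) -> int:
        return int(round(self.fraction_seasonal * self.n_entities))

    def is_seasonal(self, entity_index: int) -> bool:
        return entity_index < self.n_seasonal

    def is_partial(self, entity_index: int) -> bool:
        if self.partial_year_flags is None:
            return False
        return bool(self.partial_year_flags[entity_index])

    def ground_truth(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_entities):
            seasonal = self.is_seasonal(i)
            rows.append({
                "entity_id": f"F{i:05d}",
                "is_seasonal": seasonal,
                "period_months": self.period_months if seasonal else np.nan,
                "peak_month": self.peak_month if seasonal else np.nan,
                "partial_year": self.is_partial(i),
            })
        return pd.DataFrame(rows)


def _entity_rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


def _noise(rng: np.random.Generator, spec: SyntheticCohortSpec, n: int) -> np.ndarray:
    if spec.noise_sd == 0:
        return np.zeros(n)
    if spec.noise_kind == "student_t":
        scale = spec.noise_sd / np.sqrt(spec.noise_df / (spec.noise_df - 2))
        return scale * rng.standard_t(spec.noise_df, n)
    return spec.noise_sd * rng.standard_normal(n)


def generate_series(
    spec: SyntheticCohortSpec, entity_index: int, depth_index: int = 0
) -> EntitySeries:
    """One entity's monthly series at one depth.

    Seasonal entities follow ``baseline + amplitude*cos(2*pi*(t - t_peak) /
    period) + noise`` with the cosine maximum anchored to the first grid
    month whose calendar month equals ``peak_month``; non-seasonal entities
    are ``baseline + noise``.  Partial-year entities carry the sinusoid only
    within the grid's second 12-month window.  Values are clipped at zero
    (intensities are non-negative).
    """
    _require(0 <= entity_index < spec.n_entities, "entity_index",
             f"must be < n_entities ({spec.n_entities})")
    _require(0 <= depth_index < len(spec.depths), "depth_index",
             f"must index depths ({len(spec.depths)})")
    months = spec.months
    n = len(months)
    t = np.arange(n, dtype=float)
    rng = _entity_rng(spec.seed, entity_index, depth_index)
    values = spec.baseline + _noise(rng, spec, n)
    if spec.is_seasonal(entity_index):
        cal = months.month.to_numpy()
        t_peak = float(np.flatnonzero(cal == spec.peak_month)[0])
        signal = spec.amplitude * np.cos(
            2 * np.pi * (t - t_peak) / spec.period_months
        )
        if spec.is_partial(entity_index):
            window = (t >= 12) & (t < 24)
            signal = np.where(window, signal, 0.0)
        values = values + signal
    return EntitySeries(
        entity_id=f"F{entity_index:05d}",
        entity_kind="DOM",
        depth=spec.depths[depth_index],
        months=months,
        values=np.clip(values, 0.0, None),
    )


def generate_feature_table(
    spec: SyntheticCohortSpec,
    blank_contaminant_fraction: float = 0.1,
    n_batches: int = 5,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Feature x injection table with blank / pool / batch structure.

    One sample injection per (depth, month), one process blank per sampling
    event (month), and two pool injections per batch.  Contaminant features
    (an exact ``round(fraction * n_entities)`` subset) have blank mean >=
    sample mean by construction; all other features are absent from blanks.
    Returns the table plus a ground-truth sidecar with per-feature classes.
    """
    _require(0 <= blank_contaminant_fraction <= 1,
             "blank_contaminant_fraction", "must be in [0, 1]")
    _require(n_batches >= 1, "n_batches", "must be >= 1")

    months = spec.months
    n_months = len(months)
    rng = _entity_rng(spec.seed, 10_000)

    # injection metadata; injection order is run order (used by pool-RSD)
    batch_of_month = np.minimum(
        (np.arange(n_months) * n_batches) // n_months, n_batches - 1
    )
    inj_rows = []
    for mi, month in enumerate(months):
        batch = f"B{batch_of_month[mi] + 1}"
        date = str(month.to_timestamp().date())
        for di, depth in enumerate(spec.depths):
            inj_rows.append({
                "injection_id": f"S_{month}_{depth}", "kind": "sample",
                "batch": batch, "depth": depth, "event_time": date,
            })
        inj_rows.append({
            "injection_id": f"BL_{month}", "kind": "process_blank",
            "batch": batch, "depth": None, "event_time": date,
        })
    for b in range(n_batches):
        first_month = months[np.flatnonzero(batch_of_month == b)[0]]
        for k in range(2):
            inj_rows.append({
                "injection_id": f"P_{b + 1}_{k + 1}", "kind": "pool",
                "batch": f"B{b + 1}", "depth": None,
                "event_time": str(first_month.to_timestamp().date()),
            })
    injections = pd.DataFrame(inj_rows)

    n_contam = int(round(blank_contaminant_fraction * spec.n_entities))
    contam = np.zeros(spec.n_entities, dtype=bool)
    contam[rng.choice(spec.n_entities, n_contam, replace=False)] = True

    feature_ids = [f"F{i:05d}" for i in range(spec.n_entities)]
    matrix = np.zeros((spec.n_entities, len(injections)))
    col_of = {iid: j for j, iid in enumerate(injections["injection_id"])}
    for i in range(spec.n_entities):
        sample_vals = np.empty((len(spec.depths), n_months))
        for di in range(len(spec.depths)):
            series = generate_series(spec, i, di)
            sample_vals[di] = series.values
            for mi, month in enumerate(months):
                matrix[i, col_of[f"S_{month}_{spec.depths[di]}"]] = series.values[mi]
        smean = sample_vals.mean()
        if contam[i]:
            # blank mean >= sample mean by construction
            for month in months:
                matrix[i, col_of[f"BL_{month}"]] = 2.0 * smean
        pool_noise = 1.0 + 0.03 * rng.standard_normal(2 * n_batches)
        j = 0
        for b in range(n_batches):
            for k in range(2):
                matrix[i, col_of[f"P_{b + 1}_{k + 1}"]] = max(
                    smean * pool_noise[j], 0.0
                )
                j += 1

    features = pd.DataFrame({
        "feature_id": feature_ids,
        "mz": 100.0 + 0.37 * np.arange(spec.n_entities),
        "rt": 60.0 + rng.uniform(0, 600, spec.n_entities).round(1),
        "peak_width": rng.uniform(3, 14, spec.n_entities).round(2),
        "median_rt_range": rng.uniform(0, 4, spec.n_entities).round(2),
        "isotope_flag": False,
        "adduct_flag": False,
    })
    intensities = pd.DataFrame(
        matrix, index=pd.Index(feature_ids, name="feature_id"),
        columns=list(injections["injection_id"]),
    )
    truth = spec.ground_truth()
    truth["is_contaminant"] = contam
    return FeatureTable(features, injections, intensities), truth


# ---------------------------------------------------------------------------
# Metagenome KO tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCommunitySpec:
    """Ground-truth description of a synthetic metagenome cohort.

    Each sample holds ``S_true`` taxa, each carrying exactly one contig per
    single-copy marker gene.  Each target KO is assigned to
    ``ceil(carrier_fraction * S_true)`` taxa whose RPKM contributions are
    drawn from a symmetric Dirichlet with concentration
    ``contribution_skew`` (infinity = exactly equal shares; small values =
    skewed toward few dominant carriers).
    """

    n_samples: int = 4
    S_true: int = 10
    scmg_ids: tuple[str, ...] = DEFAULT_SCMG_IDS
    ko_ids: tuple[str, ...] = ("K00244",)
    carrier_fraction: float = 1.0
    contribution_skew: float = math.inf
    season_labels: tuple[str, ...] | None = None
    rpkm_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_samples >= 1, "n_samples", "must be >= 1")
        _require(self.S_true >= 1, "S_true", "must be >= 1")
        _require(0 < self.carrier_fraction <= 1, "carrier_fraction",
                 "must be in (0, 1]")
        _require(self.contribution_skew > 0, "contribution_skew",
                 "must be > 0")
        _require(len(self.scmg_ids) >= 1, "scmg_ids", "must be non-empty")
        if self.season_labels is not None:
            _require(len(self.season_labels) == self.n_samples,
                     "season_labels", "length must equal n_samples")


def _hill_shannon(shares: np.ndarray) -> float:
    p = shares / shares.sum()
    p = p[p > 0]
    return float(np.exp(-(p * np.log(p)).sum()))


def generate_ko_table(
    spec: SyntheticCommunitySpec,
    ko_roles: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contig-level KO table plus a ground-truth CE sidecar.

    Returns ``(records, truth)`` where ``records`` has one row per contig
    with columns sample_id, contig_id, ko_id, rpkm, taxon, is_scmg,
    scmg_pass, evalue, season, role, and ``truth`` has the contribution
    evenness implied by the drawn shares for every (sample, KO).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 77]))
    ko_roles = ko_roles or {}
    rows = []
    truth_rows = []
    for si in range(spec.n_samples):
        sample = f"SMP{si:03d}"
        season = (spec.season_labels[si] if spec.season_labels is not None
                  else "summer_stratified")
        taxa = [f"taxon_{si:03d}_{t:04d}" for t in range(spec.S_true)]
        # exactly one SCMG contig per taxon per marker KO
        for t, taxon in enumerate(taxa):
            for scmg in spec.scmg_ids:
                rows.append({
                    "sample_id": sample,
                    "contig_id": f"{sample}_c{t:04d}_{scmg}",
                    "ko_id": scmg,
                    "rpkm": float(spec.rpkm_scale * rng.uniform(0.5, 2.0)),
                    "taxon": taxon, "is_scmg": True, "scmg_pass": True,
                    "evalue": 0.0, "season": season,
                    "role": "none",
                })
        for ko in spec.ko_ids:
            n_carriers = math.ceil(spec.carrier_fraction * spec.S_true)
            carriers = rng.choice(spec.S_true, n_carriers, replace=False)
            if math.isinf(spec.contribution_skew):
                shares = np.full(n_carriers, 1.0 / n_carriers)
            else:
                shares = rng.dirichlet(
                    np.full(n_carriers, spec.contribution_skew)
                )
            for c, share in zip(carriers, shares):
                rows.append({
                    "sample_id": sample,
                    "contig_id": f"{sample}_c{c:04d}_{ko}",
                    "ko_id": ko,
                    "rpkm": float(spec.rpkm_scale * spec.S_true * share),
                    "taxon": taxa[c], "is_scmg": False, "scmg_pass": False,
                    "evalue": 1e-15, "season": season,
                    "role": ko_roles.get(ko, "none"),
                })
            d1 = _hill_shannon(shares)
            ce = 1.0 if spec.S_true == 1 else (d1 - 1.0) / (spec.S_true - 1.0)
            truth_rows.append({
                "sample_id": sample, "ko_id": ko,
                "true_CE": ce, "n_carriers": n_carriers, "S_true": spec.S_true,
            })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def write_table_with_truth(
    table: pd.DataFrame, truth: pd.DataFrame, out_dir: str | Path,
    name: str = "table",
) -> None:
    """Write a generated table as TSV with a YAML ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    with open(out / f"{name}.truth.yaml", "w") as fh:
        yaml.safe_dump(truth.to_dict(orient="records"), fh, sort_keys=False)
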