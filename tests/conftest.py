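import numpy as np
import pandas as pd
import pytest

from domcycle import EntitySeries
from domcycle.qc import FeatureTable


def make_cosine_series(
    period=12.0, peak_month=7, amplitude=10.0, baseline=100.0,
    noise_sd=0.0, seed=0, start="2016-07", end="2019-07",
    entity_id="e", depth="1m", kind="DOM",
):
    """Monthly cosine series with the seasonal maximum in ``peak_month``."""
    months = pd.period_range(start, end, freq="M")
    t = np.arange(len(months), dtype=float)
    cal = months.month.to_numpy()
    t_peak = float(np.flatnonzero(cal == peak_month)[0])
    values = baseline + amplitude * np.cos(2 * np.pi * (t - t_peak) / period)
    if noise_sd > 0:
        values = values + noise_sd * np.random.default_rng(seed).standard_normal(
            len(months)
        )
    return EntitySeries(entity_id, kind, depth, months, np.clip(values, 0, None))


@pytest.fixture
def cosine_series():
    return make_cosine_series


@pytest.fixture
def blank_fixture_table():
    """Ten-feature worked table for the blank filter, built from clean logs.

    Intensities are 10**x - 1 so that log10(I + 1) equals the designed log
    values exactly; two identical sample and two identical blank injections
    make the per-kind mean logs equal the designed values.
    """
    s_log = [1, 2, 2, 3, 3, 2.8, 3.5, 3, 4, 3.2]
    b_log = [2, 1.5, 2.2, 1.5, 2, 2.4, 2, 2.9, 2.5, 3.4]
    S = 10 ** np.array(s_log, dtype=float) - 1
    B = 10 ** np.array(b_log, dtype=float) - 1
    fids = [f"F{i + 1}" for i in range(10)]
    features = pd.DataFrame({
        "feature_id": fids, "mz": 100.0, "rt": 60.0, "peak_width": 5.0,
        "median_rt_range": 1.0, "isotope_flag": False, "adduct_flag": False,
    })
    injections = pd.DataFrame({
        "injection_id": ["s1", "s2", "b1", "b2"],
        "kind": ["sample", "sample", "process_blank", "process_blank"],
        "batch": "B1", "depth": None, "event_time": None,
    })
    intensities = pd.DataFrame(
        {"s1": S, "s2": S, "b1": B, "b2": B},
        index=pd.Index(fids, name="feature_id"),
    )
    table = FeatureTable(features, injections, intensities)
    # frozen from the hand computation of bins, per-bin thresholds, decisions
    expected_kept = ["F4", "F5", "F6", "F7", "F8", "F9"]
    return table, expected_kept, (s_log, b_log)


def make_minimal_table(features_kwargs, n_samples=4, n_blanks=1, value=100.0):
    """Small feature table with uniform intensities for metadata-only filters."""
    features = pd.DataFrame(features_kwargs)
    n_feat = len(features)
    ids = [f"s{i}" for i in range(n_samples)] + [f"b{i}" for i in range(n_blanks)]
    kinds = ["sample"] * n_samples + ["process_blank"] * n_blanks
    injections = pd.DataFrame({
        "injection_id": ids, "kind": kinds, "batch": "B1",
        "depth": None, "event_time": None,
    })
    intensities = pd.DataFrame(
        np.full((n_feat, len(ids)), value),
        index=pd.Index(features["feature_id"], name="feature_id"), columns=ids,
    )
    return FeatureTable(features, injections, intensities)


def default_feature_meta(n, **overrides):
    meta = {
        "feature_id": [f"F{i}" for i in range(n)],
        "mz": [100.0 + i for i in range(n)],
        "rt": [60.0] * n,
        "peak_width": [5.0] * n,
        "median_rt_range": [1.0] * n,
        "isotope_flag": [False] * n,
        "adduct_flag": [False] * n,
    }
    meta.update(overrides)
    return meta
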