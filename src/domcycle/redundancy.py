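"""Functional redundancy from contig-level metagenome KO tables.

Functional redundancy of a metabolic gene (KEGG ortholog, KO) is quantified
with *contribution evenness* (CE): the effective number of community members
contributing to the KO (a Hill number of the RPKM contribution shares),
normalized by the sample's species richness S estimated from universal
single-copy marker genes (SCMGs, assumed one copy per genome).

CE = (D_q - 1) / (S - 1), clipped to [0, 1]:
CE = 0 means a single contributor (no redundancy); CE = 1 means all S
members contribute equally (absolute redundancy).  The default Hill order
q = 1 uses the exponential of the Shannon entropy of the shares.

The module also covers the surrounding bookkeeping: HMM e-value filtering,
SCMG richness, core-gene presence (> 85% of samples), RPKM-based functional
taxonomy, and Wilcoxon rank-sum comparisons of CE between groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CEResult",
    "evalue_filter",
    "richness",
    "contribution_evenness",
    "ce_table",
    "core_gene_presence",
    "functional_taxonomy",
    "group_tests",
]

REQUIRED_COLUMNS = ["sample_id", "contig_id", "ko_id", "rpkm", "is_scmg"]


@dataclass
class CEResult:
    sample_id: str
    ko_id: str
    CE: float
    S: int
    n_contributors: int
    total_rpkm: float


def evalue_filter(records: pd.DataFrame, threshold: float = 1e-10) -> pd.DataFrame:
    """Keep non-SCMG records with e-value <= threshold.

    SCMG hits are instead kept iff their precomputed score-threshold pass
    flag (``scmg_pass``) is set, regardless of e-value.
    """
    is_scmg = records["is_scmg"].astype(bool)
    scmg_pass = records.get("scmg_pass", pd.Series(False, index=records.index))
    keep = np.where(
        is_scmg,
        scmg_pass.astype(bool),
        records["evalue"].astype(float) <= threshold,
    )
    return records.loc[keep].copy()


def richness(
    sample_records: pd.DataFrame, method: str = "median"
) -> int:
    """Sample richness S from single-copy marker gene contig counts.

    Counts distinct contigs per SCMG KO and aggregates across markers with
    the given method (median by default, robust to a single anomalous
    marker; ``mean`` and ``sum`` available).  Median/mean results are
    rounded half-up to an integer.
    """
    scmg = sample_records[sample_records["is_scmg"].astype(bool)]
    if scmg.empty:
        raise ValueError("no SCMG records: richness undefined")
    counts = scmg.groupby("ko_id")["contig_id"].nunique()
    if method == "median":
        value = float(np.median(counts.to_numpy()))
    elif method == "mean":
        value = float(counts.mean())
    elif method == "sum":
        value = float(counts.sum())
    else:
        raise ValueError(f"unknown richness method {method!r}")
    return int(math.floor(value + 0.5))


def _hill_number(p: np.ndarray, q: float) -> float:
    p = p[p > 0]
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def contribution_evenness(
    contributions, S: int, q: float = 1.0
) -> float:
    """Contribution evenness of a KO from its per-contig RPKM contributions.

    Parameters
    ----------
    contributions : array-like
        Non-negative RPKM contributions, at least one positive.
    S : int
        Community richness from SCMGs.
    q : float
        Hill order of the effective-contributor number (1 = Shannon).

    Returns
    -------
    float in [0, 1]; 0 iff one contributor (for S > 1), 1 when all S members
    contribute equally.  Defined as 1 when S = 1.  If the effective number
    exceeds S (contributors outnumber SCMG-estimated richness) the value is
    clipped to 1 with a warning.
    """
    c = np.asarray(contributions, dtype=float)
    if (c < 0).any():
        raise ValueError("contributions must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero contributions: CE undefined")
    if S < 1:
        raise ValueError("S must be >= 1")
    if S == 1:
        return 1.0
    d_q = _hill_number(c / total, q)
    if d_q > S + 1e-9:
        warnings.warn(
            f"effective contributors ({d_q:.3g}) exceed SCMG richness ({S}); "
            "CE clipped to 1",
            stacklevel=2,
        )
    ce = (d_q - 1.0) / (S - 1.0)
    return float(min(max(ce, 0.0), 1.0))


def ce_table(
    records: pd.DataFrame,
    ko_ids: list[str] | None = None,
    *,
    q: float = 1.0,
    richness_method: str = "median",
) -> pd.DataFrame:
    """Per-(sample, KO) contribution evenness with SCMG richness.

    ``records`` should already be e-value filtered.  Returns one row per
    sample per target KO present in that sample, with columns CE, S,
    n_contributors, total_rpkm (one :class:`CEResult` per row).
    """
    rows: list[CEResult] = []
    for sample, grp in records.groupby("sample_id", sort=True):
        S = richness(grp, method=richness_method)
        targets = grp[~grp["is_scmg"].astype(bool)]
        if ko_ids is not None:
            targets = targets[targets["ko_id"].isin(ko_ids)]
        for ko, sub in targets.groupby("ko_id", sort=True):
            contribs = sub.groupby("contig_id")["rpkm"].sum().to_numpy()
            positive = contribs[contribs > 0]
            if len(positive) == 0:
                continue
            rows.append(
                CEResult(
                    sample_id=str(sample),
                    ko_id=str(ko),
                    CE=contribution_evenness(contribs, S, q=q),
                    S=S,
                    n_contributors=int(len(positive)),
                    total_rpkm=float(contribs.sum()),
                )
            )
    return pd.DataFrame([vars(r) for r in rows])


def core_gene_presence(
    records: pd.DataFrame, min_fraction: float = 0.85
) -> pd.DataFrame:
    """Fraction of samples in which each KO is present; core iff strictly above.

    Presence means >= 1 passing contig in the sample; core genes are those
    present in strictly more than ``min_fraction`` of all samples.
    """
    samples = records["sample_id"].unique()
    if len(samples) < 2:
        raise ValueError("core-gene presence needs >= 2 samples")
    targets = records[~records["is_scmg"].astype(bool)]
    present = (
        targets.groupby("ko_id")["sample_id"].nunique() / len(samples)
    ).rename("present_fraction").reset_index()
    present["is_core"] = present["present_fraction"] > min_fraction
    return present


def functional_taxonomy(
    records: pd.DataFrame,
    ko_set: list[str],
    *,
    unannotated_label: str = "unannotated",
    min_samples_displayed: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative taxonomic contribution to each KO, per sample, by RPKM.

    For each (sample, KO): group RPKM / total annotated RPKM for that KO
    (unannotated contigs are excluded from the denominator).  Returns
    ``(contributions, taxon_totals)``: the long contribution table (samples
    with zero annotated RPKM for a KO are omitted — the contribution is
    undefined there) and per-(sample, taxon) totals for pie scaling, with a
    ``displayed`` flag for taxa present in >= ``min_samples_displayed``
    samples.
    """
    sub = records[
        (~records["is_scmg"].astype(bool))
        & records["ko_id"].isin(ko_set)
        & (records["taxon"].astype(str) != unannotated_label)
        & records["taxon"].notna()
    ]
    by_group = (
        sub.groupby(["sample_id", "ko_id", "taxon"])["rpkm"].sum().reset_index()
    )
    totals = by_group.groupby(["sample_id", "ko_id"])["rpkm"].transform("sum")
    by_group["relative_contribution"] = by_group["rpkm"] / totals
    by_group = by_group[totals > 0]

    taxon_totals = (
        by_group.groupby(["sample_id", "taxon"])["relative_contribution"]
        .sum()
        .rename("total_relative_contribution")
        .reset_index()
    )
    n_samples_per_taxon = by_group.groupby("taxon")["sample_id"].nunique()
    taxon_totals["displayed"] = taxon_totals["taxon"].map(
        n_samples_per_taxon >= min_samples_displayed
    )
    return by_group, taxon_totals


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across groups; p = 1", stacklevel=3)
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_tests(
    ce_results: pd.DataFrame,
    group_col: str,
    value_col: str = "CE",
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between groups of CE values.

    One row per unordered pair of group labels, with the rank-sum statistic,
    p-value, and a significance flag at ``alpha`` (use 0.01 for
    metabolite-level and 0.1 for season-level comparisons).
    """
    groups = {
        str(k): g[value_col].to_numpy(dtype=float)
        for k, g in ce_results.groupby(group_col)
    }
    labels = sorted(groups)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            x, y = groups[a], groups[b]
            if len(x) < 3 or len(y) < 3:
                raise ValueError(
                    f"groups {a!r} vs {b!r}: need >= 3 values per group"
                )
            stat, p = _rank_sum(x, y)
            rows.append({
                "group_a": a, "group_b": b,
                "n_a": len(x), "n_b": len(y),
                "statistic": stat, "p_value": p,
                "significant": p <= alpha,
            })
    return pd.DataFrame(rows)
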