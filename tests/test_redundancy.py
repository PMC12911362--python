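import itertools
import math

import numpy as np
import pandas as pd
import pytest

from domcycle import (
    SyntheticCommunitySpec,
    ce_table,
    contribution_evenness,
    core_gene_presence,
    evalue_filter,
    functional_taxonomy,
    generate_ko_table,
    group_tests,
    richness,
)


def make_records(rows):
    defaults = {
        "sample_id": "S1", "contig_id": "c", "ko_id": "K00001", "rpkm": 1.0,
        "taxon": "t", "is_scmg": False, "scmg_pass": False, "evalue": 1e-15,
        "season": "summer_stratified", "role": "none",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestEvalueFilter:
    def test_boundary_inclusive(self):
        rec = make_records([
            {"contig_id": "a", "evalue": 1e-12},
            {"contig_id": "b", "evalue": 1e-10},
            {"contig_id": "c", "evalue": 1e-9},
        ])
        out = evalue_filter(rec)
        assert list(out["contig_id"]) == ["a", "b"]

    def test_scmg_uses_pass_flag_not_evalue(self):
        rec = make_records([
            {"contig_id": "a", "is_scmg": True, "scmg_pass": False,
             "evalue": 1e-30},
            {"contig_id": "b", "is_scmg": True, "scmg_pass": True,
             "evalue": 1.0},
        ])
        out = evalue_filter(rec)
        assert list(out["contig_id"]) == ["b"]

    def test_toy_counts(self):
        evs = [1e-12, 1e-11, 1e-10, 1e-9, 1e-8, 1e-5, 1.0, 1e-15, 2e-10]
        rec = make_records(
            [{"contig_id": f"c{i}", "evalue": e} for i, e in enumerate(evs)]
        )
        assert len(evalue_filter(rec)) == 4


class TestRichness:
    def test_uniform_marker_counts(self):
        rows = [
            {"contig_id": f"c{k}_{i}", "ko_id": f"K{k:05d}", "is_scmg": True}
            for k in range(10) for i in range(50)
        ]
        assert richness(make_records(rows)) == 50

    def test_median_over_markers(self):
        counts = [48, 49, 50, 50, 50, 50, 50, 51, 52, 60]
        rows = [
            {"contig_id": f"c{k}_{i}", "ko_id": f"K{k:05d}", "is_scmg": True}
            for k, n in enumerate(counts) for i in range(n)
        ]
        assert richness(make_records(rows)) == 50

    def test_single_marker(self):
        rows = [{"contig_id": f"c{i}", "ko_id": "K01409", "is_scmg": True}
                for i in range(30)]
        assert richness(make_records(rows)) == 30

    def test_median_rounds_half_up(self):
        rows = [{"contig_id": "c1", "ko_id": "K1", "is_scmg": True},
                {"contig_id": "c2", "ko_id": "K2", "is_scmg": True},
                {"contig_id": "c3", "ko_id": "K2", "is_scmg": True}]
        assert richness(make_records(rows)) == 2  # median(1, 2) = 1.5 -> 2

    def test_invariant_to_duplicating_non_scmg_records(self):
        scmg = [{"contig_id": f"c{i}", "ko_id": "K01409", "is_scmg": True}
                for i in range(5)]
        other = [{"contig_id": "x", "ko_id": "K00244", "is_scmg": False}] * 7
        assert richness(make_records(scmg + other)) == richness(
            make_records(scmg)
        )

    def test_no_scmg_error(self):
        with pytest.raises(ValueError):
            richness(make_records([{"is_scmg": False}]))


class TestContributionEvenness:
    def test_single_contributor_is_zero(self):
        assert contribution_evenness([5.0], S=10) == 0.0
        assert contribution_evenness([5.0, 0.0, 0.0], S=10) == 0.0

    def test_all_members_equal_is_one(self):
        assert contribution_evenness([3.0] * 10, S=10) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_two_equal_of_four(self):
        assert contribution_evenness([2.0, 2.0], S=4) == pytest.approx(1 / 3)

    def test_scale_invariance(self):
        c = np.array([0.3, 1.2, 4.5, 0.7])
        a = contribution_evenness(c, S=8)
        b = contribution_evenness(1e4 * c, S=8)
        assert a == pytest.approx(b, abs=1e-14)

    def test_schur_concavity_robin_hood_transfers(self):
        # moving mass from a larger to a smaller contributor never lowers CE
        rng = np.random.default_rng(101)
        for _ in range(1000):
            k = int(rng.integers(2, 9))
            v = rng.gamma(1.0, 1.0, k) + 1e-6
            i, j = np.argmax(v), np.argmin(v)
            if v[i] == v[j]:
                continue
            delta = rng.uniform(0, 0.5) * (v[i] - v[j])
            w = v.copy()
            w[i] -= delta
            w[j] += delta
            assert contribution_evenness(w, S=10) >= contribution_evenness(
                v, S=10
            ) - 1e-12

    def test_effective_number_above_richness_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            ce = contribution_evenness([1.0] * 10, S=5)
        assert ce == 1.0

    def test_s_equal_one_defined_as_one(self):
        assert contribution_evenness([2.0], S=1) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            contribution_evenness([0.0, 0.0], S=5)

    def test_hill_order_generalisation_endpoints(self):
        for q in (0.5, 2.0):
            assert contribution_evenness([1.0] * 10, S=10, q=q) == pytest.approx(1.0)
            assert contribution_evenness([1.0], S=10, q=q) == 0.0


class TestCeTable:
    def test_recovers_generator_ground_truth(self):
        spec = SyntheticCommunitySpec(
            n_samples=5, S_true=20, carrier_fraction=0.6,
            contribution_skew=0.8, ko_ids=("K00244", "K13057"), seed=23,
        )
        records, truth = generate_ko_table(spec)
        result = ce_table(evalue_filter(records))
        merged = result.merge(truth, on=["sample_id", "ko_id"])
        assert len(merged) == len(truth)
        assert np.allclose(merged["CE"], merged["true_CE"], atol=1e-12)
        assert (merged["S"] == spec.S_true).all()


class TestCoreGenePresence:
    def test_ubiquitous_ko_is_core(self):
        rows = [{"sample_id": f"S{i}", "contig_id": f"c{i}",
                 "ko_id": "K00244"} for i in range(10)]
        out = core_gene_presence(make_records(rows))
        assert out["present_fraction"].iloc[0] == 1.0
        assert bool(out["is_core"].iloc[0])

    def test_exactly_85_percent_not_core(self):
        rows = [{"sample_id": f"S{i}", "contig_id": f"c{i}",
                 "ko_id": "K1"} for i in range(17)]
        rows += [{"sample_id": f"S{i}", "contig_id": f"d{i}", "ko_id": "K2"}
                 for i in range(20)]
        out = core_gene_presence(make_records(rows)).set_index("ko_id")
        assert out.loc["K1", "present_fraction"] == pytest.approx(0.85)
        assert not bool(out.loc["K1", "is_core"])

    def test_24_of_28_samples_is_core(self):
        rows = [{"sample_id": f"S{i}", "contig_id": f"c{i}", "ko_id": "K1"}
                for i in range(24)]
        rows += [{"sample_id": f"S{i}", "contig_id": f"d{i}", "ko_id": "K2"}
                 for i in range(28)]
        out = core_gene_presence(make_records(rows)).set_index("ko_id")
        assert out.loc["K1", "present_fraction"] == pytest.approx(24 / 28)
        assert bool(out.loc["K1", "is_core"])


class TestFunctionalTaxonomy:
    def test_single_taxon_full_contribution(self):
        rec = make_records([
            {"taxon": "Alphaproteobacteria", "rpkm": 12.0, "ko_id": "K00244"},
        ])
        contrib, _ = functional_taxonomy(rec, ["K00244"])
        assert contrib["relative_contribution"].iloc[0] == 1.0

    def test_thirty_seventy_split(self):
        rec = make_records([
            {"contig_id": "a", "taxon": "A", "rpkm": 30.0, "ko_id": "K1"},
            {"contig_id": "b", "taxon": "B", "rpkm": 70.0, "ko_id": "K1"},
        ])
        contrib, _ = functional_taxonomy(rec, ["K1"])
        by_taxon = contrib.set_index("taxon")["relative_contribution"]
        assert by_taxon["A"] == pytest.approx(0.3)
        assert by_taxon["B"] == pytest.approx(0.7)

    def test_unannotated_excluded_from_denominator(self):
        rec = make_records([
            {"contig_id": "a", "taxon": "A", "rpkm": 30.0, "ko_id": "K1"},
            {"contig_id": "b", "taxon": "unannotated", "rpkm": 70.0,
             "ko_id": "K1"},
        ])
        contrib, _ = functional_taxonomy(rec, ["K1"])
        assert contrib["relative_contribution"].iloc[0] == 1.0

    def test_seeded_table_matches_bruteforce_groupby(self):
        rng = np.random.default_rng(55)
        rows = []
        for s in range(3):
            for t in range(4):
                for ko in ("K1", "K2"):
                    rows.append({
                        "sample_id": f"S{s}", "contig_id": f"c{s}{t}{ko}",
                        "taxon": f"T{t}", "ko_id": ko,
                        "rpkm": float(rng.uniform(1, 50)),
                    })
        rec = make_records(rows)
        contrib, totals = functional_taxonomy(rec, ["K1", "K2"])
        for _, row in contrib.iterrows():
            sub = rec[(rec["sample_id"] == row["sample_id"])
                      & (rec["ko_id"] == row["ko_id"])]
            expected = (
                sub[sub["taxon"] == row["taxon"]]["rpkm"].sum()
                / sub["rpkm"].sum()
            )
            assert row["relative_contribution"] == pytest.approx(expected)
        assert (totals.groupby("sample_id")["total_relative_contribution"]
                .sum().round(9) == 2.0).all()


def exact_rank_sum_p(x, y):
    """Brute-force exact two-sided rank-sum p-value by enumeration."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[: len(x)].sum()
    n = len(pooled)
    total = 0
    extreme = 0
    mean_w = len(x) * (n + 1) / 2
    for comb in itertools.combinations(range(n), len(x)):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mean_w) >= abs(obs - mean_w) - 1e-12:
            extreme += 1
    return extreme / total


class TestGroupTests:
    def test_identical_groups_p_one(self):
        df = pd.DataFrame({
            "CE": [0.5] * 6, "metabolite": ["a"] * 3 + ["b"] * 3,
        })
        with pytest.warns(UserWarning, match="tied"):
            out = group_tests(df, "metabolite")
        assert out["p_value"].iloc[0] == 1.0

    def test_separated_groups_match_exact_enumeration(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0.0, 0.3, 10)
        y = rng.uniform(0.7, 1.0, 10)
        df = pd.DataFrame({
            "CE": np.r_[x, y],
            "metabolite": ["trehalose"] * 10 + ["succinate"] * 10,
        })
        out = group_tests(df, "metabolite", alpha=0.01)
        # completely separated: exact two-sided p = 2 / C(20, 10)
        assert out["p_value"].iloc[0] == pytest.approx(2 / math.comb(20, 10))
        assert bool(out["significant"].iloc[0])

    def test_matches_bruteforce_enumeration_small_n(self):
        rng = np.random.default_rng(71)
        x = rng.normal(0.4, 0.1, 5)
        y = rng.normal(0.6, 0.1, 6)
        df = pd.DataFrame({"CE": np.r_[x, y],
                           "season": ["w"] * 5 + ["s"] * 6})
        out = group_tests(df, "season", alpha=0.1)
        assert out["p_value"].iloc[0] == pytest.approx(
            exact_rank_sum_p(y, x), abs=1e-9
        )

    def test_detection_power_for_generator_imposed_shift(self):
        # shift 0.2 at n = 12/group should be detected > 80% of the time
        rng = np.random.default_rng(202)
        detected = 0
        n_rep = 200
        for _ in range(n_rep):
            a = np.clip(rng.normal(0.3, 0.15, 12), 0, 1)
            b = np.clip(rng.normal(0.5, 0.15, 12), 0, 1)
            df = pd.DataFrame({"CE": np.r_[a, b],
                               "season": ["w"] * 12 + ["s"] * 12})
            out = group_tests(df, "season", alpha=0.05)
            detected += int(out["significant"].iloc[0])
        assert detected / n_rep > 0.8

    def test_small_groups_rejected(self):
        df = pd.DataFrame({"CE": [0.1, 0.2, 0.3, 0.4],
                           "g": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError):
            group_tests(df, "g")
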