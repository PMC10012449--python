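"""Proximity-enrichment statistic: success ratios, Mann-Whitney, Fisher loci."""
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import smokewas as sw
from smokewas import gwasprox


def catalog_from(positions, group="A", chromosome="chr1"):
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(len(positions))],
        "chromosome": [chromosome] * len(positions),
        "position": positions,
        "pvalue": [1e-8] * len(positions),
        "group": [group] * len(positions),
    })


ONE_CPG = pd.DataFrame({"cpg_id": ["c1"], "chromosome": ["chr1"], "position": [100_000]})


class TestDatasetFilter:
    def test_threshold_rules(self):
        meta = pd.DataFrame({
            "dataset": ["a", "b", "c", "d"],
            "confidence": ["high", "high", "low", "high"],
            "h2": [0.02, 0.005, 0.5, 0.02],
            "h2_z": [8.0, 10.0, 20.0, 6.9],
        })
        kept = sw.filter_gwas_datasets(meta)
        assert list(kept["dataset"]) == ["a"]

    def test_empty_metadata(self):
        meta = pd.DataFrame(columns=["dataset", "confidence", "h2", "h2_z"])
        assert len(sw.filter_gwas_datasets(meta)) == 0

    def test_missing_column_rejected(self):
        with pytest.raises(KeyError):
            sw.filter_gwas_datasets(pd.DataFrame({"h2": [0.1]}))

    def test_snp_filter_directions(self):
        cat = catalog_from([1, 2])
        cat["pvalue"] = [1e-8, 0.5]
        assert list(sw.filter_snps(cat)["snp_id"]) == ["rs0"]
        assert list(sw.filter_snps(cat, keep="above")["snp_id"]) == ["rs1"]


class TestSuccessRatios:
    def test_distance_rule(self):
        cat = catalog_from([99_500, 101_200, 110_000, 150_000])
        ratios = sw.success_ratios(ONE_CPG, cat, [1_000])
        assert ratios["success_ratio"].iloc[0] == pytest.approx(0.25)

    def test_strict_boundary_excluded(self):
        # SNP at exactly D = 50,000 bp away does not count
        cat = catalog_from([99_500, 101_200, 110_000, 150_000])
        ratios = sw.success_ratios(ONE_CPG, cat, [50_000])
        assert ratios["success_ratio"].iloc[0] == pytest.approx(0.75)

    def test_other_chromosome_never_counts(self):
        cat = catalog_from([100_000], chromosome="chr2")
        ratios = sw.success_ratios(ONE_CPG, cat, [1_000, 50_000])
        assert (ratios["successes"] == 0).all()

    def test_monotone_in_distance(self):
        rng = np.random.default_rng(4)
        cat = catalog_from(sorted(rng.integers(1, 1_000_000, 200)))
        cpgs = pd.DataFrame({"cpg_id": [f"c{i}" for i in range(10)],
                             "chromosome": ["chr1"] * 10,
                             "position": rng.integers(1, 1_000_000, 10)})
        ratios = sw.success_ratios(cpgs, cat, [1_000, 5_000, 25_000, 100_000])
        for _, sub in ratios.groupby("cpg_id"):
            vals = sub.sort_values("max_distance")["success_ratio"].to_numpy()
            assert (np.diff(vals) >= 0).all()

    def test_empty_group_warns_and_emits_missing(self):
        cat = catalog_from([99_500])
        cat["group"] = pd.Categorical(["A"], categories=["A", "B"])
        with pytest.warns(UserWarning, match="zero SNPs"):
            ratios = sw.success_ratios(ONE_CPG, cat, [1_000])
        b_row = ratios[ratios["group"] == "B"]
        assert len(b_row) == 1 and np.isnan(b_row["success_ratio"].iloc[0])

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            sw.success_ratios(ONE_CPG, catalog_from([1]), [0])


class TestMannWhitney:
    def test_two_by_two_example(self):
        u, p = sw.compare_groups([0.9, 0.8], [0.1, 0.2], "greater")
        assert u == 4 and p == pytest.approx(1 / 6)

    def test_wrong_tail_gives_one(self):
        u, p = sw.compare_groups([1, 2, 3], [4, 5, 6], "greater")
        assert u == 0 and p == pytest.approx(1.0)

    def test_three_by_three_extreme(self):
        u, p = sw.compare_groups([4, 5, 6], [1, 2, 3], "greater")
        assert u == 9 and p == pytest.approx(1 / 20)

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            for alt in ("greater", "less"):
                u, p = sw.compare_groups(a, b, alt)
                ref = stats.mannwhitneyu(a, b, alternative=alt, method="exact")
                assert u == pytest.approx(ref.statistic)
                assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_exact_matches_independent_enumeration(self):
        a, b = [0.0, 0.5, 0.5], [0.0, 0.0, 0.2]
        u_obs, p = sw.compare_groups(a, b, "greater")
        pooled = np.asarray(a + b)
        ranks = stats.rankdata(pooled)

        def u_of(idx):
            return ranks[list(idx)].sum() - len(idx) * (len(idx) + 1) / 2

        total = comb(6, 3)
        hits = sum(u_of(idx) >= u_obs - 1e-9
                   for idx in combinations(range(6), 3))
        assert p == pytest.approx(hits / total)

    def test_swapping_groups_and_tail_preserves_p(self):
        rng = np.random.default_rng(9)
        for n in (4, 8, 20):
            a = rng.uniform(size=n)
            b = rng.uniform(size=n)
            _, p1 = sw.compare_groups(a, b, "greater")
            _, p2 = sw.compare_groups(b, a, "less")
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sw.compare_groups([], [1.0])


class TestLocusEnrichment:
    def make_two_group_catalog(self, rel_within, rel_total, ctl_within, ctl_total):
        # "within" SNPs sit 500 bp from the CpG, the rest 1 Mb away
        positions, groups = [], []
        for n_within, n_total, g in ((rel_within, rel_total, "rel"),
                                     (ctl_within, ctl_total, "ctl")):
            positions += [100_500] * n_within + [1_100_000] * (n_total - n_within)
            groups += [g] * n_total
        cat = catalog_from(positions)
        cat["group"] = groups
        return cat

    def test_matches_hypergeometric_tail_oracle(self):
        cat = self.make_two_group_catalog(6, 10, 5, 100)
        table = sw.locus_enrichment(ONE_CPG, cat, "rel", "ctl", [1_000])
        # fixed-margins tail: P(X >= 6), X hypergeom(N=110, K=10, n=11)
        expected = stats.hypergeom.sf(5, 110, 10, 11)
        assert table["p_value"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_no_successes_gives_p_one(self):
        cat = self.make_two_group_catalog(0, 5, 0, 5)
        table = sw.locus_enrichment(ONE_CPG, cat, "rel", "ctl", [1_000])
        assert table["p_value"].iloc[0] == 1.0

    def test_all_relevant_within_extreme(self):
        # 3 relevant all within, 5 control all beyond: p = 1/C(8,3) = 1/56
        cat = self.make_two_group_catalog(3, 3, 0, 5)
        table = sw.locus_enrichment(ONE_CPG, cat, "rel", "ctl", [1_000])
        assert table["p_value"].iloc[0] == pytest.approx(1 / 56)

    def test_summary_reports_largest_significant_distance(self):
        table = pd.DataFrame({
            "cpg_id": ["c1"] * 3,
            "gene": ["G"] * 3,
            "max_distance": [1_000, 5_000, 50_000],
            "relevant_within": [3, 3, 3],
            "control_within": [0, 0, 3],
            "p_value": [0.001, 0.002, 0.4],
            "fdr": [0.01, 0.02, 0.6],
        })
        summary = sw.summarize_locus_enrichment(table)
        assert len(summary) == 1
        assert summary["max_distance"].iloc[0] == 5_000

    def test_missing_group_rejected(self):
        cat = self.make_two_group_catalog(1, 2, 1, 2)
        with pytest.raises(ValueError):
            sw.locus_enrichment(ONE_CPG, cat, "rel", "nope", [1_000])


class TestDualViews:
    def test_histogram_counts_cover_nonzero_ratios(self):
        rng = np.random.default_rng(10)
        cat = catalog_from(sorted(rng.integers(1, 500_000, 100)))
        cpgs = pd.DataFrame({"cpg_id": [f"c{i}" for i in range(8)],
                             "chromosome": ["chr1"] * 8,
                             "position": rng.integers(1, 500_000, 8)})
        ratios = sw.success_ratios(cpgs, cat, [25_000])
        hist = gwasprox.success_ratio_histogram(ratios, n_bins=5)
        nonzero = (ratios["success_ratio"] > 0).sum()
        assert hist["count"].sum() == nonzero

    def test_per_snp_view_bounded(self):
        cat = catalog_from([99_000, 500_000])
        table = gwasprox.per_snp_success(ONE_CPG, cat, [5_000])
        assert list(table["cpgs_within"]) == [1, 0]
        assert (table["success_ratio"] <= 1).all()
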