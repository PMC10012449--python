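"""Interaction-model fits, BH arithmetic, tiers and plot tables."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smokewas as sw
from smokewas.ewas import build_design
from smokewas.preprocess import MethylationMatrix


def random_sample_table(rng, n=12):
    return pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n)],
        "age": rng.integers(40, 67, n),
        "cigarettes_total": rng.integers(0, 5_000, n),
        "ic50": rng.uniform(0.1, 5.0, n),
        "smoker_class": ["past"] * n,
    })


def brute_force_bh(pvals, m_total):
    """Independent step-up oracle, straight from the definition."""
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    adj = [None] * len(pvals)
    best = 1.0
    for rank in range(len(pvals), 0, -1):
        i = order[rank - 1]
        best = min(best, m_total * pvals[i] / rank)
        adj[i] = best
    return adj


class TestFit:
    def test_noiseless_coefficients_recovered_exactly(self, cohort):
        effects = {
            "ic50_main": [(0, 0.2)],
            "smoking_main": [(1, 1e-6)],
            "interaction": [(2, 5e-7)],
            "age": [(3, 0.01)],
        }
        my = sw.generate_methylome(cohort, 20, n_cell_types=1, effects=effects,
                                   noise_sd=0.0, seed=1)
        res = sw.run_ewas(MethylationMatrix(my.mvalues, "mvalue"), cohort)
        assert res.loc[0, "ic50_main_coef"] == pytest.approx(0.2, abs=1e-9)
        assert res.loc[1, "smoking_main_coef"] == pytest.approx(1e-6, abs=1e-12)
        assert res.loc[2, "interaction_coef"] == pytest.approx(5e-7, abs=1e-12)
        # probes without planted effects fit zero
        assert abs(res.loc[10, "interaction_coef"]) < 1e-12

    def test_matches_independent_regression_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        for _ in range(25):
            samples = random_sample_table(rng)
            y = rng.normal(size=len(samples))
            got = sw.fit_interaction_model(y, samples)
            x, _ = build_design(samples)
            fit = sm.OLS(y, x).fit()
            for eff, col in (("ic50_main", 1), ("smoking_main", 2), ("interaction", 3)):
                coef, t, p = got[eff]
                assert coef == pytest.approx(fit.params[col], abs=1e-10, rel=1e-10)
                assert t == pytest.approx(fit.tvalues[col], abs=1e-8, rel=1e-8)
                assert p == pytest.approx(fit.pvalues[col], abs=1e-10, rel=1e-8)

    def test_constant_probe_reports_p_one(self, cohort):
        y = np.full(len(cohort), 2.5)
        got = sw.fit_interaction_model(y, cohort)
        for coef, t, p in got.values():
            assert coef == pytest.approx(0.0, abs=1e-9)
            assert t == 0.0 and p == 1.0

    def test_rank_deficient_design_flagged(self, cohort):
        broken = cohort.copy()
        broken["cigarettes_total"] = 0          # smoking and interaction collinear
        with pytest.raises(np.linalg.LinAlgError):
            sw.fit_interaction_model(np.zeros(len(broken)), broken)

    def test_row_conservation_and_sample_check(self, cohort, methylome):
        mat = MethylationMatrix(methylome.mvalues, "mvalue")
        res = sw.run_ewas(mat, cohort)
        assert len(res) == len(methylome.mvalues)
        with pytest.raises(ValueError, match="mismatch"):
            sw.run_ewas(mat, cohort.iloc[:20])

    def test_effect_size_for_t_calibrates_expected_t(self, cohort):
        # noiseless check: planting exactly b3 gives t -> infinity; instead
        # verify the linear-algebra identity t = b3 / (sd * sqrt((X'X)^-1_33))
        b3 = sw.effect_size_for_t(cohort, 8.0, 0.1)
        x, _ = build_design(cohort)
        se_unit = 0.1 * np.sqrt(np.linalg.inv(x.T @ x)[3, 3])
        assert b3 / se_unit == pytest.approx(8.0, rel=1e-12)


class TestBH:
    def test_forced_step_up_arithmetic(self):
        assert np.allclose(sw.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_scales_by_m_total(self):
        assert sw.bh_fdr([1e-6], m_total=1_000_000)[0] == pytest.approx(1.0)
        assert sw.bh_fdr([1e-8], m_total=1_000_000)[0] == pytest.approx(0.01)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 21))
            p = rng.uniform(1e-6, 1.0, n)
            m_total = n + int(rng.integers(0, 100))
            assert np.allclose(sw.bh_fdr(p, m_total), brute_force_bh(list(p), m_total))

    def test_matches_statsmodels_when_m_equals_length(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 40)
        ours = sw.bh_fdr(p)
        theirs = sm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=60, derandomize=True)
    def test_permutation_invariant_and_monotone(self, pvals):
        p = np.asarray(pvals)
        adj = sw.bh_fdr(p)
        assert ((adj > 0) & (adj <= 1)).all()
        # permutation invariance
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        assert np.allclose(sw.bh_fdr(p[perm]), adj[perm])
        # monotone in p
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sw.bh_fdr([0.1, 0.2], m_total=1)
        with pytest.raises(ValueError):
            sw.bh_fdr([0.0])


class TestTiers:
    @pytest.mark.parametrize("p,fdr,tier", [
        (4.27e-06, 0.049, "genome_wide"),
        (5e-06, 0.2, "suggestive"),
        (0.5, 0.9, "none"),
        (2e-05, 0.2, "none"),
    ])
    def test_tier_rules(self, p, fdr, tier):
        assert sw.classify_significance(p, fdr) == tier


class TestPlotTables:
    def test_qq_expected_quantiles(self):
        res = pd.DataFrame({
            "probe_id": ["a", "b", "c"],
            "interaction_coef": [0.0] * 3,
            "interaction_p": [0.5, 0.1, 0.9],
            "interaction_fdr": [0.9, 0.3, 0.9],
        })
        qq = sw.plot_tables(res)["qq"]
        assert np.allclose(qq["expected_neg_log10_p"],
                           -np.log10([0.25, 0.5, 0.75]))
        assert np.allclose(qq["observed_neg_log10_p"],
                           -np.log10([0.1, 0.5, 0.9]))

    def test_uniform_pvalues_hug_the_diagonal(self):
        rng = np.random.default_rng(13)
        m = 2_000
        p = rng.uniform(size=m)
        res = pd.DataFrame({
            "probe_id": [f"c{i}" for i in range(m)],
            "interaction_coef": np.zeros(m),
            "interaction_p": p,
            "interaction_fdr": sw.bh_fdr(p),
        })
        qq = sw.plot_tables(res)["qq"]
        # compare on the p scale where the KS bound applies
        obs = 10.0 ** (-qq["observed_neg_log10_p"].to_numpy())
        exp = 10.0 ** (-qq["expected_neg_log10_p"].to_numpy())
        assert np.abs(obs - exp).max() < 2 * 1.63 / np.sqrt(m)

    def test_volcano_tiers_match_classifier(self, cohort, methylome):
        res = sw.run_ewas(MethylationMatrix(methylome.mvalues, "mvalue"), cohort,
                          annotation=methylome.annotation)
        volcano = sw.plot_tables(res)["volcano"]
        expected = sw.classify_significance(res["interaction_p"].to_numpy(),
                                            res["interaction_fdr"].to_numpy())
        assert (volcano["tier"].to_numpy() == expected).all()
        manhattan = sw.plot_tables(res)["manhattan"]
        assert len(manhattan) == len(res)
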