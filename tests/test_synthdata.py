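"""Generator contracts: study-like ranges, determinism, ground-truth invariants."""
import numpy as np
import pandas as pd
import pytest

import smokewas as sw
from smokewas import synthdata
from smokewas.genesets import hypergeom_ora
from smokewas.gwasprox import success_ratios


class TestCohort:
    def test_default_cohort_matches_study_ranges(self, cohort):
        assert len(cohort) == 34
        assert cohort["age"].between(40, 66).all()
        assert cohort["cigarettes_total"].between(0, 268_800).all()
        assert cohort["ic50"].between(0.061, 9.49).all()
        assert cohort["sample_id"].is_unique

    def test_never_smokers_have_zero_cigarettes(self, cohort):
        never = cohort["smoker_class"] == "never"
        assert (cohort.loc[never, "cigarettes_total"] == 0).all()
        assert (cohort.loc[~never, "cigarettes_total"] > 0).all()

    def test_all_never_config_forces_zero(self):
        cfg = sw.CohortConfig(smoker_class_probs=(1.0, 0.0, 0.0))
        c = sw.generate_cohort(20, cfg, seed=3)
        assert (c["cigarettes_total"] == 0).all()

    def test_seeded_reproducibility(self):
        a = sw.generate_cohort(34, seed=5)
        b = sw.generate_cohort(34, seed=5)
        assert a.to_csv() == b.to_csv()

    @pytest.mark.parametrize("n", [0, 1])
    def test_too_few_samples_rejected(self, n):
        with pytest.raises(ValueError):
            sw.generate_cohort(n)

    def test_degenerate_config_rejected(self):
        cfg = sw.CohortConfig(cigarettes_range=(100.0, 100.0))
        with pytest.raises(ValueError):
            sw.generate_cohort(10, cfg)


class TestMethylome:
    def test_cell_proportions_sum_to_one(self, methylome):
        rows = methylome.truth.cell_proportions.sum(axis=1)
        assert np.abs(rows - 1.0).max() < 1e-12
        assert (methylome.truth.cell_proportions.to_numpy() >= 0).all()

    def test_intensities_nonnegative_and_beta_in_open_interval(self, methylome):
        assert (methylome.intensities.m_signal.to_numpy() >= 0).all()
        assert (methylome.intensities.u_signal.to_numpy() >= 0).all()
        beta = sw.compute_beta(methylome.intensities).values.to_numpy()
        assert ((beta > 0) & (beta < 1)).all()

    def test_intensity_round_trip_recovers_mvalues(self, methylome):
        beta = sw.compute_beta(methylome.intensities)
        m = sw.beta_to_m(beta)
        err = np.abs(m.values.to_numpy() - methylome.mvalues.to_numpy()).max()
        assert err < 1e-9

    def test_seeded_reproducibility(self, cohort):
        a = sw.generate_methylome(cohort, 50, seed=9)
        b = sw.generate_methylome(cohort, 50, seed=9)
        assert a.mvalues.equals(b.mvalues)
        assert a.annotation.equals(b.annotation)

    def test_annotation_exercises_filters(self, cohort):
        my = sw.generate_methylome(cohort, 2_000, seed=4)
        ann = my.annotation
        assert (ann["chromosome"] == "chrY").any()
        assert ann["snp_overlap"].any()
        assert (ann["position"] >= 1).all()

    def test_invalid_inputs_rejected(self, cohort):
        with pytest.raises(ValueError):
            sw.generate_methylome(cohort, 10, noise_sd=-0.1)
        with pytest.raises(ValueError):
            sw.generate_methylome(cohort, 10, effects={"interaction": [("cg9999999", 1e-6)]})
        with pytest.raises(ValueError):
            sw.generate_methylome(cohort, 10, effects={"bogus_kind": [(0, 1e-6)]})

    def test_shared_effect_probes_rejected_by_default(self, cohort):
        effects = {"interaction": [(0, 1e-6)], "ic50_main": [(0, 0.1)]}
        with pytest.raises(ValueError):
            sw.generate_methylome(cohort, 10, effects=effects)
        cfg = sw.MethylomeConfig(allow_shared_effect_probes=True)
        sw.generate_methylome(cohort, 10, effects=effects, config=cfg)  # no raise

    def test_truth_record_json_round_trip(self, methylome, tmp_path):
        path = tmp_path / "truth.json"
        methylome.truth.save(path)
        import json
        loaded = json.loads(path.read_text())
        assert loaded["noise_sd"] == methylome.truth.noise_sd
        assert loaded["cell_proportions"]["sample_id"][0] == "S001"


class TestGwasCatalog:
    def test_clustered_group_has_higher_success_ratio(self):
        targets = [("chr1", 2_000_000), ("chr1", 7_000_000), ("chr2", 4_000_000)]
        res = synthdata.generate_gwas_catalog(
            {"A": 150, "B": 150}, targets,
            clustering={"A": (10_000, 0.5)}, seed=21)
        cpgs = pd.DataFrame({
            "cpg_id": ["c1", "c2", "c3"],
            "chromosome": [t[0] for t in targets],
            "position": [t[1] for t in targets],
        })
        ratios = success_ratios(cpgs, res.catalog, [10_000])
        mean = ratios.groupby("group", observed=True)["success_ratio"].mean()
        assert mean["A"] > mean["B"]
        assert res.planted["planted"].sum() > 0

    def test_uniform_placement_matches_expectation(self):
        # one 10 Mb chromosome, central CpG, D = 50 kb: E[ratio] = 2D/L = 0.01
        genome = {"chr1": 10_000_000}
        n = 2_000
        res = synthdata.generate_gwas_catalog({"U": n}, [], genome=genome, seed=22)
        cpgs = pd.DataFrame({"cpg_id": ["c"], "chromosome": ["chr1"],
                             "position": [5_000_000]})
        ratios = success_ratios(cpgs, res.catalog, [50_000])
        expected = 0.01
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(ratios["success_ratio"].iloc[0] - expected) < 3 * se

    def test_seeded_reproducibility(self):
        a = synthdata.generate_gwas_catalog({"A": 30}, [("chr1", 100)], seed=1)
        b = synthdata.generate_gwas_catalog({"A": 30}, [("chr1", 100)], seed=1)
        assert a.catalog.equals(b.catalog)

    def test_clustering_without_targets_rejected(self):
        with pytest.raises(ValueError):
            synthdata.generate_gwas_catalog({"A": 10}, [], clustering={"A": (1000, 0.5)})


class TestGeneSets:
    def test_enriched_set_beats_random_set(self):
        universe = [f"G{i}" for i in range(300)]
        query = universe[:40]
        wins = 0
        for seed in range(100):
            sets = synthdata.generate_gene_sets(
                3, universe, enriched_set=(query, 3.0),
                set_size_range=(40, 40), seed=seed)
            ora = hypergeom_ora(query, sets, universe).set_index("set_id")
            wins += ora.loc["GS_ENRICHED", "p_value"] < ora.loc["GS0002", "p_value"]
        assert wins >= 95

    def test_empty_collection(self):
        assert synthdata.generate_gene_sets(0, ["a", "b"]) == {}

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            synthdata.generate_gene_sets(1, ["a", "b"], set_size_range=(5, 5))


class TestValidationTable:
    def test_planted_sites_are_near_discovery(self, methylome):
        disc = methylome.annotation.head(20)
        table, planted = synthdata.generate_validation_table(
            disc, fraction_validated=1.0, n_background=10, seed=5)
        assert len(planted) == 20
        # every discovery CpG has at least one site within the window
        res = sw.vicinity_match(disc, table, window=5_000, q_threshold=0.05)
        assert res.summary["validated"].all()
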