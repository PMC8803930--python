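import numpy as np
import pandas as pd
import pytest

from regenconverge import AbundanceMatrix, PlantedMetabolite, SynthConfig, gen_metabolome_study
from regenconverge.convergence import (
    build_direction_matrix,
    model_similarity,
    permutation_correlation,
    plsda_ordination,
    select_candidates,
)
from regenconverge.metabolome import auto_scale, impute_minimum, rescale_median

from conftest import make_annotation, make_contrast, run_dpmp


class TestDirectionMatrix:
    def contrast_tables(self):
        up = make_contrast([("m1", 2.0, 0.001, True, "up")])
        also_up = make_contrast([("m1", 1.5, 0.002, True, "up")])
        tested_null = make_contrast([("m1", 0.1, 0.7, False, "up")])
        other = make_contrast([("m2", -1.0, 0.01, True, "down")])
        return {"A": up, "B": also_up, "C": tested_null, "D": other}

    def test_codes_and_counts(self):
        table = build_direction_matrix(self.contrast_tables())
        row = table.codes.loc["m1"]
        assert row["A"] == 1 and row["B"] == 1 and row["C"] == 0
        assert np.isnan(row["D"])  # untested is absent, never 0
        assert table.up_count["m1"] == 2
        assert table.down_count["m2"] == 1

    def test_model_order_permutes_columns_only(self):
        tables = self.contrast_tables()
        reordered = {k: tables[k] for k in ["D", "C", "B", "A"]}
        a = build_direction_matrix(tables)
        b = build_direction_matrix(reordered)
        pd.testing.assert_frame_equal(a.codes, b.codes[a.codes.columns])

    def test_empty_input_gives_empty_matrix(self):
        table = build_direction_matrix({"A": make_contrast([]), "B": make_contrast([])})
        assert table.codes.empty


class TestSelectCandidates:
    def build(self, ups, super_map):
        tables = {}
        for model in range(4):
            rows = []
            for metab, k in ups.items():
                sig = model < k
                rows.append((metab, 2.0 if sig else 0.1, 0.01 if sig else 0.8, sig, "up"))
            tables[f"model{model}"] = make_contrast(rows)
        return build_direction_matrix(tables), make_annotation(super_map)

    def test_threshold_and_super_pathway_filter(self):
        table, ann = self.build(
            {"m_nuc": 4, "m_few": 3, "m_xeno": 4},
            {"m_nuc": "Nucleotide", "m_few": "Nucleotide", "m_xeno": "Xenobiotics"},
        )
        selected = select_candidates(table, ann, min_models=4)
        assert list(selected.index) == ["m_nuc"]  # m_few below k, m_xeno filtered

    def test_monotone_in_min_models(self):
        table, ann = self.build(
            {f"m{i}": i for i in range(5)}, {f"m{i}": "Lipid" for i in range(5)}
        )
        sizes = [len(select_candidates(table, ann, min_models=k)) for k in range(1, 5)]
        assert sizes == sorted(sizes, reverse=True)

    def test_tie_break_by_max_abs_log2fc(self):
        strong = make_contrast([("a", 1.0, 0.01, True, "up"), ("b", 3.0, 0.01, True, "up")])
        weak = make_contrast([("a", 1.2, 0.01, True, "up"), ("b", 2.0, 0.01, True, "up")])
        table = build_direction_matrix({"x": strong, "y": weak})
        ann = make_annotation({"a": "Lipid", "b": "Lipid"})
        selected = select_candidates(table, ann, min_models=2)
        assert list(selected.index) == ["b", "a"]
        assert selected.loc["b", "max_abs_log2fc"] == 3.0

    def test_unknown_super_pathway_in_filter_rejected(self):
        table, ann = self.build({"m0": 4}, {"m0": "Lipid"})
        with pytest.raises(ValueError, match="Lipids"):
            select_candidates(table, ann, super_filter=frozenset({"Lipids"}))

    def test_planted_convergent_metabolites_recovered(self, small_study):
        tables = {m: run_dpmp(small_study, m) for m in small_study.matrices}
        table = build_direction_matrix(tables)
        selected = select_candidates(table, small_study.annotation, min_models=3)
        assert "M0001" in selected.index


class TestModelSimilarity:
    def test_identical_profiles_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        profiles = pd.DataFrame({"A": base, "B": base, "C": rng.normal(size=30)})
        tree = model_similarity(profiles)
        first_pair = set(tree.linkage_matrix[0, :2].astype(int))
        assert first_pair == {0, 1}
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_has_distance_two(self):
        x = np.linspace(-1, 1, 20)
        profiles = pd.DataFrame({"A": x, "B": -x})
        tree = model_similarity(profiles)
        assert tree.linkage_matrix[0, 2] == pytest.approx(2.0)

    def test_correlation_metric_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(1)
        profiles = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("ABCD"))
        rescaled = profiles * [2.0, 0.5, 10.0, 1.0] + [1.0, -3.0, 0.0, 7.0]
        a = model_similarity(profiles).linkage_matrix
        b = model_similarity(rescaled).linkage_matrix
        assert np.allclose(a, b)

    def test_shared_effect_models_join_before_outsider(self):
        """Two models planted from one effect vector cluster together >=95% of seeds."""
        joined_first = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            effect = rng.normal(0, 1, size=60)
            profiles = pd.DataFrame(
                {
                    "A": effect + rng.normal(0, 0.5, 60),
                    "B": effect + rng.normal(0, 0.5, 60),
                    "C": rng.normal(0, 1, 60),
                }
            )
            tree = model_similarity(profiles)
            joined_first += set(tree.linkage_matrix[0, :2].astype(int)) == {0, 1}
        assert joined_first / n_seeds >= 0.95

    def test_pairwise_complete_handles_distinct_panels(self):
        rng = np.random.default_rng(2)
        profiles = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("ABC"))
        profiles.loc[:9, "A"] = np.nan
        profiles.loc[20:, "B"] = np.nan
        tree = model_similarity(profiles)
        assert len(tree.labels) == 3

    def test_too_few_shared_features_errors(self):
        profiles = pd.DataFrame(
            {"A": [1.0, np.nan, np.nan], "B": [np.nan, 1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="share"):
            model_similarity(profiles)

    def test_newick_roundtrip_preserves_leaves_and_heights(self):
        import io as _io

        from Bio import Phylo

        rng = np.random.default_rng(3)
        profiles = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("ABCDE"))
        tree = model_similarity(profiles)
        parsed = Phylo.read(_io.StringIO(tree.to_newick()), "newick")
        assert {leaf.name for leaf in parsed.get_terminals()} == set("ABCDE")
        # root-to-leaf depth equals the final merge height (ultrametric, average linkage)
        depths = parsed.depths()
        leaf_depths = [d for clade, d in depths.items() if clade.name]
        assert np.allclose(leaf_depths, tree.merge_heights()[-1], atol=1e-5)


class TestPlsda:
    def scaled_two_group(self, effect, seed=0, n=6, n_feat=30):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(2 * n, n_feat))
        X[:n, :5] += effect
        m = AbundanceMatrix(
            pd.DataFrame(
                X, index=[f"s{i}" for i in range(2 * n)],
                columns=[f"M{j}" for j in range(n_feat)],
            ),
            stage="median_scaled",
        )
        return auto_scale(m), ["high"] * n + ["ctrl"] * n

    def test_scores_shape_contract(self):
        m, labels = self.scaled_two_group(effect=3.0)
        scores = plsda_ordination(m, labels, n_components=2)
        assert scores.shape == (12, 2)

    def test_planted_separation_gives_positive_silhouette(self):
        from sklearn.metrics import silhouette_score

        m, labels = self.scaled_two_group(effect=3.0)
        scores = plsda_ordination(m, labels)
        assert silhouette_score(scores[["PLS1"]], labels) > 0

    def test_permuted_labels_average_silhouette_near_zero(self):
        """Random groupings show no separation along a fixed ordination axis."""
        from sklearn.metrics import silhouette_score

        m, labels = self.scaled_two_group(effect=0.0, seed=1)
        scores = plsda_ordination(m, labels)
        rng = np.random.default_rng(10)
        sils = [
            silhouette_score(scores[["PLS1"]], list(rng.permutation(labels)))
            for _ in range(50)
        ]
        mean, se = np.mean(sils), np.std(sils, ddof=1) / np.sqrt(len(sils))
        assert abs(mean) <= 3 * se + 0.05

    def test_single_class_rejected(self):
        m, _ = self.scaled_two_group(effect=1.0)
        with pytest.raises(ValueError, match="class"):
            plsda_ordination(m, ["same"] * 12)


class TestPermutationCorrelation:
    def matrix_and_design(self, X):
        n = X.shape[0] // 2
        ids = [f"h{i}" for i in range(n)] + [f"c{i}" for i in range(n)]
        m = AbundanceMatrix(
            pd.DataFrame(X, index=ids, columns=[f"M{j}" for j in range(X.shape[1])]),
            stage="median_scaled",
        )
        design = pd.DataFrame(
            {"sample_id": ids, "group": ["high_regen"] * n + ["control"] * n,
             "replicate": list(range(n)) * 2}
        )
        return m, design

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        m, design = self.matrix_and_design(rng.lognormal(size=(8, 6)))
        a = permutation_correlation(m, design, n_perm=30, seed=123)
        b = permutation_correlation(m, design, n_perm=30, seed=123)
        pd.testing.assert_frame_equal(a.mean_permuted, b.mean_permuted)
        pd.testing.assert_frame_equal(a.p_values, b.p_values)

    def test_perfectly_correlated_pair_gets_add_one_minimum_p(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(size=8)
        noise = rng.lognormal(size=(8, 2))
        X = np.column_stack([base, base * 2.0, noise[:, 0], noise[:, 1]])
        m, design = self.matrix_and_design(X)
        out = permutation_correlation(m, design, n_perm=100, seed=0)
        assert out.observed.iloc[0, 1] == pytest.approx(1.0)
        assert out.p_values.iloc[0, 1] == pytest.approx(1 / 101)

    def test_independent_metabolites_have_small_mean_absolute_r(self):
        rng = np.random.default_rng(6)
        m, design = self.matrix_and_design(rng.normal(10, 1, size=(12, 20)))
        out = permutation_correlation(m, design, n_perm=20, seed=1)
        off_diag = out.observed.to_numpy()[~np.eye(20, dtype=bool)]
        assert np.mean(np.abs(off_diag)) <= 3 / np.sqrt(12)

    def test_fewer_than_three_replicates_rejected(self):
        rng = np.random.default_rng(7)
        m, design = self.matrix_and_design(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="3 replicates"):
            permutation_correlation(m, design, n_perm=5)

    def test_nonpositive_n_perm_rejected(self):
        rng = np.random.default_rng(8)
        m, design = self.matrix_and_design(rng.normal(size=(8, 3)))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_correlation(m, design, n_perm=0)
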