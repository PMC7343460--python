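import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import adjusted_rand_score

from agingphases import (
    OmicsMatrix,
    pathway_predictivity,
    phase_stratified_predictivity,
    predictivity_phase_contrast,
    predictivity_profiles,
    succession_clustering,
)
from agingphases._forest import BaggedTreeClassifier


def expr_matrix(values, features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"G{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=features,
                      columns=[f"S{j}" for j in range(values.shape[1])])
    return OmicsMatrix(df, kind="expression", scale="log2_tpm")


def labels_for(n_per_class, k=4):
    vals = np.repeat(np.arange(1, k + 1), n_per_class)
    return pd.Series(vals, index=[f"S{j}" for j in range(len(vals))])


class TestBaggedTrees:
    def test_matches_random_forest_accuracy(self):
        """The bagged-tree ensemble is the same model as a random forest
        with mtry = all features; their held-out accuracies agree."""
        rng = np.random.default_rng(0)
        n = 120
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 6)) + y[:, None] * 0.8
        xt = rng.normal(size=(n, 6)) + y[:, None] * 0.8
        ours = BaggedTreeClassifier(n_trees=300, random_state=1).fit(x, y)
        sk = RandomForestClassifier(n_estimators=300, max_features=None,
                                    random_state=1).fit(x, y)
        acc_ours = (ours.predict(xt) == y).mean()
        acc_sk = (sk.predict(xt) == y).mean()
        assert abs(acc_ours - acc_sk) < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 5))
        y = np.repeat([0, 1], 20)
        p1 = BaggedTreeClassifier(50, random_state=9).fit(x, y).predict_proba(x)
        p2 = BaggedTreeClassifier(50, random_state=9).fit(x, y).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_probabilities_normalized(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 4))
        y = np.repeat([0, 1, 2], 10)
        proba = BaggedTreeClassifier(30, random_state=0).fit(x, y).predict_proba(x)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


class TestPathwayPredictivity:
    def test_same_seed_identical_replicates(self):
        rng = np.random.default_rng(0)
        m = expr_matrix(rng.normal(size=(5, 40)))
        y = labels_for(10)
        r1 = pathway_predictivity(m, [f"G{i}" for i in range(5)], y,
                                  n_reps=3, seed=5, n_trees=25)
        r2 = pathway_predictivity(m, [f"G{i}" for i in range(5)], y,
                                  n_reps=3, seed=5, n_trees=25)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)

    def test_pure_noise_near_chance(self):
        rng = np.random.default_rng(1)
        m = expr_matrix(rng.normal(size=(8, 48)))
        y = labels_for(12)
        r = pathway_predictivity(m, [f"G{i}" for i in range(8)], y,
                                 n_reps=4, seed=2, n_trees=40)
        assert abs(r.mean - 0.25) < 0.12

    def test_separable_gene_high_accuracy(self):
        y = labels_for(10)
        gene = y.map({1: 0.0, 2: 10.0, 3: 20.0, 4: 30.0}).to_numpy()
        rng = np.random.default_rng(2)
        vals = np.vstack([gene + rng.normal(0, 0.3, len(y)),
                          rng.normal(size=len(y))])
        m = expr_matrix(vals)
        r = pathway_predictivity(m, ["G0", "G1"], y, n_reps=2, seed=0, n_trees=50)
        assert r.mean >= 0.95

    def test_no_matched_genes_rejected(self):
        m = expr_matrix(np.zeros((2, 20)) + np.arange(20))
        y = labels_for(5)
        with pytest.raises(ValueError, match="no genes"):
            pathway_predictivity(m, ["NOPE"], y, n_reps=1)

    def test_small_phase_guidance_error(self):
        rng = np.random.default_rng(0)
        m = expr_matrix(rng.normal(size=(3, 13)))
        y = pd.Series([1] * 10 + [2] * 3, index=[f"S{j}" for j in range(13)])
        with pytest.raises(ValueError, match="fold count"):
            pathway_predictivity(m, ["G0"], y, n_reps=1)

    def test_permutation_null_near_chance(self):
        y = labels_for(10)
        gene = y.map({1: 0.0, 2: 10.0, 3: 20.0, 4: 30.0}).to_numpy()
        m = expr_matrix(gene.reshape(1, -1))
        r = pathway_predictivity(m, ["G0"], y, n_reps=4, seed=1, n_trees=40,
                                 permute_labels=True)
        assert r.mean < 0.45  # informative gene is useless under shuffled labels


class TestPhaseStratified:
    def test_profile_covers_every_phase(self):
        rng = np.random.default_rng(4)
        m = expr_matrix(rng.normal(size=(4, 40)))
        y = labels_for(10)
        res = phase_stratified_predictivity(m, [f"G{i}" for i in range(4)], y,
                                            n_reps=2, seed=0, n_trees=25)
        assert sorted(res) == [1, 2, 3, 4]
        for phase, r in res.items():
            assert r.mode == "one_vs_all" and r.phase == phase
            assert r.chance == pytest.approx(0.75)

    def test_phase_specific_signal_peaks_at_that_phase(self):
        y = labels_for(12)
        rng = np.random.default_rng(5)
        gene = np.where(y == 4, 4.0, 0.0) + rng.normal(0, 0.5, len(y))
        vals = np.vstack([gene, rng.normal(size=len(y))])
        res = phase_stratified_predictivity(expr_matrix(vals), ["G0", "G1"], y,
                                            n_reps=2, seed=1, n_trees=40)
        means = {p: r.mean for p, r in res.items()}
        assert means[4] == max(means.values())
        assert means[4] > 0.9


class TestSuccessionClustering:
    def test_identical_profiles_merge_into_one_cluster(self):
        profiles = pd.DataFrame([[0.2, 0.4, 0.6, 0.4]] * 3,
                                index=["a", "b", "c"], columns=[1, 2, 3, 4])
        summary = succession_clustering(profiles, n_groups=1)
        assert summary.groups.nunique() == 1
        assert (summary.linkage_matrix[:, 2] == 0).all()  # zero merge heights

    def test_constant_profile_warns_and_is_kept(self):
        profiles = pd.DataFrame([[0.5, 0.5, 0.5, 0.5], [0.1, 0.2, 0.9, 0.3]],
                                index=["flat", "peaked"], columns=[1, 2, 3, 4])
        with pytest.warns(UserWarning, match="constant"):
            summary = succession_clustering(profiles, n_groups=2)
        assert set(summary.groups.index) == {"flat", "peaked"}
        assert summary.peak_phase["flat"] == 1  # argmax tie -> earliest

    def test_peak_tie_takes_earliest_phase(self):
        profiles = pd.DataFrame([[0.3, 0.6, 0.6, 0.4], [0.1, 0.2, 0.3, 0.9]],
                                index=["tied", "late"], columns=[1, 2, 3, 4])
        summary = succession_clustering(profiles, n_groups=2)
        assert summary.peak_phase["tied"] == 2
        assert summary.peak_phase["late"] == 4

    def test_archetype_profiles_recovered(self):
        from agingphases.simulate import DEFAULT_ARCHETYPES
        rng = np.random.default_rng(0)
        rows, names, truth = [], [], []
        for arch, profile in DEFAULT_ARCHETYPES.items():
            for i in range(3):
                rows.append(np.asarray(profile) + rng.normal(0, 0.02, 4))
                names.append(f"{arch}_{i}")
                truth.append(arch)
        profiles = pd.DataFrame(rows, index=names, columns=[1, 2, 3, 4])
        summary = succession_clustering(profiles, n_groups=3)
        assert adjusted_rand_score(truth, summary.groups.to_numpy()) == 1.0
        peaks = summary.peak_phase.groupby(pd.Series(truth, index=names)).first()
        assert peaks["primary"] <= peaks["secondary"] <= peaks["integrative"]


class TestPhaseContrast:
    def test_all_zero_deltas_p_one(self):
        profiles = pd.DataFrame([[0.5, 0.5], [0.6, 0.6]], columns=[3, 4])
        res = predictivity_phase_contrast(profiles, 3, 4)
        assert res.p == 1.0

    def test_uniform_decrease_exact_signed_rank(self):
        """Six sets each dropping 0.1: exact one-sided signed-rank p is
        1/64 (only the all-negative sign assignment is as extreme)."""
        n = 6
        deltas = np.full(n, -0.1) + np.arange(n) * 1e-6  # distinct magnitudes
        stat_observed = 0.0  # sum of positive ranks
        count = 0
        for signs in itertools.product([1, -1], repeat=n):
            w_pos = sum(r for r, s in zip(range(1, n + 1), signs) if s > 0)
            if w_pos <= stat_observed:
                count += 1
        p_oracle = count / 2 ** n
        assert p_oracle == pytest.approx(1 / 64)

        profiles = pd.DataFrame({3: np.linspace(0.5, 0.8, n),
                                 4: np.linspace(0.5, 0.8, n) + deltas})
        res = predictivity_phase_contrast(profiles, 3, 4)
        assert res.p == pytest.approx(p_oracle)

    def test_wrong_direction_not_significant(self):
        n = 8
        profiles = pd.DataFrame({3: np.linspace(0.4, 0.6, n),
                                 4: np.linspace(0.4, 0.6, n) + 0.1})
        res = predictivity_phase_contrast(profiles, 3, 4)
        assert res.p >= 0.5

    def test_few_sets_flagged_low_power(self):
        profiles = pd.DataFrame({3: [0.5, 0.6, 0.7], 4: [0.4, 0.5, 0.6]})
        res = predictivity_phase_contrast(profiles, 3, 4)
        assert res.low_power


class TestProfilesTable:
    def test_profiles_table_shape_and_order(self):
        rng = np.random.default_rng(6)
        m = expr_matrix(rng.normal(size=(3, 40)))
        y = labels_for(10)
        per_set = {
            name: phase_stratified_predictivity(m, ["G0", "G1", "G2"], y,
                                                n_reps=1, seed=i, n_trees=15)
            for i, name in enumerate(["b_set", "a_set"])
        }
        table = predictivity_profiles(per_set)
        assert list(table.index) == ["b_set", "a_set"]
        assert list(table.columns) == [1, 2, 3, 4]
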