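"""Discriminative-family discovery: pre-filter, SVM-RFE, screens."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mycolife import (GeneFamilyMatrix, anova_prefilter,
                      fisher_category_enrichment, phylo_logistic_screen,
                      svm_rfe_select)
from tests.conftest import random_tree


def binary_labels(n_true, n_false, prefix="g"):
    ids = [f"{prefix}{i}" for i in range(n_true + n_false)]
    return pd.Series([True] * n_true + [False] * n_false,
                     index=pd.Index(ids), name="target")


class TestAnovaPrefilter:
    def test_zero_variance_family_skipped(self):
        labels = binary_labels(3, 3)
        counts = pd.DataFrame({"flat": [2] * 6, "var": [5, 6, 5, 0, 1, 0]},
                              index=labels.index)
        res = anova_prefilter(counts, labels)
        assert res.loc["flat", "note"].startswith("skipped")
        assert not res.loc["flat", "selected"]

    def test_f_matches_hand_oracle(self):
        """Six-genome toy: F equals between/within mean-square ratio."""
        labels = binary_labels(3, 3)
        x = np.array([4.0, 5.0, 6.0, 1.0, 2.0, 3.0])
        counts = pd.DataFrame({"f": x}, index=labels.index)
        res = anova_prefilter(counts, labels)
        a, b = x[:3], x[3:]
        grand = x.mean()
        ssb = 3 * (a.mean() - grand) ** 2 + 3 * (b.mean() - grand) ** 2
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_oracle = (ssb / 1) / (ssw / 4)
        assert res.loc["f", "f"] == pytest.approx(f_oracle, rel=1e-12)

    def test_direction_tracks_group_means(self):
        labels = binary_labels(3, 3)
        counts = pd.DataFrame({"up": [9, 8, 9, 1, 2, 1],
                               "down": [0, 1, 0, 7, 8, 9]},
                              index=labels.index)
        res = anova_prefilter(counts, labels)
        assert res.loc["up", "direction"] == 1
        assert res.loc["down", "direction"] == -1

    def test_empty_group_rejected(self):
        labels = pd.Series([True, True], index=["a", "b"], name="t")
        counts = pd.DataFrame({"f": [1, 2]}, index=labels.index)
        with pytest.raises(ValueError):
            anova_prefilter(counts, labels)


class TestSvmRfe:
    def test_perfect_family_among_noise_is_kept(self):
        rng = np.random.default_rng(5)
        labels = binary_labels(15, 15)
        counts = pd.DataFrame(
            rng.integers(0, 4, size=(30, 50)), index=labels.index,
            columns=[f"f{i}" for i in range(50)])
        counts["f13"] = np.where(labels, 8, 0) + rng.integers(0, 2, 30)
        res = svm_rfe_select(counts, labels, step=10, min_features=5, seed=5)
        assert "f13" in res.selected
        assert res.cv_accuracy >= 0.95

    def test_shuffled_labels_full_set_near_chance_and_unstable(self):
        """Under label shuffling the full-feature LOOCV accuracy sits near
        chance and the selected sets are unstable across shuffles.  (The
        accuracy of the post-elimination set is optimistically biased by
        construction — elimination is not re-run per fold — so the null
        check targets the pre-elimination accuracy.)"""
        rng = np.random.default_rng(6)
        labels = binary_labels(10, 10)
        counts = pd.DataFrame(
            rng.integers(0, 5, size=(20, 30)), index=labels.index,
            columns=[f"f{i}" for i in range(30)])
        full_accs = []
        from collections import Counter
        seen = Counter()
        n_rep = 12
        for rep in range(n_rep):
            sh = pd.Series(rng.permutation(labels.to_numpy()),
                           index=labels.index, name="target")
            res = svm_rfe_select(counts, sh, step=10, min_features=5,
                                 seed=rep)
            full_accs.append(
                res.accuracy_trace["cv_accuracy"].iloc[0])
            seen.update(res.selected)
        assert 0.2 <= np.mean(full_accs) <= 0.8
        assert max(seen.values()) <= 0.75 * n_rep

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        labels = binary_labels(8, 8)
        counts = pd.DataFrame(
            rng.integers(0, 5, size=(16, 25)), index=labels.index,
            columns=[f"f{i}" for i in range(25)])
        a = svm_rfe_select(counts, labels, seed=3)
        b = svm_rfe_select(counts, labels, seed=3)
        assert a.selected == b.selected
        assert a.accuracy_trace.equals(b.accuracy_trace)

    def test_trace_sizes_step_arithmetic(self):
        rng = np.random.default_rng(8)
        labels = binary_labels(8, 8)
        counts = pd.DataFrame(
            rng.integers(0, 5, size=(16, 37)), index=labels.index,
            columns=[f"f{i}" for i in range(37)])
        res = svm_rfe_select(counts, labels, step=10, min_features=10, seed=1)
        assert res.accuracy_trace["n_features"].tolist() == [37, 27, 17, 10]


class TestFisher:
    def test_extreme_table_infinite_odds(self):
        ann = pd.DataFrame({"category": ["CAZyme"] * 4 + ["other"] * 6},
                           index=[f"f{i}" for i in range(10)])
        res = fisher_category_enrichment([f"f{i}" for i in range(4)],
                                         list(ann.index), ann)
        assert res.odds_ratio == np.inf
        # point mass of the hypergeometric tail
        assert res.p == pytest.approx(1 / 210)  # 1 / C(10,4)

    def test_p_matches_hypergeometric_enumeration(self):
        ann = pd.DataFrame(
            {"category": ["CAZyme"] * 12 + ["other"] * 38},
            index=[f"f{i}" for i in range(50)])
        selected = [f"f{i}" for i in range(8)] + ["f20", "f21"]
        res = fisher_category_enrichment(selected, list(ann.index), ann)
        # oracle: P(X >= 8) with X ~ Hypergeom(N=50, K=12, n=10)
        oracle = sum(stats.hypergeom.pmf(k, 50, 12, 10) for k in range(8, 11))
        assert res.p == pytest.approx(oracle, rel=1e-9)

    def test_balanced_category_odds_near_one(self):
        ann = pd.DataFrame({"category": (["CAZyme", "other"] * 10)},
                           index=[f"f{i}" for i in range(20)])
        selected = ["f0", "f1", "f2", "f3"]  # 2 CAZyme, 2 other
        res = fisher_category_enrichment(selected, list(ann.index), ann)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.1)


class TestPhyloLogisticScreen:
    def test_orthogonal_effect_detected_and_constant_skipped(self):
        rng = np.random.default_rng(7)
        tree = random_tree(rng, 30)
        ids = tree.tip_names
        labels = pd.Series(rng.random(30) < 0.5, index=ids, name="t")
        # family tracking the labels directly, orthogonal to phylogeny;
        # strong but overlapping (complete separation would leave the
        # Wald test powerless)
        counts = pd.DataFrame({
            "hit": np.where(labels, 3, 0) + rng.poisson(1.5, 30),
            "noise": rng.integers(0, 3, 30),
            "flat": np.ones(30, dtype=int),
        }, index=ids)
        res = phylo_logistic_screen(counts, labels, tree, k=3)
        assert res.loc["hit", "q"] < 0.05
        assert res.loc["flat", "note"].startswith("skipped")

    def test_clade_confounded_marker_attenuated(self):
        """A pure clade marker coinciding with a clade-confounded label
        loses significance once phylogenetic position is in the model."""
        rng = np.random.default_rng(11)
        wins = 0
        n_sims = 25
        for _ in range(n_sims):
            tree = random_tree(rng, 24)
            ids = tree.tip_names
            pd_mat = tree.patristic_distances(ids)
            # clade = tips nearest to tip 0
            order = pd_mat.iloc[0].sort_values().index
            clade = set(order[:12])
            labels = pd.Series([t in clade for t in ids], index=ids, name="t")
            counts = pd.DataFrame(
                {"marker": [5 if t in clade else 0 for t in ids]}, index=ids)
            res = phylo_logistic_screen(counts, labels, tree, k=4)
            x = (counts["marker"] - counts["marker"].mean())
            x = x / counts["marker"].std()
            naive = np.hstack([np.ones((24, 1)), x.to_numpy()[:, None]])
            from mycolife.features import _ridge_logistic_wald
            beta, se = _ridge_logistic_wald(naive, labels.to_numpy(float),
                                            1e-3)
            p_naive = 2 * stats.norm.sf(abs(beta[-1] / se[-1]))
            if res.loc["marker", "p"] > p_naive or np.isnan(res.loc["marker", "p"]):
                wins += 1
        assert wins >= 0.8 * n_sims
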