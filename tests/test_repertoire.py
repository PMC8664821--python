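"""Phylogeny-corrected repertoire comparison: distances, PERMANOVA, dbRDA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from mycolife import (GeneFamilyMatrix, Phylogeny, category_count_anova,
                      dbrda, discriminant_top_loadings, jaccard_distances,
                      lifestyle_network, pairwise_permanova, permanova,
                      phylogeny_pcs)


def euclid(points: pd.DataFrame) -> pd.DataFrame:
    d = squareform(pdist(points.to_numpy()))
    return pd.DataFrame(d, index=points.index, columns=points.index)


class TestPhylogenyPCs:
    def test_star_tree_is_fully_degenerate(self):
        """Equal pairwise distances (star tree) put the genomes at the
        vertices of a regular simplex: no principal direction dominates,
        so every component carries the same variance and the score
        geometry is exchangeable across genomes."""
        tips = ",".join(f"t{i}:1" for i in range(6))
        tree = Phylogeny.from_newick(f"({tips}):0;")
        pcs, evr = phylogeny_pcs(tree, k=3)
        assert np.allclose(evr, evr[0], atol=1e-9)

    def test_pc1_separates_distant_clades(self):
        tree = Phylogeny.from_newick(
            "((a:0.1,b:0.1):10,(c:0.1,d:0.1):10):0;")
        pcs, _ = phylogeny_pcs(tree, k=2)
        within = pcs.loc[["a", "b"], "PC1"].var() + pcs.loc[["c", "d"], "PC1"].var()
        between = (pcs.loc[["a", "b"], "PC1"].mean()
                   - pcs.loc[["c", "d"], "PC1"].mean()) ** 2
        assert between > 100 * within

    def test_orthogonality(self, small_bundle):
        bundle, _ = small_bundle
        pcs, _ = phylogeny_pcs(bundle.tree, k=4)
        x = pcs.to_numpy() - pcs.to_numpy().mean(axis=0)
        gram = x.T @ x
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_k_too_large_raises(self, quartet_tree):
        with pytest.raises(ValueError):
            phylogeny_pcs(quartet_tree, k=4)


class TestJaccard:
    def test_identity_symmetry_range(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 5, size=(8, 20)),
                              index=[f"g{i}" for i in range(8)])
        d = jaccard_distances(counts).to_numpy()
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        assert d.min() >= 0 and d.max() <= 1

    def test_disjoint_supports_are_one(self):
        counts = pd.DataFrame({"f1": [3, 0], "f2": [0, 2]}, index=["a", "b"])
        assert jaccard_distances(counts).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_oracle(self):
        counts = pd.DataFrame({"f1": [2, 1], "f2": [0, 1]}, index=["a", "b"])
        # B = (1+1)/(3+1) = 0.5, J = 2*0.5/1.5 = 2/3
        assert jaccard_distances(counts).loc["a", "b"] == pytest.approx(2 / 3)

    def test_all_zero_pair_is_zero(self):
        counts = pd.DataFrame({"f1": [0, 0], "f2": [0, 0]}, index=["a", "b"])
        assert jaccard_distances(counts).loc["a", "b"] == 0.0


class TestPermanova:
    def test_duplicated_groups_exhaust_variance(self):
        pts = pd.DataFrame({"x": [1, 1, 1, 5, 5, 5], "y": [0, 0, 0, 2, 2, 2]},
                           index=list("abcdef"))
        labels = pd.Series(["u"] * 3 + ["v"] * 3, index=pts.index, name="grp")
        res = permanova(euclid(pts), None, labels, interactions=False,
                        n_perm=49, seed=0)
        assert res.loc["grp", "r2"] == pytest.approx(1.0, abs=1e-9)

    def test_r2_partition_sums_to_one(self, small_bundle):
        bundle, _ = small_bundle
        labels = bundle.lifestyles.labels.rename("lifestyle")
        pcs, _ = phylogeny_pcs(bundle.tree, k=3)
        dist = jaccard_distances(bundle.matrix)
        res = permanova(dist, pcs, labels, n_perm=29, seed=1)
        assert res.drop(index="Total")["r2"].sum() == pytest.approx(1.0,
                                                                    abs=1e-9)

    def test_exhaustive_p_matches_label_enumeration(self):
        """n=6 toy: permutation p equals exhaustive enumeration over the
        C(6,3) distinct group assignments."""
        import itertools
        rng = np.random.default_rng(6)
        pts = pd.DataFrame(rng.normal(size=(6, 2)), index=list("abcdef"))
        pts.iloc[:3] += 1.5
        d = euclid(pts)
        labels = pd.Series(["u"] * 3 + ["v"] * 3, index=pts.index, name="grp")
        res = permanova(d, None, labels, interactions=False, exhaustive=True)

        # oracle: recompute pseudo-F for every distinct assignment
        def pseudo_f(assign):
            g = np.asarray(assign)
            a = -0.5 * d.to_numpy() ** 2
            j = np.eye(6) - np.ones((6, 6)) / 6
            gm = j @ a @ j
            x = np.column_stack([np.ones(6), g])
            h = x @ np.linalg.pinv(x.T @ x) @ x.T
            ss = np.sum((h - np.ones((6, 6)) / 6) * gm)
            ssr = np.sum((np.eye(6) - h) * gm)
            return (ss / 1) / (ssr / 4)

        obs = pseudo_f([1, 1, 1, 0, 0, 0])
        fs = [pseudo_f([1 if i in c else 0 for i in range(6)])
              for c in itertools.combinations(range(6), 3)]
        oracle_p = np.mean([f >= obs - 1e-12 for f in fs])
        assert res.loc["grp", "p"] == pytest.approx(oracle_p)

    def test_pseudo_f_matches_independent_implementation(self):
        """One-way case: pseudo-F agrees with scikit-bio's PERMANOVA."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        pts = pd.DataFrame(rng.normal(size=(12, 4)),
                           index=[f"s{i}" for i in range(12)])
        pts.iloc[:6] += 0.8
        d = euclid(pts)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=pts.index,
                           name="grp")
        mine = permanova(d, None, labels, interactions=False, n_perm=99,
                         seed=3)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            labels.values, permutations=99)
        assert mine.loc["grp", "f"] == pytest.approx(
            ref["test statistic"], rel=1e-9)

    def test_type_one_error_controlled(self):
        """Random labels: rejection rate near alpha over null simulations."""
        rng = np.random.default_rng(9)
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            pts = pd.DataFrame(rng.normal(size=(12, 3)),
                               index=[f"s{i}" for i in range(12)])
            labels = pd.Series(rng.permutation(["u"] * 6 + ["v"] * 6),
                               index=pts.index, name="grp")
            res = permanova(euclid(pts), None, labels, interactions=False,
                            n_perm=99, seed=int(rng.integers(2 ** 31)))
            hits += res.loc["grp", "p"] <= 0.05
        assert 0.03 <= hits / n_sims <= 0.08

    def test_interactions_never_inflate_earlier_lifestyle_r2(self, small_bundle):
        bundle, _ = small_bundle
        labels = bundle.lifestyles.labels.rename("lifestyle")
        pcs, _ = phylogeny_pcs(bundle.tree, k=2)
        dist = jaccard_distances(bundle.matrix)
        with_int = permanova(dist, pcs, labels, interactions=True,
                             n_perm=9, seed=0)
        without = permanova(dist, pcs, labels, interactions=False,
                            n_perm=9, seed=0)
        assert with_int.loc["lifestyle", "r2"] == pytest.approx(
            without.loc["lifestyle", "r2"], abs=1e-9)


class TestPairwise:
    def test_bh_never_decreases_p(self):
        rng = np.random.default_rng(12)
        pts = pd.DataFrame(rng.normal(size=(15, 3)),
                           index=[f"s{i}" for i in range(15)])
        labels = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5,
                           index=pts.index, name="grp")
        pw = pairwise_permanova(euclid(pts), None, labels, n_perm=49, seed=2)
        ok = pw["p"].notna()
        assert (pw.loc[ok, "p_adjusted"] >= pw.loc[ok, "p"] - 1e-12).all()

    def test_singleton_group_skipped(self):
        rng = np.random.default_rng(13)
        pts = pd.DataFrame(rng.normal(size=(7, 2)),
                           index=[f"s{i}" for i in range(7)])
        labels = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"],
                           index=pts.index, name="grp")
        pw = pairwise_permanova(euclid(pts), None, labels, n_perm=19, seed=2)
        skipped = pw[pw["note"].str.startswith("skipped")]
        assert set(skipped["group_b"]) == {"c"}

    def test_displaced_group_detected(self):
        rng = np.random.default_rng(19)
        pts = pd.DataFrame(rng.normal(size=(18, 3)),
                           index=[f"s{i}" for i in range(18)])
        pts.iloc[12:] += 6.0  # displace group c
        labels = pd.Series(["a"] * 6 + ["b"] * 6 + ["c"] * 6,
                           index=pts.index, name="grp")
        pw = pairwise_permanova(euclid(pts), None, labels, n_perm=199, seed=19)
        pw = pw.set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "p_adjusted"] < 0.05
        assert pw.loc[("b", "c"), "p_adjusted"] < 0.05
        assert pw.loc[("a", "b"), "p_adjusted"] >= 0.05


class TestDbrda:
    def test_matches_classical_rda_on_euclidean(self):
        rng = np.random.default_rng(4)
        y = pd.DataFrame(rng.normal(size=(10, 3)),
                         index=[f"s{i}" for i in range(10)])
        x = pd.DataFrame(rng.normal(size=(10, 2)), index=y.index,
                         columns=["x1", "x2"])
        res = dbrda(euclid(y), None, x)
        yc = (y - y.mean()).to_numpy()
        xc = (x - x.mean()).to_numpy()
        h = xc @ np.linalg.pinv(xc.T @ xc) @ xc.T
        fit = h @ yc
        ev = np.sort(np.linalg.eigvalsh(fit.T @ fit))[::-1]
        assert np.allclose(res.eigenvalues, ev[:len(res.eigenvalues)],
                           atol=1e-8)

    def test_condition_equal_constraint_gives_zero(self):
        rng = np.random.default_rng(5)
        y = pd.DataFrame(rng.normal(size=(8, 3)),
                         index=[f"s{i}" for i in range(8)])
        x = pd.DataFrame(rng.normal(size=(8, 2)), index=y.index,
                         columns=["x1", "x2"])
        res = dbrda(euclid(y), x, x)
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-8)

    def test_labels_fully_explaining_distances(self):
        rng = np.random.default_rng(6)
        pts = np.repeat(rng.normal(size=(3, 2)), 4, axis=0)
        d = pd.DataFrame(squareform(pdist(pts)),
                         index=[f"t{i}" for i in range(12)])
        d.columns = d.index
        labels = pd.Series([g for g in "abc" for _ in range(4)],
                           index=d.index, name="grp")
        res = dbrda(d, None, labels, groups=labels)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-6)

    def test_single_member_group_has_zero_ellipse(self):
        rng = np.random.default_rng(7)
        pts = pd.DataFrame(rng.normal(size=(5, 2)),
                           index=[f"t{i}" for i in range(5)])
        labels = pd.Series(["a", "a", "a", "a", "b"], index=pts.index,
                           name="grp")
        res = dbrda(euclid(pts), None, labels, groups=labels)
        assert res.ellipses.loc["b", "area"] == 0.0


class TestNetwork:
    def make_inputs(self, pvals):
        pw = pd.DataFrame({
            "group_a": ["a", "a", "b"], "group_b": ["b", "c", "c"],
            "p": pvals, "p_adjusted": pvals,
        })
        rng = np.random.default_rng(1)
        pts = pd.DataFrame(rng.normal(size=(9, 2)),
                           index=[f"t{i}" for i in range(9)])
        labels = pd.Series([g for g in "abc" for _ in range(3)],
                           index=pts.index, name="grp")
        ordn = dbrda(euclid(pts), None, labels, groups=labels)
        return pw, ordn

    def test_all_significant_gives_edgeless(self):
        pw, ordn = self.make_inputs([0.001, 0.002, 0.003])
        net = lifestyle_network(pw, ordn)
        assert net.number_of_edges() == 0
        assert set(net.nodes) == {"a", "b", "c"}

    def test_nonsignificant_pairs_connected_with_inverse_distance(self):
        pw, ordn = self.make_inputs([0.9, 0.001, 0.001])
        net = lifestyle_network(pw, ordn)
        assert set(net.edges) == {("a", "b")}
        dist = np.linalg.norm(ordn.centroids.loc["a"] - ordn.centroids.loc["b"])
        assert net.edges["a", "b"]["weight"] == pytest.approx(1 / dist)


class TestCategoryAnova:
    def test_identical_groups_share_letter(self):
        counts = pd.Series([5.0] * 9, index=[f"g{i}" for i in range(9)])
        labels = pd.Series([g for g in "abc" for _ in range(3)],
                           index=counts.index, name="grp")
        table, letters = category_count_anova(counts, None, labels,
                                              interactions=False)
        assert letters["letters"].nunique() == 1

    def test_shifted_group_distinct_letter(self):
        rng = np.random.default_rng(23)
        counts = pd.Series(rng.normal(10, 1, 18),
                           index=[f"g{i}" for i in range(18)])
        labels = pd.Series([g for g in "abc" for _ in range(6)],
                           index=counts.index, name="grp")
        counts[labels == "c"] += 50
        table, letters = category_count_anova(counts, None, labels,
                                              interactions=False)
        assert table.loc["grp", "p"] < 1e-6
        c_letters = set(letters.loc["c", "letters"])
        others = set(letters.loc["a", "letters"]) | set(letters.loc["b", "letters"])
        assert not (c_letters & others)

    def test_f_matches_ols_oracle(self):
        """Sequential F for the group term equals a direct RSS-comparison
        oracle on a 12-genome toy with one covariate."""
        rng = np.random.default_rng(31)
        ids = [f"g{i}" for i in range(12)]
        cov = pd.DataFrame({"PC1": rng.normal(size=12)}, index=ids)
        labels = pd.Series([g for g in "ab" for _ in range(6)], index=ids,
                           name="grp")
        counts = pd.Series(rng.normal(size=12) + cov["PC1"].to_numpy()
                           + (labels == "b") * 1.5, index=ids)
        table, _ = category_count_anova(counts, cov, labels,
                                        interactions=False)
        y = counts.to_numpy()
        x0 = np.column_stack([np.ones(12), cov["PC1"]])
        x1 = np.column_stack([x0, (labels == "b").astype(float)])

        def rss(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            return r @ r

        f_oracle = (rss(x0) - rss(x1)) / (rss(x1) / (12 - 3))
        assert table.loc["grp", "f"] == pytest.approx(f_oracle, rel=1e-9)


class TestDiscriminantLoadings:
    def test_single_informative_family_tops_axis_one(self):
        rng = np.random.default_rng(2)
        ids = [f"g{i}" for i in range(12)]
        counts = pd.DataFrame(rng.integers(0, 3, size=(12, 10)), index=ids,
                              columns=[f"f{i}" for i in range(10)])
        labels = pd.Series([g for g in "ab" for _ in range(6)], index=ids,
                           name="grp")
        counts.loc[labels == "b", "f7"] += 20
        res = discriminant_top_loadings(GeneFamilyMatrix(counts), labels,
                                        n_axes=1, top=3)
        assert res.iloc[0]["family"] == "f7"

    def test_loadings_invariant_to_family_order(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(10)]
        counts = pd.DataFrame(rng.integers(0, 4, size=(10, 8)), index=ids,
                              columns=[f"f{i}" for i in range(8)])
        labels = pd.Series([g for g in "ab" for _ in range(5)], index=ids,
                           name="grp")
        a = discriminant_top_loadings(GeneFamilyMatrix(counts), labels,
                                      n_axes=1, top=8)
        shuffled = counts[list(counts.columns[::-1])]
        b = discriminant_top_loadings(GeneFamilyMatrix(shuffled), labels,
                                      n_axes=1, top=8)
        fa = a.set_index("family")["loading"].abs().sort_index()
        fb = b.set_index("family")["loading"].abs().sort_index()
        assert np.allclose(fa, fb, atol=1e-9)

    def test_axes_truncated_to_groups_minus_one(self):
        rng = np.random.default_rng(4)
        ids = [f"g{i}" for i in range(8)]
        counts = pd.DataFrame(rng.integers(0, 4, size=(8, 6)), index=ids,
                              columns=[f"f{i}" for i in range(6)])
        labels = pd.Series([g for g in "ab" for _ in range(4)], index=ids,
                           name="grp")
        with pytest.warns(UserWarning, match="truncated"):
            res = discriminant_top_loadings(GeneFamilyMatrix(counts), labels,
                                            n_axes=3, top=2)
        assert res["axis"].max() == 1
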