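"""Co-expression network construction, modules and trait association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from efnet import network as nw


def random_expr(rng, n_genes=6, n_samples=8):
    return pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
    )


def brute_force_tom(A):
    n = len(A)
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            tom[i, j] = (L + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
    return tom


class TestCorrelation:
    def test_duplicate_gene_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        expr = random_expr(rng, 3, 10)
        expr.loc["g1"] = expr.loc["g0"]
        assert nw.correlation_matrix(expr).loc["g0", "g1"] == pytest.approx(1.0)

    def test_negated_gene_has_minus_one(self):
        rng = np.random.default_rng(1)
        expr = random_expr(rng, 2, 10)
        expr.loc["g1"] = -expr.loc["g0"]
        assert nw.correlation_matrix(expr).loc["g0", "g1"] == pytest.approx(-1.0)

    def test_matches_definitional_formula_entrywise(self):
        rng = np.random.default_rng(2)
        expr = random_expr(rng, 4, 5)
        cor = nw.correlation_matrix(expr)
        X = expr.to_numpy()
        for i in range(4):
            for j in range(4):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cor.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_named(self):
        expr = random_expr(np.random.default_rng(3), 3, 6)
        expr.loc["g2"] = 1.0
        with pytest.raises(ValueError, match="g2"):
            nw.correlation_matrix(expr)


class TestAdjacency:
    def test_powering_examples(self):
        cor = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=list("ab"), columns=list("ab"))
        assert nw.adjacency(cor, 3).loc["a", "b"] == pytest.approx(0.125)
        neg = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=list("ab"), columns=list("ab"))
        assert nw.adjacency(neg, 1).loc["a", "b"] == pytest.approx(0.5)

    def test_endpoints_fixed_for_any_power(self):
        cor = pd.DataFrame(
            [[1, 0, -1], [0, 1, 0], [-1, 0, 1]], dtype=float,
            index=list("abc"), columns=list("abc"),
        )
        for beta in (1, 3, 7):
            a = nw.adjacency(cor, beta)
            assert a.loc["a", "b"] == 0.0
            assert a.loc["a", "c"] == 1.0

    def test_raising_beta_weakly_decreases_offdiagonal(self):
        rng = np.random.default_rng(5)
        cor = nw.correlation_matrix(random_expr(rng, 8, 10))
        prev = nw.adjacency(cor, 1).to_numpy()
        for beta in (2, 4, 9):
            cur = nw.adjacency(cor, beta).to_numpy()
            off = ~np.eye(8, dtype=bool)
            assert (cur[off] <= prev[off] + 1e-15).all()
            prev = cur

    def test_beta_below_one_rejected(self):
        cor = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            nw.adjacency(cor, 0.5)


class TestTOM:
    def test_complete_graph_gives_all_ones(self):
        A = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        np.testing.assert_allclose(nw.topological_overlap(A).to_numpy(), 1.0)

    def test_star_leaves_share_the_hub(self):
        # hub a connected to leaves b, c; b-c not directly connected
        A = pd.DataFrame(
            [[1, 1, 1], [1, 1, 0], [1, 0, 1]], dtype=float,
            index=list("abc"), columns=list("abc"),
        )
        tom = nw.topological_overlap(A)
        assert tom.loc["b", "c"] > 0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(3, 7)
            A = rng.random((n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            adf = pd.DataFrame(A, index=range(n), columns=range(n))
            np.testing.assert_allclose(
                nw.topological_overlap(adf).to_numpy(), brute_force_tom(A), atol=1e-12
            )

    def test_asymmetric_input_rejected(self):
        A = pd.DataFrame([[1, 0.2], [0.4, 1]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            nw.topological_overlap(A)


class TestSoftThreshold:
    def test_trivial_cut_selects_smallest_candidate(self):
        expr = random_expr(np.random.default_rng(1), 30, 10)
        scan = nw.pick_soft_threshold(expr, range(1, 6), r2_cut=-2.0)
        assert scan.chosen_beta == 1 and scan.satisfied

    def test_forced_singleton_warns_when_poor(self):
        expr = random_expr(np.random.default_rng(2), 20, 8)
        with pytest.warns(UserWarning, match="forced beta=3"):
            scan = nw.pick_soft_threshold(expr, [3], r2_cut=0.999)
        assert scan.chosen_beta == 3

    def test_choice_matches_independent_rescan(self):
        expr = random_expr(np.random.default_rng(3), 60, 12)
        r2_cut = 0.5
        scan = nw.pick_soft_threshold(expr, range(1, 11), r2_cut=r2_cut)
        # independent rescan: recompute the fit index per candidate
        cor = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(cor, 0.0)
        chosen = None
        best, best_beta = -np.inf, None
        for beta in range(1, 11):
            r2 = nw.scale_free_r2((cor**beta).sum(axis=1))
            if np.isnan(r2):
                continue
            if r2 > best:
                best, best_beta = r2, beta
            if chosen is None and r2 >= r2_cut:
                chosen = beta
        assert scan.chosen_beta == (chosen if chosen is not None else best_beta)

    def test_fit_index_penalises_positive_slope(self):
        # frequency increasing with K must score negatively
        k = np.concatenate([np.full(5, 1.0), np.full(20, 5.0), np.full(75, 10.0)])
        assert nw.scale_free_r2(k, n_bins=5) < 0


def block_expr(rng, sizes, n_samples=20, within=0.9):
    rows = []
    for size in sizes:
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(
                np.sqrt(within) * f
                + np.sqrt(1 - within) * rng.standard_normal(n_samples)
            )
    return pd.DataFrame(rows, index=[f"g{i:03d}" for i in range(sum(sizes))])


class TestModuleDetection:
    def test_two_separated_blocks_give_two_modules(self):
        rng = np.random.default_rng(0)
        expr = block_expr(rng, [40, 45])
        tom = nw.topological_overlap(nw.adjacency(nw.correlation_matrix(expr), 3))
        labels = nw.detect_modules(expr, tom, min_module_size=30)
        mods = set(labels) - {nw.GREY}
        assert len(mods) == 2
        assert labels.iloc[:40].nunique() == 1
        assert labels.iloc[40:].nunique() == 1

    def test_undersized_cluster_goes_grey(self):
        rng = np.random.default_rng(1)
        expr = block_expr(rng, [25, 40])
        tom = nw.topological_overlap(nw.adjacency(nw.correlation_matrix(expr), 3))
        labels = nw.cluster_modules(tom, min_module_size=30)
        assert (labels.iloc[:25] == nw.GREY).all()

    def test_tiny_input_is_all_grey_with_warning(self):
        rng = np.random.default_rng(2)
        expr = block_expr(rng, [10])
        tom = nw.topological_overlap(nw.adjacency(nw.correlation_matrix(expr), 3))
        with pytest.warns(UserWarning, match="grey"):
            labels = nw.cluster_modules(tom, min_module_size=30)
        assert (labels == nw.GREY).all()

    def test_colors_assigned_by_decreasing_size(self):
        rng = np.random.default_rng(3)
        expr = block_expr(rng, [50, 35])
        tom = nw.topological_overlap(nw.adjacency(nw.correlation_matrix(expr), 3))
        labels = nw.detect_modules(expr, tom, min_module_size=30)
        sizes = labels[labels != nw.GREY].value_counts()
        assert list(sizes.index[:2]) == ["turquoise", "blue"]

    def test_permuting_gene_order_permutes_labels(self):
        rng = np.random.default_rng(4)
        expr = block_expr(rng, [40, 40])
        tom = nw.topological_overlap(nw.adjacency(nw.correlation_matrix(expr), 3))
        labels = nw.cluster_modules(tom, 30)
        perm = rng.permutation(len(expr))
        tom_p = tom.iloc[perm, perm]
        labels_p = nw.cluster_modules(tom_p, 30)
        joint = pd.crosstab(labels[tom_p.index], labels_p)
        # one-to-one correspondence between label sets
        assert (joint.gt(0).sum(axis=1) == 1).all()


class TestEigengenes:
    def test_identical_genes_give_their_standardized_profile(self):
        rng = np.random.default_rng(0)
        profile = rng.standard_normal(10)
        expr = pd.DataFrame(
            [2 * profile + 1, 5 * profile - 3, profile],
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series("turquoise", index=expr.index)
        me = nw.module_eigengenes(expr, labels)["turquoise"]
        z = (profile - profile.mean()) / profile.std(ddof=1)
        expected = z / np.linalg.norm(z)
        np.testing.assert_allclose(me.to_numpy(), expected, atol=1e-10)

    def test_explains_at_least_as_much_variance_as_random_directions(self):
        rng = np.random.default_rng(5)
        expr = block_expr(rng, [20], n_samples=12, within=0.5)
        labels = pd.Series("turquoise", index=expr.index)
        me = nw.module_eigengenes(expr, labels)["turquoise"].to_numpy()
        X = expr.to_numpy()
        Xs = ((X.T - X.mean(axis=1)) / X.std(axis=1, ddof=1)).T
        var_me = ((Xs @ me) ** 2).sum()
        for _ in range(100):
            v = rng.standard_normal(12)
            v /= np.linalg.norm(v)
            assert ((Xs @ v) ** 2).sum() <= var_me + 1e-9

    def test_sign_flip_of_members_leaves_trait_association_invariant(self):
        rng = np.random.default_rng(6)
        expr = block_expr(rng, [15], n_samples=14)
        labels = pd.Series("turquoise", index=expr.index)
        trait = pd.Series(rng.standard_normal(14), index=expr.columns)
        me1 = nw.module_eigengenes(expr, labels)["turquoise"]
        me2 = nw.module_eigengenes(-expr, labels)["turquoise"]
        r1 = stats.pearsonr(me1, trait).statistic
        r2 = stats.pearsonr(me2, trait).statistic
        assert abs(r1) == pytest.approx(abs(r2), abs=1e-10)

    def test_zero_variance_member_rejected(self):
        expr = block_expr(np.random.default_rng(7), [5], n_samples=8)
        expr.iloc[0] = 3.0
        labels = pd.Series("turquoise", index=expr.index)
        with pytest.raises(ValueError, match="zero-variance"):
            nw.module_eigengenes(expr, labels)


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(0)
        expr = block_expr(rng, [10], n_samples=14)
        labels = pd.Series("turquoise", index=expr.index)
        me = nw.module_eigengenes(expr, labels)
        traits = pd.DataFrame({"rfi": me["turquoise"]})
        table = nw.module_trait_correlation(me, traits)
        assert table["r"].iloc[0] == pytest.approx(1.0)
        assert table["p"].iloc[0] < 1e-10

    def test_p_value_matches_t_transform(self):
        # r = 0.6 at n = 14: p = 2 * P(T_12 > r sqrt(12 / (1 - r^2)))
        r, n = 0.6, 14
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(t, df=n - 2)
        rng = np.random.default_rng(1)
        # build a trait vector with exact sample correlation r to an ME
        expr = block_expr(rng, [10], n_samples=n)
        labels = pd.Series("turquoise", index=expr.index)
        me = nw.module_eigengenes(expr, labels)
        v = me["turquoise"].to_numpy()
        w = rng.standard_normal(n)
        w = w - w.mean() - (w @ v) / (v @ v) * v  # orthogonal, zero-mean
        trait = r * v / np.linalg.norm(v) + np.sqrt(1 - r**2) * w / np.linalg.norm(w)
        table = nw.module_trait_correlation(
            me, pd.DataFrame({"rfi": trait}, index=me.index)
        )
        assert table["r"].iloc[0] == pytest.approx(r, abs=1e-10)
        assert table["p"].iloc[0] == pytest.approx(expected, rel=1e-8)


class TestTraitModuleSelection:
    table = pd.DataFrame(
        {
            "module": ["m1", "m1", "m2", "m2", "m3", "m3", "m4", "m4"],
            "trait": ["rfi", "rig"] * 4,
            "r": [0.6, -0.4, 0.5, 0.2, 0.7, -0.1, -0.3, 0.2],
            "p": [0.05, 0.3, 0.04, 0.5, 0.2, 0.6, 0.4, 0.5],
        }
    )

    def test_clear_pass_selected_with_sign_pattern(self):
        sel = nw.select_trait_modules(self.table)
        assert list(sel["module"]) == ["m1"]
        assert sel["sign_pattern"].iloc[0] == "rfi+/rig-"

    def test_boundary_r_not_selected(self):
        # m2: r = 0.5 exactly -> strict inequality excludes it
        sel = nw.select_trait_modules(self.table)
        assert "m2" not in set(sel["module"])

    def test_p_gate_blocks_strong_r(self):
        # m3: r = 0.7 but p = 0.2 > 0.1
        sel = nw.select_trait_modules(self.table)
        assert "m3" not in set(sel["module"])


class TestModuleMembership:
    def test_gene_identical_to_eigengene_retained(self):
        rng = np.random.default_rng(0)
        expr = block_expr(rng, [10, 10], n_samples=14)
        labels = pd.Series(
            ["turquoise"] * 10 + ["blue"] * 10, index=expr.index
        )
        me = nw.module_eigengenes(expr, labels)
        expr.loc["g000"] = me["turquoise"].to_numpy()
        kme = nw.module_membership(expr, me)
        assert kme.loc["g000", "turquoise"] == pytest.approx(1.0)
        lists = nw.filter_by_membership(kme, labels)
        if abs(kme.loc["g000", "blue"]) < 0.6:
            assert "g000" in lists["turquoise"]

    def test_cross_module_gate_drops_ambiguous_gene(self):
        kme = pd.DataFrame(
            {"turquoise": [0.7, 0.9], "blue": [0.65, 0.1]}, index=["ga", "gb"]
        )
        labels = pd.Series(["turquoise", "turquoise"], index=kme.index)
        lists = nw.filter_by_membership(kme, labels)
        assert lists["turquoise"] == ["gb"]

    def test_kme_matches_direct_correlation(self):
        rng = np.random.default_rng(2)
        expr = block_expr(rng, [8], n_samples=10)
        labels = pd.Series("turquoise", index=expr.index)
        me = nw.module_eigengenes(expr, labels)
        kme = nw.module_membership(expr, me)
        for g in expr.index:
            expected = stats.pearsonr(expr.loc[g], me["turquoise"]).statistic
            assert kme.loc[g, "turquoise"] == pytest.approx(expected, abs=1e-12)
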