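"""Mixed RM-ANOVA maps, GG epsilon, clustering, permutation, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from bse import cluster_stats as cs


def naive_mixed_anova(x, groups):
    """Textbook balanced mixed-design ANOVA, loops and means only.

    x: (N, a, b) one observation per subject x cell; groups: labels (N,)
    with equal group sizes.  Returns {effect: F}.
    """
    n, a, b = x.shape
    levels = sorted(set(groups))
    g_idx = {g: [i for i in range(n) if groups[i] == g] for g in levels}
    n_g = {g: len(v) for g, v in g_idx.items()}
    m = x.mean()
    m_g = {g: x[v].mean() for g, v in g_idx.items()}
    m_j = x.mean(axis=(0, 2))
    m_k = x.mean(axis=(0, 1))
    m_jk = x.mean(axis=0)
    m_i = x.mean(axis=(1, 2))
    m_ij = x.mean(axis=2)
    m_ik = x.mean(axis=1)
    m_gj = {g: x[v].mean(axis=(0, 2)) for g, v in g_idx.items()}
    m_gk = {g: x[v].mean(axis=(0, 1)) for g, v in g_idx.items()}
    m_gjk = {g: x[v].mean(axis=0) for g, v in g_idx.items()}
    G = len(levels)

    ss_group = a * b * sum(n_g[g] * (m_g[g] - m) ** 2 for g in levels)
    ss_subj = a * b * sum((m_i[i] - m_g[groups[i]]) ** 2 for i in range(n))
    f_group = (ss_group / (G - 1)) / (ss_subj / (n - G))

    ss_a = n * b * sum((mj - m) ** 2 for mj in m_j)
    ss_ag = b * sum(n_g[g] * sum((m_gj[g][j] - m_g[g] - m_j[j] + m) ** 2
                                 for j in range(a)) for g in levels)
    ss_ea = b * sum((m_ij[i, j] - m_i[i] - m_gj[groups[i]][j] + m_g[groups[i]]) ** 2
                    for i in range(n) for j in range(a))
    df_ea = (a - 1) * (n - G)
    f_a = (ss_a / (a - 1)) / (ss_ea / df_ea)
    f_ag = (ss_ag / ((a - 1) * (G - 1))) / (ss_ea / df_ea)

    ss_b = n * a * sum((mk - m) ** 2 for mk in m_k)
    ss_bg = a * sum(n_g[g] * sum((m_gk[g][k] - m_g[g] - m_k[k] + m) ** 2
                                 for k in range(b)) for g in levels)
    ss_eb = a * sum((m_ik[i, k] - m_i[i] - m_gk[groups[i]][k] + m_g[groups[i]]) ** 2
                    for i in range(n) for k in range(b))
    df_eb = (b - 1) * (n - G)
    f_b = (ss_b / (b - 1)) / (ss_eb / df_eb)
    f_bg = (ss_bg / ((b - 1) * (G - 1))) / (ss_eb / df_eb)

    ss_ab = n * sum((m_jk[j, k] - m_j[j] - m_k[k] + m) ** 2
                    for j in range(a) for k in range(b))
    ss_abg = sum(n_g[g] * sum((m_gjk[g][j, k] - m_gj[g][j] - m_gk[g][k] + m_g[g]
                               - m_jk[j, k] + m_j[j] + m_k[k] - m) ** 2
                              for j in range(a) for k in range(b)) for g in levels)
    ss_eab = sum((x[i, j, k] - m_ij[i, j] - m_ik[i, k] + m_i[i]
                  - m_gjk[groups[i]][j, k] + m_gj[groups[i]][j]
                  + m_gk[groups[i]][k] - m_g[groups[i]]) ** 2
                 for i in range(n) for j in range(a) for k in range(b))
    df_eab = (a - 1) * (b - 1) * (n - G)
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_eab / df_eab)
    f_abg = (ss_abg / ((a - 1) * (b - 1) * (G - 1))) / (ss_eab / df_eab)
    return {"group": f_group, "A": f_a, "A*group": f_ag, "B": f_b,
            "B*group": f_bg, "A*B": f_ab, "A*B*group": f_abg}


def two_factor_design(n_per_group=4, a=3, b=6):
    groups = np.array(["AN"] * n_per_group + ["HC"] * n_per_group)
    within = {"A": tuple(f"a{j}" for j in range(a)),
              "B": tuple(f"b{k}" for k in range(b))}
    return cs.MixedDesign(within=within, groups=groups)


class TestPointwiseAnova:
    def test_matches_naive_ss_decomposition_all_effects(self, rng):
        """Every F map equals the loop-and-means textbook decomposition."""
        design = two_factor_design()
        n, a, b = 8, 3, 6
        x = rng.normal(size=(n, a, b))
        x += np.linspace(0, 1, a)[None, :, None]  # some real structure
        x[:4] += 0.5 * np.linspace(1, -1, b)[None, None, :]
        maps = cs.pointwise_rm_anova(x.reshape(n, a * b, 1, 1), design,
                                     gg_threshold=0.0)
        expect = naive_mixed_anova(x, list(design.groups))
        for ours, theirs in [("group", "group"), ("A", "A"), ("A*group", "A*group"),
                             ("B", "B"), ("B*group", "B*group"),
                             ("A*B", "A*B"), ("A*B*group", "A*B*group")]:
            assert maps[ours].F.ravel()[0] == pytest.approx(expect[theirs], rel=1e-6), ours

    def test_all_equal_data_gives_zero_f(self):
        design = two_factor_design()
        x = np.full((8, 18, 2, 3), 3.7)
        maps = cs.pointwise_rm_anova(x, design)
        for fmap in maps.values():
            assert np.all(fmap.F == 0.0)
            assert np.all(fmap.p == 1.0)

    def test_subject_order_invariance(self, rng):
        design = two_factor_design()
        x = rng.normal(size=(8, 18, 4, 2))
        perm = rng.permutation(8)
        design_p = cs.MixedDesign(within=design.within, groups=design.groups[perm])
        a = cs.pointwise_rm_anova(x, design)
        b = cs.pointwise_rm_anova(x[perm], design_p)
        for name in a:
            assert np.allclose(a[name].F, b[name].F, rtol=1e-10)

    def test_missing_cells_rejected(self, rng):
        design = two_factor_design()
        x = rng.normal(size=(8, 18, 1, 1))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cs.pointwise_rm_anova(x, design)

    def test_balanced_two_way_matches_pingouin(self, rng):
        """Independent cross-check of the mixed model against pingouin."""
        import pingouin as pg

        n, k = 12, 4
        x = rng.normal(size=(n, k)) + np.linspace(0, 0.8, k)
        groups = np.array(["AN"] * 6 + ["HC"] * 6)
        design = cs.MixedDesign(within={"w": tuple("wxyz")}, groups=groups)
        maps = cs.pointwise_rm_anova(x.reshape(n, k, 1, 1), design, gg_threshold=0.0)
        df = pd.DataFrame({
            "score": x.ravel(),
            "w": np.tile(list("wxyz"), n),
            "s": np.repeat(np.arange(n), k),
            "g": np.repeat(groups, k),
        })
        aov = pg.mixed_anova(data=df, dv="score", within="w", subject="s", between="g")
        by_src = {r["Source"]: r for _, r in aov.iterrows()}
        assert maps["group"].F.ravel()[0] == pytest.approx(by_src["g"]["F"], rel=1e-8)
        assert maps["w"].F.ravel()[0] == pytest.approx(by_src["w"]["F"], rel=1e-8)
        assert maps["w*group"].F.ravel()[0] == pytest.approx(
            by_src["Interaction"]["F"], rel=1e-8)


class TestGreenhouseGeisser:
    def test_compound_symmetry_gives_one(self):
        cov = 0.6 * np.ones((5, 5)) + 0.4 * np.eye(5)
        assert cs.gg_epsilon(cov) == pytest.approx(1.0, abs=1e-12)

    def test_two_levels_always_one(self, rng):
        a = rng.normal(size=(2, 2))
        assert cs.gg_epsilon(a @ a.T) == pytest.approx(1.0)

    def test_random_covariance_matches_eigen_formula(self, rng):
        """Epsilon equals the eigenvalue form of the double-centred covariance."""
        a = rng.normal(size=(4, 4))
        cov = a @ a.T
        k = 4
        c = np.eye(k) - np.ones((k, k)) / k
        lam = np.linalg.eigvalsh(c @ cov @ c)
        lam = lam[lam > 1e-12]
        expect = lam.sum() ** 2 / ((k - 1) * np.sum(lam**2))
        assert cs.gg_epsilon(cov) == pytest.approx(expect, rel=1e-9)

    def test_singular_covariance_hits_lower_bound(self):
        cov = np.outer([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])  # centred -> zero
        with pytest.warns(UserWarning):
            assert cs.gg_epsilon(cov) == pytest.approx(1.0 / 2.0)


def chain_adjacency(n_sites, n_times, neighbor_pairs):
    spatial = sparse.csr_matrix(
        (np.ones(2 * len(neighbor_pairs)),
         ([p for pr in neighbor_pairs for p in pr],
          [p for pr in neighbor_pairs for p in reversed(pr)])),
        shape=(n_sites, n_sites))
    return cs.grid_adjacency(n_sites, n_times, spatial)


def flood_fill(mask2d, neighbor_pairs):
    """Independent BFS clustering over a (sites, times) boolean grid."""
    nbrs = {}
    for i, j in neighbor_pairs:
        nbrs.setdefault(i, set()).add(j)
        nbrs.setdefault(j, set()).add(i)
    seen, comps = set(), []
    points = {(s, t) for s, t in zip(*np.nonzero(mask2d))}
    for p in sorted(points):
        if p in seen:
            continue
        comp, stack = set(), [p]
        while stack:
            s, t = stack.pop()
            if (s, t) in seen:
                continue
            seen.add((s, t))
            comp.add((s, t))
            cands = [(s, t - 1), (s, t + 1)] + [(s2, t) for s2 in nbrs.get(s, ())]
            stack.extend(c for c in cands if c in points and c not in seen)
        comps.append(comp)
    return comps


class TestClustering:
    neighbor_pairs = [(0, 1), (1, 2), (2, 3), (3, 4)]

    def _fmap(self, f, p):
        return cs.FMap("picture", f, p, np.ones_like(f), np.ones_like(f),
                       None, f.shape)

    def test_no_suprathreshold_points_empty(self):
        f = np.ones((5, 6))
        p = np.full((5, 6), 0.5)
        adj = chain_adjacency(5, 6, self.neighbor_pairs)
        assert cs.form_clusters(self._fmap(f, p), adj) == []

    def test_isolated_point_single_cluster(self):
        f = np.ones((5, 6))
        p = np.full((5, 6), 0.5)
        f[2, 3], p[2, 3] = 7.5, 0.01
        adj = chain_adjacency(5, 6, self.neighbor_pairs)
        clusters = cs.form_clusters(self._fmap(f, p), adj)
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(7.5)
        assert list(clusters[0].members) == [2 * 6 + 3]

    def test_two_separated_blobs_match_flood_fill(self, rng):
        f = rng.uniform(1, 5, size=(5, 8))
        p = np.full((5, 8), 0.5)
        for s, t in [(0, 1), (0, 2), (1, 1)]:
            p[s, t] = 0.01
        for s, t in [(3, 6), (4, 6), (4, 7)]:
            p[s, t] = 0.01
        adj = chain_adjacency(5, 8, self.neighbor_pairs)
        clusters = cs.form_clusters(self._fmap(f, p), adj)
        comps = flood_fill(p < 0.05, self.neighbor_pairs)
        assert len(clusters) == len(comps) == 2
        ours = {frozenset((m // 8, m % 8) for m in c.members) for c in clusters}
        assert ours == {frozenset(c) for c in comps}

    def test_cluster_mass_invariant_to_site_relabeling(self, rng):
        """Relabeling sites with the matching adjacency keeps the masses."""
        n_s, n_t = 6, 5
        f = rng.uniform(0.5, 9, size=(n_s, n_t))
        p = np.where(rng.random((n_s, n_t)) < 0.4, 0.01, 0.5)
        pairs = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)]
        perm = rng.permutation(n_s)
        inv = np.argsort(perm)  # site s moves to position inv[s]
        pairs_perm = [(int(inv[i]), int(inv[j])) for i, j in pairs]
        adj = chain_adjacency(n_s, n_t, pairs)
        adj_p = chain_adjacency(n_s, n_t, pairs_perm)
        m1 = sorted(c.mass for c in cs.form_clusters(self._fmap(f, p), adj))
        m2 = sorted(c.mass for c in cs.form_clusters(self._fmap(f[perm], p[perm]), adj_p))
        assert np.allclose(m1, m2)


class TestMergeClusters:
    def _cluster(self, members, mass, effect="task"):
        return cs.Cluster(effect=effect, members=np.asarray(members),
                          mass=mass, map_shape=(5, 6), p=0.01)

    def test_disjoint_non_adjacent_unchanged(self):
        adj = chain_adjacency(5, 6, [(0, 1)])
        a = self._cluster([0], 1.0)   # site 0, t 0
        b = self._cluster([4 * 6 + 5], 2.0)  # site 4, t 5
        merged = cs.merge_clusters([a, b], adj)
        assert sorted(c.mass for c in merged) == [1.0, 2.0]

    def test_temporally_abutting_clusters_union(self):
        adj = chain_adjacency(5, 6, [])
        a = self._cluster([2 * 6 + 1], 1.5)
        b = self._cluster([2 * 6 + 2], 2.5)  # same site, next sample
        merged = cs.merge_clusters([a, b], adj)
        assert len(merged) == 1
        assert merged[0].mass == pytest.approx(4.0)

    def test_idempotent_and_order_independent(self, rng):
        adj = chain_adjacency(5, 6, [(0, 1), (1, 2)])
        parts = [self._cluster([0, 1], 1.0), self._cluster([2], 0.5),
                 self._cluster([6 * 4 + 0], 2.0), self._cluster([2 * 6 + 5], 0.7)]
        results = []
        for order in ([0, 1, 2, 3], [3, 2, 1, 0], [1, 3, 0, 2]):
            merged = cs.merge_clusters([parts[i] for i in order], adj)
            again = cs.merge_clusters(merged, adj)
            assert len(again) == len(merged)
            results.append(sorted(round(c.mass, 9) for c in merged))
        assert results[0] == results[1] == results[2]

    def test_different_effects_never_merge(self):
        adj = chain_adjacency(5, 6, [])
        a = self._cluster([0], 1.0, effect="task")
        b = self._cluster([1], 1.0, effect="picture")
        assert len(cs.merge_clusters([a, b], adj)) == 2


class TestPermutationTest:
    def test_huge_effect_reaches_floor_p(self, rng):
        """An overwhelming effect gets p = 1/(n_perm+1), the estimator floor.

        Three within levels: with two, a coherent label flip across all
        subjects (probability 2^-N per draw) reproduces the observed mass
        exactly and lifts p off the floor.
        """
        design = cs.MixedDesign(within={"w": ("x", "y", "z")},
                                groups=np.array(["AN"] * 6 + ["HC"] * 6))
        x = rng.normal(size=(12, 3, 8, 5)) * 0.01
        x[:, 1] += 5.0  # massive within effect everywhere
        adj = cs.grid_adjacency(8, 5, None)
        test = cs.permutation_cluster_test(x, design, "w", adj, n_perm=100, seed=0)
        assert test.clusters[0].p == pytest.approx(1.0 / 101.0)

    def test_seeded_determinism(self, rng):
        design = cs.MixedDesign(within={"w": ("x", "y", "z")},
                                groups=np.array(["AN"] * 5 + ["HC"] * 5))
        x = rng.normal(size=(10, 3, 6, 4))
        adj = cs.grid_adjacency(6, 4, None)
        t1 = cs.permutation_cluster_test(x, design, "w*group", adj, n_perm=120, seed=7)
        t2 = cs.permutation_cluster_test(x, design, "w*group", adj, n_perm=120, seed=7)
        assert np.array_equal(t1.null_max_mass, t2.null_max_mass)
        assert [c.p for c in t1.clusters] == [c.p for c in t2.clusters]

    def test_unknown_effect_rejected(self, rng):
        design = cs.MixedDesign(within={"w": ("x", "y")},
                                groups=np.array(["AN"] * 4 + ["HC"] * 4))
        x = rng.normal(size=(8, 2, 3, 3))
        adj = cs.grid_adjacency(3, 3, None)
        with pytest.raises(ValueError):
            cs.permutation_cluster_test(x, design, "bogus", adj, n_perm=100)


class TestExtractClusterMean:
    def test_single_point_and_uniform(self, rng):
        x = rng.normal(size=(4, 6, 5, 3))
        c = cs.Cluster("e", np.array([2 * 3 + 1]), 1.0, (5, 3))
        assert np.allclose(cs.extract_cluster_mean(x, c), x[:, :, 2, 1])
        x_const = np.full_like(x, 2.5)
        c2 = cs.Cluster("e", np.arange(15), 1.0, (5, 3))
        assert np.allclose(cs.extract_cluster_mean(x_const, c2), 2.5)

    def test_matches_naive_loop(self, rng):
        x = rng.normal(size=(3, 4, 6, 7))
        members = np.array([5, 11, 12, 40])
        c = cs.Cluster("e", members, 0.0, (6, 7))
        got = cs.extract_cluster_mean(x, c)
        for i in range(3):
            for j in range(4):
                vals = [x[i, j, m // 7, m % 7] for m in members]
                assert got[i, j] == pytest.approx(np.mean(vals))


class TestPolynomialContrasts:
    def test_weights_orthogonal_and_classic_for_six_levels(self):
        lin = cs.poly_contrast_weights(6, 1)
        quad = cs.poly_contrast_weights(6, 2)
        assert lin @ quad == pytest.approx(0.0, abs=1e-12)
        assert lin.sum() == pytest.approx(0.0, abs=1e-12)
        classic_lin = np.array([-5, -3, -1, 1, 3, 5], dtype=float)
        classic_quad = np.array([5, -1, -4, -4, -1, 5], dtype=float)
        assert np.allclose(lin, classic_lin / np.linalg.norm(classic_lin))
        assert np.allclose(quad, classic_quad / np.linalg.norm(classic_quad))

    def test_perfectly_linear_data_has_zero_quadratic_f(self, rng):
        slopes = rng.uniform(0.5, 2.0, size=10)
        means = slopes[:, None] * np.arange(6)[None, :]
        res = cs.polynomial_contrast(means, 2)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_f_equals_hand_computed_squared_t(self):
        means = np.array([[1.0, 2.0, 3.5, 4.0, 6.0, 7.0],
                          [0.5, 1.5, 2.0, 3.0, 4.5, 5.0],
                          [2.0, 2.5, 4.0, 5.5, 6.0, 8.0]])
        w = cs.poly_contrast_weights(6, 1)
        scores = means @ w
        t = scores.mean() / (scores.std(ddof=1) / np.sqrt(3))
        res = cs.polynomial_contrast(means, 1)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(stats.f.sf(t**2, 1, 2), rel=1e-10)

    def test_quadratic_needs_three_levels(self):
        with pytest.raises(ValueError):
            cs.poly_contrast_weights(2, 2)

    def test_group_difference_in_trend(self, rng):
        means = np.vstack([
            np.arange(6) * 1.0 + rng.normal(0, 0.01, size=(5, 6)),
            np.arange(6) * -1.0 + rng.normal(0, 0.01, size=(5, 6)),
        ])
        groups = np.array(["AN"] * 5 + ["HC"] * 5)
        res = cs.polynomial_contrast(means, 1, groups=groups)
        assert res.p < 1e-6
        assert res.mean_score > 0  # AN minus HC linear score


class TestPosthoc:
    def test_identical_pairs_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = cs.paired_ttest(x, x.copy())
        assert res["t"] == 0.0 and res["d"] == 0.0

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        res = cs.paired_ttest(x, y)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        assert res["t"] == pytest.approx(t, rel=1e-12)
        assert res["p"] == pytest.approx(2 * stats.t.sf(abs(t), 11), rel=1e-12)

    def test_sign_flip_antisymmetry(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert cs.paired_ttest(x, y)["t"] == pytest.approx(-cs.paired_ttest(y, x)["t"])

    def test_posthoc_table(self, rng):
        df = pd.DataFrame({"viewing": rng.normal(size=8),
                           "bar": rng.normal(size=8) + 1.0,
                           "body": rng.normal(size=8) + 2.0})
        groups = np.array(["AN"] * 4 + ["HC"] * 4)
        table = cs.posthoc_ttests(df, [("body", "bar"), ("bar", "viewing")],
                                  groups=groups)
        assert len(table) == 4
        assert {"paired", "independent"} == set(table["kind"])
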