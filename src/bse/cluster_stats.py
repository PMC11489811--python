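"""Mass-univariate mixed RM-ANOVA with nonparametric cluster-permutation control.

For every source site and time point, a univariate mixed-design
repeated-measures ANOVA is computed over the within factors (task, body
picture) and the between factor (group).  Each within effect is evaluated
on orthonormal contrast scores of the subject's cell means, with its own
error stratum (the classic univariate RM decomposition); sphericity is
handled by the Greenhouse-Geisser epsilon, applied when epsilon < 0.75.

Multiplicity over the site x time grid is controlled with the
cluster-permutation scheme of the mass-univariate tradition: pointwise
F maps are thresholded at an uncorrected alpha, suprathreshold points are
grouped into spatiotemporally connected clusters (Delaunay neighbours on
the shell, +-1 sample in time), and each cluster's mass (sum of F) is
referred to the permutation distribution of the maximal cluster mass.
Effects involving the between factor permute group labels across subjects
(exact exchangeability); pure within effects permute condition labels
within subjects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.linalg import helmert
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull

from .psychometrics import group_ttest  # noqa: F401  (re-exported for post hocs)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class MixedDesign:
    """Within-factor structure and group assignment of a balanced design.

    ``within`` maps factor name to its ordered levels; the condition axis of
    the data must enumerate the Cartesian product of levels in this factor
    order (last factor fastest).  ``groups`` assigns each subject a label of
    the between factor.
    """

    within: dict[str, tuple[str, ...]]
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        self.group_levels = tuple(sorted(pd.unique(self.groups)))
        for g in self.group_levels:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.groups)

    @property
    def within_shape(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.within.values())

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.within_shape))

    def cells(self) -> pd.DataFrame:
        names = list(self.within)
        rows = list(itertools.product(*self.within.values()))
        return pd.DataFrame(rows, columns=names)

    def effect_names(self) -> list[str]:
        names = ["group"]
        factors = list(self.within)
        for r in range(1, len(factors) + 1):
            for combo in itertools.combinations(factors, r):
                names.append("*".join(combo))
                names.append("*".join(combo) + "*group")
        return names


def _contrast_matrix(design: MixedDesign, subset: tuple[str, ...]) -> np.ndarray:
    """Kronecker contrast rows spanning the effect subspace of ``subset``.

    Factors in the subset contribute orthonormal zero-sum (Helmert) rows;
    the others contribute the normalized averaging vector, so that the
    classic balanced-design sums of squares are N * sum(score means^2).
    """
    mat = np.ones((1, 1))
    for f, levels in design.within.items():
        l = len(levels)
        block = helmert(l) if f in subset else np.full((1, l), 1.0 / np.sqrt(l))
        mat = np.kron(mat, block)
    return mat


# ---------------------------------------------------------------------------
# Greenhouse-Geisser
# ---------------------------------------------------------------------------

def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a within-cell covariance matrix.

    epsilon = tr(M)^2 / ((k-1) tr(M^2)) with M the covariance of the
    orthonormalized difference scores; bounded in [1/(k-1), 1].
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within levels")
    c = helmert(k)
    m = c @ cov @ c.T
    denom = (k - 1) * np.trace(m @ m)
    lower = 1.0 / (k - 1)
    if denom <= 0:
        warnings.warn("singular within-cell covariance; epsilon at lower bound",
                      stacklevel=2)
        return lower
    eps = float(np.trace(m) ** 2 / denom)
    return float(np.clip(eps, lower, 1.0))


def _epsilon_map(resid: np.ndarray, df_pool: int) -> np.ndarray:
    """Pointwise epsilon from residual scores, shape (N, m, P) -> (P,).

    The scores are already in an orthonormal contrast basis, so epsilon is
    tr(S)^2 / (m tr(S^2)) of their pooled covariance S.
    """
    m = resid.shape[1]
    if m == 1:
        return np.ones(resid.shape[2])
    s = np.einsum("nip,njp->pij", resid, resid) / df_pool
    tr = np.trace(s, axis1=1, axis2=2)
    tr2 = np.einsum("pij,pji->p", s, s)
    lower = 1.0 / m
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = np.where(tr2 > 0, tr**2 / (m * tr2), lower)
    return np.clip(eps, lower, 1.0)


# ---------------------------------------------------------------------------
# pointwise mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass
class FMap:
    """Pointwise F statistics for one effect over the site x time grid."""

    effect: str
    F: np.ndarray
    p: np.ndarray
    df1: np.ndarray
    df2: np.ndarray
    epsilon: np.ndarray | None
    map_shape: tuple[int, ...]


def _f_and_p(ss_eff, df1, ss_err, df_err, eps=None, gg_threshold=0.75, ss_scale=None):
    ms_eff = ss_eff / df1
    ms_err = ss_err / df_err
    # sums of squares below float dust relative to the data level are zero
    tol = 0.0 if ss_scale is None else 1e-14 * ss_scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ss_eff <= tol, 0.0,
                     np.where(ss_err <= tol, np.inf,
                              ms_eff / np.where(ms_err > 0, ms_err, 1.0)))
    if eps is not None:
        corr = eps < gg_threshold
        e = np.where(corr, eps, 1.0)
    else:
        e = 1.0
    d1 = df1 * e
    d2 = df_err * e
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(f, d1, d2)
    p = np.where(f <= 0, 1.0, p)
    return f, np.clip(p, np.finfo(float).tiny, 1.0), d1 * np.ones_like(f), d2 * np.ones_like(f)


def _group_indicator(groups: np.ndarray, levels: tuple) -> list[np.ndarray]:
    return [np.flatnonzero(groups == g) for g in levels]


def _within_effect_maps(
    z: np.ndarray,
    groups: np.ndarray,
    group_levels: tuple,
    gg_threshold: float,
    ss_scale: np.ndarray | None = None,
) -> dict[str, tuple]:
    """F/p maps for an effect subspace: the within effect and its x group.

    ``z``: contrast scores (N, m, P).  Returns dict with keys "within" and
    "interaction", values (F, p, df1, df2, eps).
    """
    n, m, n_points = z.shape
    idx = _group_indicator(groups, group_levels)
    n_g = np.array([len(i) for i in idx], dtype=float)
    g_means = np.stack([z[i].mean(axis=0) for i in idx])  # (G, m, P)
    grand_w = z.mean(axis=0)                               # weighted grand mean
    n_groups = len(idx)
    # residuals around own group mean: the effect's error stratum
    resid = z.copy()
    for gi, i in enumerate(idx):
        resid[i] -= g_means[gi]
    ss_err = np.einsum("nip,nip->p", resid, resid)
    df_err = (n - n_groups) * m
    eps = _epsilon_map(resid, n - n_groups)

    # within main effect: unweighted mean of group means (Type III style)
    t_unw = g_means.mean(axis=0)
    c_eff = 1.0 / np.sum(1.0 / (n_groups**2 * n_g))
    ss_within = c_eff * np.einsum("ip,ip->p", t_unw, t_unw)
    f_w, p_w, d1_w, d2_w = _f_and_p(ss_within, m, ss_err, df_err, eps,
                                    gg_threshold, ss_scale)

    # within x group interaction: between-group dispersion of score means
    dev = g_means - grand_w[None]
    ss_int = np.einsum("g,gip->p", n_g, dev**2)
    df_int = m * (n_groups - 1)
    f_i, p_i, d1_i, d2_i = _f_and_p(ss_int, df_int, ss_err, df_err, eps,
                                    gg_threshold, ss_scale)
    return {
        "within": (f_w, p_w, d1_w, d2_w, eps),
        "interaction": (f_i, p_i, d1_i, d2_i, eps),
    }


def _group_effect_map(y: np.ndarray, groups: np.ndarray, group_levels: tuple,
                      ss_scale: np.ndarray | None = None):
    """One-way between-subjects ANOVA on subject means, (N, P) -> maps."""
    n, n_points = y.shape
    idx = _group_indicator(groups, group_levels)
    n_g = np.array([len(i) for i in idx], dtype=float)
    g_means = np.stack([y[i].mean(axis=0) for i in idx])
    grand = y.mean(axis=0)
    ss_b = np.einsum("g,gp->p", n_g, (g_means - grand[None]) ** 2)
    resid = y.copy()
    for gi, i in enumerate(idx):
        resid[i] -= g_means[gi]
    ss_w = np.einsum("np,np->p", resid, resid)
    df1, df2 = len(idx) - 1, n - len(idx)
    f, p, d1, d2 = _f_and_p(ss_b, df1, ss_w, df2, None, ss_scale=ss_scale)
    return f, p, d1, d2


def pointwise_rm_anova(
    data: np.ndarray,
    design: MixedDesign,
    effects: list[str] | None = None,
    gg_threshold: float = 0.75,
) -> dict[str, FMap]:
    """Mixed RM-ANOVA F map per effect over every (site, time) point.

    ``data``: (n_subjects, n_cells, *map_shape) with cells enumerating the
    within-factor crossing in design order.  Returns one :class:`FMap` per
    requested effect; names follow ``design.effect_names()`` (e.g.
    ``"picture"``, ``"picture*group"``, ``"group"``).
    """
    data = np.asarray(data, dtype=float)
    n, n_cells = data.shape[:2]
    if n != design.n_subjects:
        raise ValueError("subject axis does not match the design")
    if n_cells != design.n_cells:
        raise ValueError(
            f"expected {design.n_cells} condition cells, got {n_cells}"
        )
    if np.isnan(data).any():
        raise ValueError("data contains NaN (missing cells?)")
    map_shape = data.shape[2:]
    x = data.reshape(n, n_cells, -1)
    ss_scale = np.einsum("ncp,ncp->p", x, x)  # dust threshold reference
    wanted = effects or design.effect_names()
    out: dict[str, FMap] = {}
    factors = list(design.within)
    for name in wanted:
        parts = name.split("*")
        if name == "group":
            c = _contrast_matrix(design, ())
            y = np.einsum("mc,ncp->nmp", c, x)[:, 0, :]
            f, p, d1, d2 = _group_effect_map(y, design.groups, design.group_levels,
                                             ss_scale)
            out[name] = FMap(name, *(a.reshape(map_shape) for a in (f, p, d1, d2)),
                             epsilon=None, map_shape=map_shape)
            continue
        with_group = parts[-1] == "group"
        subset = tuple(p for p in parts if p != "group")
        if not subset or any(s not in factors for s in subset):
            raise ValueError(f"unknown effect {name!r}")
        c = _contrast_matrix(design, subset)
        z = np.einsum("mc,ncp->nmp", c, x)
        maps = _within_effect_maps(z, design.groups, design.group_levels,
                                   gg_threshold, ss_scale)
        key = "interaction" if with_group else "within"
        f, p, d1, d2, eps = maps[key]
        out[name] = FMap(name, f.reshape(map_shape), p.reshape(map_shape),
                         d1.reshape(map_shape), d2.reshape(map_shape),
                         epsilon=eps.reshape(map_shape) if z.shape[1] > 1 else None,
                         map_shape=map_shape)
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def spatial_adjacency(positions: np.ndarray) -> sparse.csr_matrix:
    """Delaunay (convex-hull) neighbour graph of shell sites, symmetric."""
    positions = np.asarray(positions, dtype=float)
    hull = ConvexHull(positions)
    n = positions.shape[0]
    rows, cols = [], []
    for simplex in hull.simplices:
        for i, j in itertools.combinations(simplex, 2):
            rows += [i, j]
            cols += [j, i]
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    adj.data[:] = 1.0
    return adj


def grid_adjacency(n_sites: int, n_times: int,
                   spatial: sparse.spmatrix | None = None) -> sparse.csr_matrix:
    """Spatiotemporal adjacency over flat (site-major) grid indices.

    Neighbours: spatially adjacent sites at the same sample, and the same
    site at +-1 sample.  ``spatial=None`` means no spatial edges (pure
    temporal chains), useful for site-wise lattices in tests.
    """
    chain = sparse.diags([np.ones(n_times - 1)] * 2, [-1, 1], format="csr")
    adj = sparse.kron(sparse.eye(n_sites), chain, format="csr")
    if spatial is not None:
        adj = adj + sparse.kron(spatial, sparse.eye(n_times), format="csr")
    adj.data[:] = 1.0
    return adj.tocsr()


@dataclass
class Cluster:
    """Connected suprathreshold set with its mass statistic."""

    effect: str
    members: np.ndarray        # flat (site-major) grid indices
    mass: float
    map_shape: tuple[int, ...]
    p: float | None = None

    @property
    def sites(self) -> np.ndarray:
        return np.unique(self.members // self.map_shape[1])

    @property
    def time_indices(self) -> np.ndarray:
        return np.unique(self.members % self.map_shape[1])

    def time_extent_ms(self, times_ms: np.ndarray) -> tuple[float, float]:
        ti = self.time_indices
        return float(times_ms[ti.min()]), float(times_ms[ti.max()])


def form_clusters(
    fmap: FMap,
    adjacency: sparse.spmatrix,
    point_alpha: float = 0.05,
) -> list[Cluster]:
    """Threshold the p map and group suprathreshold points into clusters."""
    mask = fmap.p.ravel() < point_alpha
    return _clusters_from_mask(fmap.F.ravel(), mask, adjacency, fmap.effect, fmap.map_shape)


def _clusters_from_mask(f_flat, mask, adjacency, effect, map_shape) -> list[Cluster]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    clusters = []
    for k in range(n_comp):
        members = idx[labels == k]
        clusters.append(
            Cluster(effect=effect, members=members,
                    mass=float(f_flat[members].sum()), map_shape=tuple(map_shape))
        )
    clusters.sort(key=lambda c: -c.mass)
    return clusters


def _max_cluster_mass(f_flat, mask, adjacency) -> float:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 0.0
    sub = adjacency[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    masses = np.bincount(labels, weights=f_flat[idx])
    return float(masses.max())


def merge_clusters(clusters: list[Cluster], adjacency: sparse.spmatrix) -> list[Cluster]:
    """Union same-effect clusters whose member sets touch under the adjacency.

    Masses add; the merged cluster keeps the smallest member p (the
    permutation p of a merged blob is at most that of its largest part).
    Idempotent and order independent.
    """
    by_effect: dict[str, list[Cluster]] = {}
    for c in clusters:
        by_effect.setdefault(c.effect, []).append(c)
    merged: list[Cluster] = []
    for effect, group in by_effect.items():
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                mi, mj = group[i].members, group[j].members
                touching = (
                    np.intersect1d(mi, mj).size > 0
                    or adjacency[mi][:, mj].nnz > 0
                )
                if touching:
                    parent[find(i)] = find(j)
        buckets: dict[int, list[Cluster]] = {}
        for i, c in enumerate(group):
            buckets.setdefault(find(i), []).append(c)
        for comps in buckets.values():
            members = np.unique(np.concatenate([c.members for c in comps]))
            ps = [c.p for c in comps if c.p is not None]
            merged.append(
                Cluster(
                    effect=effect,
                    members=members,
                    mass=float(sum(c.mass for c in comps)),
                    map_shape=comps[0].map_shape,
                    p=min(ps) if ps else None,
                )
            )
    merged.sort(key=lambda c: -c.mass)
    return merged


def extract_cluster_mean(data: np.ndarray, cluster: Cluster) -> np.ndarray:
    """Mean activity over the cluster's (site, time) points.

    ``data``: (n_subjects, n_cells, n_sites, n_times) -> (n_subjects, n_cells).
    """
    n, n_cells = data.shape[:2]
    flat = data.reshape(n, n_cells, -1)
    if cluster.members.max() >= flat.shape[2]:
        raise ValueError("cluster members outside the data grid")
    return flat[:, :, cluster.members].mean(axis=2)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass
class ClusterTest:
    """Observed clusters with permutation p-values and the null masses."""

    effect: str
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    fmap: FMap

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p < alpha]


def _permute_within(x, subset_axes, within_shape, rng):
    """Permute the listed within-factor level axes independently per subject."""
    n = x.shape[0]
    xr = x.reshape(n, *within_shape, -1)
    out = np.empty_like(xr)
    for i in range(n):
        xi = xr[i]
        for ax in subset_axes:  # factor axes of the per-subject block
            perm = rng.permutation(xi.shape[ax - 1])
            xi = np.take(xi, perm, axis=ax - 1)
        out[i] = xi
    return out.reshape(x.shape)


def permutation_cluster_test(
    data: np.ndarray,
    design: MixedDesign,
    effect: str,
    adjacency: sparse.spmatrix,
    n_perm: int = 1000,
    point_alpha: float = 0.05,
    seed: int = 0,
    gg_threshold: float = 0.75,
) -> ClusterTest:
    """Cluster-permutation test of one ANOVA effect over the full grid.

    Effects involving the between factor permute group labels across
    subjects (exact); pure within effects permute the involved factor
    levels within each subject (interaction nulls are approximate and rely
    on cell exchangeability).  Cluster p = (1 + #{null >= observed}) /
    (1 + n_perm), the standard finite-sample-valid estimator.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(seed)
    observed = pointwise_rm_anova(data, design, effects=[effect],
                                  gg_threshold=gg_threshold)[effect]
    clusters = form_clusters(observed, adjacency, point_alpha)

    parts = effect.split("*")
    involves_group = parts[-1] == "group" or effect == "group"
    subset = tuple(p for p in parts if p != "group")
    factors = list(design.within)
    null = np.empty(n_perm)
    n = data.shape[0]
    for r in range(n_perm):
        if involves_group:
            perm_design = MixedDesign(design.within, rng.permutation(design.groups))
            fmap = pointwise_rm_anova(data, perm_design, effects=[effect],
                                      gg_threshold=gg_threshold)[effect]
        else:
            axes = [factors.index(s) + 1 for s in subset]
            x_perm = _permute_within(
                data.reshape(n, design.n_cells, -1),
                [a for a in axes],
                design.within_shape,
                rng,
            ).reshape(data.shape)
            fmap = pointwise_rm_anova(x_perm, design, effects=[effect],
                                      gg_threshold=gg_threshold)[effect]
        null[r] = _max_cluster_mass(
            fmap.F.ravel(), fmap.p.ravel() < point_alpha, adjacency
        )
    for c in clusters:
        c.p = float((1 + np.sum(null >= c.mass)) / (1 + n_perm))
    return ClusterTest(effect=effect, clusters=clusters, null_max_mass=null, fmap=observed)


# ---------------------------------------------------------------------------
# planned contrasts and post hoc tests
# ---------------------------------------------------------------------------

def poly_contrast_weights(k: int, degree: int) -> np.ndarray:
    """Orthogonal-polynomial contrast weights for k equally spaced levels.

    Gram-Schmidt over powers of the level index; zero-sum and orthogonal to
    all lower degrees, normalized to unit length.  For k=6 these are
    proportional to the classic integer tables (linear -5..5, quadratic
    5,-1,-4,-4,-1,5).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if k < degree + 1:
        raise ValueError(f"need at least {degree + 1} levels for degree {degree}")
    x = np.arange(k, dtype=float)
    basis = np.vander(x, degree + 1, increasing=True)  # columns 1, x, x^2, ...
    q, _ = np.linalg.qr(basis)
    w = q[:, degree]
    if w[-1] < 0:  # fix sign: ascending linear weights positive at the top
        w = -w
    return w / np.linalg.norm(w)


@dataclass
class ContrastResult:
    trend: str
    F: float
    df: tuple[float, float]
    p: float
    partial_eta_sq: float
    weights: np.ndarray
    mean_score: float = 0.0  # mean contrast score (group difference when grouped)


def polynomial_contrast(
    cell_means: np.ndarray,
    degree: int,
    groups: np.ndarray | None = None,
) -> ContrastResult:
    """Linear/quadratic (or higher) trend over ordered factor levels.

    ``cell_means``: (n_subjects, k) per-subject means over the k ordered
    levels.  Without groups, the trend is tested against zero with a
    one-sample t (F = t^2, df (1, N-1)); with two groups the *difference*
    in trend between groups is tested with an independent-samples t
    (F = t^2, df (1, N-2)).
    """
    cell_means = np.asarray(cell_means, dtype=float)
    n, k = cell_means.shape
    w = poly_contrast_weights(k, degree)
    scores = cell_means @ w
    # scores that are pure float dust relative to the data level are zero
    if np.abs(scores).max() <= 1e-10 * max(1.0, np.abs(cell_means).max()):
        scores = np.zeros_like(scores)
    if groups is None:
        se = scores.std(ddof=1) / np.sqrt(n)
        t = scores.mean() / se if se > 0 else 0.0
        df = (1.0, float(n - 1))
        mean_score = float(scores.mean())
    else:
        groups = np.asarray(groups)
        levels = sorted(pd.unique(groups))
        if len(levels) != 2:
            raise ValueError("group trend comparison needs exactly 2 groups")
        res = group_ttest(scores[groups == levels[0]], scores[groups == levels[1]])
        t, df = res["t"], (1.0, res["df"])
        mean_score = float(
            scores[groups == levels[0]].mean() - scores[groups == levels[1]].mean()
        )
    f = float(t**2)
    p = float(stats.f.sf(f, *df)) if f > 0 else 1.0
    eta = f / (f + df[1]) if f > 0 else 0.0
    names = {1: "linear", 2: "quadratic", 3: "cubic"}
    return ContrastResult(trend=names.get(degree, f"degree{degree}"), F=f, df=df,
                          p=p, partial_eta_sq=float(eta), weights=w,
                          mean_score=mean_score)


def paired_ttest(x: np.ndarray, y: np.ndarray) -> dict:
    """Paired t with Cohen's d based on the difference SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired test needs two equal-length samples, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0:
        return {"t": 0.0, "df": n - 1, "p": 1.0, "d": 0.0}
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return {"t": float(t), "df": n - 1, "p": float(p), "d": float(d.mean() / sd)}


def posthoc_ttests(
    values: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Post hoc contrasts on cluster-mean activity.

    ``values``: wide table, one row per subject, one column per condition.
    Each (a, b) comparison is a paired t-test of column a vs column b; when
    ``groups`` is given, rows "a vs b" additionally compare the two groups
    on the a-b difference (independent t, Welch when flagged).
    """
    rows = []
    for a, b in comparisons:
        res = paired_ttest(values[a].to_numpy(), values[b].to_numpy())
        rows.append({"comparison": f"{a} vs {b}", "kind": "paired", **res})
        if groups is not None:
            diff = values[a].to_numpy() - values[b].to_numpy()
            levels = sorted(pd.unique(np.asarray(groups)))
            res_g = group_ttest(diff[np.asarray(groups) == levels[0]],
                                diff[np.asarray(groups) == levels[1]])
            rows.append({"comparison": f"{a} vs {b} ({levels[0]} vs {levels[1]})",
                         "kind": "independent", **res_g})
    return pd.DataFrame(rows)
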