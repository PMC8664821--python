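"""Phylogeny-corrected comparison of gene repertoires across lifestyles.

The central question — do lifestyles differ in gene-family composition
beyond what shared ancestry explains? — is answered by entering
phylogenetic principal components as covariates BEFORE the lifestyle
term in sequential (type-I) models: a PERMANOVA on quantitative Jaccard
distances, per-category count ANOVAs with Tukey post hocs, and a pair of
conditioned distance-based redundancy analyses whose ordination ellipses
and centroids feed a lifestyle similarity network.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ._ordination import gower_center, hat_matrix, matrix_rank
from .datamodel import GeneFamilyMatrix, Phylogeny

WEIGHT_CAP = 1e6  # edge weight for coincident ordination centroids


# ---------------------------------------------------------------------------
# Phylogenetic covariates
# ---------------------------------------------------------------------------

def phylogeny_pcs(tree: Phylogeny, genomes: list[str] | None = None,
                  k: int = 4) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the patristic distance matrix.

    Each genome's feature vector is its row of pairwise path-length
    distances; column-centered PCA scores of the first ``k`` components
    summarize phylogenetic position and serve as covariates downstream.
    Returns (scores, explained-variance fractions).
    """
    genomes = list(genomes) if genomes is not None else tree.tip_names
    if k >= len(genomes):
        raise ValueError("k must be smaller than the number of genomes")
    dm = tree.patristic_distances(genomes).to_numpy()
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(dm)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(scores, index=pd.Index(genomes, name="genome_id"),
                         columns=cols),
            pca.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def jaccard_distances(matrix: GeneFamilyMatrix | pd.DataFrame,
                      families: list[str] | None = None) -> pd.DataFrame:
    """Quantitative Jaccard distance between genome copy-number profiles.

    From Bray-Curtis B(x, y) = sum|x-y| / sum(x+y), the quantitative
    Jaccard extension is J = 2B / (1 + B); genome pairs whose profiles
    are both all-zero get J = 0.
    """
    counts = matrix.counts if isinstance(matrix, GeneFamilyMatrix) else matrix
    if families is not None:
        if not len(families):
            raise ValueError("empty family subset")
        counts = counts[list(families)]
    x = counts.to_numpy(float)
    if (x < 0).any():
        raise ValueError("negative counts")
    num = squareform(pdist(x, metric="cityblock"))
    sums = x.sum(axis=1)
    denom = sums[:, None] + sums[None, :]
    with np.errstate(invalid="ignore"):
        b = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    j = 2 * b / (1 + b)
    np.fill_diagonal(j, 0.0)
    return pd.DataFrame(j, index=counts.index, columns=counts.index)


# ---------------------------------------------------------------------------
# Model matrices
# ---------------------------------------------------------------------------

def _dummies(labels: pd.Series) -> pd.DataFrame:
    d = pd.get_dummies(labels, drop_first=True, dtype=float)
    d.columns = [f"{labels.name or 'group'}[{c}]" for c in d.columns]
    return d


def _model_terms(covariates: pd.DataFrame | None, labels: pd.Series | None,
                 interactions: bool) -> list[tuple[str, pd.DataFrame]]:
    """Ordered (term name, columns) pairs: PCs, then group, then PC:group."""
    terms: list[tuple[str, pd.DataFrame]] = []
    if covariates is not None:
        for col in covariates.columns:
            terms.append((col, covariates[[col]].astype(float)))
    if labels is not None:
        dum = _dummies(labels)
        terms.append((labels.name or "group", dum))
        if interactions and covariates is not None:
            for col in covariates.columns:
                inter = dum.mul(covariates[col], axis=0)
                inter.columns = [f"{col}:{c}" for c in dum.columns]
                terms.append((f"{col}:{labels.name or 'group'}", inter))
    return terms


def _sequential_projectors(terms, n):
    """Hat-matrix increments and dfs for the nested model sequence."""
    ones = np.ones((n, 1))
    x_cum = ones
    h_prev = hat_matrix(ones)
    rank_prev = 1
    out = []
    for name, cols in terms:
        x_cum = np.hstack([x_cum, cols.to_numpy(float)])
        rank = matrix_rank(x_cum)
        df = rank - rank_prev
        if df == 0:
            warnings.warn(f"term {name!r} fully aliased; dropped", stacklevel=3)
            continue
        h = hat_matrix(x_cum)
        out.append((name, h - h_prev, df))
        h_prev, rank_prev = h, rank
    return out, h_prev, rank_prev


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova(distances: pd.DataFrame, covariates: pd.DataFrame | None,
              labels: pd.Series, interactions: bool = True,
              n_perm: int = 999, seed: int = 0,
              exhaustive: bool = False) -> pd.DataFrame:
    """Sequential (type-I) PERMANOVA on a distance matrix.

    Terms enter in formula order — each phylogenetic PC, then the group
    factor, then PC:group interactions — so the group term measures
    composition differences after phylogeny.  Significance comes from
    jointly permuting rows and columns of the distance matrix; the
    observed statistic is included in numerator and denominator:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  With
    ``exhaustive=True`` all n! permutations are enumerated instead
    (feasible for n <= 8) and p is the exact fraction.

    Returns a table with one row per term plus Residual and Total
    (columns df, ss, r2, f, p).  R2 entries sum to 1.
    """
    ids = list(distances.index)
    n = len(ids)
    d = distances.to_numpy(float)
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels = labels.loc[ids]
    if covariates is not None:
        covariates = covariates.loc[ids]
    g = gower_center(d)
    terms = _model_terms(covariates, labels, interactions)
    projs, h_full, rank_full = _sequential_projectors(terms, n)
    r_proj = np.eye(n) - h_full
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("model saturates the data; no residual df")

    def term_stats(gmat):
        ss = np.array([np.sum(p * gmat) for _, p, _ in projs])
        ss_res = np.sum(r_proj * gmat)
        dfs = np.array([df for _, _, df in projs], dtype=float)
        f = (ss / dfs) / (ss_res / df_res)
        return ss, ss_res, f

    ss_obs, ss_res_obs, f_obs = term_stats(g)
    ss_total = float(np.trace(g))

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        count = np.zeros(len(projs))
        n_total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            _, _, f_perm = term_stats(g[np.ix_(idx, idx)])
            count += f_perm >= f_obs - 1e-12
            n_total += 1
        pvals = count / n_total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(projs))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, _, f_perm = term_stats(g[np.ix_(idx, idx)])
            count += f_perm >= f_obs - 1e-12
        pvals = (1.0 + count) / (1.0 + n_perm)

    rows = []
    for (name, _, df), ss, f, p in zip(projs, ss_obs, f_obs, pvals):
        rows.append((name, df, ss, ss / ss_total, f, p))
    rows.append(("Residual", df_res, ss_res_obs, ss_res_obs / ss_total,
                 np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["term", "df", "ss", "r2", "f", "p"]
                        ).set_index("term")


def pairwise_permanova(distances: pd.DataFrame,
                       covariates: pd.DataFrame | None, labels: pd.Series,
                       n_perm: int = 999, seed: int = 0,
                       adjust: str = "fdr_bh") -> pd.DataFrame:
    """PERMANOVA restricted to each pair of groups, BH-adjusted.

    Covariates are retained in each pairwise model; interactions are
    omitted (the pairwise question is a main-effect contrast).  Groups
    with fewer than 2 members are skipped with a note column.
    """
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = labels.value_counts()
    rows = []
    for a, b in itertools.combinations(groups, 2):
        if sizes.get(a, 0) < 2 or sizes.get(b, 0) < 2:
            rows.append((a, b, np.nan, np.nan, "skipped: group with < 2 members"))
            continue
        ids = labels.index[labels.isin([a, b])]
        term = labels.name or "group"
        try:
            res = permanova(distances.loc[ids, ids],
                            covariates.loc[ids] if covariates is not None
                            else None,
                            labels.loc[ids], interactions=False,
                            n_perm=n_perm, seed=seed)
        except ValueError as err:
            rows.append((a, b, np.nan, np.nan, f"skipped: {err}"))
            continue
        if term not in res.index:  # covariates saturate the tiny subset
            rows.append((a, b, np.nan, np.nan,
                         "skipped: group term aliased by covariates"))
            continue
        rows.append((a, b, res.loc[term, "f"], res.loc[term, "p"], ""))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "f", "p", "note"])
    ok = out["p"].notna()
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(out.loc[ok, "p"],
                                                  method=adjust)[1]
    return out


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Constrained ordination: site scores, inertia and group geometry."""

    site_scores: pd.DataFrame          # samples x constrained axes
    eigenvalues: np.ndarray            # non-increasing, >= 0
    dropped_negative: np.ndarray       # negative eigenvalues of the input
    total_inertia: float
    conditioned_inertia: float
    constrained_inertia: float
    centroids: pd.DataFrame | None = None      # group x first two axes
    ellipses: pd.DataFrame | None = None       # group x (area, cov entries)

    @property
    def constrained_fraction(self) -> float:
        denom = self.total_inertia - self.conditioned_inertia
        return self.constrained_inertia / denom if denom > 0 else 0.0


def _group_geometry(scores: pd.DataFrame, groups: pd.Series):
    """Centroids and 1-sd data ellipses on the first two axes.

    Ellipse area is pi * sqrt(l1 * l2) with l the eigenvalues of the 2x2
    covariance of a group's scores; single-member groups get area 0.
    """
    axes = scores.columns[:2]
    two = scores[axes].copy()
    for missing in range(len(axes), 2):
        two[f"pad{missing}"] = 0.0
    cents, ells = {}, {}
    for grp in sorted(groups.unique()):
        ids = groups.index[groups == grp].intersection(scores.index)
        pts = two.loc[ids].to_numpy()
        cents[grp] = pts.mean(axis=0)
        if len(pts) < 2:
            cov = np.zeros((2, 2))
        else:
            cov = np.cov(pts.T)
        lam = np.clip(np.linalg.eigvalsh(cov), 0, None)
        ells[grp] = {
            "area": math.pi * math.sqrt(lam[0] * lam[1]),
            "cov_11": cov[0, 0], "cov_12": cov[0, 1], "cov_22": cov[1, 1],
        }
    centroids = pd.DataFrame(cents, index=["axis1", "axis2"]).T
    ellipses = pd.DataFrame(ells).T
    centroids.index.name = ellipses.index.name = groups.name or "group"
    return centroids, ellipses


def dbrda(distances: pd.DataFrame,
          condition: pd.DataFrame | pd.Series | None,
          constraints: pd.DataFrame | pd.Series,
          groups: pd.Series | None = None) -> OrdinationResult:
    """Distance-based redundancy analysis with an optional Condition().

    The Gower-centered matrix is first residualized on the condition
    variables (projection complement on both sides), then the residual is
    projected onto the span of the (condition-residualized) constraint
    variables and eigen-decomposed.  Negative eigenvalues of the input
    geometry are dropped and reported, with no additive-constant
    correction.  Factor inputs are expanded to dummy variables.
    """
    ids = list(distances.index)
    n = len(ids)
    g = gower_center(distances.to_numpy(float))
    total = float(np.trace(g))

    def expand(v):
        if v is None:
            return None
        if isinstance(v, pd.Series):
            v = _dummies(v.loc[ids]) if v.dtype == object else v.loc[ids].to_frame()
        else:
            v = v.loc[ids]
        return v.to_numpy(float)

    w = expand(condition)
    x = expand(constraints)
    center = np.eye(n) - np.ones((n, n)) / n
    if w is not None:
        hw = hat_matrix(center @ w)
        r = np.eye(n) - hw
        g_r = r @ g @ r
        x_r = r @ (center @ x)
        conditioned = total - float(np.trace(g_r))
    else:
        g_r = center @ g @ center
        x_r = center @ x
        conditioned = 0.0
    hx = hat_matrix(x_r)
    m = hx @ g_r @ hx
    m = (m + m.T) / 2
    vals, vecs = np.linalg.eigh(m)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-9 * max(1.0, abs(vals).max() if len(vals) else 1.0)
    keep = vals > tol
    eig = vals[keep]
    scores = vecs[:, keep] * np.sqrt(eig)
    neg = vals[vals < -tol]
    cols = [f"dbRDA{i + 1}" for i in range(scores.shape[1])]
    site = pd.DataFrame(scores, index=pd.Index(ids, name=distances.index.name),
                        columns=cols)
    res = OrdinationResult(
        site_scores=site, eigenvalues=eig, dropped_negative=neg,
        total_inertia=total, conditioned_inertia=conditioned,
        constrained_inertia=float(eig.sum()))
    if groups is not None:
        if site.shape[1] == 0:
            site = pd.DataFrame(np.zeros((n, 2)), index=site.index,
                                columns=["dbRDA1", "dbRDA2"])
        res.centroids, res.ellipses = _group_geometry(site, groups.loc[ids])
    return res


# ---------------------------------------------------------------------------
# Lifestyle network
# ---------------------------------------------------------------------------

def lifestyle_network(pairwise: pd.DataFrame, ordination: OrdinationResult,
                      alpha: float = 0.05,
                      use_adjusted: bool = True) -> nx.Graph:
    """Similarity network: lifestyles connect when NOT significantly different.

    Node size is the group's ordination ellipse area; edge weight is the
    inverse Euclidean distance between group centroids on the first two
    constrained axes (capped for coincident centroids).
    """
    if ordination.centroids is None or ordination.ellipses is None:
        raise ValueError("ordination lacks group geometry; pass groups to dbrda")
    graph = nx.Graph()
    for grp, row in ordination.ellipses.iterrows():
        graph.add_node(grp, size=float(row["area"]))
    col = "p_adjusted" if use_adjusted else "p"
    for _, row in pairwise.iterrows():
        p = row[col]
        if pd.isna(p) or p < alpha:
            continue
        a, b = row["group_a"], row["group_b"]
        if a == b or a not in graph or b not in graph:
            continue
        dist = float(np.linalg.norm(ordination.centroids.loc[a]
                                    - ordination.centroids.loc[b]))
        weight = min(1.0 / dist, WEIGHT_CAP) if dist > 0 else WEIGHT_CAP
        graph.add_edge(a, b, weight=weight)
    return graph


# ---------------------------------------------------------------------------
# Category-count ANOVA with Tukey letters
# ---------------------------------------------------------------------------

def _compact_letters(groups: list[str], nonsig: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different.
    """
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all((min(g, h), max(g, h)) in nonsig for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in sorted(s):
            out[g] += letter
    return out


def category_count_anova(counts: pd.Series, covariates: pd.DataFrame | None,
                         labels: pd.Series, interactions: bool = True,
                         alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential OLS ANOVA of per-genome category counts, plus Tukey letters.

    The model is Count ~ PC1+..+PCk + Lifestyle (+ PC:Lifestyle
    interactions, dropped with a warning when there are too few genomes).
    The Tukey HSD post hoc compares covariate-adjusted lifestyle means
    using the model residual mean square; the compact-letter display
    assigns shared letters to lifestyles that do not differ at ``alpha``.
    Returns (anova table, letters table).
    """
    ids = list(counts.index)
    labels = labels.loc[ids]
    if covariates is not None:
        covariates = covariates.loc[ids]
    y = counts.to_numpy(float)
    n = len(y)

    terms = _model_terms(covariates, labels, interactions)
    n_params = 1 + sum(t[1].shape[1] for t in terms)
    if interactions and n_params >= n:
        warnings.warn("too few genomes for interactions; dropped", stacklevel=2)
        terms = _model_terms(covariates, labels, False)
    projs, h_full, rank_full = _sequential_projectors(terms, n)
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("model saturates the data")
    resid = (np.eye(n) - h_full) @ y
    ss_res = float(resid @ resid)
    mse = ss_res / df_res

    rows = []
    for name, p, df in projs:
        ss = float(y @ p @ y)
        f = (ss / df) / mse if mse > 0 else np.inf
        pval = float(stats.f.sf(f, df, df_res)) if np.isfinite(f) else 0.0
        rows.append((name, df, ss, f, pval))
    rows.append(("Residual", df_res, ss_res, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "ss", "f", "p"]
                         ).set_index("term")

    # covariate-adjusted means: remove the fitted covariate part
    if covariates is not None:
        xc = np.hstack([np.ones((n, 1)), covariates.to_numpy(float)])
        beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
        y_adj = y - xc[:, 1:] @ beta[1:]
    else:
        y_adj = y
    y_adj = pd.Series(y_adj, index=ids)
    groups = sorted(labels.unique())
    means = {g: y_adj[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    k = len(groups)
    nonsig: set[tuple[str, str]] = set()
    pair_rows = []
    for a, b in itertools.combinations(groups, 2):
        diff = means[a] - means[b]
        se = math.sqrt(mse / 2 * (1 / sizes[a] + 1 / sizes[b]))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_res))
        pair_rows.append((a, b, diff, p))
        if p >= alpha:
            nonsig.add((min(a, b), max(a, b)))
    letters = _compact_letters(groups, nonsig)
    letters_df = pd.DataFrame({
        "mean_adjusted": pd.Series(means), "n": pd.Series(sizes),
        "letters": pd.Series(letters),
    })
    letters_df.index.name = labels.name or "group"
    letters_df.attrs["tukey_pairs"] = pd.DataFrame(
        pair_rows, columns=["group_a", "group_b", "diff", "p"])
    return table, letters_df


# ---------------------------------------------------------------------------
# Discriminant loadings
# ---------------------------------------------------------------------------

def discriminant_top_loadings(matrix: GeneFamilyMatrix | pd.DataFrame,
                              labels: pd.Series, n_axes: int = 3,
                              top: int = 5) -> pd.DataFrame:
    """Top high-loading families on label-constrained ordination axes.

    Copy numbers are standardized per family (zero-variance families
    dropped), the matrix is constrained by group labels (redundancy
    analysis), and the families with the largest |loading| on each of the
    first ``n_axes`` constrained axes are reported with their sign.
    """
    counts = matrix.counts if isinstance(matrix, GeneFamilyMatrix) else matrix
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    max_axes = len(groups) - 1
    if n_axes > max_axes:
        warnings.warn(f"n_axes truncated to {max_axes} (groups - 1)",
                      stacklevel=2)
        n_axes = max_axes
    counts = counts.loc[labels.index]
    std = counts.std(axis=0, ddof=1)
    keep = std > 0
    y = (counts.loc[:, keep] - counts.loc[:, keep].mean()) / std[keep]
    yv = y.to_numpy(float)
    h = hat_matrix(np.hstack([np.ones((len(y), 1)),
                              _dummies(labels).to_numpy(float)]))
    center = np.eye(len(y)) - np.ones((len(y), len(y))) / len(y)
    yfit = h @ center @ yv
    _, s, vt = np.linalg.svd(yfit, full_matrices=False)
    rows = []
    for axis in range(min(n_axes, (s > 1e-9).sum())):
        load = pd.Series(vt[axis], index=y.columns)
        ranked = load.abs().sort_values(ascending=False).index[:top]
        for rank, fam in enumerate(ranked, start=1):
            rows.append((axis + 1, rank, fam, float(load[fam])))
    return pd.DataFrame(rows, columns=["axis", "rank", "family", "loading"])
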