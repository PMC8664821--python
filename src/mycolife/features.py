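"""Minimal discriminative gene-family discovery for a binary grouping.

Pipeline: per-family ANOVA F pre-filter at an FDR threshold, then a
linear support-vector machine with recursive feature elimination
(SVM-RFE) tracking leave-one-out accuracy, returning the smallest
feature set that achieves the best recorded accuracy.  Companion
screens: one-sided Fisher tests for annotation-category enrichment of
the selected set, and a phylogenetic-eigenvector logistic regression
that asks whether each family separates the groups independently of
phylogeny.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneFamilyMatrix, Phylogeny
from .repertoire import phylogeny_pcs


def _counts(matrix) -> pd.DataFrame:
    return matrix.counts if isinstance(matrix, GeneFamilyMatrix) else matrix


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# ANOVA pre-filter
# ---------------------------------------------------------------------------

def anova_prefilter(matrix, labels: pd.Series, fdr: float = 0.05
                    ) -> pd.DataFrame:
    """Per-family one-way F test between the two groups, BH-adjusted.

    Zero-variance families cannot be tested and are reported with a
    note.  ``direction`` is +1 for families enriched in the target
    (True) group, -1 for depleted.  ``selected`` flags q < fdr.
    """
    counts = _counts(matrix).loc[labels.index]
    y = labels.astype(bool).to_numpy()
    if y.all() or (~y).all():
        raise ValueError("both groups must be non-empty")
    x = counts.to_numpy(float)
    a, b = x[y], x[~y]
    var = x.var(axis=0)
    testable = var > 0
    fvals = np.full(x.shape[1], np.nan)
    pvals = np.full(x.shape[1], np.nan)
    f, p = stats.f_oneway(a[:, testable], b[:, testable])
    # constant-within-both-groups families with equal means yield NaN: no
    # evidence of a difference, p = 1
    p = np.where(np.isnan(p), 1.0, p)
    fvals[testable], pvals[testable] = f, p
    qvals = np.full(x.shape[1], np.nan)
    if testable.any():
        qvals[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
    out = pd.DataFrame({
        "f": fvals, "p": pvals, "q": qvals,
        "direction": np.sign(a.mean(axis=0) - b.mean(axis=0)).astype(int),
        "selected": (qvals < fdr) & testable,
        "note": np.where(testable, "", "skipped: zero variance"),
    }, index=counts.columns)
    out.index.name = "family_id"
    return out


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

@dataclass
class FeatureSelectionResult:
    """Selected families with final-model weights and the accuracy trace."""

    selected: list[str]
    coefficients: pd.Series          # signed weights of the final model
    cv_accuracy: float               # LOOCV accuracy of the final feature set
    accuracy_trace: pd.DataFrame     # n_features -> loocv accuracy per step
    direction: pd.Series             # +1 enriched / -1 depleted in target group
    seed: int


def _loocv_accuracy(x: np.ndarray, y: np.ndarray, c: float) -> float:
    correct = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        clf = SVC(kernel="linear", C=c)
        clf.fit(x[mask], y[mask])
        correct += clf.predict(x[i:i + 1])[0] == y[i]
    return correct / len(y)


def svm_rfe_select(matrix, labels: pd.Series, step: int = 10,
                   min_features: int = 10, C: float = 1.0,
                   seed: int = 0, standardize: bool = True,
                   per_fold_scaling: bool = False) -> FeatureSelectionResult:
    """Linear SVM with recursive feature elimination.

    At each step the ``step`` features with the smallest |weight| are
    dropped until ``min_features`` remain; leave-one-out accuracy is
    recorded for every intermediate feature set, and the SMALLEST set
    achieving the maximal recorded accuracy is returned (a minimal
    discriminative set).  Standardization statistics are computed on the
    full matrix by default; ``per_fold_scaling=True`` recomputes them
    inside every CV fold (leakage-free variant).
    """
    counts = _counts(matrix).loc[labels.index]
    y = labels.astype(bool).to_numpy()
    fams = np.array(counts.columns)
    x_raw = counts.to_numpy(float)
    x = _standardize(x_raw) if standardize else x_raw

    if per_fold_scaling:
        def loocv(cols):
            correct = 0
            for i in range(len(y)):
                mask = np.ones(len(y), dtype=bool)
                mask[i] = False
                tr = x_raw[np.ix_(mask, cols)]
                mu, sd = tr.mean(axis=0), tr.std(axis=0)
                sd[sd == 0] = 1.0
                clf = SVC(kernel="linear", C=C)
                clf.fit((tr - mu) / sd, y[mask])
                xte = (x_raw[i:i + 1, cols] - mu) / sd
                correct += clf.predict(xte)[0] == y[i]
            return correct / len(y)
    else:
        def loocv(cols):
            return _loocv_accuracy(x[:, cols], y, C)

    active = np.arange(len(fams))
    trace = []
    sets: dict[int, np.ndarray] = {}
    while True:
        acc = loocv(active)
        trace.append((len(active), acc))
        sets[len(active)] = active.copy()
        if len(active) <= min_features:
            break
        clf = SVC(kernel="linear", C=C)
        clf.fit(x[:, active], y)
        w = np.abs(clf.coef_).ravel()
        n_drop = min(step, len(active) - min_features)
        drop = np.argsort(w, kind="stable")[:n_drop]
        active = np.delete(active, drop)

    trace_df = pd.DataFrame(trace, columns=["n_features", "cv_accuracy"])
    best_acc = trace_df["cv_accuracy"].max()
    best_n = int(trace_df.loc[
        trace_df["cv_accuracy"] >= best_acc - 1e-12, "n_features"].min())
    chosen = sets[best_n]
    final = SVC(kernel="linear", C=C)
    final.fit(x[:, chosen], y)
    coef = pd.Series(final.coef_.ravel(), index=fams[chosen])
    mean_diff = x_raw[y][:, chosen].mean(axis=0) - x_raw[~y][:, chosen].mean(axis=0)
    return FeatureSelectionResult(
        selected=list(fams[chosen]), coefficients=coef,
        cv_accuracy=float(trace_df.set_index("n_features")
                          .loc[best_n, "cv_accuracy"]),
        accuracy_trace=trace_df,
        direction=pd.Series(np.sign(mean_diff).astype(int), index=fams[chosen]),
        seed=seed)


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentTestResult:
    table: np.ndarray        # [[sel&cat, sel&~cat], [~sel&cat, ~sel&~cat]]
    odds_ratio: float        # conditional MLE; inf for empty off-diagonal
    p: float


def fisher_category_enrichment(selected: list[str], universe: list[str],
                               annotations: pd.DataFrame,
                               category: str = "CAZyme",
                               alternative: str = "greater"
                               ) -> EnrichmentTestResult:
    """One-sided Fisher exact test for annotation enrichment.

    The 2x2 table crosses membership in the selected set with membership
    in the annotation category, over the given family universe (the
    pre-filtered set the selection was drawn from).
    """
    uni = pd.Index(universe)
    missing = uni.difference(annotations.index)
    if len(missing):
        raise ValueError(f"annotation missing for {len(missing)} families")
    in_cat = annotations.loc[uni, "category"] == category
    in_sel = uni.isin(selected)
    table = np.array([
        [int((in_sel & in_cat).sum()), int((in_sel & ~in_cat).sum())],
        [int((~in_sel & in_cat).sum()), int((~in_sel & ~in_cat).sum())],
    ])
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        orat = np.nan  # empty margin: odds ratio undefined
    elif table[0, 1] == 0 or table[1, 0] == 0:
        orat = np.inf
    elif table[0, 0] == 0 or table[1, 1] == 0:
        orat = 0.0
    else:
        orat = float(stats.contingency.odds_ratio(table).statistic)
    return EnrichmentTestResult(table=table, odds_ratio=orat, p=p)


# ---------------------------------------------------------------------------
# Phylogenetic logistic screen
# ---------------------------------------------------------------------------

def _ridge_logistic_wald(x: np.ndarray, y: np.ndarray, ridge: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Newton-fitted logistic regression with an optional ridge penalty.

    Returns (coefficients, Wald standard errors).  The ridge keeps the
    fit finite under complete separation.
    """
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(100):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        wdiag = np.clip(mu * (1 - mu), 1e-10, None)
        grad = x.T @ (y - mu) - ridge * beta
        hess = (x * wdiag[:, None]).T @ x + ridge * np.eye(p)
        delta = np.linalg.solve(hess, grad)
        beta = beta + delta
        if np.max(np.abs(delta)) < 1e-10:
            break
    eta = np.clip(x @ beta, -30, 30)
    mu = 1 / (1 + np.exp(-eta))
    wdiag = np.clip(mu * (1 - mu), 1e-10, None)
    hess = (x * wdiag[:, None]).T @ x + ridge * np.eye(p)
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


def phylo_logistic_screen(matrix, labels: pd.Series, tree: Phylogeny,
                          fdr: float = 0.05, k: int = 4,
                          ridge_fallback: float = 1e-3) -> pd.DataFrame:
    """Per-family logistic screen with phylogenetic-eigenvector correction.

    For each family, group membership is regressed on the standardized
    copy number plus the leading phylogenetic principal components; the
    Wald p-value of the count coefficient asks whether the family tracks
    the grouping beyond phylogenetic position.  This eigenvector
    adjustment approximates a penalized-likelihood phylogenetic GLM; it
    is an approximation, not an equivalent.  Complete separation falls
    back to a small ridge penalty (noted per family).
    """
    counts = _counts(matrix).loc[labels.index]
    y = labels.astype(bool).to_numpy(float)
    pcs, _ = phylogeny_pcs(tree, list(labels.index), k=k)
    z = pcs.to_numpy(float)
    n = len(y)
    base = np.hstack([np.ones((n, 1)), z])
    fams = counts.columns
    rows = []
    for fam in fams:
        v = counts[fam].to_numpy(float)
        sd = v.std()
        if sd == 0:
            rows.append((np.nan, np.nan, 0, "skipped: zero variance"))
            continue
        xf = np.hstack([base, ((v - v.mean()) / sd)[:, None]])
        note = ""
        beta, se = _ridge_logistic_wald(xf, y, 0.0)
        if not np.all(np.isfinite(se)) or np.abs(beta[-1]) > 15:
            beta, se = _ridge_logistic_wald(xf, y, ridge_fallback)
            note = "ridge fallback (separation)"
        zstat = beta[-1] / se[-1]
        p = float(2 * stats.norm.sf(abs(zstat)))
        rows.append((beta[-1], p, int(np.sign(beta[-1])), note))
    out = pd.DataFrame(rows, columns=["coef", "p", "direction", "note"],
                       index=fams)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    out.index.name = "family_id"
    return out
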