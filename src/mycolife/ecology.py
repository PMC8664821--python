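"""Prevalence, abundance and compartment-enrichment statistics.

Works on amplicon read-count surveys: per-taxon sample coverage
(prevalence above a relative-abundance threshold), mean relative
abundance, and root-versus-soil enrichment by two-sided Mann-Whitney U
tests with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AbundanceSurvey


def filter_samples(survey: AbundanceSurvey, min_reads: int = 1000
                   ) -> AbundanceSurvey:
    """Keep samples with strictly more than ``min_reads`` total reads."""
    depths = survey.depths()
    keep = depths.index[depths > min_reads]
    return survey.subset_samples(keep)


def relative_abundances(survey: AbundanceSurvey) -> pd.DataFrame:
    depths = survey.depths()
    return survey.counts.div(depths.replace(0, np.nan), axis=0).fillna(0.0)


def taxon_profiles(survey: AbundanceSurvey, compartment: str = "root",
                   positivity_threshold: float = 1e-4) -> pd.DataFrame:
    """Per-taxon coverage and mean RA in one compartment.

    A sample is positive for a taxon when its RA strictly exceeds the
    threshold (default 0.01%).  Coverage is the fraction of retained
    compartment samples that are positive; ``mean_ra_positive`` averages
    RA over positive samples only (0 when the taxon is absent), while
    ``mean_ra_all`` averages over every retained compartment sample.
    """
    samples = survey.compartment_samples(compartment)
    ra = relative_abundances(survey).loc[samples]
    positive = ra > positivity_threshold
    coverage = positive.mean(axis=0)
    n_pos = positive.sum(axis=0)
    mean_pos = ra.where(positive).sum(axis=0) / n_pos.replace(0, np.nan)
    return pd.DataFrame({
        "coverage": coverage,
        "mean_ra_positive": mean_pos.fillna(0.0),
        "mean_ra_all": ra.mean(axis=0),
    })


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both groups have <= 8 observations and
    there are no ties; normal approximation with tie correction
    otherwise.
    """
    exact = (len(x) <= 8 and len(y) <= 8
             and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def enrichment_test(survey: AbundanceSurvey, taxa: list[str] | None = None,
                    fdr: float = 0.05,
                    compartments: tuple[str, str] = ("root", "soil")
                    ) -> pd.DataFrame:
    """Root-vs-soil enrichment per taxon.

    log2FC compares compartment means of RA taken over ALL retained
    samples (zeros included), with a pseudocount of half the smallest
    nonzero compartment-mean RA to keep the ratio finite.  p-values are
    two-sided Mann-Whitney U on per-sample RA, adjusted across taxa by
    Benjamini-Hochberg; ``enriched`` flags q < fdr and positive log2FC.
    """
    a, b = compartments
    sa = survey.compartment_samples(a)
    sb = survey.compartment_samples(b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 retained samples in each compartment")
    ra = relative_abundances(survey)
    taxa = list(taxa) if taxa is not None else survey.taxa
    xa, xb = ra.loc[sa, taxa], ra.loc[sb, taxa]
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    nonzero = pd.concat([mean_a[mean_a > 0], mean_b[mean_b > 0]])
    eps = nonzero.min() / 2.0 if len(nonzero) else 1.0
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    pvals = np.array([
        1.0 if (xa[t].nunique() == 1 and xb[t].nunique() == 1
                and xa[t].iloc[0] == xb[t].iloc[0])
        else _mannwhitney_p(xa[t].to_numpy(), xb[t].to_numpy())
        for t in taxa
    ])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "log2fc": log2fc, "p": pvals, "q": qvals,
        "enriched": (qvals < fdr) & (log2fc > 0),
    }, index=pd.Index(taxa, name="taxon"))


def cumulative_abundance(survey: AbundanceSurvey, taxa: list[str],
                         compartment: str = "root") -> float:
    """Fraction of all reads in a compartment attributable to ``taxa``."""
    samples = survey.compartment_samples(compartment)
    if not samples:
        raise ValueError(f"no samples in compartment {compartment!r}")
    counts = survey.counts.loc[samples]
    total = counts.to_numpy().sum()
    if total == 0:
        return 0.0
    return float(counts[list(taxa)].to_numpy().sum() / total)
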