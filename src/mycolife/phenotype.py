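"""Plant-performance and colonization statistics for recolonization assays.

Per plate, the plant performance index (PPI) is the mean shoot fresh
weight of grown plants multiplied by the germination proportion, so
seeds that never germinated count against the treatment.  Strain effects
are standardized against mock plates (Hedges' g), classified
beneficial/neutral/detrimental by Kruskal-Wallis plus Dunn tests against
mock, and related to a qPCR colonization index by rank correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import PlatePhenotypeSet, QpcrRecords


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def plate_ppi(seeds_sown: int, plants_grown: int,
              sfw_mg: list[float]) -> dict:
    """Per-plate germination rate, mean SFW and PPI (mg).

    PPI = mean SFW of grown plants x (plants grown / seeds sown).
    Plates where nothing grew get PPI 0 with the mean flagged undefined.
    """
    if seeds_sown <= 0:
        raise ValueError("seeds_sown must be positive")
    if len(sfw_mg) != plants_grown:
        raise ValueError("number of SFW values must equal plants grown")
    gr = plants_grown / seeds_sown
    if plants_grown == 0:
        return {"gr": 0.0, "mean_sfw": np.nan, "ppi": 0.0}
    mean_sfw = float(np.mean(sfw_mg))
    return {"gr": gr, "mean_sfw": mean_sfw, "ppi": mean_sfw * gr}


def performance_table(plates: PlatePhenotypeSet) -> pd.DataFrame:
    """PPI for every plate, with strain and Pi level carried along."""
    rows = {}
    for pid, row in plates.plates.iterrows():
        entry = plate_ppi(row["seeds_sown"], row["plants_grown"], row["sfw_mg"])
        entry.update({"strain": row["strain"], "pi_level": row["pi_level"]})
        rows[pid] = entry
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "plate_id"
    return out[["strain", "pi_level", "gr", "mean_sfw", "ppi"]]


# ---------------------------------------------------------------------------
# Hedges' g
# ---------------------------------------------------------------------------

def hedges_g(treatment: np.ndarray, mock: np.ndarray) -> float:
    """Pooled-SD standardized mean difference with small-sample correction.

    g = (mean_t - mean_m) / s_pooled * J, with J = 1 - 3/(4 df - 1) and
    df = n_t + n_m - 2.  Identical zero-variance groups give 0; unequal
    means with zero pooled variance give signed infinity.
    """
    t = np.asarray(treatment, float)
    m = np.asarray(mock, float)
    if len(t) < 2 or len(m) < 2:
        raise ValueError("both groups need n >= 2")
    df = len(t) + len(m) - 2
    sp2 = ((len(t) - 1) * t.var(ddof=1) + (len(m) - 1) * m.var(ddof=1)) / df
    diff = t.mean() - m.mean()
    if sp2 == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    j = 1 - 3 / (4 * df - 1)
    return float(diff / math.sqrt(sp2) * j)


def effect_sizes(performance: pd.DataFrame, mock_label: str = "mock"
                 ) -> pd.DataFrame:
    """Hedges' g of each strain's plate PPIs versus mock, per Pi level."""
    rows = []
    for pi in sorted(performance["pi_level"].unique()):
        sub = performance[performance["pi_level"] == pi]
        mock = sub.loc[sub["strain"] == mock_label, "ppi"].to_numpy()
        for strain in sorted(sub["strain"].unique()):
            if strain == mock_label:
                continue
            t = sub.loc[sub["strain"] == strain, "ppi"].to_numpy()
            rows.append((strain, pi, hedges_g(t, mock)))
    return pd.DataFrame(rows, columns=["strain", "pi_level", "hedges_g"])


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn classification
# ---------------------------------------------------------------------------

def _dunn_vs_control(groups: dict[str, np.ndarray], control: str
                     ) -> pd.DataFrame:
    """Dunn z tests of every group against the control on pooled ranks.

    Uses tie-corrected pooled-rank variance:
    var = (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j).
    """
    names = [k for k in groups if k != control]
    all_vals = np.concatenate([groups[k] for k in groups])
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    offsets = {}
    pos = 0
    for k in groups:
        offsets[k] = ranks[pos:pos + len(groups[k])]
        pos += len(groups[k])
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12 - tie_term
    rows = []
    rbar_c = offsets[control].mean()
    for k in names:
        rbar = offsets[k].mean()
        var = base_var * (1 / len(groups[k]) + 1 / len(groups[control]))
        z = (rbar - rbar_c) / math.sqrt(var) if var > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append((k, z, p))
    return pd.DataFrame(rows, columns=["strain", "z", "p"])


def classify_effects(performance: pd.DataFrame, mock_label: str = "mock",
                     alpha: float = 0.05, adjust: str = "holm",
                     pi_level: str | None = None) -> pd.DataFrame:
    """Classify strains as beneficial / neutral / detrimental.

    A global Kruskal-Wallis across all strains (mock included) is
    followed by Dunn z tests of each strain against mock with
    tie-corrected pooled ranks, adjusted (Holm by default) over the
    strain-vs-mock family.  A strain is detrimental when its adjusted p
    < alpha and its median plate PPI lies below mock, beneficial when
    above; otherwise neutral.
    """
    perf = performance
    if pi_level is not None:
        perf = perf[perf["pi_level"] == pi_level]
    groups = {s: perf.loc[perf["strain"] == s, "ppi"].to_numpy()
              for s in sorted(perf["strain"].unique())}
    if mock_label not in groups:
        raise ValueError(f"no {mock_label!r} plates present")
    vals = list(groups.values())
    if len({v for g in vals for v in g}) == 1:
        out = pd.DataFrame({
            "strain": [s for s in groups if s != mock_label]})
        out["z"] = 0.0
        out["p"] = 1.0
        out["p_adjusted"] = 1.0
        out["classification"] = "neutral"
        out.attrs["kruskal_p"] = 1.0
        return out
    kw = stats.kruskal(*vals)
    dunn = _dunn_vs_control(groups, mock_label)
    dunn["p_adjusted"] = multipletests(dunn["p"], method=adjust)[1]
    mock_median = np.median(groups[mock_label])
    cls = []
    for _, row in dunn.iterrows():
        med = np.median(groups[row["strain"]])
        if row["p_adjusted"] < alpha and med < mock_median:
            cls.append("detrimental")
        elif row["p_adjusted"] < alpha and med > mock_median:
            cls.append("beneficial")
        else:
            cls.append("neutral")
    dunn["classification"] = cls
    dunn.attrs["kruskal_p"] = float(kw.pvalue)
    return dunn


# ---------------------------------------------------------------------------
# Colonization index
# ---------------------------------------------------------------------------

def colonization_index(cq_its1: float, cq_ubq10: float) -> float:
    """Index = 2^(-Cq(ITS1) / Cq(UBQ10)); higher means more fungal template."""
    if cq_its1 <= 0 or cq_ubq10 <= 0:
        raise ValueError("Cq values must be positive")
    return float(2.0 ** (-cq_its1 / cq_ubq10))


def colonization_table(qpcr: QpcrRecords) -> pd.DataFrame:
    """Per-sample colonization index with strain carried along."""
    df = qpcr.records.copy()
    df["index"] = [colonization_index(a, b)
                   for a, b in zip(df["cq_its1"], df["cq_ubq10"])]
    return df


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    note: str = ""


def correlate_metrics(x: pd.Series, y: pd.Series) -> CorrelationResult:
    """Spearman rank correlation of two per-strain metrics.

    Ties are handled by average ranks.  For n <= 9 the p-value is
    computed by exhaustive enumeration of rank permutations (two-sided);
    larger samples use the t approximation.  Constant inputs leave rho
    undefined (flagged).
    """
    common = x.index.intersection(y.index)
    if len(common) < 4:
        raise ValueError("need at least 4 paired observations")
    a = x.loc[common].to_numpy(float)
    b = y.loc[common].to_numpy(float)
    n = len(common)
    if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
        return CorrelationResult(np.nan, np.nan, n, "constant input")
    rho = float(stats.spearmanr(a, b).statistic)
    if n <= 9:
        # exact permutation null: only the cross-product varies with the
        # permutation, so enumerate it vectorized
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        ra_c = ra - ra.mean()
        rb_c = rb - rb.mean()
        denom = math.sqrt((ra_c ** 2).sum() * (rb_c ** 2).sum())
        obs = abs(ra_c @ rb_c)
        perms = np.array(list(itertools.permutations(rb_c)))
        cross = np.abs(perms @ ra_c)
        p = float(np.mean(cross >= obs - 1e-9 * denom))
    else:
        p = float(stats.spearmanr(a, b).pvalue)
    return CorrelationResult(rho, float(p), n)
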