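"""Cross-strain comparison of in-planta induction at orthogroup level.

Per-gene differential-expression results (log2 fold-change with adjusted
p-values, estimated upstream) are aggregated to orthogroups by summing
the log2FC of significant genes, so strains with different gene
complements become comparable.  The shared core of orthogroups
over-expressed by every strain is the headline statistic; Bray-Curtis
principal-coordinate analysis compares whole expression profiles.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._ordination import gower_center, pcoa_from_gower
from .datamodel import DETable


def rpkm(counts: pd.DataFrame, gene_lengths_bp: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    RPKM = count * 1e9 / (library size * length).  Library sizes default
    to per-sample column sums of the count matrix.
    """
    lengths = gene_lengths_bp.loc[counts.index].to_numpy(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    libs = library_sizes.loc[counts.columns].to_numpy(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e9 / (libs[None, :] * lengths[:, None])


def orthogroup_log2fc(table: DETable, alpha: float = 0.05,
                      positive_only: bool = False) -> pd.DataFrame:
    """Sum significant per-gene log2FC within each orthogroup.

    Genes with padj < alpha contribute their log2FC (both signs by
    default; ``positive_only=True`` restricts to positive values).  An
    orthogroup counts as over-expressed when the sum is > 0.  Unmapped
    genes are skipped; their count is stored in ``attrs['n_unmapped']``.
    """
    genes = table.genes
    mapped = genes.index.intersection(table.gene_map.index)
    n_unmapped = len(genes) - len(mapped)
    sig = genes.loc[mapped]
    sig = sig[sig["padj"] < alpha]
    if positive_only:
        sig = sig[sig["log2fc"] > 0]
    og = table.gene_map.loc[sig.index]
    summed = sig["log2fc"].groupby(og).sum()
    out = pd.DataFrame({"sum_log2fc": summed})
    out["overexpressed"] = out["sum_log2fc"] > 0
    out.index.name = "orthogroup"
    out.attrs["n_unmapped"] = n_unmapped
    out.attrs["strain"] = table.strain
    return out


def core_overexpressed(profiles: dict[str, pd.DataFrame]
                       ) -> tuple[list[str], pd.DataFrame]:
    """Orthogroups over-expressed by every strain, plus Venn-style counts.

    Returns the sorted intersection and a table of exact combination
    counts (one row per non-empty strain combination, partitioning the
    union of per-strain over-expressed sets).
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 strains")
    sets = {s: set(p.index[p["overexpressed"]]) for s, p in profiles.items()}
    strains = sorted(sets)
    core = set.intersection(*sets.values())
    union = set.union(*sets.values())
    membership = {og: frozenset(s for s in strains if og in sets[s])
                  for og in union}
    rows = []
    for r in range(1, len(strains) + 1):
        for combo in itertools.combinations(strains, r):
            n = sum(1 for m in membership.values() if m == frozenset(combo))
            if n:
                rows.append(("+".join(combo), r, n))
    counts = pd.DataFrame(rows, columns=["combination", "n_strains", "n"])
    return sorted(core), counts


def bray_curtis_pcoa(counts: pd.DataFrame
                     ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Classical PCoA of Bray-Curtis distances between sample profiles.

    Returns (coordinates, positive eigenvalues, dropped negative
    eigenvalues).  Uses the shared Gower-centering backing the other
    distance-based ordinations.
    """
    if counts.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    x = counts.to_numpy(float)
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample profile")
    num = squareform(pdist(x, metric="cityblock"))
    sums = x.sum(axis=1)
    d = num / (sums[:, None] + sums[None, :])
    np.fill_diagonal(d, 0.0)
    coords, eig, neg = pcoa_from_gower(gower_center(d))
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=counts.index, columns=cols), eig, neg)
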