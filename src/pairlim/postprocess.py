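"""Effect sizes, significance filtering and clustering of pair results.

The effect size for a gene-metabolite pair is the difference in Spearman rank
correlation between the two phenotype groups, ``delta_r = r_group1 -
r_group0``: a pair strongly correlated in one group and not (or oppositely)
in the other has a large |delta_r|. Significant pairs (BH-adjusted
interaction p below a cutoff AND |delta_r| above a cutoff, both strict) are
hierarchically clustered on their two-group correlation signature
(Euclidean distance, complete linkage), which typically separates pairs
correlated in group 1 from pairs anti-correlated in group 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import DomainError
from .io import MultiOmicsDataset
from .results import PairResultTable

#: Minimum paired observations per group for a defined Spearman correlation.
MIN_GROUP_OBS = 3


@dataclass
class EffectSize:
    """Per-group Spearman correlations and their difference."""

    r_group0: float
    r_group1: float

    @property
    def delta_r(self) -> float:
        return self.r_group1 - self.r_group0


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman r on pairwise-complete observations; NaN when undefined."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < MIN_GROUP_OBS:
        return np.nan
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return np.nan
    return float(stats.spearmanr(xs, ys).statistic)


def spearman_by_group(
    gene_values: np.ndarray,
    metabolite_values: np.ndarray,
    encoding: np.ndarray,
) -> EffectSize:
    """Within-group Spearman correlations for one pair.

    ``encoding`` is the 0/1 phenotype vector. Each group's r uses average
    ranks (ties get the mean of their rank range) on pairwise-complete
    observations; fewer than 3 observations or a constant vector yields NaN
    for that group, and then for delta_r.
    """
    g = np.asarray(gene_values, dtype=float)
    m = np.asarray(metabolite_values, dtype=float)
    enc = np.asarray(encoding)
    r0 = _spearman(g[enc == 0], m[enc == 0])
    r1 = _spearman(g[enc == 1], m[enc == 1])
    return EffectSize(r_group0=r0, r_group1=r1)


def _rank_z(block: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and L2-normalized; constant rows NaN."""
    ranks = stats.rankdata(block, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = ranks / norm[:, None]
    z[norm == 0] = np.nan
    return z

def spearman_matrix(genes: np.ndarray, metabolites: np.ndarray) -> np.ndarray:
    """All-pairs Spearman correlation between row sets sharing columns.

    Complete rows go through a vectorized rank-then-inner-product path
    (Spearman r is the Pearson correlation of average ranks); rows with
    missing values fall back to per-pair pairwise-complete computation.
    """
    genes = np.asarray(genes, dtype=float)
    metabolites = np.asarray(metabolites, dtype=float)
    n = genes.shape[1]
    out = np.full((genes.shape[0], metabolites.shape[0]), np.nan)
    if n < MIN_GROUP_OBS:
        return out
    g_ok = ~np.isnan(genes).any(axis=1)
    m_ok = ~np.isnan(metabolites).any(axis=1)
    if g_ok.any() and m_ok.any():
        zg = _rank_z(genes[g_ok])
        zm = _rank_z(metabolites[m_ok])
        out[np.ix_(g_ok, m_ok)] = zg @ zm.T
    for i in np.flatnonzero(~g_ok):
        for j in range(metabolites.shape[0]):
            out[i, j] = _spearman(genes[i], metabolites[j])
    for j in np.flatnonzero(~m_ok):
        for i in np.flatnonzero(g_ok):
            out[i, j] = _spearman(genes[i], metabolites[j])
    return out


def spearman_matrices_by_group(
    dataset: MultiOmicsDataset,
) -> tuple[np.ndarray, np.ndarray]:
    """(r_group0, r_group1) matrices of shape (n_genes, n_metabolites)."""
    enc = dataset.phenotype_vector()
    out = []
    for grp in (0, 1):
        cols = enc == grp
        out.append(
            spearman_matrix(dataset.genes.values[:, cols], dataset.metabolites.values[:, cols])
        )
    return out[0], out[1]


def filter_pairs(
    results: PairResultTable,
    fdr_cutoff: float = 0.10,
    min_abs_delta_r: float = 0.5,
) -> PairResultTable:
    """Keep pairs with fdr_p < fdr_cutoff AND |delta_r| > min_abs_delta_r.

    Both inequalities are strict; rows with missing fdr_p or delta_r are
    excluded.
    """
    if not 0 < fdr_cutoff <= 1:
        raise DomainError(f"fdr_cutoff must be in (0, 1], got {fdr_cutoff}")
    if not 0 <= min_abs_delta_r <= 2:
        raise DomainError(
            f"min_abs_delta_r must be in [0, 2], got {min_abs_delta_r}"
        )
    df = results.df
    fdr = df["fdr_p"].to_numpy(dtype=float)
    dr = df["delta_r"].to_numpy(dtype=float)
    keep = (fdr < fdr_cutoff) & (np.abs(dr) > min_abs_delta_r)
    keep &= ~np.isnan(fdr) & ~np.isnan(dr)
    return PairResultTable(df.loc[keep].reset_index(drop=True))


@dataclass
class ClusterResult:
    """Hierarchical clustering of pairs over their (r_group0, r_group1) signature."""

    pairs: pd.DataFrame  # columns gene, metabolite, r_group0, r_group1
    labels: np.ndarray  # one cluster label per pair row
    linkage: np.ndarray | None  # scipy linkage matrix, None when < 2 pairs
    leaf_order: np.ndarray  # dendrogram leaf order (indices into pairs)
    n_excluded_missing: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def signature_matrix(self) -> np.ndarray:
        return self.pairs[["r_group0", "r_group1"]].to_numpy(dtype=float)

    def cluster_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def as_frame(self) -> pd.DataFrame:
        out = self.pairs.copy()
        out["cluster"] = self.labels
        out["leaf_position"] = np.argsort(self.leaf_order)
        return out


def cluster_pairs(filtered: PairResultTable, k: int = 2) -> ClusterResult:
    """Complete-linkage agglomeration of pairs on (r_group0, r_group1).

    Euclidean distance over the 2-column correlation signature; cluster
    labels come from cutting the dendrogram into ``k`` clusters (k is capped
    at the number of pairs). Pairs with a missing correlation are excluded
    and counted.
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    df = filtered.df
    sig = df[["r_group0", "r_group1"]].to_numpy(dtype=float)
    ok = ~np.isnan(sig).any(axis=1)
    n_excluded = int((~ok).sum())
    pairs = (
        df.loc[ok, ["gene", "metabolite", "r_group0", "r_group1"]]
        .astype({"gene": str, "metabolite": str})
        .reset_index(drop=True)
    )
    n = len(pairs)
    if n == 0:
        return ClusterResult(
            pairs, np.array([], dtype=int), None, np.array([], dtype=int), n_excluded
        )
    if n == 1:
        return ClusterResult(
            pairs, np.array([1]), None, np.array([0]), n_excluded
        )
    z = hierarchy.linkage(
        pairs[["r_group0", "r_group1"]].to_numpy(dtype=float),
        method="complete",
        metric="euclidean",
    )
    labels = hierarchy.fcluster(z, t=min(k, n), criterion="maxclust")
    leaves = hierarchy.leaves_list(z)
    return ClusterResult(pairs, labels, z, leaves, n_excluded)


def volcano_data(results: PairResultTable) -> pd.DataFrame:
    """Per-pair (delta_r, -log10 fdr_p) for a volcano plot.

    Adjusted p-values of exactly 0 are clamped to the smallest positive
    float before the log and flagged in the ``clamped`` column.
    """
    df = results.df
    fdr = df["fdr_p"].to_numpy(dtype=float)
    clamped = fdr == 0
    tiny = np.finfo(float).tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        y = -np.log10(np.where(clamped, tiny, fdr))
    return pd.DataFrame(
        {
            "gene": df["gene"].astype(str).to_numpy(),
            "metabolite": df["metabolite"].astype(str).to_numpy(),
            "delta_r": df["delta_r"].to_numpy(dtype=float),
            "minus_log10_fdr_p": y,
            "clamped": clamped,
        }
    )


def pair_scatter_data(
    dataset: MultiOmicsDataset, gene: str, metabolite: str
) -> tuple[pd.DataFrame, int]:
    """Per-sample (gene, metabolite, phenotype) triples for one pair.

    Returns the triples with missing metabolite values omitted, plus the
    count of omitted samples. Unknown IDs raise a lookup error naming them.
    """
    g = dataset.genes.feature_values(gene)
    m = dataset.metabolites.feature_values(metabolite)
    pheno = dataset.metadata.phenotype().astype(str).to_numpy()
    ok = ~np.isnan(m) & ~np.isnan(g)
    n_missing = int((~ok).sum())
    out = pd.DataFrame(
        {
            "sample_id": np.asarray(dataset.sample_ids)[ok],
            "gene_value": g[ok],
            "metabolite_value": m[ok],
            "phenotype": pheno[ok],
        }
    )
    return out, n_missing
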