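"""All-pairs gene-metabolite interaction linear models.

For every (gene, metabolite) pair the model

    m = b1 + b2*g + b3*p + b4*(g x p) + e,    e ~ N(0, sigma)

is fit by ordinary least squares, where m and g are the log2 metabolite and
gene levels and p is the 0/1-encoded phenotype. The interaction coefficient
b4 measures how the gene->metabolite slope differs between the two phenotype
groups; its two-tailed t-test is the core inference, and its p-values are
corrected across all pairs with the Benjamini-Hochberg step-up procedure.

The solver iterates over genes: each gene's design matrix is factored once
(thin SVD) and solved simultaneously against every metabolite as a
multi-right-hand-side least-squares problem, which makes millions of models
tractable in seconds without changing the per-pair answer. An independent
single-model path, :func:`interaction_pvalue_reference`, exists for audit
and as the fallback when per-pair missing data forces a pair-specific
design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ValidationError
from .io import MultiOmicsDataset
from .postprocess import spearman_matrices_by_group
from .results import PairResultTable

logger = logging.getLogger(__name__)

#: Relative condition cutoff below which the design is declared rank-deficient.
RANK_RCOND = 1e-10

#: Relative tolerance declaring a residual sum of squares "exactly zero".
ZERO_RESID_RTOL = 1e-12

FLAG_OK = ""
FLAG_DEGENERATE = "degenerate"
FLAG_ZERO_RESIDUAL = "zero_residual"
FLAG_INSUFFICIENT = "insufficient_samples"
_FLAG_CODES = [FLAG_OK, FLAG_DEGENERATE, FLAG_ZERO_RESIDUAL, FLAG_INSUFFICIENT]


@dataclass
class ModelSpec:
    """Model configuration: covariates and the minimum per-group sample count.

    Covariates are sample-metadata column names appended to the design as
    main effects only (no covariate x gene interactions).
    """

    covariates: list = field(default_factory=list)
    min_group_size: int = 4


@dataclass
class PairFit:
    """OLS fit of one pair's 4(+covariate)-column design."""

    betas: np.ndarray  # (intercept, gene, phenotype, interaction, covariates...)
    se4: float
    t4: float
    df: int
    p_interaction: float
    n_used: int
    flag: str = FLAG_OK

    @property
    def beta1(self) -> float:
        return float(self.betas[0])

    @property
    def beta2(self) -> float:
        return float(self.betas[1])

    @property
    def beta3(self) -> float:
        return float(self.betas[2])

    @property
    def beta4(self) -> float:
        return float(self.betas[3])


def _degenerate_fit(k: int, n_used: int, flag: str) -> PairFit:
    return PairFit(
        betas=np.full(k, np.nan),
        se4=np.nan,
        t4=np.nan,
        df=max(n_used - k, 0),
        p_interaction=np.nan,
        n_used=n_used,
        flag=flag,
    )


def interaction_pvalue_reference(
    design: np.ndarray, response: np.ndarray, interaction_index: int = 3
) -> PairFit:
    """Single-model least-squares fit; the slow-path oracle.

    Solves one OLS problem with a generic least-squares routine and computes
    the interaction t-test from the pseudo-inverse of the normal equations.
    Kept deliberately independent of the batch solver so the two can be
    cross-checked.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if n <= k:
        return _degenerate_fit(k, n, FLAG_INSUFFICIENT)
    betas, _, rank, _ = np.linalg.lstsq(X, y, rcond=RANK_RCOND)
    if rank < k:
        return _degenerate_fit(k, n, FLAG_DEGENERATE)
    resid = y - X @ betas
    ssr = float(resid @ resid)
    df = n - k
    xtx_inv = np.linalg.pinv(X.T @ X)
    d = float(xtx_inv[interaction_index, interaction_index])
    tss = float(y @ y)
    if ssr <= ZERO_RESID_RTOL * max(tss, 1.0):
        return PairFit(betas, 0.0, np.nan, df, np.nan, n, FLAG_ZERO_RESIDUAL)
    sigma2 = ssr / df
    se4 = float(np.sqrt(sigma2 * d))
    t4 = float(betas[interaction_index] / se4)
    p = float(2.0 * stats.t.sf(abs(t4), df))
    return PairFit(betas, se4, t4, df, p, n, FLAG_OK)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are excluded from the family size m and returned as NaN.
    Values outside [0, 1] raise a domain error.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _build_design(
    g: np.ndarray, p: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    cols = [np.ones_like(g), g, p.astype(float), g * p]
    if covariates is not None:
        cols.extend(covariates.T)
    return np.column_stack(cols)


def _covariate_matrix(dataset: MultiOmicsDataset, spec: ModelSpec) -> np.ndarray | None:
    if not spec.covariates:
        return None
    missing = [c for c in spec.covariates if c not in dataset.metadata.table.columns]
    if missing:
        raise ValidationError(f"covariate columns not in metadata: {missing}")
    cov = dataset.metadata.table[spec.covariates].to_numpy(dtype=float)
    if np.isnan(cov).any():
        raise ValidationError("covariates contain missing values")
    return cov


def fit_all_pairs(
    dataset: MultiOmicsDataset,
    spec: ModelSpec | None = None,
    compute_effect_sizes: bool = True,
    progress_every: int | None = None,
) -> PairResultTable:
    """Fit the interaction model for every gene x metabolite pair.

    Returns a :class:`PairResultTable` with exactly
    ``n_genes * n_metabolites`` rows, including BH-adjusted p-values and
    (unless ``compute_effect_sizes=False``) per-group Spearman correlations
    and delta_r. Pairs whose design cannot be fit (constant gene, too few
    complete cases, zero residual variance) are flagged with missing
    statistics rather than fabricated numbers.

    Missing metabolite values are handled per pair by complete-case
    analysis: metabolites fully observed for a gene's retained samples share
    one batched solve; the rest fall back to the single-model reference
    path.
    """
    spec = spec or ModelSpec()
    p = dataset.phenotype_vector()
    n0 = int((p == 0).sum())
    n1 = int((p == 1).sum())
    if min(n0, n1) < spec.min_group_size:
        raise ValidationError(
            f"phenotype groups have {n0} and {n1} samples; "
            f"minimum {spec.min_group_size} per group required"
        )
    cov = _covariate_matrix(dataset, spec)
    k = 4 + (0 if cov is None else cov.shape[1])

    G = dataset.genes.values
    M = dataset.metabolites.values
    ng, nm = G.shape[0], M.shape[0]

    betas = np.full((4, ng, nm), np.nan)
    se4 = np.full((ng, nm), np.nan)
    t4 = np.full((ng, nm), np.nan)
    dfree = np.zeros((ng, nm), dtype=np.int32)
    pval = np.full((ng, nm), np.nan)
    n_used = np.zeros((ng, nm), dtype=np.int32)
    flags = np.zeros((ng, nm), dtype=np.int8)

    met_has_nan = np.isnan(M).any(axis=1)

    for i in range(ng):
        if progress_every and i and i % progress_every == 0:
            logger.info("fit_all_pairs: %d/%d genes", i, ng)
        g = G[i]
        rows = ~np.isnan(g)
        _fit_gene(
            g, p, cov, M, rows, met_has_nan, k,
            betas[:, i], se4[i], t4[i], dfree[i], pval[i], n_used[i], flags[i],
        )

    pval_flat = pval.ravel()
    fdr = adjust_fdr(pval_flat)

    if compute_effect_sizes:
        r0, r1 = spearman_matrices_by_group(dataset)
    else:
        r0 = np.full((ng, nm), np.nan)
        r1 = np.full((ng, nm), np.nan)

    gene_codes = np.repeat(np.arange(ng, dtype=np.int32), nm)
    met_codes = np.tile(np.arange(nm, dtype=np.int32), ng)
    df_out = pd.DataFrame(
        {
            "gene": pd.Categorical.from_codes(gene_codes, categories=dataset.genes.feature_ids),
            "metabolite": pd.Categorical.from_codes(
                met_codes, categories=dataset.metabolites.feature_ids
            ),
            "beta1": betas[0].ravel(),
            "beta2": betas[1].ravel(),
            "beta3": betas[2].ravel(),
            "beta4": betas[3].ravel(),
            "se_interaction": se4.ravel(),
            "t_interaction": t4.ravel(),
            "p_interaction": pval_flat,
            "fdr_p": fdr,
            "r_group0": r0.ravel(),
            "r_group1": r1.ravel(),
            "delta_r": (r1 - r0).ravel(),
            "df": dfree.ravel(),
            "n_used": n_used.ravel(),
            "flag": pd.Categorical.from_codes(flags.ravel(), categories=_FLAG_CODES),
        }
    )
    n_flagged = int((flags != 0).sum())
    if n_flagged:
        logger.info("fit_all_pairs: %d of %d pairs flagged", n_flagged, ng * nm)
    return PairResultTable(df_out)


def _fit_gene(g, p, cov, M, rows, met_has_nan, k, betas, se4, t4, dfree, pval, n_used, flags):
    """Fit one gene against all metabolites, writing into row views."""
    nm = M.shape[0]
    n_rows = int(rows.sum())
    gene_all_rows = bool(rows.all())

    batch = ~met_has_nan if gene_all_rows else ~np.isnan(M[:, rows]).any(axis=1)
    loop = np.flatnonzero(~batch)
    batch_idx = np.flatnonzero(batch)

    if batch_idx.size:
        _fit_batch(
            g[rows], p[rows], None if cov is None else cov[rows], M[np.ix_(batch_idx, rows)],
            k, n_rows, batch_idx, betas, se4, t4, dfree, pval, n_used, flags,
        )

    for j in loop:
        m = M[j]
        sub = rows & ~np.isnan(m)
        nj = int(sub.sum())
        n_used[j] = nj
        psub = p[sub]
        if nj < k + 2 or (psub == 0).sum() == 0 or (psub == 1).sum() == 0:
            flags[j] = _FLAG_CODES.index(FLAG_INSUFFICIENT)
            dfree[j] = max(nj - k, 0)
            continue
        X = _build_design(g[sub], psub, None if cov is None else cov[sub])
        fit = interaction_pvalue_reference(X, m[sub])
        betas[:, j] = fit.betas[:4]
        se4[j] = fit.se4
        t4[j] = fit.t4
        dfree[j] = fit.df
        pval[j] = fit.p_interaction
        flags[j] = _FLAG_CODES.index(fit.flag)
        if fit.flag in (FLAG_DEGENERATE, FLAG_INSUFFICIENT):
            betas[:, j] = np.nan
            se4[j] = np.nan


def _fit_batch(g, p, cov, Y, k, n, met_idx, betas, se4, t4, dfree, pval, n_used, flags):
    """One SVD of the gene's design, solved against all complete metabolites."""
    n_used[met_idx] = n
    df = n - k
    dfree[met_idx] = max(df, 0)
    if n < k + 2 or (p == 0).sum() == 0 or (p == 1).sum() == 0:
        flags[met_idx] = _FLAG_CODES.index(FLAG_INSUFFICIENT)
        return
    X = _build_design(g, p, cov)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < RANK_RCOND:
        flags[met_idx] = _FLAG_CODES.index(FLAG_DEGENERATE)
        return
    Yt = Y.T  # n x K
    B = (Vt.T / s) @ (U.T @ Yt)  # k x K coefficient matrix
    resid = Yt - X @ B
    ssr = np.einsum("ij,ij->j", resid, resid)
    tss = np.einsum("ij,ij->j", Yt, Yt)
    # diagonal element of (X'X)^-1 for the interaction column
    d_int = float(np.sum((Vt[:, 3] / s) ** 2))

    betas[:, met_idx] = B[:4]
    zero = ssr <= ZERO_RESID_RTOL * np.maximum(tss, 1.0)
    sigma2 = ssr / df
    se = np.sqrt(sigma2 * d_int)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[3] / se
    pv = 2.0 * stats.t.sf(np.abs(t), df)

    se[zero] = 0.0
    t[zero] = np.nan
    pv[zero] = np.nan
    flags[met_idx[zero]] = _FLAG_CODES.index(FLAG_ZERO_RESIDUAL)

    se4[met_idx] = se
    t4[met_idx] = t
    pval[met_idx] = pv
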