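"""Preprocessing filters for omics matrices.

Implements the standard cleanup chain for array-based transcriptomics and
Metabolon-style metabolomics before pairwise modeling:

* coefficient-of-variation (CV) filtering of metabolites across technical
  replicates (a consistency filter),
* log2 transform and technical-replicate averaging,
* post-hoc detection of minimum-imputed values (metabolomics pipelines
  commonly impute a metabolite's missing values by its observed minimum, so
  the number of samples sitting exactly at the minimum, minus the one true
  minimum, estimates the imputed count),
* removal of metabolites with a high imputed fraction,
* collapse of many-to-one microarray probes to one probe per gene (highest
  mean expression), and
* removal of the lowest-expressing fraction of genes.

Every filter is a pure row-subset operation: surviving rows are identical to
their input rows, and each stage returns a :class:`FilterReport` with
conserved counts (in = removed + out).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, MappingError, ValidationError
from .io import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReplicateMap:
    """biological sample ID -> list of technical replicate column IDs."""

    groups: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for bio, cols in self.groups.items():
            if len(cols) < 1:
                raise ValidationError(f"replicate group {bio!r} is empty")
            for c in cols:
                if c in seen:
                    raise ValidationError(
                        f"replicate column {c!r} assigned to both "
                        f"{seen[c]!r} and {bio!r}"
                    )
                seen[c] = bio

    def check_against(self, matrix: OmicsMatrix) -> None:
        cols = set(matrix.sample_ids)
        missing = [
            c for reps in self.groups.values() for c in reps if c not in cols
        ]
        if missing:
            raise MappingError(f"replicate columns absent from matrix: {missing}")

    @classmethod
    def from_csv(cls, path) -> "ReplicateMap":
        df = pd.read_csv(path, dtype=str)
        if not {"biological_sample", "replicate_column"} <= set(df.columns):
            raise ValidationError(
                "replicate map CSV needs columns biological_sample, replicate_column"
            )
        groups: dict[str, list[str]] = {}
        for bio, col in zip(df["biological_sample"], df["replicate_column"]):
            groups.setdefault(bio, []).append(col)
        return cls(groups)


@dataclass
class ProbeGeneMap:
    """probe ID -> gene symbol (many probes may map to one gene)."""

    mapping: Mapping[str, str]

    @classmethod
    def from_csv(cls, path) -> "ProbeGeneMap":
        df = pd.read_csv(path, dtype=str)
        if not {"probe_id", "gene_symbol"} <= set(df.columns):
            raise ValidationError(
                "probe map CSV needs columns probe_id, gene_symbol"
            )
        df = df.dropna(subset=["gene_symbol"])
        if df["probe_id"].duplicated().any():
            dups = sorted(df.loc[df["probe_id"].duplicated(), "probe_id"].unique())
            raise ValidationError(f"probe IDs mapped more than once: {dups}")
        return cls(dict(zip(df["probe_id"], df["gene_symbol"])))


@dataclass
class FilterReport:
    stage: str
    n_in: int
    n_removed: int
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.n_removed < 0 or self.n_removed > self.n_in:
            raise ValidationError(
                f"{self.stage}: removed {self.n_removed} of {self.n_in}"
            )

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_in": self.n_in,
            "n_removed": self.n_removed,
            "n_out": self.n_out,
            "threshold": self.threshold,
        }


def median_replicate_cv(matrix: OmicsMatrix, replicates: ReplicateMap) -> pd.Series:
    """Per-feature median CV (sd/mean, sample sd) across replicate groups.

    CV is computed within each biological sample's replicate columns on the
    raw (pre-log) scale, missing values excluded; groups with fewer than two
    non-missing replicates or a zero mean contribute no CV. Features with no
    defined CV in any group get NaN.
    """
    replicates.check_against(matrix)
    col_idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    cvs = np.full((matrix.n_features, len(replicates.groups)), np.nan)
    for j, (bio, reps) in enumerate(replicates.groups.items()):
        block = matrix.values[:, [col_idx[c] for c in reps]]
        n_obs = np.sum(~np.isnan(block), axis=1)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(np.where(np.isnan(block), np.nan, block), axis=1)
            sd = np.nanstd(block, axis=1, ddof=1)
        ok = (n_obs >= 2) & (mean != 0) & ~np.isnan(mean)
        n_zero_mean = int(np.sum((n_obs >= 2) & (mean == 0)))
        if n_zero_mean:
            logger.warning(
                "median_replicate_cv: %d zero-mean replicate group(s) for "
                "biological sample %r excluded",
                n_zero_mean,
                bio,
            )
        cvs[ok, j] = sd[ok] / mean[ok]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(cvs, axis=1)
    return pd.Series(med, index=matrix.feature_ids)


def filter_metabolites_by_cv(
    matrix: OmicsMatrix,
    replicates: ReplicateMap,
    cv_threshold: float = 0.3,
    remove_high: bool = True,
) -> tuple[OmicsMatrix, FilterReport]:
    """Remove metabolites whose median replicate CV crosses the threshold.

    With ``remove_high`` (default), metabolites with median CV >= threshold
    are removed — the consistency-filter reading. ``remove_high=False``
    inverts the comparison (remove CV < threshold). Metabolites whose CV is
    undefined everywhere are retained with a warning.
    """
    med = median_replicate_cv(matrix, replicates)
    n_undef = int(med.isna().sum())
    if n_undef:
        logger.warning(
            "filter_metabolites_by_cv: %d feature(s) with undefined CV retained",
            n_undef,
        )
    if remove_high:
        remove = med >= cv_threshold
    else:
        remove = med < cv_threshold
    remove &= med.notna()
    keep = [f for f, r in zip(matrix.feature_ids, remove) if not r]
    report = FilterReport("cv_filter", matrix.n_features, int(remove.sum()), cv_threshold)
    return matrix.subset_features(keep), report


def average_replicates(matrix: OmicsMatrix, replicates: ReplicateMap) -> OmicsMatrix:
    """Collapse technical replicate columns to their per-cell mean.

    Intended for log2-scale data (average after transform). Missing values
    are excluded from each mean; an all-missing group stays missing.
    """
    replicates.check_against(matrix)
    col_idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    out = np.full((matrix.n_features, len(replicates.groups)), np.nan)
    bio_ids = list(replicates.groups)
    for j, bio in enumerate(bio_ids):
        block = matrix.values[:, [col_idx[c] for c in replicates.groups[bio]]]
        any_obs = (~np.isnan(block)).any(axis=1)
        with np.errstate(invalid="ignore"):
            out[any_obs, j] = np.nanmean(block[any_obs], axis=1)
    return OmicsMatrix(list(matrix.feature_ids), bio_ids, out, matrix.layer_name)


def estimate_imputed_counts(matrix: OmicsMatrix) -> pd.Series:
    """Estimate per-feature minimum-imputed value counts.

    count = (#samples equal to the feature's minimum) - 1, with equality at
    full stored precision (minimum imputation writes identical values, so no
    epsilon is used). Entirely-missing features count as fully imputed.
    """
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise ValidationError("matrix is empty")
    counts = np.zeros(matrix.n_features, dtype=int)
    all_missing = np.isnan(matrix.values).all(axis=1)
    if all_missing.any():
        logger.warning(
            "estimate_imputed_counts: %d entirely-missing feature(s) treated "
            "as fully imputed",
            int(all_missing.sum()),
        )
        counts[all_missing] = matrix.n_samples
    present = ~all_missing
    if present.any():
        vals = matrix.values[present]
        mins = np.nanmin(vals, axis=1)
        counts[present] = np.nansum(vals == mins[:, None], axis=1) - 1
    return pd.Series(counts, index=matrix.feature_ids)


def filter_by_imputed_fraction(
    matrix: OmicsMatrix, max_fraction: float = 0.80
) -> tuple[OmicsMatrix, FilterReport]:
    """Remove features whose imputed fraction strictly exceeds the cutoff."""
    counts = estimate_imputed_counts(matrix)
    frac = counts / matrix.n_samples
    remove = frac > max_fraction
    keep = [f for f, r in zip(matrix.feature_ids, remove) if not r]
    report = FilterReport(
        "imputed_filter", matrix.n_features, int(remove.sum()), max_fraction
    )
    return matrix.subset_features(keep), report


def collapse_probes(
    matrix: OmicsMatrix, probe_map: ProbeGeneMap
) -> tuple[OmicsMatrix, FilterReport]:
    """Keep one probe per gene: the one with the highest mean expression.

    Probes without a gene mapping are dropped. Ties on the mean are broken by
    the lexicographically smallest probe ID. Output rows are relabeled with
    the gene symbol and ordered lexicographically by gene.
    """
    if not probe_map.mapping:
        raise MappingError("probe-gene map is empty")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(
            np.where(np.isnan(matrix.values), np.nan, matrix.values), axis=1
        )
    best: dict[str, tuple[float, str, int]] = {}
    n_mapped = 0
    for i, probe in enumerate(matrix.feature_ids):
        gene = probe_map.mapping.get(probe)
        if gene is None:
            continue
        n_mapped += 1
        # sort key: higher mean wins; on ties the smaller probe ID wins
        cand = (-(means[i] if not np.isnan(means[i]) else -np.inf), probe, i)
        if gene not in best or cand < best[gene]:
            best[gene] = cand
    if not best:
        raise MappingError("no probe in the matrix maps to a gene")
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    out = OmicsMatrix(genes, list(matrix.sample_ids), matrix.values[rows], "gene")
    report = FilterReport(
        "probe_collapse", matrix.n_features, matrix.n_features - len(genes), None
    )
    return out, report


def filter_low_expression(
    matrix: OmicsMatrix, drop_fraction: float = 0.10
) -> tuple[OmicsMatrix, FilterReport]:
    """Drop the floor(drop_fraction * n) lowest-mean features.

    Ties at the cut are resolved by lexicographic feature ID: among equal
    means, lower IDs are removed first.
    """
    if not 0 <= drop_fraction < 1:
        raise DomainError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    n_drop = int(np.floor(drop_fraction * matrix.n_features))
    if n_drop == 0:
        return matrix.subset_features(list(matrix.feature_ids)), FilterReport(
            "low_expression", matrix.n_features, 0, drop_fraction
        )
    with np.errstate(invalid="ignore"):
        means = np.nanmean(
            np.where(np.isnan(matrix.values), np.nan, matrix.values), axis=1
        )
    means = np.where(np.isnan(means), -np.inf, means)
    order = sorted(range(matrix.n_features), key=lambda i: (means[i], matrix.feature_ids[i]))
    dropped = set(order[:n_drop])
    keep = [f for i, f in enumerate(matrix.feature_ids) if i not in dropped]
    report = FilterReport("low_expression", matrix.n_features, n_drop, drop_fraction)
    return matrix.subset_features(keep), report


def log2_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Elementwise log2; missing stays missing; non-positive values error."""
    bad = ~np.isnan(matrix.values) & (matrix.values <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DomainError(
            f"non-positive value {matrix.values[i, j]} at feature "
            f"{matrix.feature_ids[i]!r}, sample {matrix.sample_ids[j]!r}: "
            "log2 requires positive values"
        )
    with np.errstate(invalid="ignore"):
        out = np.log2(matrix.values)
    return OmicsMatrix(
        list(matrix.feature_ids), list(matrix.sample_ids), out, matrix.layer_name
    )
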