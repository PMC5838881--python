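"""Synthetic multi-omics datasets with known ground truth.

The generator realizes the interaction model generatively: log2 gene levels
are Gaussian around per-gene baselines (mimicking log2 microarray
intensities), and each metabolite is a linear response

    m_j = b1_j + b2 * g_anchor(j) + b3 * p + sum_{i in I_j} b4 * g_i * p + e

with Gaussian residual noise. Each metabolite has one "anchor" gene carrying
the shared baseline slope b2; the designated interacting pairs (i, j) in I_j
contribute a phenotype-dependent slope b4, so the marginal model of m_j on
any single gene matches the fitted interaction model (genes are mutually
independent). Pairs outside the truth set have a true interaction
coefficient of zero.

On top of the clean aligned dataset the generator emulates the messy raw
materials preprocessing must handle: minimum-imputed metabolite cells,
technical replicate columns with small multiplicative noise (on the raw
scale), and redundant microarray probes per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SpecError, ValidationError
from .io import MultiOmicsDataset, OmicsMatrix, SampleMetadata
from .postprocess import filter_pairs
from .preprocess import ProbeGeneMap, ReplicateMap
from .results import PairResultTable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticData",
    "generate",
    "evaluate_recovery",
]


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic two-phenotype experiment.

    Defaults describe a small cell-line-like study: two groups of 12
    samples, log2 gene levels N(mean, 1) with means spread over [4, 12],
    residual SD 0.5 on the log2 metabolite scale, and a strong interaction
    slope of 2 for the truly phenotype-specific pairs.
    """

    n_group0: int = 12
    n_group1: int = 12
    n_genes: int = 200
    n_metabolites: int = 50
    fraction_interacting: float = 0.0
    beta4_magnitude: float = 2.0
    baseline_slope: float = 0.0
    phenotype_shift: float = 0.0
    noise_sd: float = 0.5
    imputed_fraction: float = 0.0
    replicates_per_sample: int = 1
    probes_per_gene: int = 1
    replicate_noise_sd: float = 0.05
    gene_mean_range: tuple = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group0", "n_group1", "n_genes", "n_metabolites"):
            if getattr(self, name) < 1:
                raise SpecError(f"{name} must be positive")
        for name in ("fraction_interacting", "imputed_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise SpecError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        if self.replicates_per_sample < 1 or self.probes_per_gene < 1:
            raise SpecError("replicates_per_sample and probes_per_gene must be >= 1")
        n_pairs = self.n_genes * self.n_metabolites
        if self.fraction_interacting > 0 and round(self.fraction_interacting * n_pairs) < 1:
            raise SpecError(
                f"fraction_interacting {self.fraction_interacting} yields no "
                f"interacting pair among {n_pairs}"
            )

    @property
    def n_samples(self) -> int:
        return self.n_group0 + self.n_group1

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Truly interacting pairs and their generative coefficients."""

    #: columns gene, metabolite, beta1, beta2, beta3, beta4
    table: pd.DataFrame
    n_genes: int = 0
    n_metabolites: int = 0

    @property
    def pairs(self) -> set:
        return set(zip(self.table["gene"], self.table["metabolite"]))


@dataclass
class SyntheticData:
    """Everything :func:`generate` produces."""

    dataset: MultiOmicsDataset  # clean, aligned, log2, post-preprocessing scale
    gene_probe_matrix: OmicsMatrix  # probe-level log2 expression
    metabolite_replicate_matrix: OmicsMatrix  # raw-scale, replicate columns
    metadata: SampleMetadata
    replicate_map: ReplicateMap
    probe_gene_map: ProbeGeneMap
    truth: GroundTruth
    imputed_counts: pd.Series = field(default_factory=pd.Series)


def _sample_ids(spec: SyntheticSpec) -> list:
    return [f"S{i + 1:03d}" for i in range(spec.n_samples)]


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Generate a dataset plus raw materials, reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = _sample_ids(spec)
    pheno = np.array([0] * spec.n_group0 + [1] * spec.n_group1)

    gene_ids = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    met_ids = [f"M{j + 1:04d}" for j in range(spec.n_metabolites)]

    lo, hi = spec.gene_mean_range
    gene_means = rng.uniform(lo, hi, size=spec.n_genes)
    G = gene_means[:, None] + rng.normal(0.0, 1.0, size=(spec.n_genes, n))

    n_pairs = spec.n_genes * spec.n_metabolites
    n_true = int(round(spec.fraction_interacting * n_pairs))
    # Spread interacting genes over metabolites as evenly as possible: each
    # extra interacting gene on the same metabolite inflates that group's
    # residual variance for its sibling pairs, which would couple per-pair
    # power to the random assignment.
    true_gene = np.empty(n_true, dtype=int)
    true_met = np.empty(n_true, dtype=int)
    perm_m = rng.permutation(spec.n_metabolites)
    used: dict[int, set] = {}
    for t in range(n_true):
        j = int(perm_m[t % spec.n_metabolites])
        taken = used.setdefault(j, set())
        if len(taken) >= spec.n_genes:
            raise SpecError("more interacting pairs requested than exist")
        while True:
            i = int(rng.integers(spec.n_genes))
            if i not in taken:
                break
        taken.add(i)
        true_gene[t] = i
        true_met[t] = j
    anchors = rng.integers(0, spec.n_genes, size=spec.n_metabolites)
    beta1 = rng.uniform(8.0, 14.0, size=spec.n_metabolites)

    M = (
        beta1[:, None]
        + spec.phenotype_shift * pheno[None, :]
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_metabolites, n))
    )
    # Interacting pairs realize the full generative model
    # m = b1 + b2*g + b3*p + b4*g*p + e for their gene; metabolites without
    # any interacting gene get the baseline slope through an anchor gene so
    # that plain (non-phenotype-specific) associations exist too.
    has_true = np.zeros(spec.n_metabolites, dtype=bool)
    has_true[true_met] = True
    plain = ~has_true
    M[plain] += spec.baseline_slope * G[anchors[plain]]
    for gi, mj in zip(true_gene, true_met):
        M[mj] += (spec.baseline_slope + spec.beta4_magnitude * pheno) * G[gi]

    # Minimum imputation: floor k cells per metabolite (never the realized
    # argmin itself) to the metabolite's minimum, so the post-hoc
    # (#at-minimum - 1) estimator recovers exactly k.
    k_imp = int(round(spec.imputed_fraction * n))
    imputed_counts = np.zeros(spec.n_metabolites, dtype=int)
    if k_imp > 0:
        k_imp = min(k_imp, n - 1)
        for j in range(spec.n_metabolites):
            amin = int(np.argmin(M[j]))
            others = np.delete(np.arange(n), amin)
            chosen = rng.choice(others, size=k_imp, replace=False)
            M[j, chosen] = M[j, amin]
            imputed_counts[j] = k_imp

    truth_rows = {
        "gene": [gene_ids[i] for i in true_gene],
        "metabolite": [met_ids[j] for j in true_met],
        "beta1": beta1[true_met],
        "beta2": np.full(n_true, spec.baseline_slope),
        "beta3": np.full(n_true, spec.phenotype_shift),
        "beta4": np.full(n_true, spec.beta4_magnitude),
    }
    truth = GroundTruth(
        pd.DataFrame(truth_rows), n_genes=spec.n_genes, n_metabolites=spec.n_metabolites
    )

    level = np.where(pheno == 0, "control", "case")
    metadata = SampleMetadata(
        pd.DataFrame({"phenotype": level}, index=pd.Index(samples, name="sample_id")),
        phenotype_column="phenotype",
    )
    dataset = MultiOmicsDataset(
        genes=OmicsMatrix(gene_ids, samples, G, "gene"),
        metabolites=OmicsMatrix(met_ids, samples, M, "metabolite"),
        metadata=metadata,
        phenotype_encoding={"control": 0, "case": 1},
    )

    # raw materials: replicate columns on the raw (2**log2) scale
    rep_cols: list = []
    rep_groups: dict = {}
    blocks = []
    for si, s in enumerate(samples):
        cols = [f"{s}_r{r + 1}" for r in range(spec.replicates_per_sample)]
        rep_groups[s] = cols
        rep_cols.extend(cols)
        noise = (
            rng.normal(0.0, spec.replicate_noise_sd, size=(spec.n_metabolites, spec.replicates_per_sample))
            if spec.replicates_per_sample > 1
            else np.zeros((spec.n_metabolites, 1))
        )
        blocks.append(2.0 ** (M[:, [si]] + noise))
    met_raw = OmicsMatrix(met_ids, rep_cols, np.hstack(blocks), "metabolite")
    replicate_map = ReplicateMap(rep_groups)

    probe_ids: list = []
    probe_rows = []
    probe_map: dict = {}
    for i, gid in enumerate(gene_ids):
        offsets = rng.normal(0.0, 0.5, size=spec.probes_per_gene)
        for pr in range(spec.probes_per_gene):
            pid = f"P{i + 1:04d}_{pr + 1}"
            probe_ids.append(pid)
            probe_map[pid] = gid
            probe_rows.append(G[i] + offsets[pr])
    gene_probes = OmicsMatrix(probe_ids, samples, np.vstack(probe_rows), "gene")

    return SyntheticData(
        dataset=dataset,
        gene_probe_matrix=gene_probes,
        metabolite_replicate_matrix=met_raw,
        metadata=metadata,
        replicate_map=replicate_map,
        probe_gene_map=ProbeGeneMap(probe_map),
        truth=truth,
        imputed_counts=pd.Series(imputed_counts, index=met_ids),
    )


@dataclass
class RecoveryMetrics:
    sensitivity: float  # NaN when there are no true pairs
    observed_fdr: float  # 0 when there are no discoveries
    n_true: int
    n_discovered: int
    n_true_discovered: int


def evaluate_recovery(
    results: PairResultTable,
    truth: GroundTruth,
    fdr_cutoff: float = 0.10,
    min_abs_delta_r: float = 0.5,
) -> RecoveryMetrics:
    """Sensitivity and observed FDR of the default significance filter."""
    res_pairs = set(
        zip(results.df["gene"].astype(str), results.df["metabolite"].astype(str))
    )
    if truth.n_genes and truth.n_metabolites:
        if len(res_pairs) != truth.n_genes * truth.n_metabolites:
            raise ValidationError(
                "results and ground truth cover different pair universes"
            )
    if not truth.pairs <= res_pairs:
        raise ValidationError("ground-truth pairs missing from the result table")
    hits = filter_pairs(results, fdr_cutoff, min_abs_delta_r)
    found = set(zip(hits.df["gene"].astype(str), hits.df["metabolite"].astype(str)))
    true_pairs = truth.pairs
    n_true_found = len(found & true_pairs)
    sensitivity = n_true_found / len(true_pairs) if true_pairs else float("nan")
    fdr = (len(found) - n_true_found) / len(found) if found else 0.0
    return RecoveryMetrics(
        sensitivity=sensitivity,
        observed_fdr=fdr,
        n_true=len(true_pairs),
        n_discovered=len(found),
        n_true_discovered=n_true_found,
    )
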