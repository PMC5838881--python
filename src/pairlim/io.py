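"""Omics data model and CSV input/output.

The pipeline works on feature-by-sample matrices (genes x samples and
metabolites x samples) plus a sample-metadata table carrying a two-level
phenotype column. All files are plain CSV: UTF-8, comma-separated, first row
sample IDs, first column feature IDs. Empty cells and ``NA`` are missing
values and become NaN internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    AlignmentError,
    FormatError,
    ParseError,
    PhenotypeError,
    ValidationError,
)
from .results import PairResultTable, RESULT_COLUMNS

logger = logging.getLogger(__name__)

#: Tokens treated as missing on input (plus the empty cell).
MISSING_TOKENS = ("", "NA")


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = sorted(counts.index[counts > 1].tolist())
    if dups:
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class OmicsMatrix:
    """One omics layer: a features x samples numeric matrix.

    ``values`` is float64 with NaN as the missing marker. Whether the matrix
    is on raw or log2 scale is a pipeline-stage property, not enforced here.
    """

    feature_ids: list
    sample_ids: list
    values: np.ndarray
    layer_name: str = "gene"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if np.isinf(self.values).any():
            raise ValidationError("matrix contains infinite values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    def subset_features(self, keep: Sequence[str]) -> "OmicsMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in keep]
        return OmicsMatrix(list(keep), list(self.sample_ids), self.values[rows], self.layer_name)

    def subset_samples(self, keep: Sequence[str]) -> "OmicsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in keep]
        return OmicsMatrix(list(self.feature_ids), list(keep), self.values[:, cols], self.layer_name)

    def feature_values(self, feature: str) -> np.ndarray:
        from .errors import LookupIDError

        try:
            i = self.feature_ids.index(feature)
        except ValueError:
            raise LookupIDError(
                f"unknown {self.layer_name} feature {feature!r}"
            ) from None
        return self.values[i]


@dataclass
class SampleMetadata:
    """Per-sample attributes, including the phenotype column."""

    table: pd.DataFrame  # indexed by sample ID
    phenotype_column: str

    def __post_init__(self) -> None:
        self.table.index = self.table.index.astype(str)
        _check_unique(self.table.index.tolist(), "sample IDs")
        if self.phenotype_column not in self.table.columns:
            raise PhenotypeError(
                f"phenotype column {self.phenotype_column!r} not in metadata "
                f"columns {list(self.table.columns)}"
            )

    @property
    def sample_ids(self) -> list:
        return self.table.index.tolist()

    def phenotype(self) -> pd.Series:
        return self.table[self.phenotype_column]

    def subset_samples(self, keep: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(keep)].copy(), self.phenotype_column)


@dataclass
class MultiOmicsDataset:
    """Aligned gene + metabolite matrices with encoded two-level phenotype.

    ``phenotype_encoding`` maps each observed phenotype level to 0 or 1; the
    reference level is coded 0.
    """

    genes: OmicsMatrix
    metabolites: OmicsMatrix
    metadata: SampleMetadata
    phenotype_encoding: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (
            self.genes.sample_ids
            == self.metabolites.sample_ids
            == self.metadata.sample_ids
        ):
            raise AlignmentError("gene, metabolite and metadata sample IDs differ")
        if self.genes.n_features == 0 or self.metabolites.n_features == 0:
            raise ValidationError("both omics layers must be non-empty")
        levels = set(map(str, self.metadata.phenotype().unique()))
        if set(self.phenotype_encoding) != levels or set(
            self.phenotype_encoding.values()
        ) != {0, 1}:
            raise PhenotypeError(
                f"encoding {dict(self.phenotype_encoding)} does not cover the "
                f"observed levels {sorted(levels)} with codes {{0, 1}}"
            )

    @property
    def sample_ids(self) -> list:
        return self.genes.sample_ids

    @property
    def n_samples(self) -> int:
        return self.genes.n_samples

    @property
    def reference_level(self) -> str:
        return next(k for k, v in self.phenotype_encoding.items() if v == 0)

    def phenotype_vector(self) -> np.ndarray:
        """0/1 int vector over the aligned samples."""
        ph = self.metadata.phenotype().astype(str)
        return ph.map(self.phenotype_encoding).to_numpy(dtype=int)


def read_omics_csv(path, layer_name: str = "gene") -> OmicsMatrix:
    """Read a feature-by-sample CSV matrix.

    First column = feature IDs, header = sample IDs. Empty cells and ``NA``
    become NaN. Non-numeric cells raise :class:`ParseError` naming the
    offending feature and sample.
    """
    import csv

    path = Path(path)
    try:
        with open(path, newline="") as fh:
            header = next(csv.reader(fh), None)
        if header is None or len(header) < 2:
            raise FormatError(f"{path}: no sample columns found in header")
        raw = pd.read_csv(
            path,
            index_col=0,
            na_values=list(MISSING_TOKENS),
            keep_default_na=False,
            skipinitialspace=True,
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    features = raw.index.astype(str).tolist()
    samples = [str(s) for s in header[1:]]
    _check_unique(features, f"feature IDs in {path}")
    _check_unique(samples, f"sample IDs in {path}")

    # non-numeric columns survive as object dtype; name the first bad cell
    for j, col in enumerate(raw.columns):
        if raw[col].dtype == object:
            for i, v in enumerate(raw[col]):
                if isinstance(v, str):
                    try:
                        float(v)
                    except ValueError:
                        raise ParseError(
                            f"{path}: non-numeric value {v!r} at feature "
                            f"{features[i]!r}, sample {samples[j]!r}"
                        ) from None
    values = raw.to_numpy(dtype=float)
    return OmicsMatrix(features, samples, values, layer_name)


def write_omics_csv(matrix: OmicsMatrix, path) -> None:
    """Write a matrix in the same dialect :func:`read_omics_csv` reads.

    Floats are written with shortest round-trip representation, so
    read(write(x)) reproduces the values exactly.
    """
    matrix.to_frame().to_csv(Path(path), index_label="feature_id")


def read_sample_metadata(path, phenotype_column: str) -> SampleMetadata:
    """Read the sample-metadata CSV (first column = sample ID)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, index_col=0, na_values=["NA"])
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    return SampleMetadata(table, phenotype_column)


def write_sample_metadata(metadata: SampleMetadata, path) -> None:
    metadata.table.to_csv(Path(path), index_label="sample_id")


def align_dataset(
    genes: OmicsMatrix,
    metabolites: OmicsMatrix,
    metadata: SampleMetadata,
    phenotype_column: str | None = None,
    reference_level: str | None = None,
) -> MultiOmicsDataset:
    """Restrict all three components to their common samples, in gene order.

    Samples with a missing phenotype are dropped (count logged). The phenotype
    is encoded 0/1; the reference (coded 0) is ``reference_level`` when given,
    otherwise the lexicographically first observed level.
    """
    if phenotype_column is not None and phenotype_column != metadata.phenotype_column:
        metadata = SampleMetadata(metadata.table, phenotype_column)

    common = [s for s in genes.sample_ids if s in set(metabolites.sample_ids)]
    meta_ids = set(metadata.sample_ids)
    common = [s for s in common if s in meta_ids]
    if not common:
        raise AlignmentError(
            "no sample IDs shared by the gene matrix, metabolite matrix and metadata"
        )

    pheno = metadata.table.loc[common, metadata.phenotype_column]
    keep = [s for s, v in zip(common, pheno) if pd.notna(v)]
    dropped = len(common) - len(keep)
    if dropped:
        logger.info("align_dataset: dropped %d samples with missing phenotype", dropped)
    if not keep:
        raise AlignmentError("all shared samples have a missing phenotype")

    levels = sorted(set(metadata.table.loc[keep, metadata.phenotype_column].astype(str)))
    if len(levels) != 2:
        raise PhenotypeError(
            f"phenotype column {metadata.phenotype_column!r} has "
            f"{len(levels)} level(s) among retained samples "
            f"({levels}); exactly 2 required"
        )
    if reference_level is None:
        reference_level = levels[0]
    elif str(reference_level) not in levels:
        raise PhenotypeError(
            f"reference level {reference_level!r} not among observed levels {levels}"
        )
    other = next(l for l in levels if l != str(reference_level))
    encoding = {str(reference_level): 0, other: 1}

    return MultiOmicsDataset(
        genes=genes.subset_samples(keep),
        metabolites=metabolites.subset_samples(keep),
        metadata=metadata.subset_samples(keep),
        phenotype_encoding=encoding,
    )


def write_results_csv(results: PairResultTable, path) -> None:
    """Write a result table, rows sorted by (gene, metabolite)."""
    if results is None:
        raise ValidationError("results table is None")
    results.sorted().df.to_csv(Path(path), index=False)


def read_results_csv(path) -> PairResultTable:
    df = pd.read_csv(
        Path(path),
        dtype={"gene": str, "metabolite": str, "flag": str},
        float_precision="round_trip",
    )
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: results CSV missing columns {missing}")
    df["flag"] = df["flag"].fillna("")
    return PairResultTable(df)


def load_manifest(path) -> dict:
    """Load a YAML manifest naming the three input CSVs and phenotype column.

    Keys: ``gene_csv``, ``metabolite_csv``, ``metadata_csv``,
    ``phenotype_column``, optional ``reference_level``. Relative paths are
    resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise FormatError(f"{path}: manifest must be a YAML mapping")
    required = ["gene_csv", "metabolite_csv", "metadata_csv", "phenotype_column"]
    missing = [k for k in required if k not in manifest]
    if missing:
        raise FormatError(f"{path}: manifest missing keys {missing}")
    for key in ("gene_csv", "metabolite_csv", "metadata_csv"):
        p = Path(manifest[key])
        if not p.is_absolute():
            p = path.parent / p
        manifest[key] = str(p)
    manifest.setdefault("reference_level", None)
    return manifest


def load_dataset_from_manifest(manifest: dict) -> MultiOmicsDataset:
    genes = read_omics_csv(manifest["gene_csv"], "gene")
    metabolites = read_omics_csv(manifest["metabolite_csv"], "metabolite")
    metadata = read_sample_metadata(manifest["metadata_csv"], manifest["phenotype_column"])
    return align_dataset(
        genes, metabolites, metadata, reference_level=manifest.get("reference_level")
    )
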