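"""Result container for all-pairs interaction fits.

A :class:`PairResultTable` holds one row per (gene, metabolite) pair with the
fitted coefficients of the interaction model, the interaction test, the
BH-adjusted p-value and the per-group Spearman correlations with their
difference (the effect size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns written to / read from the results CSV, in order.
RESULT_COLUMNS = [
    "gene",
    "metabolite",
    "beta1",
    "beta2",
    "beta3",
    "beta4",
    "se_interaction",
    "t_interaction",
    "p_interaction",
    "fdr_p",
    "r_group0",
    "r_group1",
    "delta_r",
    "df",
    "n_used",
    "flag",
]

#: Float-valued statistic columns (everything but the IDs and the flag).
STAT_COLUMNS = [c for c in RESULT_COLUMNS if c not in ("gene", "metabolite", "flag")]


@dataclass
class PairResultTable:
    """One row per gene-metabolite pair.

    The underlying frame always carries :data:`RESULT_COLUMNS`. ``flag`` is an
    empty string for clean fits, otherwise one of ``degenerate``,
    ``zero_residual`` or ``insufficient_samples``; flagged rows have missing
    (NaN) test statistics rather than fabricated ones.
    """

    df: pd.DataFrame = field(default_factory=lambda: _empty_frame())

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"result table missing columns: {missing}")
        self.df = self.df[RESULT_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "PairResultTable":
        """Deterministic row order: gene then metabolite, lexicographic."""
        out = self.df.sort_values(
            ["gene", "metabolite"], kind="mergesort", ignore_index=True
        )
        return PairResultTable(out)

    def equals(self, other: "PairResultTable", tol: float = 0.0) -> bool:
        a, b = self.sorted().df, other.sorted().df
        if len(a) != len(b):
            return False
        for col in ("gene", "metabolite", "flag"):
            if not (a[col].astype(str) == b[col].astype(str)).all():
                return False
        for col in STAT_COLUMNS:
            x = a[col].to_numpy(dtype=float)
            y = b[col].to_numpy(dtype=float)
            if not np.array_equal(np.isnan(x), np.isnan(y)):
                return False
            ok = np.isnan(x) | (np.abs(x - y) <= tol)
            if not ok.all():
                return False
        return True


def _empty_frame() -> pd.DataFrame:
    data: dict = {c: pd.Series(dtype=float) for c in RESULT_COLUMNS}
    for c in ("gene", "metabolite", "flag"):
        data[c] = pd.Series(dtype=str)
    return pd.DataFrame(data)


def empty_result_table() -> PairResultTable:
    return PairResultTable(_empty_frame())
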