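"""Core data containers for the analysis pipeline.

Counts and expression matrices are oriented genes x samples throughout,
matching the convention of bulk RNA-seq count files. Clinical tables are
oriented samples x covariates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneCountMatrix",
    "VSTMatrix",
    "CLINICAL_NUMERIC_COLUMNS",
    "ARMS",
    "RESPONSE_DAS28_CUTOFF",
    "validate_clinical",
]

#: Treatment arms: etanercept (TNF inhibitor), tocilizumab (IL6-receptor
#: inhibitor), rituximab (anti-CD20 B-cell depleter).
ARMS = ("etanercept", "tocilizumab", "rituximab")

#: DAS28-ESR below this value at week 16 defines treatment response
#: (low disease activity).
RESPONSE_DAS28_CUTOFF = 3.2

CLINICAL_NUMERIC_COLUMNS = (
    "tjc28",
    "sjc28",
    "vas",
    "rf_titre",
    "ccp_titre",
    "esr",
    "crp",
)


class GeneCountMatrix:
    """Integer gene x sample count matrix with unique gene and sample IDs.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, genes in rows, samples
        in columns. Index and columns must be unique.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TypeError("counts must be numeric")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"GeneCountMatrix({g} genes x {s} samples)"


@dataclass
class VSTMatrix:
    """Variance-stabilised expression on a log2-like scale.

    Attributes
    ----------
    values
        Genes x samples DataFrame of stabilised expression.
    size_factors
        Per-sample positive normalisation factors (geometric mean ~ 1).
    dispersion_trend
        ``(a0, a1)`` of the mean-dispersion trend ``alpha(mu) = a1/mu + a0``.
    """

    values: pd.DataFrame
    size_factors: pd.Series
    dispersion_trend: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("VST values must be finite")
        if (self.size_factors.to_numpy() <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def validate_clinical(clinical: pd.DataFrame, require_outcome: bool = False) -> pd.DataFrame:
    """Validate a per-sample clinical covariate table.

    Checks joint counts are integers in [0, 28], numeric covariates are
    non-negative, arms are recognised and, when both are present, that
    ``response_binary`` equals ``das28_esr_wk16 < 3.2``.
    """
    df = clinical
    for col in ("tjc28", "sjc28"):
        if col in df:
            v = df[col].to_numpy(dtype=float)
            if ((v < 0) | (v > 28)).any() or not np.allclose(v, np.round(v)):
                raise ValueError(f"{col} must be integer in [0, 28]")
    for col in CLINICAL_NUMERIC_COLUMNS:
        if col in df and (df[col].to_numpy(dtype=float) < 0).any():
            raise ValueError(f"{col} must be non-negative")
    if "arm" in df:
        unknown = set(df["arm"].unique()) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown treatment arms: {sorted(unknown)}")
    if require_outcome and not {"response_binary", "das28_esr_wk16"} <= set(df.columns):
        raise ValueError("clinical table lacks outcome columns")
    if "response_binary" in df and "das28_esr_wk16" in df:
        implied = df["das28_esr_wk16"].to_numpy(dtype=float) < RESPONSE_DAS28_CUTOFF
        if not (implied == df["response_binary"].to_numpy(dtype=bool)).all():
            raise ValueError(
                "response_binary inconsistent with DAS28-ESR < "
                f"{RESPONSE_DAS28_CUTOFF} dichotomy"
            )
    return df
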