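"""Normalization stages producing the values entering the CV and contrast stages.

RNA counts go through the median-of-ratios size-factor estimator; microbiome
profiles through per-sample relative abundance; intensity modalities
(proteomics, metabolomics) through log2 transform with per-sample median
centering; accessibility counts through counts-per-million.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "size_factors_median_ratio",
    "normalize_counts",
    "relative_abundance",
    "cpm",
    "log_median_center",
]


def size_factors_median_ratio(counts: FeatureTable, *, pseudocount: float | None = None
                              ) -> pd.Series:
    """Median-of-ratios size factors (the DESeq2 estimator).

    Reference analytes are those with no zero count; per sample, the factor
    is the median over reference analytes of count / geometric-mean
    reference value, rescaled so the factors have geometric mean 1.  With
    ``pseudocount`` set, it is added to every count first (fallback for
    tables without an all-positive analyte).
    """
    values = counts.values()
    if pseudocount is not None:
        values = values + pseudocount
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no analyte with all-positive counts; pass pseudocount= to enable "
            "the pseudocount fallback"
        )
    ref = values[positive]
    log_geo = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo[:, None]
    log_factors = np.median(ratios, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.sample_ids, name="size_factor")


def normalize_counts(counts: FeatureTable, factors: pd.Series, *,
                     log2: bool = False, pseudocount: float = 1.0) -> FeatureTable:
    """Divide each sample by its size factor; optionally log2(x + pseudocount)."""
    missing = [s for s in counts.sample_ids if s not in factors.index]
    if missing:
        raise ValueError(f"missing size factors for samples: {missing}")
    if (factors.loc[counts.sample_ids] <= 0).any():
        raise ValueError("size factors must be > 0")
    scaled = counts.data / factors.loc[counts.sample_ids]
    if log2:
        scaled = np.log2(scaled + pseudocount)
    return FeatureTable(scaled, modality=counts.modality, normalized=True)


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Scale each sample (column) to sum to 1.

    Already-relative tables (flagged normalized with unit column sums) pass
    through unchanged; a zero-sum sample is an error naming the sample.
    """
    sums = table.data.sum(axis=0)
    if table.normalized and np.allclose(sums, 1.0, atol=1e-9):
        return table
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ValueError(f"zero-sum samples: {zero}")
    return FeatureTable(table.data / sums, modality=table.modality, normalized=True)


def cpm(counts: FeatureTable) -> FeatureTable:
    """Counts per million: value / column total x 1e6."""
    totals = counts.data.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"zero-total samples: {zero}")
    return FeatureTable(counts.data / totals * 1e6, modality=counts.modality,
                        normalized=True)


def log_median_center(table: FeatureTable, *, pseudocount: float = 1.0) -> FeatureTable:
    """log2(x + pseudocount) followed by per-sample median centering.

    The stand-in normalization for intensity modalities (proteomics,
    metabolomics); the transform applied is recorded by callers in output
    provenance.
    """
    logged = np.log2(table.data + pseudocount)
    centered = logged - logged.median(axis=0)
    return FeatureTable(centered, modality=table.modality, normalized=True)
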