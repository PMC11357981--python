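"""Core in-memory containers for the longitudinal multi-omic pipeline.

The canonical substrate of every statistic in this package is an
analyte-by-sample abundance matrix (:class:`FeatureTable`) together with a
sample sheet mapping each sample to a subject, a timepoint label and a
mission phase.  Matrices are oriented analytes x samples everywhere; the
orientation is asserted at construction and never silently transposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MODALITIES",
    "FeatureTable",
    "GeneSetCollection",
    "validate_sample_info",
    "validate_tss_annotation",
]

#: Recognised assay modalities.
MODALITIES = (
    "rna_counts",
    "protein_intensity",
    "metabolite_intensity",
    "cytokine",
    "microbiome_relabund",
    "fragment_counts",
)

SAMPLE_INFO_COLUMNS = ("sample_id", "subject_id", "timepoint_label", "day_offset")
TSS_COLUMNS = ("gene_id", "chrom", "tss", "strand")


@dataclass
class FeatureTable:
    """An analyte x sample abundance matrix with a modality tag.

    Parameters
    ----------
    data
        DataFrame with analyte ids on the index and sample ids on the
        columns.  Values must be finite, and non-negative unless the table
        is flagged ``normalized`` (log-scale normalized values may be
        negative).
    modality
        One of :data:`MODALITIES`.
    normalized
        Whether the values have passed through a normalization stage.
    """

    data: pd.DataFrame
    modality: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate analyte ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("feature table values must be numeric")
        if not np.isfinite(values).all():
            raise ValueError("feature table contains non-finite values")
        if not self.normalized and (values < 0).any():
            raise ValueError("raw (non-normalized) values must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        """Matrix view (analytes x samples), float64."""
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, *, normalized: bool | None = None) -> "FeatureTable":
        """Return a new table with replaced values, revalidating invariants."""
        return FeatureTable(
            data=data,
            modality=self.modality,
            normalized=self.normalized if normalized is None else normalized,
        )


@dataclass
class GeneSetCollection:
    """Named analyte sets (GMT-style), e.g. pathway collections.

    ``sets`` maps a unique set name to a non-empty list of member ids;
    ``descriptions`` carries the optional second GMT column.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def validate_sample_info(samples: pd.DataFrame, table: FeatureTable | None = None) -> pd.DataFrame:
    """Check a sample sheet and (optionally) its coverage of a feature table.

    The sheet must have columns ``sample_id, subject_id, timepoint_label,
    day_offset`` with unique sample ids; when ``table`` is given, every
    sample of the table must appear exactly once.
    """
    missing = [c for c in SAMPLE_INFO_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sample sheet: {dups}")
    if table is not None:
        known = set(samples["sample_id"])
        absent = [s for s in table.sample_ids if s not in known]
        if absent:
            raise ValueError(f"samples without metadata: {absent}")
    return samples


def validate_tss_annotation(tss: pd.DataFrame) -> pd.DataFrame:
    """Check a TSS annotation table (0-based positions, one row per gene)."""
    missing = [c for c in TSS_COLUMNS if c not in tss.columns]
    if missing:
        raise ValueError(f"TSS annotation missing columns: {missing}")
    if tss["gene_id"].duplicated().any():
        dups = tss.loc[tss["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in TSS annotation: {dups}")
    if (tss["tss"] < 0).any():
        raise ValueError("TSS positions must be >= 0")
    bad = ~tss["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand values: {tss.loc[bad, 'strand'].unique().tolist()}")
    return tss
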