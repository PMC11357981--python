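"""Phase-contrast differential testing and recovery-profile analytics.

Named contrasts compare a pre-flight baseline against post-flight or
recovery timepoints: FP1 (flight profile, baseline vs R+1), RP1/RP2
(recovery, vs R+45 / R+82), LP1/LP2 (longitudinal, vs pooled recovery /
R+82).  Differential analytes (DEGs) pass strict thresholds
adjusted p < 0.05 and |log2FC| > 0.5.  Profile analytics quantify how the
flight response resolves: the fraction of a recovery profile's DEGs shared
with FP1, whether each shared DEG's fold-change direction reversed
(returned toward/past baseline) or persisted, and how DEGs distribute
across cell-type groups (unique vs shared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .tables import FeatureTable

__all__ = [
    "ContrastSpec",
    "default_contrasts",
    "pseudobulk_aggregate",
    "differential_test",
    "call_degs",
    "shared_fraction",
    "reversal_classification",
    "profile_uniqueness_summary",
    "UniquenessSummary",
]

_PRE = ("L-92", "L-44", "L-3")


@dataclass(frozen=True)
class ContrastSpec:
    """Baseline-vs-comparison timepoint sets; sides disjoint and non-empty."""

    name: str
    baseline: tuple[str, ...]
    comparison: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.baseline or not self.comparison:
            raise ValueError(f"contrast {self.name!r}: both sides must be non-empty")
        overlap = set(self.baseline) & set(self.comparison)
        if overlap:
            raise ValueError(
                f"contrast {self.name!r}: sides overlap on {sorted(overlap)}")


def default_contrasts() -> dict[str, ContrastSpec]:
    """Default profile registry.

    Only LP2's composition (pre-flight baseline vs R+82) is fixed by
    definition; the remaining profiles are registry defaults that callers
    may override.  Note RP2 and LP2 coincide under these defaults.
    """
    return {
        "FP1": ContrastSpec("FP1", _PRE, ("R+1",)),
        "RP1": ContrastSpec("RP1", _PRE, ("R+45",)),
        "RP2": ContrastSpec("RP2", _PRE, ("R+82",)),
        "LP1": ContrastSpec("LP1", _PRE, ("R+45", "R+82")),
        "LP2": ContrastSpec("LP2", _PRE, ("R+82",)),
    }


def pseudobulk_aggregate(group_tables: list[FeatureTable]) -> FeatureTable:
    """Element-wise sum of per-group (e.g. per-cell-type) count tables."""
    if not group_tables:
        raise ValueError("no tables to aggregate")
    first = group_tables[0]
    total = first.data.copy()
    for t in group_tables[1:]:
        if list(t.data.index) != list(first.data.index) or \
                list(t.data.columns) != list(first.data.columns):
            raise ValueError("pseudobulk aggregation requires identical analyte "
                             "and sample universes across groups")
        total = total + t.data
    return FeatureTable(total, modality=first.modality, normalized=False)


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p.

    The exact null distribution is used whenever the groups are small
    enough (total <= 30, no ties) — at the cohort sizes this pipeline
    targets (a dozen samples per side) the normal approximation floors the
    attainable p well above what multiple-testing correction over
    thousands of analytes can ever call, so exactness matters.  Larger
    groups or ties fall back to the midrank normal approximation with
    continuity correction.
    """
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    exact = len(x) + len(y) <= 30 and not _has_ties(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    both = np.concatenate([x, y])
    return len(np.unique(both)) < len(both)


def differential_test(table: FeatureTable, samples: pd.DataFrame,
                      contrast: ContrastSpec, *, pseudocount: float = 1.0,
                      values_are_log: bool = False,
                      group: str | None = None) -> pd.DataFrame:
    """Per-analyte rank-sum differential test for one contrast.

    p is the two-sided Wilcoxon rank-sum comparing comparison- vs
    baseline-timepoint values; ``log2FC = log2((mean_cmp + pc)/(mean_base +
    pc))`` (or the plain mean difference when ``values_are_log``).
    Adjusted p is Benjamini-Hochberg across the analytes of this call (one
    call per group).  Returns columns
    ``analyte, group, log2fc, p, p_adj, n_baseline, n_comparison``.
    """
    tp = samples.set_index("sample_id")["timepoint_label"]
    base_ids = [s for s in table.sample_ids if tp.get(s) in contrast.baseline]
    cmp_ids = [s for s in table.sample_ids if tp.get(s) in contrast.comparison]
    if not base_ids or not cmp_ids:
        raise ValueError(
            f"contrast {contrast.name!r}: empty side "
            f"(baseline n={len(base_ids)}, comparison n={len(cmp_ids)})")

    B = table.data[base_ids].to_numpy(dtype=float)
    C = table.data[cmp_ids].to_numpy(dtype=float)
    mean_b = B.mean(axis=1)
    mean_c = C.mean(axis=1)
    if values_are_log:
        lfc = mean_c - mean_b
    else:
        lfc = np.log2((mean_c + pseudocount) / (mean_b + pseudocount))
    pvals = np.array([_ranksum_p(C[i], B[i]) for i in range(len(lfc))])
    padj = bh_adjust(pvals)
    return pd.DataFrame({
        "analyte": table.analyte_ids,
        "group": group,
        "log2fc": lfc,
        "p": pvals,
        "p_adj": padj,
        "n_baseline": len(base_ids),
        "n_comparison": len(cmp_ids),
    })


def call_degs(records: pd.DataFrame, alpha: float = 0.05,
              lfc_threshold: float = 0.5) -> set[str]:
    """DEG call with strict thresholds: adjusted p < alpha AND |log2FC| > tau."""
    hit = (records["p_adj"] < alpha) & (records["log2fc"].abs() > lfc_threshold)
    return set(records.loc[hit, "analyte"])


def shared_fraction(reference: set[str], target: set[str], *,
                    normalize_by: str = "target") -> float:
    """Fraction of DEGs shared between a reference profile (e.g. FP1) and a
    target profile: |target ∩ reference| / |target| by default (or /
    |reference| with ``normalize_by="reference"``).  An empty denominator
    set yields NaN (undefined), never 0."""
    if not reference:
        raise ValueError("reference DEG set is empty")
    denom = target if normalize_by == "target" else reference
    if normalize_by not in ("target", "reference"):
        raise ValueError(f"unknown normalize_by {normalize_by!r}")
    if not denom:
        return float("nan")
    return len(target & reference) / len(denom)


def reversal_classification(lfc_reference: float, lfc_target: float) -> str:
    """``"reversed"`` when the log2FC sign flips between profiles,
    ``"persistent"`` when it is retained.  Zero fold-changes are an error
    (cannot arise for DEGs under the strict |log2FC| > tau threshold)."""
    if not (np.isfinite(lfc_reference) and np.isfinite(lfc_target)):
        raise ValueError("fold changes must be finite")
    if lfc_reference == 0 or lfc_target == 0:
        raise ValueError("zero log2FC: direction undefined")
    return "persistent" if (lfc_reference > 0) == (lfc_target > 0) else "reversed"


@dataclass(frozen=True)
class UniquenessSummary:
    n_unique: int
    n_shared: int
    pct_unique: float
    pct_shared: float


def profile_uniqueness_summary(group_sets: dict[str, set[str]]) -> UniquenessSummary:
    """Count analytes unique to one group vs shared by two or more.

    Percentages are reported to one decimal, as conventionally printed
    (e.g. 211 unique + 87 shared -> 70.8% / 29.2%).
    """
    if len(group_sets) < 2:
        raise ValueError("need at least two groups")
    membership: dict[str, int] = {}
    for members in group_sets.values():
        for a in members:
            membership[a] = membership.get(a, 0) + 1
    n_unique = sum(1 for c in membership.values() if c == 1)
    n_shared = sum(1 for c in membership.values() if c >= 2)
    total = n_unique + n_shared
    if total == 0:
        raise ValueError("all groups are empty")
    return UniquenessSummary(
        n_unique=n_unique,
        n_shared=n_shared,
        pct_unique=round(100.0 * n_unique / total, 1),
        pct_shared=round(100.0 * n_shared / total, 1),
    )
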