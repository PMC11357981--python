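"""Promoter accessibility / expression concordance.

Chromatin accessibility is summarized per gene by summing fragment counts
in a promoter window (TSS +/- 500 bp; 0-based half-open coordinates, so
1,001 positions centred on the TSS, clamped at the chromosome start), then
CPM-normalizing across genes, taking log2 differences between two
conditions, and testing concordance with the matched expression
fold-changes: a one-sided rank-sum test that up-regulated DEGs gained more
promoter accessibility than down-regulated DEGs, plus the rank correlation
between accessibility delta and expression log2FC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import cpm
from .tables import FeatureTable, validate_tss_annotation

__all__ = [
    "tss_windows",
    "window_accessibility",
    "accessibility_delta",
    "concordance_test",
    "ConcordanceResult",
]


def tss_windows(tss: pd.DataFrame, halfwidth: int = 500) -> pd.DataFrame:
    """Promoter windows ``[tss - halfwidth, tss + halfwidth + 1)``, clamped
    at 0.  Windows are symmetric around the TSS, hence strand-independent.

    Returns columns ``gene_id, chrom, start, end``.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    validate_tss_annotation(tss)
    start = np.maximum(tss["tss"].to_numpy(dtype=int) - halfwidth, 0)
    end = tss["tss"].to_numpy(dtype=int) + halfwidth + 1
    return pd.DataFrame({
        "gene_id": tss["gene_id"].to_numpy(),
        "chrom": tss["chrom"].to_numpy(),
        "start": start,
        "end": end,
    })


def window_accessibility(fragments: pd.DataFrame, windows: pd.DataFrame,
                         *, group_column: str | None = None) -> FeatureTable:
    """Sum fragment counts overlapping each promoter window.

    ``fragments`` has columns ``chrom, start, end, count`` (0-based
    half-open intervals) and optionally a group column (e.g. condition);
    overlap means any shared position (``frag.start < window.end`` and
    ``frag.end > window.start``).  A window on a chromosome absent from the
    fragment records gets a zero count (the gene is still reported).
    Returns a gene x group ``fragment_counts`` table (a single ``"all"``
    group when no group column is given).
    """
    for col in ("chrom", "start", "end", "count"):
        if col not in fragments.columns:
            raise ValueError(f"fragment records missing column {col!r}")
    if (fragments["end"] <= fragments["start"]).any():
        raise ValueError("fragment intervals must satisfy end > start")
    groups = ([None] if group_column is None
              else sorted(fragments[group_column].unique()))
    genes = list(windows["gene_id"])
    out = pd.DataFrame(0.0, index=genes,
                       columns=["all"] if group_column is None else groups)
    for g in groups:
        frag = fragments if g is None else fragments[fragments[group_column] == g]
        colname = "all" if g is None else g
        for chrom, win in windows.groupby("chrom", sort=False):
            f = frag[frag["chrom"] == chrom]
            if len(f) == 0:
                continue
            fs = f["start"].to_numpy()
            fe = f["end"].to_numpy()
            fc = f["count"].to_numpy(dtype=float)
            ws = win["start"].to_numpy()[:, None]
            we = win["end"].to_numpy()[:, None]
            overlap = (fs[None, :] < we) & (fe[None, :] > ws)
            out.loc[win["gene_id"].to_numpy(), colname] = overlap @ fc
    return FeatureTable(out, modality="fragment_counts", normalized=False)


def accessibility_delta(counts: FeatureTable, condition_a: str, condition_b: str,
                        *, pseudocount: float = 1.0) -> pd.Series:
    """Per-gene log2 accessibility difference between two conditions.

    Counts are CPM-normalized per condition first; the delta is
    ``log2((cpm_b + pc) / (cpm_a + pc))`` (the pseudocount guards zeros).
    """
    for c in (condition_a, condition_b):
        if c not in counts.sample_ids:
            raise ValueError(f"condition {c!r} not in table")
    normed = cpm(counts)
    a = normed.data[condition_a]
    b = normed.data[condition_b]
    delta = np.log2((b + pseudocount) / (a + pseudocount))
    delta.name = "delta_log2_accessibility"
    return delta


@dataclass
class ConcordanceResult:
    p: float
    statistic: float
    rho: float
    rho_p: float
    n_up: int
    n_down: int
    per_gene: pd.DataFrame


def concordance_test(deltas: pd.Series, expression: pd.DataFrame) -> ConcordanceResult:
    """Test that promoter accessibility tracks expression change direction.

    ``expression`` carries columns ``analyte, log2fc, deg`` (boolean DEG
    flag).  The test is a one-sided Wilcoxon rank-sum that accessibility
    deltas of up-regulated DEGs exceed those of down-regulated DEGs; the
    Spearman correlation between delta and expression log2FC over all
    matched genes is reported alongside.  Either direction stratum having
    fewer than two genes with accessibility data is an error naming the
    stratum.
    """
    expr = expression.set_index("analyte")
    shared = [g for g in deltas.index if g in expr.index]
    d = deltas.loc[shared]
    lfc = expr.loc[shared, "log2fc"]
    deg = expr.loc[shared, "deg"].astype(bool)
    up = d[deg & (lfc > 0)]
    down = d[deg & (lfc < 0)]
    for name, stratum in (("up", up), ("down", down)):
        if len(stratum) < 2:
            raise ValueError(
                f"{name}-DEG stratum has {len(stratum)} gene(s) with "
                "accessibility data; need >= 2")
    res = stats.mannwhitneyu(up.to_numpy(), down.to_numpy(),
                             alternative="greater",
                             method="exact" if max(len(up), len(down)) <= 8
                             and len(np.unique(np.concatenate([up, down])))
                             == len(up) + len(down) else "asymptotic")
    rho, rho_p = stats.spearmanr(d.to_numpy(), lfc.to_numpy())
    per_gene = pd.DataFrame({
        "gene_id": shared,
        "delta_log2_accessibility": d.to_numpy(),
        "expression_log2fc": lfc.to_numpy(),
        "deg": deg.to_numpy(),
    })
    return ConcordanceResult(p=float(res.pvalue), statistic=float(res.statistic),
                             rho=float(rho), rho_p=float(rho_p),
                             n_up=len(up), n_down=len(down), per_gene=per_gene)
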