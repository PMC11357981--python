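"""Gene-set enrichment: preranked running-sum statistic and hypergeometric
overrepresentation, both implemented in-repo.

The preranked mode consumes an ordered analyte list with scores (e.g. the
permutation z-scores of the variability stage) and computes the weighted
Kolmogorov-Smirnov-like running-sum enrichment score (ES): walking down the
ranking, the sum rises by ``|score|^w / sum(|score|^w over hits)`` at set
members and falls by ``1/(N - n_hits)`` at non-members; the ES is the
signed extremum.  Significance comes from a gene-label permutation null
(random member sets of the same size), with the normalized enrichment
score NES = ES / mean(|null ES| of the matching sign) and an add-one
empirical p of the matching sign.  Overrepresentation (ORA) of a hit list
against a set within a universe uses the exact hypergeometric upper tail.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import GeneSetCollection

__all__ = [
    "preranked_es",
    "preranked_null",
    "nes_and_p",
    "enrich_preranked",
    "ora_hypergeometric",
    "enrich_ora",
    "bh_adjust",
    "filter_pathways",
]


def _ordered(scores: pd.Series) -> pd.Series:
    """Descending by score, lexicographic tie-break on analyte id."""
    if scores.index.has_duplicates:
        dups = scores.index[scores.index.duplicated()].unique().tolist()
        raise ValueError(f"ranked list has duplicate ids: {dups}")
    df = pd.DataFrame({"id": scores.index, "score": scores.to_numpy(dtype=float)})
    df = df.sort_values(["score", "id"], ascending=[False, True], kind="stable")
    return pd.Series(df["score"].to_numpy(), index=df["id"].to_numpy())


def preranked_es(scores: pd.Series, members, weight: float = 1.0
                 ) -> tuple[float, np.ndarray]:
    """Enrichment score of one set against a ranked list.

    ``scores`` is a Series indexed by analyte id (re-sorted internally);
    ``members`` is the set's member ids.  Returns ``(ES, running_sum)``.
    """
    ranked = _ordered(scores)
    ids = ranked.index.to_numpy()
    s = ranked.to_numpy()
    hit = np.isin(ids, list(set(members)))
    n_hits = int(hit.sum())
    n = len(ids)
    if n_hits == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_hits == n:
        # no misses: the running sum climbs monotonically to exactly 1
        running = np.cumsum(np.abs(s) ** weight / np.sum(np.abs(s) ** weight)) \
            if weight > 0 and np.any(s != 0) else np.cumsum(np.full(n, 1.0 / n))
        return 1.0, running
    w = np.abs(s) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        raise ValueError("all member scores are zero under the given weight")
    steps = np.where(hit, hit_w / denom, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def preranked_null(scores: pd.Series, set_size: int, n_perm: int,
                   seed=None, weight: float = 1.0) -> np.ndarray:
    """Gene-label permutation null: ES of ``n_perm`` random sets of
    ``set_size`` ids drawn uniformly without replacement from the list."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ranked = _ordered(scores)
    ids = ranked.index.to_numpy()
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for k in range(n_perm):
        picked = rng.choice(ids, size=set_size, replace=False)
        out[k], _ = preranked_es(ranked, picked, weight=weight)
    return out


def nes_and_p(es: float, null: np.ndarray) -> tuple[float, float, bool]:
    """Normalize an ES against its null and compute the add-one tail p.

    NES = ES / mean(|null ES| of matching sign); p is the add-one tail
    fraction among matching-sign draws.  With no matching-sign draws the p
    floors at ``1/(n_perm + 1)`` and the NES is flagged unreliable
    (returned as NaN with ``flagged=True``).
    """
    null = np.asarray(null, dtype=float)
    same = null >= 0 if es >= 0 else null < 0
    n_same = int(same.sum())
    if n_same == 0:
        return float("nan"), 1.0 / (len(null) + 1.0), True
    mean_abs = np.abs(null[same]).mean()
    nes = es / mean_abs if mean_abs > 0 else float("nan")
    extreme = int((np.abs(null[same]) >= abs(es)).sum())
    p = (1.0 + extreme) / (1.0 + n_same)
    return float(nes), float(p), not np.isfinite(nes)


def _leading_edge(ranked: pd.Series, members, running: np.ndarray) -> list[str]:
    ids = ranked.index.to_numpy()
    hit = np.isin(ids, list(set(members)))
    i = int(np.argmax(np.abs(running)))
    if running[i] >= 0:
        sel = hit[: i + 1]
        return list(ids[: i + 1][sel])
    sel = hit[i:]
    return list(ids[i:][sel])


def enrich_preranked(scores: pd.Series, collection: GeneSetCollection, *,
                     n_perm: int = 2000, seed=None, weight: float = 1.0,
                     min_overlap: int = 1) -> pd.DataFrame:
    """Preranked enrichment of every set in a collection.

    Sets are processed in name order with per-set child seeds derived from
    ``seed``, so results are deterministic and independent of collection
    ordering.  Nominal p-values are BH-adjusted into q across sets.
    """
    ranked = _ordered(scores)
    universe = set(ranked.index)
    rows = []
    base = 0 if seed is None else int(seed)
    for name in sorted(collection.sets):
        members = [m for m in collection[name] if m in universe]
        if len(members) < min_overlap:
            continue
        es, running = preranked_es(ranked, members, weight=weight)
        digest = hashlib.sha256(name.encode()).digest()
        child = np.random.SeedSequence([base, int.from_bytes(digest[:4], "big")])
        null = preranked_null(ranked, len(members), n_perm, seed=child, weight=weight)
        nes, p, flagged = nes_and_p(es, null)
        rows.append({
            "set": name, "size": len(members), "es": es, "nes": nes,
            "p": p, "flagged": flagged,
            "direction": 1 if es >= 0 else -1,
            "leading_edge": ",".join(sorted(_leading_edge(ranked, members, running))),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def ora_hypergeometric(hits, gene_set, universe) -> dict:
    """Hypergeometric overrepresentation of a hit list in a gene set.

    The set is intersected with the universe before testing; the p-value is
    ``P(X >= overlap)`` for X ~ Hypergeom(|universe|, |set ∩ universe|,
    |hits|), and the enrichment ratio is observed/expected overlap.
    """
    universe = set(universe)
    hits = set(hits)
    if not universe or not hits:
        raise ValueError("universe and hit list must be non-empty")
    if not hits <= universe:
        raise ValueError("hit list must be a subset of the universe")
    set_in_universe = set(gene_set) & universe
    overlap = len(hits & set_in_universe)
    M, K, n = len(universe), len(set_in_universe), len(hits)
    p = float(stats.hypergeom.sf(overlap - 1, M, K, n))
    expected = K * n / M
    return {
        "universe_size": M,
        "set_size": K,
        "n_hits": n,
        "overlap": overlap,
        "enrichment_ratio": overlap / expected if expected > 0 else float("nan"),
        "p": min(p, 1.0),
    }


def enrich_ora(hits, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """ORA of a hit list against every set of a collection, with BH FDR."""
    rows = []
    for name in sorted(collection.sets):
        rec = ora_hypergeometric(hits, collection[name], universe)
        rec["set"] = name
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_pathways(records: pd.DataFrame, *, fdr: float = 0.05,
                    top_n: int = 40, fdr_column: str = "fdr") -> pd.DataFrame:
    """Reporting filter: the union of the ``top_n`` lowest-FDR pathways and
    every pathway with FDR below the threshold."""
    ordered = records.sort_values([fdr_column, "set"], kind="stable")
    top = set(ordered.head(top_n)["set"])
    passing = set(records.loc[records[fdr_column] < fdr, "set"])
    keep = records["set"].isin(top | passing)
    return records.loc[keep].sort_values([fdr_column, "set"], kind="stable",
                                         ignore_index=True)
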