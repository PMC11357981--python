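"""Differential-variability statistics: per-phase CV, abundance-standardized
CV z-scores, and the shuffled-label permutation test of post-flight versus
pre-flight variability.

The procedure: for every analyte and mission-phase interval, compute the
coefficient of variation (population sd / mean) of its normalized
abundances.  Pool the (mean, CV) records of all intervals, split them into
approximately 100 equal-frequency mean-abundance bins (merged down when a
bin would hold fewer than 10 records), and record each bin's CV mean and
sd.  Each record's abundance-standardized CV is then the z-score of its CV
within its bin — removing the systematic mean-variance trend so that highly
variable analytes can be compared across the abundance range.  The
post-minus-pre difference of standardized CVs (delta-z) is tested by
re-running this entire chain on phase labels shuffled among the pooled
pre/post samples (10,000 shuffles by default), yielding a permutation
z-score and an empirical one-sided p with add-one smoothing.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phases import PHASES, POST_FLIGHT, PRE_FLIGHT, PhaseScheme, assign_phases, default_scheme
from .tables import FeatureTable

__all__ = [
    "coefficient_of_variation",
    "interval_cv",
    "QuantileReference",
    "build_quantile_reference",
    "standardize_cv",
    "permutation_delta_test",
    "rank_for_enrichment",
]

logger = logging.getLogger(__name__)


def coefficient_of_variation(values) -> float:
    """Population CV: ``np.std(x, ddof=0) / np.mean(x)``.

    Errors on empty input, non-finite values, or zero mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values")
    mean = np.mean(x)
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(np.std(x, ddof=0) / mean)


# ---------------------------------------------------------------------------
# interval CV records


def _pooled_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0)
    return mean, sd, X.shape[1]


def _per_subject_mean_stats(X: np.ndarray, subj: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray, int]:
    groups = [np.flatnonzero(subj == s) for s in np.unique(subj)]
    sub_means = np.column_stack([X[:, g].mean(axis=1) for g in groups])
    mean = sub_means.mean(axis=1)
    sd = sub_means.std(axis=1, ddof=0)
    return mean, sd, sub_means.shape[1]


def _cv_from(mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return cv


def interval_cv(table: FeatureTable, samples: pd.DataFrame,
                scheme: PhaseScheme | None = None, *,
                averaging_mode: str = "pooled",
                phases: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-analyte, per-phase mean and raw CV over the phase's samples.

    ``averaging_mode`` is ``"pooled"`` (CV over all subject x timepoint
    values in the phase; default) or ``"per_subject_mean"`` (average each
    subject's values within the phase first, then CV across subject means —
    the microbiome convention).  Only samples whose timepoint label is in
    the scheme's CV mask for the table's modality are used.  Records whose
    phase holds fewer than two usable values are flagged ``usable=False``
    (their CV is still reported when defined) and are meant to be excluded
    from reference building.

    Returns a DataFrame with columns
    ``analyte, phase, n, mean, cv, usable``.
    """
    if averaging_mode not in ("pooled", "per_subject_mean"):
        raise ValueError(f"unknown averaging_mode {averaging_mode!r}")
    scheme = scheme or default_scheme()
    info = assign_phases(samples, scheme)
    mask_labels = scheme.cv_labels(table.modality)
    info = info[info["timepoint_label"].isin(mask_labels)]
    info = info[info["sample_id"].isin(table.sample_ids)]
    wanted = phases or PHASES

    frames = []
    for phase in wanted:
        cols = info.loc[info["phase"] == phase, "sample_id"].tolist()
        if not cols:
            continue
        X = table.data[cols].to_numpy(dtype=float)
        if averaging_mode == "pooled":
            mean, sd, n = _pooled_stats(X)
        else:
            subj = info.set_index("sample_id").loc[cols, "subject_id"].to_numpy()
            mean, sd, n = _per_subject_mean_stats(X, subj)
        cv = _cv_from(mean, sd)
        frames.append(pd.DataFrame({
            "analyte": table.analyte_ids,
            "phase": phase,
            "n": n,
            "mean": mean,
            "cv": cv,
            "usable": (n >= 2) & np.isfinite(cv),
        }))
    if not frames:
        raise ValueError("no samples fall in the requested phases / CV mask")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# quantile reference and standardization


@dataclass
class QuantileReference:
    """Equal-frequency mean-abundance bins with per-bin CV mean and sd.

    ``edges`` holds the internal bin boundaries (length ``n_bins - 1``);
    assignment is half-open ``[low, high)`` with the last bin closed, and
    records outside the observed range clamp to the end bins.
    """

    edges: np.ndarray
    cv_mean: np.ndarray
    cv_sd: np.ndarray
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.cv_mean)

    def assign(self, means) -> np.ndarray:
        """Bin index for each mean (clamped to [0, n_bins - 1])."""
        return np.searchsorted(self.edges, np.asarray(means, dtype=float),
                               side="right")


def _bin_layout(n_records: int, n_bins: int, min_per_bin: int) -> int:
    if n_records < min_per_bin:
        warnings.warn(
            f"only {n_records} records for reference building (< {min_per_bin}); "
            "using a single degenerate bin", stacklevel=3)
        return 1
    if n_records / n_bins < min_per_bin:
        return max(1, n_records // min_per_bin)
    return n_bins


def _reference_from_sorted(means: np.ndarray, cvs: np.ndarray, n_bins: int,
                           min_per_bin: int):
    """Sort records by mean, split into equal-frequency bins, return
    (order, bin starts, per-bin cv mean, per-bin cv sd)."""
    order = np.argsort(means, kind="stable")
    n = len(order)
    n_eff = _bin_layout(n, n_bins, min_per_bin)
    # np.array_split layout: the first n % n_eff bins get one extra record
    base, rem = divmod(n, n_eff)
    sizes = np.full(n_eff, base)
    sizes[:rem] += 1
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    ends = starts + sizes
    cv_sorted = cvs[order]
    counts = sizes
    bmean = np.add.reduceat(cv_sorted, starts) / counts
    # two-pass variance: exact zeros for constant bins
    bin_of_sorted = np.repeat(np.arange(n_eff), sizes)
    resid = cv_sorted - bmean[bin_of_sorted]
    var = np.add.reduceat(resid ** 2, starts) / counts
    bsd = np.sqrt(var)
    # round-off residue of a constant bin is not real spread
    bsd[bsd <= 1e-9 * np.abs(bmean) + 1e-15] = 0.0
    return order, starts, ends, bmean, bsd


def build_quantile_reference(records: pd.DataFrame, n_bins: int = 100,
                             min_per_bin: int = 10) -> QuantileReference:
    """Build the phase-agnostic mean/CV reference from pooled CV records.

    Records flagged unusable or with undefined CV are excluded.  Bins are
    equal-frequency on mean abundance; the requested ``n_bins`` is reduced
    to ``n_records // min_per_bin`` (minimum 1) whenever it would leave
    fewer than ``min_per_bin`` records per bin.
    """
    use = records
    if "usable" in use.columns:
        use = use[use["usable"]]
    use = use[np.isfinite(use["mean"]) & np.isfinite(use["cv"])]
    if len(use) == 0:
        raise ValueError("no usable CV records for reference building")
    means = use["mean"].to_numpy(dtype=float)
    cvs = use["cv"].to_numpy(dtype=float)
    order, starts, _ends, bmean, bsd = _reference_from_sorted(
        means, cvs, n_bins, min_per_bin)
    sorted_means = means[order]
    edges = sorted_means[starts[1:]] if len(starts) > 1 else np.array([])
    counts = np.diff(np.append(starts, len(order)))
    if (bsd == 0).any():
        warnings.warn(
            f"{int((bsd == 0).sum())} reference bin(s) have zero CV sd; "
            "z-scores in those bins are undefined", stacklevel=2)
    return QuantileReference(edges=np.asarray(edges, dtype=float),
                             cv_mean=bmean, cv_sd=bsd, counts=counts)


def standardize_cv(records: pd.DataFrame, reference: QuantileReference) -> pd.DataFrame:
    """Attach quantile-bin index and standardized CV ``z = (CV - CVmean_q)/CVsd_q``.

    Bins with zero CV sd yield a missing z (NaN, never +/-inf).
    """
    out = records.copy()
    bins = reference.assign(out["mean"].to_numpy(dtype=float))
    m_q = reference.cv_mean[bins]
    s_q = reference.cv_sd[bins]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s_q > 0, (out["cv"].to_numpy(dtype=float) - m_q) / s_q, np.nan)
    out["bin"] = bins
    out["z"] = z
    return out


def _std_z_chain(means: np.ndarray, cvs: np.ndarray, n_bins: int,
                 min_per_bin: int) -> np.ndarray:
    """Standardized z for a flat record vector, reference rebuilt in place.

    Records are assigned to the bin they were sorted into (identical to the
    edge rule except for exact ties on a boundary).  Invalid records get
    NaN and are excluded from the reference.
    """
    z = np.full(len(means), np.nan)
    valid = np.isfinite(means) & np.isfinite(cvs)
    if valid.sum() == 0:
        return z
    vm = means[valid]
    vc = cvs[valid]
    order, starts, ends, bmean, bsd = _reference_from_sorted(vm, vc, n_bins, min_per_bin)
    bin_of_sorted = np.repeat(np.arange(len(starts)), ends - starts)
    bins = np.empty(len(vm), dtype=int)
    bins[order] = bin_of_sorted
    m_q = bmean[bins]
    s_q = bsd[bins]
    with np.errstate(divide="ignore", invalid="ignore"):
        zv = np.where(s_q > 0, (vc - m_q) / s_q, np.nan)
    z[valid] = zv
    return z


# ---------------------------------------------------------------------------
# permutation test


def _group_stats(X: np.ndarray, cols: np.ndarray, subj: np.ndarray | None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(mean, cv) per analyte over the given columns; subj enables
    per-subject-mean averaging."""
    sub = X[:, cols]
    if subj is None:
        mean, sd, n = _pooled_stats(sub)
    else:
        mean, sd, n = _per_subject_mean_stats(sub, subj[cols])
    if n < 2:
        return mean, np.full(len(mean), np.nan)
    return mean, _cv_from(mean, sd)


def permutation_delta_test(table: FeatureTable, samples: pd.DataFrame,
                           scheme: PhaseScheme | None = None, *,
                           phase_a: str = PRE_FLIGHT, phase_b: str = POST_FLIGHT,
                           n_perm: int = 10000, seed: int | None = None,
                           stratify_by_subject: bool = False,
                           averaging_mode: str = "pooled",
                           n_bins: int = 100, min_per_bin: int = 10,
                           exhaustive: bool = False) -> pd.DataFrame:
    """Shuffled-label permutation test of standardized-CV differences.

    The observed statistic per analyte is ``delta_z = z_b - z_a`` where z is
    the abundance-standardized CV of the phase interval, with the quantile
    reference built from all masked phases.  The null re-runs the entire
    interval-CV -> reference -> z chain on phase labels shuffled among the
    pooled phase-a/phase-b samples (globally, or within subject strata).
    ``exhaustive=True`` enumerates every distinct assignment instead (the
    observed one included; the empirical p is then the exact tail fraction
    without add-one smoothing).

    Returns one row per analyte:
    ``analyte, delta_z, null_mean, null_sd, perm_z, rank, p``
    with ``rank`` = number of null draws >= observed and
    ``p = (1 + rank) / (1 + n_perm)`` (one-sided, add-one rule).
    """
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scheme = scheme or default_scheme()
    info = assign_phases(samples, scheme)
    mask_labels = scheme.cv_labels(table.modality)
    info = info[info["timepoint_label"].isin(mask_labels)]
    info = info[info["sample_id"].isin(table.sample_ids)].reset_index(drop=True)

    cols_of = {}
    for phase in PHASES:
        ids = info.loc[info["phase"] == phase, "sample_id"].tolist()
        if ids:
            cols_of[phase] = ids
    for p in (phase_a, phase_b):
        if p not in cols_of:
            raise ValueError(f"phase {p!r} has no samples after masking")

    sample_order = [s for phase in cols_of for s in cols_of[phase]]
    X = table.data[sample_order].to_numpy(dtype=float)
    col_index = {s: i for i, s in enumerate(sample_order)}
    subj_codes = (info.set_index("sample_id").loc[sample_order, "subject_id"]
                  .astype("category").cat.codes.to_numpy())
    subj = subj_codes if averaging_mode == "per_subject_mean" else None
    if averaging_mode not in ("pooled", "per_subject_mean"):
        raise ValueError(f"unknown averaging_mode {averaging_mode!r}")

    idx_a = np.array([col_index[s] for s in cols_of[phase_a]])
    idx_b = np.array([col_index[s] for s in cols_of[phase_b]])
    other_phases = [p for p in cols_of if p not in (phase_a, phase_b)]
    fixed = [_group_stats(X, np.array([col_index[s] for s in cols_of[p]]), subj)
             for p in other_phases]

    n_analytes = X.shape[0]
    n_a, n_b = len(idx_a), len(idx_b)

    def delta(cols_a: np.ndarray, cols_b: np.ndarray) -> np.ndarray:
        mean_a, cv_a = _group_stats(X, cols_a, subj)
        mean_b, cv_b = _group_stats(X, cols_b, subj)
        means = np.concatenate([m for m, _ in fixed] + [mean_a, mean_b])
        cvs = np.concatenate([c for _, c in fixed] + [cv_a, cv_b])
        z = _std_z_chain(means, cvs, n_bins, min_per_bin)
        z_a = z[-2 * n_analytes:-n_analytes]
        z_b = z[-n_analytes:]
        return z_b - z_a

    observed = delta(idx_a, idx_b)
    pool = np.concatenate([idx_a, idx_b])

    if exhaustive:
        if stratify_by_subject:
            raise ValueError("exhaustive mode supports global shuffling only")
        assignments = list(itertools.combinations(range(len(pool)), n_b))
        null = np.empty((len(assignments), n_analytes))
        for k, picked in enumerate(assignments):
            sel = np.zeros(len(pool), dtype=bool)
            sel[list(picked)] = True
            null[k] = delta(pool[~sel], pool[sel])
        n_draws = len(assignments)
        with np.errstate(invalid="ignore"):
            rank = (null >= observed).sum(axis=0)
        p = rank / n_draws
    else:
        rng = np.random.default_rng(seed)
        null = np.empty((n_perm, n_analytes))
        if stratify_by_subject:
            strata = [np.flatnonzero(subj_codes[pool] == s)
                      for s in np.unique(subj_codes[pool])]
            b_flags = np.zeros(len(pool), dtype=bool)
            b_flags[n_a:] = True  # observed layout: a first, b second
            for k in range(n_perm):
                perm_flags = b_flags.copy()
                for g in strata:
                    perm_flags[g] = rng.permutation(perm_flags[g])
                null[k] = delta(pool[~perm_flags], pool[perm_flags])
        else:
            for k in range(n_perm):
                shuffled = rng.permutation(pool)
                null[k] = delta(shuffled[:n_a], shuffled[n_a:])
        n_draws = n_perm
        with np.errstate(invalid="ignore"):
            rank = (null >= observed).sum(axis=0)
        p = (1.0 + rank) / (1.0 + n_perm)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN analytes
        null_mean = np.nanmean(null, axis=0)
        null_sd = np.nanstd(null, axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)

    bad = ~np.isfinite(observed)
    p = p.astype(float)
    p[bad] = np.nan
    rank = rank.astype(float)
    rank[bad] = np.nan

    return pd.DataFrame({
        "analyte": table.analyte_ids,
        "delta_z": observed,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "perm_z": perm_z,
        "rank": rank,
        "p": p,
        "n_perm": n_draws,
    })


def rank_for_enrichment(results: pd.DataFrame, key: str = "perm_z") -> pd.DataFrame:
    """Order analytes for preranked enrichment: descending by ``key``,
    deterministic lexicographic tie-break on analyte id; analytes with a
    missing score are dropped (count logged)."""
    if len(results) == 0:
        raise ValueError("empty results")
    keep = results[np.isfinite(results[key])]
    dropped = len(results) - len(keep)
    if dropped:
        logger.info("rank_for_enrichment: dropped %d analytes with missing %s",
                    dropped, key)
    out = keep.sort_values([key, "analyte"], ascending=[False, True],
                           kind="stable", ignore_index=True)
    return out[["analyte", key]].rename(columns={key: "score"})
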