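import itertools

import numpy as np
import pandas as pd
import pytest

from astrovar.phases import assign_phases, default_scheme
from astrovar.tables import FeatureTable
from astrovar.variability import (QuantileReference, build_quantile_reference,
                                  coefficient_of_variation, interval_cv,
                                  permutation_delta_test, rank_for_enrichment,
                                  standardize_cv)

# ---------------------------------------------------------------------------
# independent oracles


def oracle_cv(values):
    x = list(map(float, values))
    mean = sum(x) / len(x)
    var = sum((v - mean) ** 2 for v in x) / len(x)
    return var ** 0.5 / mean


def oracle_bins(means, cvs, n_bins, min_per_bin):
    """Equal-frequency binning oracle: stable sort by mean, array_split
    layout, per-bin population mean/sd of CV."""
    n = len(means)
    if n < min_per_bin:
        n_eff = 1
    elif n / n_bins < min_per_bin:
        n_eff = max(1, n // min_per_bin)
    else:
        n_eff = n_bins
    order = sorted(range(n), key=lambda i: (means[i], i))
    chunks = np.array_split(order, n_eff)
    stats = []
    for chunk in chunks:
        vals = [cvs[i] for i in chunk]
        m = sum(vals) / len(vals)
        sd = (sum((v - m) ** 2 for v in vals) / len(vals)) ** 0.5
        stats.append((m, sd, len(vals)))
    return stats


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0

    def test_matches_population_formula(self):
        # sd = sqrt(8/3), mean = 4
        expected = (8.0 / 3.0) ** 0.5 / 4.0
        assert coefficient_of_variation([2, 4, 6]) == pytest.approx(expected,
                                                                    abs=1e-15)
        assert coefficient_of_variation([2, 4, 6]) == pytest.approx(0.408248,
                                                                    abs=1e-6)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            x = rng.uniform(0.5, 10, size=rng.integers(2, 12))
            assert coefficient_of_variation(x) == pytest.approx(oracle_cv(x),
                                                                abs=1e-12)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError, match="zero mean"):
            coefficient_of_variation([0, 0, 0])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([])


class TestIntervalCV:
    def test_pooled_mode_uses_all_phase_values(self, small_null_cohort):
        table, samples = small_null_cohort
        rec = interval_cv(table, samples)
        pre = rec[rec["phase"] == "pre_flight"]
        assert (pre["n"] == 12).all()  # 4 subjects x 3 pre-flight timepoints

    def test_pooled_mode_matches_groupby_oracle(self, small_null_cohort):
        table, samples = small_null_cohort
        rec = interval_cv(table, samples).set_index(["analyte", "phase"])
        info = assign_phases(samples)
        scheme = default_scheme()
        info = info[info["timepoint_label"].isin(scheme.cv_labels("rna_counts"))]
        for analyte in table.analyte_ids[:25]:
            for phase in ("pre_flight", "post_flight", "recovery"):
                cols = info.loc[info["phase"] == phase, "sample_id"]
                vals = table.data.loc[analyte, cols].to_numpy()
                row = rec.loc[(analyte, phase)]
                assert row["cv"] == pytest.approx(oracle_cv(vals), abs=1e-12)
                assert row["mean"] == pytest.approx(float(np.mean(vals)),
                                                    abs=1e-12)

    def test_per_subject_mean_with_identical_subject_means_is_zero(self):
        # two subjects, two pre-flight timepoints each, same subject means
        data = pd.DataFrame(
            [[1.0, 3.0, 4.0, 0.0]],
            index=["a"],
            columns=["C001_L-3", "C001_L-44", "C002_L-3", "C002_L-44"])
        samples = pd.DataFrame({
            "sample_id": data.columns,
            "subject_id": ["C001", "C001", "C002", "C002"],
            "timepoint_label": ["L-3", "L-44", "L-3", "L-44"],
            "day_offset": [-3, -44, -3, -44]})
        table = FeatureTable(data, modality="rna_counts", normalized=True)
        rec = interval_cv(table, samples, averaging_mode="per_subject_mean")
        assert rec.loc[rec["phase"] == "pre_flight", "cv"].iloc[0] == 0.0

    def test_in_flight_excluded_for_rna_but_not_microbiome(self, small_null_cohort):
        table, samples = small_null_cohort
        rec = interval_cv(table, samples)
        assert "in_flight" not in set(rec["phase"])
        micro = FeatureTable(table.data / table.data.sum(axis=0),
                             modality="microbiome_relabund", normalized=True)
        rec_m = interval_cv(micro, samples)
        in_flight = rec_m[rec_m["phase"] == "in_flight"]
        assert (in_flight["n"] == 8).all()  # FD2 + FD3 x 4 subjects


class TestQuantileReference:
    def _records(self, rng, n):
        return pd.DataFrame({
            "analyte": [f"a{i}" for i in range(n)],
            "phase": "pre_flight",
            "n": 12,
            "mean": rng.uniform(1, 100, size=n),
            "cv": rng.uniform(0.05, 1.0, size=n),
            "usable": True,
        })

    def test_1000_records_make_100_bins_of_10_matching_oracle(self, rng):
        rec = self._records(rng, 1000)
        ref = build_quantile_reference(rec, n_bins=100, min_per_bin=10)
        assert ref.n_bins == 100
        assert (ref.counts == 10).all()
        expected = oracle_bins(rec["mean"].tolist(), rec["cv"].tolist(), 100, 10)
        for q, (m, sd, c) in enumerate(expected):
            assert ref.cv_mean[q] == pytest.approx(m, abs=1e-10)
            assert ref.cv_sd[q] == pytest.approx(sd, abs=1e-10)
            assert ref.counts[q] == c

    def test_merge_rule_50_records_give_5_bins_of_10(self, rng):
        rec = self._records(rng, 50)
        ref = build_quantile_reference(rec, n_bins=100, min_per_bin=10)
        assert ref.n_bins == 5
        assert (ref.counts == 10).all()

    def test_constant_cv_gives_degenerate_bins(self, rng):
        rec = self._records(rng, 100)
        rec["cv"] = 0.3
        with pytest.warns(UserWarning, match="zero CV sd"):
            ref = build_quantile_reference(rec, n_bins=10, min_per_bin=10)
        assert np.allclose(ref.cv_mean, 0.3)
        assert (ref.cv_sd == 0).all()
        z = standardize_cv(rec, ref)
        assert z["z"].isna().all()  # sentinel missing, never +/-inf


class TestStandardize:
    REF = QuantileReference(edges=np.array([10.0]),
                            cv_mean=np.array([0.3, 0.6]),
                            cv_sd=np.array([0.1, 0.2]),
                            counts=np.array([5, 5]))

    def _rec(self, mean, cv):
        return pd.DataFrame({"analyte": ["x"], "phase": ["pre_flight"],
                             "n": [3], "mean": [mean], "cv": [cv],
                             "usable": [True]})

    def test_cv_equal_to_bin_mean_gives_zero(self):
        out = standardize_cv(self._rec(5.0, 0.3), self.REF)
        assert out["z"].iloc[0] == 0.0

    def test_stated_formula_arithmetic(self):
        out = standardize_cv(self._rec(5.0, 0.5), self.REF)
        assert out["z"].iloc[0] == pytest.approx(2.0)

    def test_half_open_bins_and_end_clamping(self):
        assert standardize_cv(self._rec(9.999, 0.3), self.REF)["bin"].iloc[0] == 0
        assert standardize_cv(self._rec(10.0, 0.3), self.REF)["bin"].iloc[0] == 1
        assert standardize_cv(self._rec(-5.0, 0.3), self.REF)["bin"].iloc[0] == 0
        assert standardize_cv(self._rec(1e9, 0.3), self.REF)["bin"].iloc[0] == 1

    def test_per_bin_z_is_centered_and_scaled(self, small_null_cohort):
        table, samples = small_null_cohort
        rec = interval_cv(table, samples)
        ref = build_quantile_reference(rec, n_bins=10, min_per_bin=10)
        z = standardize_cv(rec, ref)
        grouped = z.groupby("bin")["z"]
        assert grouped.mean().abs().max() < 0.1
        assert grouped.std(ddof=0).between(0.8, 1.2).all()


def oracle_exhaustive_delta(table, samples, n_bins, min_per_bin):
    """Brute-force oracle for the 2+2 exhaustive permutation test: enumerate
    every assignment of two samples to the post-flight label and re-run a
    straightforward implementation of the CV -> bins -> z chain."""
    cols = list(table.data.columns)

    def chain(cols_a, cols_b):
        rows = []
        for analyte in table.analyte_ids:
            for grp, cs in (("a", cols_a), ("b", cols_b)):
                vals = table.data.loc[analyte, cs].to_numpy()
                rows.append((analyte, grp, float(np.mean(vals)),
                             oracle_cv(vals)))
        means = [r[2] for r in rows]
        cvs = [r[3] for r in rows]
        stats = oracle_bins(means, cvs, n_bins, min_per_bin)
        order = sorted(range(len(rows)), key=lambda i: (means[i], i))
        chunks = np.array_split(order, len(stats))
        z = {}
        for q, chunk in enumerate(chunks):
            m, sd, _ = stats[q]
            for i in chunk:
                z[i] = (cvs[i] - m) / sd if sd > 0 else np.nan
        out = {}
        for i, (analyte, grp, _, _) in enumerate(rows):
            out.setdefault(analyte, {})[grp] = z[i]
        return {a: v["b"] - v["a"] for a, v in out.items()}

    obs = chain(cols[:2], cols[2:])
    deltas = []
    for picked in itertools.combinations(range(4), 2):
        b = [cols[i] for i in picked]
        a = [c for c in cols if c not in b]
        deltas.append(chain(a, b))
    p = {}
    for analyte in table.analyte_ids:
        null = [d[analyte] for d in deltas]
        p[analyte] = sum(v >= obs[analyte] for v in null) / len(null)
    return obs, p


class TestPermutationTest:
    def test_exhaustive_mode_matches_enumeration_oracle(self, tiny_table):
        table, samples = tiny_table
        res = permutation_delta_test(table, samples, exhaustive=True,
                                     n_bins=4, min_per_bin=2)
        obs, p = oracle_exhaustive_delta(table, samples, n_bins=4, min_per_bin=2)
        assert res["n_perm"].iloc[0] == 6
        for row in res.itertuples():
            assert row.delta_z == pytest.approx(obs[row.analyte], abs=1e-10)
            assert row.p == pytest.approx(p[row.analyte], abs=1e-12)

    def test_add_one_floor(self, small_null_cohort):
        table, samples = small_null_cohort
        res = permutation_delta_test(table, samples, n_perm=50, seed=1)
        assert (res["p"] >= 1 / 51 - 1e-12).all()
        assert (res["p"] <= 1.0).all()
        floor = res[res["rank"] == 0]
        if len(floor):
            assert np.allclose(floor["p"], 1 / 51)

    def test_identical_seed_identical_results(self, small_null_cohort):
        table, samples = small_null_cohort
        r1 = permutation_delta_test(table, samples, n_perm=30, seed=5)
        r2 = permutation_delta_test(table, samples, n_perm=30, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_different_seeds_differ(self, small_null_cohort):
        table, samples = small_null_cohort
        r1 = permutation_delta_test(table, samples, n_perm=30, seed=5)
        r2 = permutation_delta_test(table, samples, n_perm=30, seed=6)
        assert not np.allclose(r1["p"], r2["p"])

    def test_constant_table_gives_zero_delta_and_p_one(self):
        data = pd.DataFrame(np.full((3, 4), 7.0), index=["a", "b", "c"],
                            columns=["C001_L-3", "C002_L-3", "C001_R+1",
                                     "C002_R+1"])
        samples = pd.DataFrame({
            "sample_id": data.columns,
            "subject_id": ["C001", "C002", "C001", "C002"],
            "timepoint_label": ["L-3", "L-3", "R+1", "R+1"],
            "day_offset": [-3, -3, 4, 4]})
        table = FeatureTable(data, modality="rna_counts", normalized=True)
        res = permutation_delta_test(table, samples, exhaustive=True,
                                     n_bins=1, min_per_bin=1)
        # all CVs zero -> all z undefined... bins have sd 0 -> delta NaN
        # with identical values the chain degenerates; p must not be < 1
        assert ((res["p"].isna()) | (res["p"] == 1.0)).all()

    def test_stratified_mode_runs_and_is_deterministic(self, small_null_cohort):
        table, samples = small_null_cohort
        r1 = permutation_delta_test(table, samples, n_perm=20, seed=3,
                                    stratify_by_subject=True)
        r2 = permutation_delta_test(table, samples, n_perm=20, seed=3,
                                    stratify_by_subject=True)
        pd.testing.assert_frame_equal(r1, r2)

    def test_invalid_n_perm_errors(self, small_null_cohort):
        table, samples = small_null_cohort
        with pytest.raises(ValueError):
            permutation_delta_test(table, samples, n_perm=0)


class TestRankForEnrichment:
    def test_descending_order(self):
        res = pd.DataFrame({"analyte": ["x", "y"], "perm_z": [-1.0, 2.0]})
        out = rank_for_enrichment(res)
        assert out["analyte"].tolist() == ["y", "x"]

    def test_ties_break_lexicographically(self):
        res = pd.DataFrame({"analyte": ["b", "a", "c"],
                            "perm_z": [1.0, 1.0, 2.0]})
        out = rank_for_enrichment(res)
        assert out["analyte"].tolist() == ["c", "a", "b"]

    def test_missing_scores_dropped_with_accounting(self):
        res = pd.DataFrame({"analyte": ["a", "b", "c"],
                            "perm_z": [1.0, np.nan, 0.5]})
        out = rank_for_enrichment(res)
        assert len(out) == 2
        assert "b" not in set(out["analyte"])
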