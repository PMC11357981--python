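"""End-to-end orchestration: simulate -> normalize -> cv -> permtest ->
contrast -> enrich -> concordance -> report.

A run is driven by a single flat config (YAML or keyword overrides).  Every
output table carries a provenance header (tool version, seed, config hash)
and a machine-readable ``summary.json`` lists per-stage record counts.
Identical config and seed produce bitwise-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import accessibility_delta, concordance_test
from .contrasts import (call_degs, default_contrasts, differential_test,
                        profile_uniqueness_summary, reversal_classification,
                        shared_fraction)
from .enrichment import enrich_ora, enrich_preranked, filter_pathways
from .io import (read_feature_table, read_gmt, read_sample_info, write_feature_table,
                 write_gmt, write_sample_info)
from .normalize import normalize_counts, size_factors_median_ratio
from .simulate import (CohortConfig, ModalityConfig, Spike, generate_cohort,
                       generate_fragment_counts)
from .tables import GeneSetCollection
from .variability import (build_quantile_reference, interval_cv,
                          permutation_delta_test, rank_for_enrichment,
                          standardize_cv)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run.

    With ``table_path``/``samples_path`` unset, a synthetic cohort is
    generated carrying dispersion spike-ins (ground truth for the
    variability stage) and bidirectional post-flight mean spike-ins
    (ground truth for the contrast and concordance stages).
    """

    out_dir: str = "astrovar_run"
    seed: int = 0
    # synthetic cohort (used when no input table is given)
    n_analytes: int = 600
    n_dispersion_spikes: int = 30
    dispersion_effect: float = 3.0
    n_mean_spikes: int = 40
    mean_effect: float = 5.0
    spike_half_life: float = 10.0
    phi: float = 0.05
    sigma_subject: float = 0.1
    # optional real inputs
    table_path: str | None = None
    samples_path: str | None = None
    modality: str = "rna_counts"
    gmt_path: str | None = None
    # statistics
    n_perm: int = 10000
    n_bins: int = 100
    min_per_bin: int = 10
    alpha: float = 0.05
    lfc_threshold: float = 0.5
    averaging_mode: str = "pooled"
    stratify_by_subject: bool = False
    enrich_n_perm: int = 1000
    n_gene_sets: int = 20
    gene_set_size: int = 25
    promoter_halfwidth: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.table_path, self.samples_path, self.gmt_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.lfc_threshold < 0 or self.n_perm < 1 or self.n_bins < 1:
            raise ValueError("thresholds out of range")

    def config_hash(self) -> str:
        # out_dir does not affect results, so it is excluded from the hash
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"astrovar {__version__}",
        f"seed={config.seed}",
        f"config_hash={config.config_hash()}",
    ]


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in _provenance(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _demo_cohort(config: RunConfig):
    ids = [f"G_{i + 1:05d}" for i in range(config.n_analytes)]
    spikes = []
    for a in ids[: config.n_dispersion_spikes]:
        spikes.append(Spike(analyte=a, dispersion_effect=config.dispersion_effect,
                            half_life=config.spike_half_life))
    mean_ids = ids[config.n_dispersion_spikes:
                   config.n_dispersion_spikes + config.n_mean_spikes]
    for j, a in enumerate(mean_ids):
        effect = config.mean_effect if j % 2 == 0 else 1.0 / config.mean_effect
        spikes.append(Spike(analyte=a, mean_effect=effect,
                            half_life=config.spike_half_life))
    cohort = CohortConfig(
        modalities={"rna_counts": ModalityConfig(n_analytes=config.n_analytes,
                                                 phi=config.phi)},
        sigma_subject=config.sigma_subject,
        spikes={"rna_counts": tuple(spikes)},
        seed=config.seed,
    )
    return generate_cohort(cohort)


def _synthetic_sets(universe: list[str], truth: pd.DataFrame,
                    config: RunConfig) -> GeneSetCollection:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5e75]))
    sets: dict[str, list[str]] = {}
    disp = truth.loc[truth["dispersion_effect"] > 1, "analyte"].tolist()
    if disp:
        sets["SPIKED_DISPERSION"] = sorted(disp)
    mean_spiked = truth.loc[truth["mean_effect"] != 1, "analyte"].tolist()
    if mean_spiked:
        sets["SPIKED_MEAN"] = sorted(mean_spiked)
    for k in range(config.n_gene_sets):
        members = rng.choice(universe, size=min(config.gene_set_size, len(universe)),
                             replace=False)
        sets[f"RANDOM_{k + 1:03d}"] = sorted(members)
    return GeneSetCollection(sets=sets)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s ...", name)
        return t0

    # -- simulate / load ------------------------------------------------
    t0 = stage("simulate")
    if config.table_path is None:
        tables, samples, truth = _demo_cohort(config)
        table = tables["rna_counts"]
        write_feature_table(table, out / "counts.tsv", header_lines=_provenance(config))
        write_sample_info(samples, out / "samples.tsv")
        _write_tsv(truth, out / "spike_truth.tsv", config)
    else:
        table = read_feature_table(config.table_path, config.modality)
        samples = read_sample_info(config.samples_path)
        truth = pd.DataFrame(columns=["modality", "analyte", "phase", "mean_effect",
                                      "dispersion_effect", "half_life", "rebound"])
    summary["stages"]["simulate"] = {
        "n_analytes": table.shape[0], "n_samples": table.shape[1],
        "n_spikes": len(truth), "seconds": round(time.perf_counter() - t0, 2)}

    # -- normalize ------------------------------------------------------
    t0 = stage("normalize")
    if table.modality == "rna_counts" and not table.normalized:
        factors = size_factors_median_ratio(table)
        normed = normalize_counts(table, factors)
        factors.to_frame().reset_index(names="sample_id").pipe(
            _write_tsv, out / "size_factors.tsv", config)
    else:
        normed = table
    write_feature_table(normed, out / "normalized.tsv",
                        header_lines=_provenance(config))
    summary["stages"]["normalize"] = {
        "n_analytes": normed.shape[0], "seconds": round(time.perf_counter() - t0, 2)}

    # -- cv -------------------------------------------------------------
    t0 = stage("cv")
    records = interval_cv(normed, samples, averaging_mode=config.averaging_mode)
    reference = build_quantile_reference(records, n_bins=config.n_bins,
                                         min_per_bin=config.min_per_bin)
    records_z = standardize_cv(records, reference)
    _write_tsv(records_z, out / "cv_records.tsv", config)
    summary["stages"]["cv"] = {
        "n_records": len(records_z), "n_bins": reference.n_bins,
        "seconds": round(time.perf_counter() - t0, 2)}

    # -- permutation test ----------------------------------------------
    t0 = stage("permtest")
    perm = permutation_delta_test(
        normed, samples, n_perm=config.n_perm, seed=config.seed,
        averaging_mode=config.averaging_mode,
        stratify_by_subject=config.stratify_by_subject,
        n_bins=config.n_bins, min_per_bin=config.min_per_bin)
    _write_tsv(perm, out / "permutation.tsv", config)
    ranked = rank_for_enrichment(perm)
    _write_tsv(ranked, out / "ranked.tsv", config)
    summary["stages"]["permtest"] = {
        "n_analytes": len(perm), "n_perm": config.n_perm,
        "seconds": round(time.perf_counter() - t0, 2)}

    # -- preranked enrichment -------------------------------------------
    t0 = stage("enrich")
    if config.gmt_path is not None:
        collection = read_gmt(config.gmt_path)
    else:
        collection = _synthetic_sets(table.analyte_ids, truth, config)
        write_gmt(collection, out / "sets.gmt")
    scores = ranked.set_index("analyte")["score"]
    enr = enrich_preranked(scores, collection, n_perm=config.enrich_n_perm,
                           seed=config.seed)
    _write_tsv(enr, out / "enrichment_preranked.tsv", config)
    summary["stages"]["enrich"] = {
        "n_sets": len(enr), "seconds": round(time.perf_counter() - t0, 2)}

    # -- contrasts ------------------------------------------------------
    t0 = stage("contrast")
    registry = default_contrasts()
    deg_sets: dict[str, set[str]] = {}
    diff_records: dict[str, pd.DataFrame] = {}
    for name, spec in registry.items():
        rec = differential_test(normed, samples, spec)
        diff_records[name] = rec
        deg_sets[name] = call_degs(rec, alpha=config.alpha,
                                   lfc_threshold=config.lfc_threshold)
        _write_tsv(rec, out / f"differential_{name}.tsv", config)
    with open(out / "deg_sets.tsv", "w", newline="") as fh:
        for line in _provenance(config):
            fh.write(f"# {line}\n")
        for name in registry:
            for a in sorted(deg_sets[name]):
                fh.write(f"{name}\t{a}\n")

    profile_rows = []
    fp1 = deg_sets["FP1"]
    fp1_lfc = diff_records["FP1"].set_index("analyte")["log2fc"]
    for name in ("RP1", "RP2", "LP2"):
        target = deg_sets[name]
        tgt_lfc = diff_records[name].set_index("analyte")["log2fc"]
        both = sorted(fp1 & target)
        classes = [reversal_classification(fp1_lfc[a], tgt_lfc[a]) for a in both]
        n_rev = sum(c == "reversed" for c in classes)
        profile_rows.append({
            "reference": "FP1", "target": name,
            "shared_fraction": (shared_fraction(fp1, target) if fp1 else np.nan),
            "n_both": len(both),
            "reversed_fraction": n_rev / len(both) if both else np.nan,
            "persistent": ",".join(a for a, c in zip(both, classes)
                                   if c == "persistent"),
        })
    profiles = pd.DataFrame(profile_rows)
    _write_tsv(profiles, out / "profile_comparison.tsv", config)
    nonempty = {k: v for k, v in deg_sets.items() if v}
    if len(nonempty) >= 2:
        uniq = profile_uniqueness_summary(nonempty)
        summary["uniqueness"] = dataclasses.asdict(uniq)
    summary["stages"]["contrast"] = {
        "deg_counts": {k: len(v) for k, v in deg_sets.items()},
        "seconds": round(time.perf_counter() - t0, 2)}

    # -- ORA on FP1 DEGs ------------------------------------------------
    t0 = stage("ora")
    if fp1:
        ora = enrich_ora(fp1, collection, table.analyte_ids)
        ora = filter_pathways(ora, fdr=config.alpha)
        _write_tsv(ora, out / "enrichment_ora.tsv", config)
        summary["stages"]["ora"] = {
            "n_sets_reported": len(ora),
            "seconds": round(time.perf_counter() - t0, 2)}

    # -- promoter concordance -------------------------------------------
    t0 = stage("concordance")
    genes = table.analyte_ids
    tss = pd.DataFrame({
        "gene_id": genes,
        "chrom": "chr1",
        "tss": 10_000 * (1 + np.arange(len(genes))),
        "strand": "+",
    })
    fp1_rec = diff_records["FP1"].copy()
    fp1_rec["deg"] = fp1_rec["analyte"].isin(fp1)
    coupling = {r.analyte: float(r.log2fc)
                for r in fp1_rec.itertuples() if r.deg}
    frag = generate_fragment_counts(tss, coupling, seed=config.seed)
    write_feature_table(frag, out / "promoter_counts.tsv",
                        header_lines=_provenance(config))
    delta = accessibility_delta(frag, "baseline", "comparison")
    n_up = int(((fp1_rec["deg"]) & (fp1_rec["log2fc"] > 0)).sum())
    n_down = int(((fp1_rec["deg"]) & (fp1_rec["log2fc"] < 0)).sum())
    if n_up >= 2 and n_down >= 2:
        conc = concordance_test(delta, fp1_rec[["analyte", "log2fc", "deg"]])
        _write_tsv(conc.per_gene, out / "concordance_per_gene.tsv", config)
        summary["concordance"] = {
            "p": conc.p, "rho": conc.rho, "n_up": conc.n_up, "n_down": conc.n_down}
    else:
        summary["concordance"] = {
            "skipped": f"insufficient DEG strata (up={n_up}, down={n_down})"}
    summary["stages"]["concordance"] = {
        "n_genes": len(delta), "seconds": round(time.perf_counter() - t0, 2)}

    # timing is process-dependent; keep it out of the deterministic artifact
    deterministic = json.loads(json.dumps(summary))
    for st in deterministic["stages"].values():
        st.pop("seconds", None)
    with open(out / "summary.json", "w", newline="") as fh:
        json.dump(deterministic, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
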