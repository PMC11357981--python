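"""Seeded synthetic multi-omic longitudinal cohort generator.

Emulates a small spaceflight cohort (default four subjects, ten timepoints
spanning pre-flight, flight, immediate post-flight and recovery) across
several assay modalities, with the three statistical features the
downstream analysis assumes:

* a count-like mean-variance relationship: for analyte *i* with baseline
  mean ``m_i = exp(mu_i)``, the abundance-scale coefficient of variation is
  approximately ``sqrt(1/m_i + phi)`` (Poisson-like at low abundance,
  dispersion-dominated at high abundance);
* per-subject multiplicative random effects (log-normal, sd ``sigma_subject``);
* configurable spike-in perturbations: selected analytes have their mean
  and/or noise level multiplied within one mission phase, after which the
  perturbation decays exponentially (configurable half-life) with an
  optional homeostatic rebound that overshoots baseline before slowly
  returning (see :class:`Spike`).

Values are log-normal draws: ``x = exp(mu_i + b_s + delta_it + eps)`` with
``eps ~ N(0, (d_it * sigma_i)^2)``, ``sigma_i = sqrt(log1p(cv_i^2))``.  The
same generator serves count (RNA) and intensity (protein/metabolite)
modalities; microbiome tables are column-renormalized to relative
abundances.  One global seed expands into independent per-modality child
seeds derived from the modality name, so adding a modality never perturbs
the draws of another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phases import DEFAULT_TIMEPOINTS, POST_FLIGHT, PhaseScheme, default_scheme
from .tables import FeatureTable

__all__ = [
    "ModalityConfig",
    "Spike",
    "CohortConfig",
    "generate_cohort",
    "generate_fragment_counts",
]


@dataclass(frozen=True)
class ModalityConfig:
    """Per-modality generator settings.

    ``log_mean_loc``/``log_mean_scale`` parameterize the natural-log
    baseline-mean distribution ``mu_i ~ N(loc, scale^2)``; ``phi`` is the
    high-abundance dispersion floor of the CV law ``sqrt(1/m + phi)``.
    """

    n_analytes: int = 500
    log_mean_loc: float = float(np.log(20.0))
    log_mean_scale: float = 1.5
    phi: float = 0.05
    prefix: str = "G"

    def __post_init__(self) -> None:
        if self.n_analytes < 1:
            raise ValueError("n_analytes must be >= 1")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")


@dataclass(frozen=True)
class Spike:
    """A ground-truth perturbation of one analyte in one mission phase.

    ``mean_effect`` multiplies the abundance mean and ``dispersion_effect``
    multiplies the log-scale noise standard deviation while the affected
    phase lasts.  Afterwards the log-mean displacement follows a
    decay-plus-rebound time course in days since the end of the phase::

        A(t) = (1 + rebound) * 2**(-t/half_life)
             - rebound * 2**(-t/rebound_half_life)

    which starts at the full effect, crosses baseline, undershoots by up to
    ~``rebound`` of the original log-effect and relaxes back with the slower
    ``rebound_half_life``.  ``rebound = 0`` gives pure exponential decay.
    The dispersion excess decays with ``half_life`` and never rebounds.
    """

    analyte: str
    phase: str = POST_FLIGHT
    mean_effect: float = 1.0
    dispersion_effect: float = 1.0
    half_life: float = 10.0
    rebound: float = 1.5
    rebound_half_life: float = 35.0

    def __post_init__(self) -> None:
        if self.mean_effect <= 0 or self.dispersion_effect <= 0:
            raise ValueError("spike effects must be > 0")
        if self.half_life <= 0 or self.rebound_half_life <= 0:
            raise ValueError("spike half-lives must be > 0")
        if self.rebound < 0:
            raise ValueError("rebound must be >= 0")


@dataclass
class CohortConfig:
    n_subjects: int = 4
    timepoints: tuple[tuple[str, int], ...] = DEFAULT_TIMEPOINTS
    modalities: dict[str, ModalityConfig] = field(default_factory=lambda: {
        "rna_counts": ModalityConfig(n_analytes=2000, prefix="G"),
        "protein_intensity": ModalityConfig(
            n_analytes=400, log_mean_loc=float(np.log(1000.0)),
            log_mean_scale=1.2, phi=0.10, prefix="PROT"),
        "metabolite_intensity": ModalityConfig(
            n_analytes=250, log_mean_loc=float(np.log(500.0)),
            log_mean_scale=1.2, phi=0.15, prefix="MET"),
        "cytokine": ModalityConfig(
            n_analytes=50, log_mean_loc=float(np.log(50.0)),
            log_mean_scale=1.0, phi=0.20, prefix="CYT"),
        "microbiome_relabund": ModalityConfig(
            n_analytes=150, log_mean_loc=float(np.log(10.0)),
            log_mean_scale=1.8, phi=0.30, prefix="s__Taxon"),
    })
    sigma_subject: float = 0.1
    spikes: dict[str, tuple[Spike, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sigma_subject < 0:
            raise ValueError("sigma_subject must be >= 0")


def _child_seed(seed: int, tag: str) -> np.random.SeedSequence:
    """Derive a per-stream seed from the global seed and a stable name hash."""
    digest = hashlib.sha256(tag.encode()).digest()
    return np.random.SeedSequence([int(seed), int.from_bytes(digest[:4], "big")])


def _spike_scalars(spike: Spike, label_phase: dict[str, str],
                   day: dict[str, int]) -> dict[str, tuple[float, float]]:
    """Per-timepoint (log-mean shift, dispersion multiplier) for a spike."""
    phase_days = [day[l] for l, p in label_phase.items() if p == spike.phase]
    if not phase_days:
        raise ValueError(f"spike phase {spike.phase!r} has no timepoints")
    phase_end = max(phase_days)
    log_a = float(np.log(spike.mean_effect))
    out: dict[str, tuple[float, float]] = {}
    for label, p in label_phase.items():
        t = day[label]
        if p == spike.phase:
            out[label] = (log_a, spike.dispersion_effect)
        elif t > phase_end:
            dt = t - phase_end
            amp = (1.0 + spike.rebound) * 2.0 ** (-dt / spike.half_life) \
                - spike.rebound * 2.0 ** (-dt / spike.rebound_half_life)
            disp = 1.0 + (spike.dispersion_effect - 1.0) * 2.0 ** (-dt / spike.half_life)
            out[label] = (log_a * amp, disp)
        else:
            out[label] = (0.0, 1.0)
    return out


def generate_cohort(config: CohortConfig, scheme: PhaseScheme | None = None,
                    ) -> tuple[dict[str, FeatureTable], pd.DataFrame, pd.DataFrame]:
    """Generate the cohort.

    Returns ``(tables, samples, spike_truth)`` where ``tables`` maps each
    configured modality to a :class:`FeatureTable`, ``samples`` is the
    sample sheet (one row per subject x timepoint) and ``spike_truth``
    records every injected perturbation.  Identical config (including seed)
    yields bitwise-identical output.
    """
    scheme = scheme or default_scheme()
    subjects = [f"C{i + 1:03d}" for i in range(config.n_subjects)]
    labels = [l for l, _ in config.timepoints]
    day = {l: d for l, d in config.timepoints}
    label_phase = {l: scheme.phase_of(l) for l in labels}

    samples = pd.DataFrame(
        [
            {
                "sample_id": f"{s}_{l}",
                "subject_id": s,
                "timepoint_label": l,
                "day_offset": day[l],
            }
            for s in subjects
            for l in labels
        ]
    )
    sample_ids = samples["sample_id"].tolist()
    tp_of_sample = samples["timepoint_label"].to_numpy()
    subj_index = samples["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()

    tables: dict[str, FeatureTable] = {}
    truth_rows: list[dict] = []
    for modality in sorted(config.modalities):
        mcfg = config.modalities[modality]
        rng = np.random.default_rng(_child_seed(config.seed, f"modality:{modality}"))
        n = mcfg.n_analytes
        analytes = [f"{mcfg.prefix}_{i + 1:05d}" for i in range(n)]
        mu = rng.normal(mcfg.log_mean_loc, mcfg.log_mean_scale, size=n)
        m = np.exp(mu)
        sigma = np.sqrt(np.log1p(1.0 / m + mcfg.phi))  # log-scale sd giving CV law

        b = rng.normal(0.0, config.sigma_subject, size=(n, config.n_subjects))
        # per-value spike scalars
        shift = np.zeros((n, len(sample_ids)))
        disp = np.ones((n, len(sample_ids)))
        for spike in config.spikes.get(modality, ()):  # order as configured
            if spike.analyte not in analytes:
                raise ValueError(
                    f"spike references unknown analyte {spike.analyte!r} in {modality}"
                )
            i = analytes.index(spike.analyte)
            per_tp = _spike_scalars(spike, label_phase, day)
            for j, tp in enumerate(tp_of_sample):
                ds, dd = per_tp[tp]
                shift[i, j] += ds
                disp[i, j] *= dd
            truth_rows.append({
                "modality": modality,
                "analyte": spike.analyte,
                "phase": spike.phase,
                "mean_effect": spike.mean_effect,
                "dispersion_effect": spike.dispersion_effect,
                "half_life": spike.half_life,
                "rebound": spike.rebound,
            })

        eps = rng.normal(0.0, 1.0, size=(n, len(sample_ids)))
        log_x = mu[:, None] + b[:, subj_index] + shift + disp * sigma[:, None] * eps
        values = np.exp(log_x)
        df = pd.DataFrame(values, index=analytes, columns=sample_ids)
        if modality == "microbiome_relabund":
            df = df / df.sum(axis=0)
            tables[modality] = FeatureTable(df, modality=modality, normalized=True)
        else:
            tables[modality] = FeatureTable(df, modality=modality, normalized=False)

    truth = pd.DataFrame(truth_rows, columns=[
        "modality", "analyte", "phase", "mean_effect", "dispersion_effect",
        "half_life", "rebound"])
    return tables, samples, truth


def generate_fragment_counts(tss: pd.DataFrame, coupling: dict[str, float], *,
                             groups: tuple[str, str] = ("baseline", "comparison"),
                             base_rate_log_loc: float = float(np.log(50.0)),
                             base_rate_log_scale: float = 0.8,
                             seed: int = 0) -> FeatureTable:
    """Generate promoter-window fragment counts for two sample groups.

    ``coupling`` maps gene id -> expression log2FC tracked by accessibility
    (0 means uncoupled).  Baseline counts are Poisson with a per-gene
    log-normal rate; the comparison group's rate for a coupled gene is
    shifted by ``2**log2FC``, so accessibility moves in the direction of the
    expression change.  Genes in ``coupling`` absent from ``tss`` are an
    error.  Deterministic under a fixed seed.
    """
    genes = list(tss["gene_id"])
    unknown = sorted(set(coupling) - set(genes))
    if unknown:
        raise ValueError(f"coupling references genes absent from TSS annotation: {unknown}")
    rng = np.random.default_rng(_child_seed(seed, "fragment_counts"))
    rate = np.exp(rng.normal(base_rate_log_loc, base_rate_log_scale, size=len(genes)))
    lfc = np.array([coupling.get(g, 0.0) for g in genes])
    counts_a = rng.poisson(rate).astype(float)
    counts_b = rng.poisson(rate * 2.0 ** lfc).astype(float)
    df = pd.DataFrame({groups[0]: counts_a, groups[1]: counts_b}, index=genes)
    return FeatureTable(df, modality="fragment_counts", normalized=False)


def null_config(n_analytes: int = 1000, *, phi: float = 0.05, seed: int = 0,
                sigma_subject: float = 0.1) -> CohortConfig:
    """A single-modality RNA cohort with no spikes (null configuration)."""
    return CohortConfig(
        modalities={"rna_counts": ModalityConfig(n_analytes=n_analytes, phi=phi)},
        sigma_subject=sigma_subject,
        seed=seed,
    )


def spiked_config(n_analytes: int, spikes: tuple[Spike, ...], *, phi: float = 0.05,
                  seed: int = 0, sigma_subject: float = 0.1) -> CohortConfig:
    """A single-modality RNA cohort carrying the given spike list."""
    return CohortConfig(
        modalities={"rna_counts": ModalityConfig(n_analytes=n_analytes, phi=phi)},
        sigma_subject=sigma_subject,
        spikes={"rna_counts": spikes},
        seed=seed,
    )
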