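# Methods

## Setting and data model

The package targets longitudinal cohorts that are deep in time but tiny in
subjects: by default four subjects sampled at ten timepoints spanning
pre-flight (L-92, L-44, L-3), flight (FD1–FD3), immediate post-flight
(R+1) and recovery (R+45, R+82, R+194). All statistics operate on
analyte × sample matrices (`FeatureTable`) tagged with an assay modality;
a `PhaseScheme` maps timepoint labels to the four mission phases and
carries a per-modality mask restricting which timepoints enter
CV-interval computations. The default mask uses pre-flight, R+1 and
R+45/R+82; microbiome modalities additionally include FD2 and FD3.
R+194 is mapped to the recovery phase (so contrasts can use it) but is
excluded from the default CV mask. Timepoint labels are opaque strings;
Unicode dash variants ("L−44") are folded to ASCII ("L-44") because
source tables mix both.

## Normalization

- RNA counts: median-of-ratios size factors. Reference analytes are those
  with no zero count; each sample's factor is the median over reference
  analytes of the log-ratio to the per-analyte geometric mean (even counts
  take the log-space midpoint), exponentiated and rescaled to geometric
  mean 1. Note that scaling one sample's counts by *c* necessarily shifts
  the pseudo-reference by c^(1/m); all relative structure is invariant but
  absolute values pick up that single global factor — this is a property
  of the estimator, not an implementation artifact.
- Microbiome: per-sample relative abundance (columns sum to 1), with
  per-subject averaging before CV computation (`per_subject_mean` mode).
- Intensity modalities (proteomics, metabolomics): log2(x + 1) with
  per-sample median centering — a deliberately simple, documented stand-in
  recorded in output provenance.
- Accessibility: counts per million.

## Abundance-standardized CV and the permutation test

Per analyte and phase interval, `CV = std(x, ddof=0)/mean(x)` (population
sd). The mean–variance trend is removed by an equal-frequency binning of
all (mean abundance, CV) records pooled across phases: records are stably
sorted by mean and split into `n_bins` (default 100) contiguous bins in
`np.array_split` layout; whenever `n_records/n_bins < min_per_bin`
(default 10) the bin count is reduced to `n_records // min_per_bin`
(minimum 1). Each bin contributes its CV mean and population sd;
`z = (CV − CVmean_q)/CVsd_q`. Records used to build a reference are
assigned to the bin they were sorted into; external records are assigned
by half-open boundary intervals with end-bin clamping (permuted
recomputations can shift means slightly). Bins whose two-pass sd falls
below a 1e-9 relative threshold are reported as exactly degenerate and
yield a missing z (never ±inf); missing values propagate, never become 0.

The post-vs-pre test statistic is Δz = z_post − z_pre. Its null is built
by shuffling phase labels among the pooled pre/post samples — globally by
default, optionally within subject strata (the exchangeability unit is not
uniquely determined by the design; both are offered) — and re-running the
entire interval-CV → reference → z chain per shuffle, 10,000 times by
default. Reported per analyte: Δz, the null mean/sd, the permutation
z-score (obs − null mean)/null sd, the rank (number of null draws ≥
observed) and the one-sided add-one p = (1 + rank)/(1 + n_perm). A
two-sided view is available through |Δz|. An exhaustive mode enumerates
every distinct label assignment (the observed one included; p is then the
exact tail fraction without add-one smoothing) and is used by the tests
against a direct-enumeration oracle. The ranked list for enrichment is
ordered by permutation z, descending, ties broken lexicographically by
analyte id.

## Recovery-profile contrasts

The contrast registry defaults to FP1 = pre vs R+1, RP1 = pre vs R+45,
RP2 = pre vs R+82, LP1 = pre vs {R+45, R+82}, LP2 = pre vs R+82 (only
LP2's composition is fixed by definition; the others are overridable
defaults, and RP2/LP2 coincide under them). Differential testing is a
two-sided Wilcoxon rank-sum per analyte. The exact null distribution is
used whenever the pooled sample count is ≤ 30 and there are no ties; the
midrank normal approximation with continuity correction is used above.
The switch point matters: at 12-vs-4 the normal approximation cannot
produce p below 0.0044, which Benjamini–Hochberg over thousands of
analytes can never call — the exact distribution (minimum p = 2/1820)
keeps the DEG machinery operable at exactly the cohort sizes this package
targets. `log2FC = log2((mean_cmp + ε)/(mean_base + ε))` with ε = 1 for
counts (0 and a plain mean difference for log-scale inputs). DEGs satisfy
strict `adjusted p < 0.05` and `|log2FC| > 0.5`; tightening either
threshold can only remove calls.

Profile analytics: the shared fraction |target ∩ FP1|/|target|
(reference-normalized optionally; an empty denominator reports NaN, not
0); reversal classification by log2FC sign between FP1 and a recovery
profile; and unique-vs-shared membership counts across groups with
percentages printed to one decimal.

## Enrichment

Preranked mode computes the weighted running-sum enrichment score:
walking down the ranking, +|score|^w / Σ_hits |score|^w at members,
−1/(N − n_hits) at non-members; ES is the signed extremum (default w = 1;
w = 0 reduces to the classical two-sample Kolmogorov–Smirnov statistic on
hit/miss ranks, which the tests verify against an independent KS
implementation). The null permutes gene labels: ES of random same-size
member sets (per-set child seeds derived from the set name, so results do
not depend on collection order). NES = ES / mean(|null ES| of matching
sign); p is the add-one tail among matching-sign draws; q is BH across
sets. Overrepresentation uses the exact hypergeometric upper tail of the
hit/set overlap within the universe, with the enrichment ratio
observed/expected, BH FDR, and the reporting rule "top 40 lowest FDR ∪
FDR < 0.05".

## Promoter concordance

Genomic intervals are 0-based half-open throughout; "TSS ± 500 bp" is the
1,001-position window [tss − 500, tss + 501), clamped at the chromosome
start and strand-independent by symmetry. Window accessibility sums
fragment counts with any-position overlap (a fragment abutting the
half-open end is excluded), accepts either BED-like fragment records or a
precomputed gene × condition count table, CPM-normalizes, and takes
log2((cpm_b + 1)/(cpm_a + 1)). The concordance test is a one-sided
rank-sum that up-regulated DEGs gained more promoter accessibility than
down-regulated DEGs, with a Spearman correlation of delta vs expression
log2FC reported alongside.

## Synthetic cohort generator

Values are log-normal: `x = exp(μ_i + b_s + δ_it + ε)` with
`ε ~ N(0, (d_it σ_i)²)` and `σ_i = sqrt(log1p(1/m_i + φ))`, so the
abundance-scale CV follows the count-like law `sqrt(1/mean + φ)`. One
generator serves count and intensity modalities because the CV pipeline
consumes normalized continuous values either way. Defaults, chosen once
as representative of the assays they emulate: RNA log-mean
μ ~ N(ln 20, 1.5²) with φ = 0.05 (mean counts spanning ~1–400, CV from
~1 down to ~0.22); proteomic/metabolomic/cytokine modalities use higher
abundance locations and dispersion floors (φ = 0.10–0.30); subject
random-effect sd σ_subj = 0.1 (≈10% between-subject level differences).
The global seed expands into per-modality child streams keyed by a hash
of the modality name, so adding a modality never perturbs another's
draws; identical configs are bitwise-reproducible.

Spike-ins perturb one analyte in one phase: the mean is multiplied by
`mean_effect` and the log-scale noise sd by `dispersion_effect` (so a 3×
dispersion spike approximately triples the CV at high abundance — a
multiplier on φ alone would leave low-abundance spikes invisible beneath
Poisson-like noise, defeating their ground-truth purpose). After the
affected phase the log-mean displacement follows a decay-plus-rebound
time course,

```
A(t) = (1 + r)·2^(−t/h) − r·2^(−t/h_r),
```

*t* in days since the phase end, half-life h (default 10 d), rebound
amplitude r (default 1.5) and rebound half-life h_r (default 35 d). The
rebound term models homeostatic overshoot: recovering analytes do not
merely relax to baseline but cross it, which is what makes fold-change
directions *reverse* between the immediate post-flight contrast and the
recovery contrasts — the qualitative signature the recovery-profile
analytics are designed to detect. With the defaults, a 5× post-flight
spike shows ≈ +2.3 log2FC at R+1, ≈ −1.2 at R+45 (re-crossing the DEG
threshold with the opposite sign) and a sub-threshold residual by R+82;
`rebound=0` restores pure exponential decay. The dispersion excess decays
with h and never rebounds.

The fragment-count generator draws Poisson window counts with per-gene
log-normal rates; coupled genes shift the comparison-group rate by
2^(expression log2FC), providing ground truth for the concordance test.

What the generator does *not* emulate: sequencing-level counts (values
are continuous log-normal, not integer), compositional coupling between
analytes (except the microbiome column renormalization), real effect
sizes or taxa, batch structure, missingness, or autocorrelated
within-phase dynamics. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under a
controlled data-generating process, not performance on real astronaut
data.

## Problem sizes and observed behaviour

The test suite and the acceptance script run desk-scale versions of each
analysis: calibration at 1,000 analytes × 500 shuffles, decoupling and
spike studies at 2,000 analytes, end-to-end determinism on a 300-analyte
run with 200 shuffles. The paper-scale defaults (10,000 shuffles, 100
bins) remain the CLI defaults.

Observed, for orientation (seed-stable within ±0.01–0.05):

- null rejection rate at α = 0.05: ≈ 0.04–0.05 (calibrated);
- Spearman(mean, raw CV) ≈ −0.75 vs |Spearman(mean, z)| < 0.04
  (standardization removes the abundance trend);
- 3× dispersion spikes (100/2,000) reach the top decile of the
  variability ranking with frequency ≈ 0.6 (permutation-z ranking; ≈ 0.7
  ranking by raw Δz). This is an honest ceiling of the design, not a bug:
  the post-flight interval contains only four samples, and even an
  optimal log-scale variance statistic at n = 4 (9·χ²₃ vs χ²₃ against a
  top-decile threshold) cannot exceed ≈ 0.85 recall, while 4-sample CV
  estimates of a heavy-tailed log-normal are strongly attenuated (median
  observed CV ratio ≈ 1.8 for a true 3.3×) and spiked records inflate
  their own bins' CVsd_q. Detecting variance changes from four
  observations is intrinsically low-powered; rankings should be read as
  enrichment input, not as a classifier.
- recovery profiles under 5× spikes with 10-day half-life: ≈ 140 FP1 DEGs,
  0 LP2 DEGs, and a reversal fraction of 1.0 among FP1 ∩ RP1 DEGs.

## Numerical and degenerate-input conventions

- Population (ddof = 0) standard deviations everywhere in the CV chain,
  including bin statistics.
- Zero-mean vectors: CV undefined → error in the scalar API, missing
  record in the tabular API.
- Stable sorts with explicit tie-breaks (analyte id) wherever order
  affects output; all RNG through `numpy.random.default_rng` with
  explicitly derived child seeds.
- Empty DEG denominators, zero-sd bins and sign-free enrichment nulls all
  produce flagged missing values rather than silent zeros or infinities.
- Output TSVs carry `# astrovar <version> / seed / config hash` headers;
  `summary.json` omits wall-clock timings so identical runs are
  byte-identical.
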