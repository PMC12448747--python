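# Methods

This note documents the statistical models behind `levelscan`, the defaults
that matter, and what the synthetic generators do and do not emulate.

## Sorting-screen model and scoring

**Generator.** Each dual-guide cassette infects a lognormal number of cells
(σ = 0.5 on the log scale, mean `cells_per_guide`, default 1000 — roughly
the per-element coverage of a compact genome-wide library sorted at ~20M
cells).  A cell's reporter level is Normal(effect(gene), 1): a minimal
unit-variance model whose only free quantity is the per-gene shift in
within-cell SDs.  Bins are gated at the pooled population quantiles
(`sort_fraction` = 0.25 by default, i.e. top/bottom quarters), matching FACS
gating on the total population rather than per-genotype.  Each bin is
sequenced to a fixed depth by a multinomial over cassettes weighted by their
cells in the bin — sequencing a fixed library amount — so per-bin counts sum
exactly to `reads_per_bin`.  A fraction `recombination_rate` of emitted read
pairs takes guide B from an independently drawn cassette (weighted by bin
abundance), emulating lentiviral template switching; recombination back onto
the same cassette, or onto another cassette of the same gene, is
undetectable by the same-gene rule, so the observable recombinant fraction
sits slightly below the nominal rate.

**Parser.** A call is kept iff both guides target the same gene.
Non-targeting (NT) guides all map to one sentinel gene, so NT–NT
recombinants are indistinguishable from intact NT cassettes and are kept;
unknown guide ids are tallied separately, never silently dropped.  Counts
aggregate by guide A's cassette; same-gene cross-cassette pairs are
attributed there too.

**Guide test.** Cassettes with mean count below 10 across the compared bins
are removed (threshold configurable).  Median-ratio size factors (reference
= geometric-mean row over cassettes with no zeros; total-count fallback
below 100 usable rows) put bins on a common scale.  Note the median-ratio
formula pins the global scale only up to a factor c^(1/n) when one sample is
rescaled by c; within a table, a sample with exactly doubled counts gets a
doubled size factor and identical normalized values.  Each cassette is then
tested against a negative binomial with mean μ = normalized low-bin count
(floored at the 0.5 pseudocount) and variance from a trend
var(μ) = μ + k·μ^b fitted by regressing log(var − mean)⁺ on log(mean)
across cassettes, falling back to Poisson when the fit degenerates.
`p_high` = P(X ≥ high) tests enrichment, `p_low` = P(X ≤ high) depletion;
LFC uses a symmetric 0.5 pseudocount.

**Gene aggregation (RRA).** All cassettes — NT included — are ranked by the
directional p (ties broken by cassette id; percentile rank (r − 0.5)/N).
Per gene, only guides with p < α (default 0.25) contribute; the score is
ρ = min over j of P(Beta(j, m − j + 1) ≤ r₍ⱼ₎), the best prefix of the Beta
order-statistic tail probabilities.  Significance comes from a guide-label
permutation null: m cassettes drawn without replacement from the ranked
background, scored identically, with the +1 correction so the smallest
attainable p is 1/(n_perm + 1).  This discrete null makes exhaustive
enumeration over all C(N, m) subsets an exact oracle on small instances; at
screen scale it is indistinguishable from drawing m uniform ranks.  Two
consequences worth knowing: (i) with α < 1, genes with no selected guide
score ρ = 1, putting a legitimate point mass at p = 1 (the null-calibration
test therefore uses α = 1, where p is uniform); (ii) on tiny backgrounds
the null can redraw a top gene's own ranks, lifting its p slightly above
the floor.  NT cassettes are never merged into genes; optionally they are
grouped in stable id order into pseudo-genes of the library's guide
multiplicity as an empirical false-positive readout.  The per-gene summary
takes effect = median guide LFC and p = 2·min(p_neg, p_pos) capped at 1.

## Fixed-effects meta-analysis

Screens report effects on incomparable scales, so each screen is harmonized:
p truncated to [1e−300, 1 − 1e−16] (float64 representability; truncation is
conservative for the extreme tail), z = sign(effect)·Φ⁻¹(1 − p/2) (a
one-sided flag is available), β optionally z-scored within screen
(scale-only, preserving sign), SE = |β/z| with zero-effect rows given a
weight-0 sentinel.  Pooling is inverse-variance with one common effect:
β̂ = Σwβ/Σw, SE = (Σw)^(−1/2), w = 1/SE².  Cochran's Q (df = k − 1) and
I² = max(0, (Q − df)/Q) are reported but never switch the model to random
effects.  All screen subsets of size ≥ 2 are pooled; genes missing from a
screen are pooled over the screens that contain them, with a coverage
column making this auditable.  BH q-values are computed within each subset.

A gene is **novel** when q_meta < 0.05 while every constituent screen's own
BH q is ≥ 0.05; genes missing a constituent q are ineligible and flagged.
Screens designated *effect-filtered* (reporter screens whose effects are
LFCs) additionally require the gene's effect to deviate from the screen
mean by ≥ 1.  BH is applied uniformly to constituent screens — whatever
correction their original publications used is not reconstructed.  The
novelty filter runs after pooling.

Term enrichment is the upper-tail hypergeometric test; the permutation FDR
draws `n_perm` (default 1000) random hit sets of the same size and reports
the mean null-to-observed discovery ratio at each observed p, clamped to
[0, 1].

## Pulse-SILAC turnover

At steady state a protein with half-life T has heavy/light ratio
R* = 2^(t_s/T) − 1 after labeling time t_s; inverting gives
t½ = t_s·ln 2 / ln(1 + R).  Default label times follow a day-5 media switch:
2 days (day-7 harvest) or 10 days (day-15).  Peptide filters: contaminants;
total (light + heavy) intensity < 1000 (per-channel mode available); ratio
outside [0.01, 100] — boundaries kept, strict inequalities.  Duplicate
peptide sequences (charge states, repeat identifications) collapse to their
median ratio, then protein half-life is the harmonic mean over unique
peptides.  Half-lives are computed per replicate and contrasted afterwards
(pooling replicates first is possible by relabeling), with Welch t-tests on
log2 half-lives and BH correction; volcano cut-offs default to
|log2 FC| ≥ 0.5, p < 0.05 for half-lives and |log2 FC| ≥ 1 for abundances.

The generator draws true half-lives log-uniform on [0.5, 30] days (the
range over which single-time-point estimation at t_s = 2 is informative)
and 3–15 peptides per protein, with a mean-one lognormal multiplier on R
whose CV is `ratio_noise_cv`.  With CV = 0 the pipeline returns truth to
machine precision; with CV = 20% the per-peptide half-life error is roughly
(R/((1+R)·ln(1+R)))·CV, largest for long-lived proteins, and averaging over
≥ 3 peptides brings the median protein-level error under 5%.  Contaminants,
out-of-range ratios, and sub-floor intensities are injected at configured
fractions (the intensity-floor fraction is a generator knob the filters are
tested against) and flagged in the truth so filter behavior is verifiable.

## RNA-seq chain

Counts are assumed gene-length-normalized upstream.  Within-sample CPM,
then log2 after a pedestal of 2 (stabilizing low counts), then cyclic loess
across samples: for each sample pair a lowess trend of M vs A (frac 0.3) is
fitted and half subtracted from each member; corrections from all pairs are
accumulated and applied together at the end of the iteration, scaled by
2/n, which removes a constant per-sample offset exactly in one iteration
and makes the result independent of pair ordering (the smoother is linear
in M, so the update is symmetric under swapping a pair).  Three iterations
leave a second full pass changing values by < 1e−3 median absolute.

The noise filter computes per-condition gene means and CVs on the
linearized scale (2^value − pedestal; log-scale CV available), fits a
lowess CV trend against log10(mean) — expression spans orders of magnitude,
so the bandwidth must be multiplicative — and sets the noise threshold
where the fitted trend falls below a ceiling of median(CV) + 2·MAD(CV)
(plain MAD, linearly interpolated crossing).  A gene is removed only when
its mean is below the threshold in *every* condition.  Differential testing
is Welch t + BH on the surviving genes, with an exact-equality fast path
for zero-variance genes.  Outlier samples are reported (PCA distance
flags), never removed automatically.

Junction classification follows fixed rules on the PSI table: cryptic gain
when ΔΨ > 0.10 and the junction is present (PSI > 0.01, configurable
detection floor) in < 5% of control samples; cryptic loss when ΔΨ < −0.10
and present in > 10% of controls; other |ΔΨ| > 0.10 events are significant
but non-cryptic.  PolyA events are lengthening/shortening at |cFC| ≥ 0.25
(inclusive) and FDR < 0.05 (exclusive).

## Orchestration

`levelscan run --config run.yaml` validates the config against a schema
(unknown keys and out-of-range values rejected before any computation),
executes stages in order, and writes a manifest with parameters, seeds, the
package version, and sha256 checksums of every output.  One global seed
fans out per stage as `SeedSequence(seed, spawn_key=(stage_index,))`, so a
stage is reproducible in isolation.  Malformed TSV inputs fail with the
file and offending line identified.

## What the generators do not emulate

Synthetic data reproduces the statistical structure the methods assume —
quantile-sorting enrichment, correlated screen effects, steady-state
labeling, group-structured PSI, NB counts with a decreasing dispersion
trend — not the full messiness of real data: no read-level sequencing
errors or FASTQ synthesis (guide calls are post-demultiplexing), no
batch/library-preparation effects, no correlated peptide ionization or
missing-value structure, no transcript-model-level splice complexity
(classifying cryptic exons vs intron retention needs transcript models and
is out of scope), and effect sizes are homogeneous within a run unless
configured otherwise.  Passing tests therefore demonstrate correctness of
the computations and calibration under the assumed models, not robustness
to artifacts those models exclude.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen to make the
measured properties statistically meaningful: 500-gene screens at 500×
per-cassette depth (≈ 2M read pairs), 5000-gene null calibrations,
2000-gene meta and expression fixtures, 500-protein turnover panels.  The
differential-expression recovery checks run in a low-dispersion regime
(NB dispersion 0.01): with 3–4 replicates the Welch–Satterthwaite df is
2–5, which bounds attainable p-values and makes ≥ 90% recovery at BH
q < 0.05 a property of the low-noise regime, not of the trend-dispersion
default.  p-values are clipped to (tiny, 1]; permutation p-values use the
+1 correction; BH is delegated to statsmodels and cross-checked against a
brute-force step-up in the tests.
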