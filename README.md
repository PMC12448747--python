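# levelscan

Analytics for experiments that ask *"which genes set the level of a reporter
protein?"* — built around four readouts commonly combined in iPSC-derived
neuron studies of protein homeostasis:

1. **Dual-guide CRISPRi FACS screens.** Cells carrying two sgRNAs against
   the same gene are sorted into high/low reporter-fluorescence quantile
   bins; the per-cassette read-count shift between bins reveals modifier
   genes. `levelscan` parses guide-pair calls (removing lentiviral
   recombinants whose two guides target different genes), tests each
   cassette with a one-sided negative-binomial model, and aggregates guides
   to genes by robust rank aggregation (RRA) with a permutation null.
2. **Fixed-effects meta-analysis across screens.** Per-gene summaries from
   heterogeneous screens are harmonized (z = sign(β)·Φ⁻¹(1 − p/2),
   SE = |β/z|, extreme p truncated) and pooled by inverse-variance weighting
   for every screen subset, with Cochran's Q / I² heterogeneity and a
   *novelty* flag for genes significant only after pooling.
3. **Pulse-SILAC protein turnover.** After a switch to heavy-isotope media,
   the heavy/light ratio R at labeling time t_s gives a single-time-point
   half-life t½ = t_s·ln 2 / ln(1 + R) per peptide; protein half-lives are
   harmonic means over unique peptides, contrasted between conditions with
   Welch t-tests on log2 half-lives.
4. **RNA-seq filtering and event classification.** CPM → pedestal-2 log2 →
   cyclic loess normalization, a CV~mean noise model that removes
   noise-biased genes per condition, Welch differential testing, and
   rule-based classifiers for cryptic splice junctions (ΔΨ > 10% present in
   < 5% of controls) and alternative-polyadenylation events
   (|cFC| ≥ 0.25, FDR < 0.05).

Every input family has a synthetic generator with known ground truth
(`levelscan.synthetic_data`), so the whole pipeline is testable at desk
scale without any external accession.

## Worked example

Simulate a sorted-bin screen with 200 genes (10 true hits at −1 reporter SD,
10% guide recombination), then score it end to end:

```python
import levelscan as ls

cfg = ls.ScreenSimConfig(
    n_genes=200, guides_per_gene=4, n_control_guides=40,
    frac_true_hits=0.05, effect_size_sd_units=-1.0,
    reads_per_bin=420_000, recombination_rate=0.10, seed=7,
)
calls, counts, truth, library = ls.simulate_sorting_screen(cfg)
result = ls.score_screen(calls, library, high=["high"], low=["low"],
                         n_perm=1000, seed=8, nt_pseudogene_size=4)
print(f"reads removed as recombined: {result['tally']['recombined']}")
scores = result["gene_scores"]
print(scores.sort_values("fdr_neg").head(3)
      [["gene", "gene_lfc", "p_neg", "fdr_neg"]].to_string(index=False))
hits = set(truth.gene[truth.true_effect < 0])
detected = set(scores.gene[(scores.fdr_neg < 0.05) & ~scores.is_control])
print(f"recall: {len(detected & hits)}/{len(hits)}")
```

prints

```
reads removed as recombined: 83519
    gene  gene_lfc    p_neg  fdr_neg
GENE0011 -3.722197 0.000999 0.020979
GENE0044 -3.666377 0.000999 0.020979
GENE0060 -3.793704 0.000999 0.020979
recall: 10/10
```

About 10% of the 840k emitted read pairs are recombinants and are removed
before counting.  The three strongest depleted genes reach the permutation
floor p = 1/(n_perm + 1) ≈ 0.001 with strongly negative guide log-fold
changes, and all 10 planted hits are recovered at FDR < 0.05 with none of
the non-targeting pseudo-genes called.

The same stages are available from the shell (`levelscan simulate screen`,
`levelscan screen score`, `levelscan meta run`, `levelscan silac halflife`,
`levelscan rnaseq filter`, `levelscan splice classify`,
`levelscan polya classify`) or as a multi-stage YAML run
(`levelscan run --config run.yaml`), which writes a manifest with parameter
values, derived seeds and output checksums.

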