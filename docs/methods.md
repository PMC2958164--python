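# Methods

`crossarray` implements an analysis pipeline for cross-species microarray
experiments: RNA from a species without its own chip is hybridized on a
related species' array, sequence divergence degrades probe affinity unevenly,
and only a minority of probesets yield a quantifiable signal. The pipeline
compensates for the resulting loss of per-gene reliability by deferring all
statistical inference to the pathway level.

## Pipeline

Stages, in order:

1. **Presence filtering.** Each intensity comes with a per-chip
   present/absent call (Affymetrix letters `P`/`A`/`M` or binary `1`/`0`;
   `M`, marginal, is treated as absent because weak cross-species signal is
   uninterpretable). Only probesets called present on *every* chip are
   analysed: a low signal cannot distinguish an inactive gene from a probe
   that simply does not match the foreign transcript. When no calls file is
   given, presence defaults to intensity > 0, which lets synthetic matrices
   omit one.

2. **Quantile normalization with a smoothed reference.** The reference
   quantile vector G is the mean of the samples' order statistics (the
   average sample distribution of the data set). Each sample's value at rank
   k is replaced by G[k] — the standard rank-substitution direction
   G⁻¹(F(x)), with ties receiving the mean of the reference values at their
   tied ranks (deterministic and symmetric). Because the reference is built
   from few informative probesets over few replicates, it is noisy; it is
   therefore smoothed with a seven-point, order-2 Savitzky–Golay filter
   (classical interior weights (−2,3,6,7,6,3,−2)/21; edge points come from
   the off-center evaluation of the edge window's least-squares fit, so no
   values are fabricated beyond the observed range). Smoothing can locally
   break the monotonicity a distribution function requires, so a
   pool-adjacent-violators isotonic repair follows. The filter order is
   configurable (default 2); `smooth=False` disables the whole step.

3. **J5 selection with jackknife.** For a pairwise group contrast,
   J5(g) = (mean_a(g) − mean_b(g)) / ((1/N) Σ_j |mean_a(j) − mean_b(j)|),
   so mean |J5| = 1 by construction and the default threshold 4 selects
   probesets whose contrast is four times the array-wide average. J5 is a
   *selection score*, not a test: no per-gene p-values are computed and no
   gene-level multiple-testing correction is applied. Selection is
   two-tailed (both elevated and lowered expression). With three replicates
   per group a single aberrant chip can push a probe over the threshold, so
   four jackknife rounds each drop one sample per group (round-robin in
   label order, wrapping, after an optional seeded shuffle) and a probeset
   must clear the threshold on the full data and in every round. Scores are
   computed on normalized linear-scale intensities; this makes J5
   intensity-weighted — bright probes carry more absolute difference — which
   is a property of the statistic itself, not an artifact of this
   implementation. Three age-ordered contrasts are run (oldest−youngest,
   oldest−middle, middle−youngest; e.g. A−P, A−J, J−P for pup/juvenile/adult
   groups) and their selected lists partitioned into the seven regions of a
   three-set Venn diagram.

4. **Pathway over-representation.** Probes collapse to gene symbols by the
   any-probe rule (a gene is differential if any of its probes is selected;
   unmapped probes are dropped and counted in the log). For each pathway the
   tail probability P(X ≥ r) of a hypergeometric(N, n, R) draw is computed,
   with N the universe size, n the pathway's genes in the universe, R the
   differential genes, r the overlap. P-values are Benjamini–Hochberg
   adjusted per contrast across all tested pathways. The **universe** is the
   detected transcriptome — genes present on all chips — not the whole chip
   or database: cross-species hybridization silences much of the array, and
   counting never-measurable genes in the background would be
   anti-conservative. For the same reason the pathway size n counts only
   universe genes. A `universe="full"` mode (all annotated probes on the
   chip) exists for comparison. Per-pathway −log10 p profiles across the
   three contrasts are assembled into a comparison matrix; under the
   assumption that noise has the same technical nature in all contrasts,
   these profiles indicate relative pathway activity across ages.

## Synthetic data generator

The generator exists so that every stage — and the end-to-end claim that
pathway-level inference survives cross-species degradation — is testable
without any external data. It draws

intensity(p, s) = affinity(p) · baseline(p) · effect(gene(p), group(s)) · noise(p, s)

with per-probe affinity ~ Beta(α, β) on [0, 1] (cross-species hybridization
efficiency), per-probe lognormal baseline, gene-level multiplicative group
effects for the genes of the planted pathways, and lognormal replicate
noise. Presence is `intensity > detect_floor`, standing in for an external
presence-call algorithm. Effects act at gene level while affinity acts at
probe level, so tests can distinguish recovery of planted biology from
probe dropout.

Default conditions (one generated experiment):

| parameter | default | meaning |
|---|---|---|
| n_genes / probes_per_gene | 10,000 / 1 | chip size |
| groups | P, J, A × 3 | three age groups, three biological replicates |
| n_pathways / pathway_size | 200 / 10–40 genes | gene-set collection |
| n_planted | 5 | pathways given age-graded effects |
| effect_multipliers | (1.0, 1.6, 2.5) | monotone P < J < A profile; 1.6 ≈ geometric midpoint |
| affinity α, β | 2, 2 | symmetric, mean 0.5 hybridization efficiency |
| baseline_log_mean / sd | 6.0 / 0.6 | lognormal intensities, hundreds of fluorescence units |
| noise_sd | 0.1 | ~10% replicate CV |
| detect_floor | 150 | ≈ half the probes present on all nine chips |

`baseline_log_sd` and `noise_sd` describe the *detected* subpopulation of a
cross-species chip, not a whole healthy array: probes near background have
already been removed by the presence filter, which compresses the dynamic
range of what remains. This matters because linear-scale J5 is
intensity-weighted: with a multi-decade dynamic range, the brightest null
probes' noise differences dominate the selection tail and the three contrast
lists decouple into noise-driven singletons, which is not the age-graded,
largely nested list structure this kind of experiment shows (the largest
list between the extreme ages, the smallest between adjacent young ages, and
the triple overlap as the dominant Venn region). The defaults were fixed,
once, at values that reproduce that regime together with the ~50%
presence-filter survival; they are conditions of the simulation study, not
fitted quantities.

What the generator does **not** emulate: sequence-level cross-hybridization
(a probe picking up the wrong transcript), probe-pair (PM/MM) structure,
within-group biological heterogeneity beyond lognormal noise, correlated
expression within pathways under the null, and RNA degradation. Passing
recovery tests therefore show that the pipeline's logic is sound under the
stated generative model — not that real cross-species data meet that model.

## Numerical choices

- Quantile-normalization ties: mean of the reference values at the tied
  ranks, computed per tie group (not interpolation at the average rank).
- Savitzky–Golay needs at least `window` points and an odd window; the
  smoothed reference is isotonic-repaired with L2 pool-adjacent-violators.
- The hypergeometric tail is evaluated with the survival function of the
  exact distribution (no normal approximation); `r = 0` returns exactly 1.
- J5 requires a strictly positive array-wide mean absolute difference;
  identical group means everywhere raise a degenerate-input error rather
  than returning 0/0.
- The jackknife with `iterations = 0` reduces to plain thresholding;
  dropping requires ≥ 2 samples per group, enforced only when rounds run.
- All randomness (generator, jackknife shuffle) flows from a single seed;
  identical configuration and seed give bit-identical outputs, including
  the pipeline's `report.json`.

## Design choices that were genuinely open

- **Direction of the normalization map.** The rank-substitution direction
  (replace each sample's k-th order statistic with the reference's k-th
  quantile) is the standard one and the one implemented; the alternative
  reading (mapping reference ranks through the sample's inverse CDF) would
  invert it and does not yield a common target distribution.
- **Jackknife resampling plan.** Deterministic round-robin (round k drops
  sample k mod group size from each group) covers every sample once rounds
  reach the group size and is reproducible; an optional seeded shuffle
  decouples the plan from input order.
- **Threshold on |J5|, not signed J5** — both directions of change are
  biologically relevant.
- **Enrichment universe = detected genes** (see above); exposed as a switch
  because a full-chip universe is the convention of some commercial tools.
- **BH per contrast**, not jointly across contrasts: each contrast is its
  own family of pathway hypotheses.

## Problem sizes used in the checks

The automated checks run the default 10,000-probe experiment over 20 seeds
for recovery and Venn-structure properties, a 200-run null calibration at
2,000 probes / 50 pathways, exhaustive hypergeometric enumeration up to
N = 20, and from-definition J5/jackknife re-computation on a grid of small
matrices (≤ 10 probes, ≤ 4 samples per group). These sizes make every
stochastic property an average over many independent data sets while one
full run of the suite stays in the tens of seconds.

## Known limitations

- Linear-scale J5 favors bright probesets; a log-scale switch would change
  which genes are selected (deliberately not the default, since the method
  normalizes intensities, not log-intensities).
- Presence calls are consumed, not computed: the probe-level algorithms that
  produce P/A/M calls from probe-pair data are out of scope.
- Pathway p-values depend strongly on the universe definition; numbers
  produced with a proprietary database universe are not comparable to the
  detected-universe defaults here.
- The empirical FDR of *gene-level* selection is uncontrolled by design —
  the method is deliberately liberal at gene level and relies on pathway
  aggregation for error control.
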