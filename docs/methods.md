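# Methods

## The meta-analytic model

The pipeline treats each of E independent case/control expression
experiments as a noisy vote on whether a gene is dysregulated. The only
cross-experiment quantity carried forward is the binary call, which makes
the method robust to platform-specific effect scales at the cost of
discarding effect sizes — there is deliberately no random-effects pooling of
fold changes.

For gene g, let `n_pos(g)` be the number of experiments that called g (up or
down) and `n_neg(g)` the number that measured g without calling it.
Direction is intentionally ignored in the tally ("dysregulated" counts both
ways); per-direction counts are kept in the output for inspection. The
meta-statistic is a two-sided Fisher exact test of

```
[[n_pos(g), n_neg(g)], [N_pos − n_pos(g), N_neg − n_neg(g)]]
```

where `N_pos, N_neg` sum over all genes; the focal gene is excluded from the
background row. Under the null that g behaves like a typical gene, its votes
are exchangeable with the pool; a small p flags a gene called far more often
than the background rate. The test is exact and, being discrete with a small
gene-row margin (≤ E), conservative — the null fraction of p < α is well
below α, which the calibration benchmark confirms.

Two-sided p-values use the minimum-likelihood rule (sum of hypergeometric
probabilities of all same-margin tables no more likely than the observed
one, with a 1e-7 relative tie tolerance, matching common practice). The pmf
is evaluated in log space through the t-factor reduction
`C(t,k)·∏(m−i)·∏(N−m−i)/∏(N−i)` with t = gene-row total, so backgrounds of
10⁶ votes cost thirteen log terms, not factorials; agreement with exact
rational enumeration is ~1e-14 worst-case relative error.

The candidate threshold defaults to the fixed family-wise constant
P < 1×10⁻⁵ conventional for a ~30,663-gene universe (note 0.05/30,663 ≈
1.6×10⁻⁶; the fixed constant is the field's printed convention, and
`bonferroni_exact` recomputes 0.05/G for purists).

## Per-experiment calling (SAM)

The two-class unpaired SAM statistic is `d = r/(s + s0)` with
`r = mean(case) − mean(control)` and
`s = sqrt(((1/n1 + 1/n2)/(n1 + n2 − 2)) (SS_case + SS_ctrl))`.
`s0` is selected over the percentiles {0, 5, …, 100} of s by minimising the
coefficient of variation of the median absolute deviations of d within 100
quantile bins of s (ties to the smallest candidate; if all s are equal that
value is returned).

The null reference is B unrestricted label permutations (B = 100 by default;
designs with fewer than B distinct case assignments switch to full
enumeration). With `d̄_(i)` the mean permuted order statistics, the up-cut is
the smallest **nonnegative** ordered d with `d_(i) − d̄_(i) ≥ Δ` and the
down-cut the largest nonpositive one with `d_(i) − d̄_(i) ≤ −Δ`; the sign
restriction matters — an excursion above the expected order statistic deep
in the opposite tail must not set the cutoff, or a pure-null dataset ends up
with a mid-distribution cutoff and half the genome called. Estimated
FDR(Δ) = π̂₀ · median permuted exceedance / observed call count, with
π̂₀ = min(1, 2·#{d in the permuted IQR}/G) and FDR ≡ 0 for empty call sets.
Δ is the smallest grid value (40 points spanning the observed deviations)
whose running-minimum FDR path meets the target; the running minimum keeps
the reported path monotone in Δ. Per-gene q-values are the smallest FDR at
which the gene enters the call set along that grid.

The per-experiment significance criterion (delta at median-FDR ≤ 0.05) is a
package default, configurable; a Welch-t/BH engine is provided as a sanity
cross-check and agrees with SAM at Jaccard ≥ 0.8 on strong planted signals.

## Synthetic compendium generator

`generate_compendium` emulates the study design the pipeline targets:
13 experiments totalling 251 cases and 428 controls (split as evenly as
possible; the complementary 428/251 split is available via
`swap_case_control`, and per-experiment sizes are overridable), a gene
universe with per-experiment Bernoulli(coverage) platform membership, and
log2 intensities `N(μ_g, σ_g²)` with `μ_g ~ N(8, 1.5²)` and
`σ_g = 0.5·sqrt(4/χ²₄)` — a scaled inverse-chi-square that produces the
low-variance genes motivating the fudge factor. Planted genes carry a fixed
per-gene sign (so "consistently dysregulated" is well defined) and are
active per experiment with probability `activity_prob`, shifting case means
by `effect_size·σ_g`. All draws flow from one seed with fixed per-experiment
substream offsets, so any experiment regenerates identically in isolation.

What the generator does **not** emulate: probe-level effects, normalisation
artifacts, batch structure, correlated genes, heavy-tailed noise, or
missing values. Passing benchmarks therefore demonstrate correctness of the
machinery and calibration under the stated noise model, not performance on
real arrays.

Benchmark scale: the calibration and recovery experiments run at a
2,000-gene universe (the full 679-sample, 13-experiment design otherwise
unchanged) with B = 100 permutations — the gene dimension only affects
Monte-Carlo resolution here, and 2,000 genes resolve call rates to ~0.5%.

## Downstream statistics

*Enrichment* is the plain hypergeometric upper tail P(X ≥ k) with BH (or
Bonferroni) adjustment; no modified/EASE score, no ontology-graph
propagation — terms are treated as flat sets from a GMT file. *Hub ranking*
is degree centrality on the candidate-induced subgraph after deduplicating
parallel edges and dropping self-loops; top ties are flagged rather than
silently broken. Edge provenance is opaque user input.

*IHC grading* maps percent-positive cells to grades via breakpoints
<5 → 0, ≤30 → 1, ≤70 → 2, else 3; the stated rubric leaves (30, 31) percent
unassigned and the closed lower breakpoints make the mapping total and
monotone. The chi-square is uncorrected Pearson on the table after dropping
all-zero rows/columns (df from the reduced shape). The bundled 92-patient
H3K27me3 cohort reproduces its printed pathology statistic (15.598, df 4)
exactly; the printed gender and age statistics do not correspond to
uncorrected Pearson values on their printed 2×4 counts (which give ≈5.18 and
≈4.79) and whatever collapsing produced them is unstated, so only the
pathology stratum is used as an anchor.

## Numerical and design choices

- Degenerate cut overlap (both cuts satisfied) assigns a gene by the sign of
  its d; reachable only at Δ ≈ 0.
- Ranking ties: ascending p, then descending n_pos, then lexicographic gene
  id — fully deterministic output ordering.
- Genes measured in zero experiments are excluded from scoring and reported
  separately; NaNs are rejected at read time rather than imputed.
- All output tables are TSV with fixed float formatting; the run manifest
  records versions, seed, stage counts and per-file SHA-256 but no
  timestamps, so identical config+seed reruns are byte-identical.
- Randomness: one top-level seed; per-experiment DE seeds derive from fixed
  offsets of it.

## Limitations

Vote counting discards effect sizes and inter-experiment weighting; a large
well-powered experiment counts exactly as much as a small one. The Fisher
background pools all other genes, so pervasive miscalibration of one
experiment shifts every gene's background rather than being detected. The
permutation FDR inherits SAM's known optimism for very small sample sizes.
Survival modelling, covariate adjustment and SNP-based association are out
of scope.
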