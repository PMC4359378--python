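# Methods note

This note records the statistical model behind each component, the
default parameters and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical choices that
affect results.

## Coordinates and dialects

All intervals are 0-based half-open (BED convention); a TSS is a single
0-based position (the first transcribed base, strand-aware). On disk,
`summit_offset` is relative to the interval start; in memory, summits
are absolute. Readers validate every line and report errors as
`path:lineno: message`; writers and readers round-trip byte-identically
for the peak and gene dialects.

## Screen hit calling

Each well's PDC is `n_diff_cells / n_total_cells`. Within every
replicate, construct PDCs are z-normalized against that replicate's
negative-control wells (mean/SD with ddof = 1; ≥ 2 controls with
nonzero variance required). Per-construct replicate z-scores are
combined with Stouffer's method, `Z = mean(z)·sqrt(n)`, converted to a
two-sided normal p, and Bonferroni-corrected over the number of
non-control constructs. The fold change is the construct's mean PDC
over the pooled control mean PDC. A construct is a hit iff
`fc ≥ 1.5` and `p_bonferroni ≤ 0.05` (both inclusive). A stricter
`all-significant` combiner (every replicate individually significant)
is available for sensitivity analyses. Constructs with missing
replicates are flagged `incomplete` but still tested with the
replicates present.

Defaults (fc 1.5, alpha 0.05) are the conventional thresholds for
arrayed differentiation screens of this size; with ~750 constructs,
Bonferroni keeps the family-wise error rate at the plate level, which
the null-screen simulation confirms empirically (mean hits < 1 over
seeds with no planted effects).

## Interval toolkit

- **Merging** pools sorted calls and coalesces clusters with gap ≤ 0
  (adjacent intervals merge). The merged summit is taken from the
  highest-scoring source call, else the midpoint.
- **Annotation** assigns the first matching category in the priority
  order TSS (± 500 bp of the TSS) > exon > intron > proximal
  (≤ 10 kb from the gene body) > distal.
- **Peak–gene assignment** links a peak to every gene whose body is
  within 10 kb (gap, not center distance); **closest gene** uses
  |summit − TSS| with lexicographic tie-breaking, and signs the distance
  negative when the summit is upstream on the gene's strand.
- **Shifted-peak null**: each interval is re-placed uniformly on its own
  chromosome with length preserved, which keeps the per-chromosome
  interval count and length distribution and destroys only position.
  Overlap enrichment reports observed/expected/fold, a permutation p
  `(1 + #{null ≥ obs}) / (n_shifts + 1)`, and a Fisher's exact p on the
  2×2 table contrasting real peaks with the (rounded) average shifted
  overlap.
- **Signal matrices** extend tags 200 bp in the 5'→3' direction, bin
  coverage in a 2 kb summit-centered window (5 bp bins), divide by the
  sample's size factor and take log2(x+1); rows are ordered by
  decreasing mean signal in a chosen reference sample. Summits too close
  to a chromosome edge are flagged and zero-filled rather than silently
  truncated.

## Negative-binomial differential test

Size factors use the median-of-ratios method: per-feature geometric
means across samples form a pseudo-reference; a sample's factor is the
median ratio to that reference over features with all-positive counts.
This assumes the *typical* feature is unchanged between conditions;
under strongly asymmetric global changes, part of the effect is
absorbed into the factors (an inherent property of the method, observed
directly in validation — see Limitations).

Per-feature dispersions are estimated by method-of-moments on
size-factor-normalized counts and then replaced by a fitted mean trend
`alpha(mu) = a0 + a1/mu` (non-negative least squares), unless the raw
estimate exceeds 10× the trend, in which case the raw estimate is kept
(outlier guard, `DISPERSION_OUTLIER_MULT = 10`). With 2–3 replicates,
per-feature estimates are far too noisy to use directly; the
trend-with-guard rule was selected by comparing null calibration
(target P(p < 0.05) ≈ 0.05) and planted-effect power across candidate
rules on simulation seeds held out from the test suite.

The test itself is an exact-style conditional binomial-mixture test: it
pools counts within each condition, conditions on the total
`k_a + k_b`, and enumerates allocations of that total between the two
conditions under NB marginals with effective dispersion
`disp · sum(s_i^2) / S^2`; the two-sided p sums probabilities ≤ the
observed outcome's probability (with a 1 + 1e-10 tie tolerance). BH
adjustment gives padj. Fold changes use a pseudocount of 0.5 on the
normalized condition means. All-zero features are classed `untested`.

Classification thresholds follow the conventions of the field:
up `fc ≥ 1.5, padj ≤ 0.01`; down `fc ≤ 0.67, padj ≤ 0.01` (the
two-decimal rounded reciprocal, exposed as `fc_down`); dynamic binding
late-only `fc ≥ 2, padj ≤ 0.1` on early-vs-late region counts (early
days −2/0, late days 2/4), early-only symmetric, else static. A gene is
late-only if any region in its body + 500 bp upstream window is
late-only and none is early-only (the early call vetoes). A region is
"expressed" by POLII occupancy when tags per 500 bp ≥ 10 (inclusive).

## Motifs

A PWM is a 4×L log2-odds matrix against a uniform background with a
+0.25 pseudocount per cell. The reported `score_fraction` is
`(raw − min) / (max − min)` where min/max are the matrix's worst/best
attainable scores, so 1.0 is a perfect consensus match and the default
cutoff 0.85 is scale-free. `N` bases take the position minimum. The
minus strand is scanned with the reverse-complement PWM and reported in
forward coordinates; a numeric tolerance of 1e-12 is subtracted from
the cutoff so exact-boundary scores are kept regardless of float
rounding. Peak-level scanning uses a 100 bp summit-centered window;
density profiles count hit starts in an 800 bp window, 10 bp bins,
normalized to hits per bp per peak.

## Network permutation tests

The targeting statistic is `|network ∩ bound ∩ down|`. The null redraws
gene sets of the network's size uniformly without replacement from a
stated universe; `perm_p = (1 + #{null ≥ obs}) / (n_perm + 1)`, so the
minimal attainable p is `1/(n_perm+1)` and the p-value is never 0. The
analytic null mean `|network|·|bound ∩ down|/|universe|` (hypergeometric)
is reported as `expected`. Network genes outside the universe are
dropped with a warning. The shipped adipogenic-network file is a
synthetic stand-in assembled from regulators commonly named in the
adipogenesis literature; it demonstrates the interface and is not a
curated resource.

## Synthetic data generator

The generator's defaults ARE the study conditions used for validation;
they were fixed before the validation outcomes were inspected.

- **Genome**: 2 chromosomes × 500 kb, GC 0.42, 150 non-overlapping
  genes (2–10 kb, 1–5 exons). Placement retries are bounded; impossible
  configurations raise instead of looping.
- **Binding time course**: 600 regions (mean length 300 bp), of which
  10% early-only, 15% late-only, the rest static; 30% are co-bound by a
  second factor whose partner summits lie within ± 100 bp. Per-region
  expected tag counts: low state 50 (`depth_mean`), high state
  `50 · 2^2 = 200` (`planted_log2fc = 2`); counts are NB with
  dispersion 0.1 (var = mu + disp·mu²), two replicates per condition,
  per-sample library factors. The low state is deliberately set at
  depth 50 so a 4-fold change is detectable at the stated
  sensitivity/specificity targets (≥ 0.90 / ≥ 0.95) with n = 2.
- **Motifs**: the E-box consensus is planted at a summit offset drawn
  from [−50, 50 − L] in 40% of regions, so every planted instance lies
  inside the 100 bp scan window.
- **Screen**: 734 constructs, 16 negative-control wells, 3 replicates,
  1000 cells/well; control PDC ~ truncated Normal(0.479, 0.05); 26
  planted enhancers shifted +10 control SDs (≈ 2-fold PDC), chosen for
  unambiguous separability because the screen acceptance questions are
  about false positives (FWER), not marginal power.

What the generator does **not** emulate: read-level data (alignment,
GC/mappability bias, duplicates), peak calling itself (region
boundaries are given, not discovered), plate-position or batch effects
in the screen, correlated features, overdispersion heterogeneity beyond
the single trend, and real genome sequence composition beyond GC
content. Genome-scale region/gene counts from real studies (tens of
thousands of peaks, thousands of DE genes) are out of scope at desk
scale; problem sizes here (≈ 600 regions, ≈ 150 genes) are the
package's own choice for fast, deterministic validation.

## Numerical choices

- Permutation and shift p-values use the add-one estimator, never 0.
- Wilcoxon rank-sum comparisons are exact when both sets have ≤ 8
  measured genes, tie-corrected normal approximation otherwise.
- Chi-square cluster enrichment uses continuity correction and falls
  back to Fisher's exact test when any expected cell is < 5.
- All randomness flows through `numpy.random.default_rng(seed)`;
  every CLI run is reproducible from `--seed` and the run manifest.

## Limitations

- The exact-style NB test is quadratic in pooled counts per feature; it
  is intended for region/gene counts in the hundreds-to-thousands, not
  genome-scale matrices.
- Median-of-ratios normalization biases fold changes when most features
  change in one direction (measured: ≈ −0.27 log2 bias when 33% of
  features are planted 2-fold up; ≈ 0 when planted effects are a
  minority and balanced). Spike-in-based normalization would be needed
  for globally asymmetric designs.
- Dispersion-trend shrinkage trades per-feature adaptivity for
  calibration at n ≤ 3; features with genuinely moderate extra variance
  (below the 10× guard) are tested slightly liberally.
- The shifted-peak null preserves only chromosome and length, not local
  chromatin context; enrichment folds against it are upper bounds
  relative to matched-background nulls.
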