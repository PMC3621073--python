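# Methods

This note records the statistical model behind the package, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions adopted where the procedure being
reproduced left the choice open.

## The analysis in one paragraph

The pipeline takes a normalized log2 expression matrix over a
genotype (wild type vs knockout) × condition (control vs drought) × tissue
factorial with replicates, calls drought-responsive genes per genotype with
a SAM-style permutation statistic gated at p ≤ 0.05 and |FC| ≥ 2, and then
asks, for each wild-type responder, how much of its response survives in
the mutant. The per-gene statistic is the attenuation a = 1 − ρ with
ρ = log2FC_mut / log2FC_wt; a data-driven cutoff on the attenuation column
splits responders into transcription-factor–dependent and -independent
classes, which are then profiled by promoter cis-element content and
gene-set membership.

## Differential expression

* **Statistic.** d = (x̄_D − x̄_C) / (s + s₀), with s the pooled standard
  error of the difference of means (pooled variance, (1/n₁ + 1/n₂) scaling).
  s₀ defaults to the median of the per-gene s. The original SAM tunes s₀ by
  minimizing the coefficient of variation of d across s-percentile windows;
  at the few-thousand-gene, 3-replicate scale this refinement changes calls
  negligibly while costing a grid search, so the median rule is the default
  and s₀ is exposed as a parameter.
* **Null.** Condition labels are permuted within the contrast's samples and
  the permuted |d*| are pooled across genes (standard SAM practice; with 20
  label assignments a per-gene null would have resolution 1/20).
  p = (1 + #{|d*| ≥ |d|}) / (1 + N_pool). With 3 vs 3 replicates there are
  C(6,3) = 20 distinct assignments; the 19 non-observed ones are enumerated
  exactly, the observed labeling entering through the +1 smoothing. This is
  the standard permutation-test convention; counting the observed labeling
  in the pool as well would double-count it against the +1 and bias p
  upward by one grid step, which matters exactly at the p = 0.05 gate in
  the noise-free limit. Monte-Carlo label shuffles (seeded) are used only
  when the assignment count exceeds the requested permutation number.
* **q-values.** SAM's ratio estimate: median over permutations of the
  false-positive count at threshold |d|, divided by the observed count,
  clipped to [0, 1] and monotonized to be non-increasing in |d|. The
  significance gate is applied to p, not q, matching the reproduced
  procedure; both are reported.
* **Degenerate genes.** Zero spread with zero mean difference gives d = 0;
  zero spread with a nonzero difference gives d = ±∞ (an extreme rank),
  never NaN.
* **Calls.** UP iff FC_linear ≥ 2 and p ≤ 0.05 (both inclusive); DOWN
  symmetrically; FC_linear is signed (−2 = halved), so the same magnitude
  gate covers both directions.

## Dependence classification

* **Why attenuation.** The source procedure thresholds "the ratio" of
  mutant to wild-type fold changes at "the 99% confidence interval" without
  stating the ratio's orientation, the CI bound used, or the treatment of
  down-regulated genes. Re-expressing the ratio as attenuation a = 1 − ρ
  gives a single orientation — larger a always means a weaker mutant
  response — that covers UP and DOWN genes uniformly, and makes "value ≥
  threshold ⇒ dependent" unambiguous. This is a documented interpretation,
  not a literal transcription.
* **Threshold.** Upper bound of the 99% t-interval for the *mean* of the
  attenuation column (what a "column statistics" panel computes), i.e.
  mean + t₀.₉₉₅,ₙ₋₁ · sd/√n. Because the interval is for the mean, it is
  narrow for large n and sits between the independent mode (a ≈ 0) and the
  dependent mode (a ≈ 1) whenever dependent genes form a substantial
  minority-to-majority of responders — the regime reported for this system
  (roughly 45–75% dependent). An empirical-quantile alternative
  (`method="percentile"`) is provided for sensitivity analysis.
* **Edge cases.** ρ < 0 (response inverted in the mutant) gives a > 1 and
  classifies dependent. A zero-variance attenuation column makes the cutoff
  the common value with ties going to INDEPENDENT: dependence requires
  strict evidence of attenuation. An empty responder set yields an empty
  classification with a warning, not an error.
* **Identities.** CDPRG + CIDIG = #WT-up and CDNRG + CIDRG = #WT-down are
  asserted on every classification and at pipeline level.

## Motif scanning

* IUPAC symbols expand to their letter sets; a pattern's occurrence set is
  exactly its word expansion. Matching uses a regex with a lookahead so
  overlapping occurrences are all reported (per-gene counts are "2-CGCG;
  5-CGTG"-style tallies of occurrences, not binary flags).
* Coordinates are 0-based half-open on the promoter string, position 0 the
  most-upstream base; the anchor used to extract promoters (TSS vs start
  codon) is the caller's choice and only relative coordinates are recorded.
* Default strand policy is *both*: the CGTG element is asymmetric and the
  CGCG box's expansion is only partially reverse-complement closed
  (revcomp(CCGCGT) = ACGCGG is a CGCG-box word but revcomp(ACGCGC) = GCGCGT
  is not), so forward-only scanning misses real sites. Forward-only is a
  flag.
* `N` in a sequence matches no motif symbol, including motif `N` —
  conservative, so ambiguous bases never inflate frequencies.
* Class frequency = 100 × (#genes in class with ≥ 1 occurrence) / (#genes
  in class); an empty class reports NA.

## Annotation

* Venn partitions report the seven exclusive regions of a query against
  three sets plus the uncovered remainder; region sums are asserted.
* Crosstab percentages use as denominator the class genes annotated to at
  least one set of the collection (the convention behind "14 of 35
  hormone-annotated genes = 40.0%"), with half-up rounding to one decimal.
* Enrichment is one-sided over-representation only (singular-enrichment
  semantics): p = P(X ≥ k), X ~ Hypergeom(N, K, n), with
  Benjamini–Yekutieli step-up adjustment (valid under arbitrary
  dependence). Odds ratios add 0.5 to all cells when any cell is zero. The
  universe defaults to the expression matrix's gene list, overridable by a
  supplied GMT universe.

## Physiology metrics

RWC = 100·(FW − DW)/(TW − DW) — the printed equation omits the parentheses
but plant physiology fixes the precedence; TW = DW is fatal and FW < DW is
returned negative for the caller to flag. The qPCR quantification follows
the standard Livak scheme, ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = ΔCt_condition − ΔCt_control, fold = 2^(−ΔΔCt); the source's wording
conflates ΔCt and ΔΔCt, and the standard scheme is what its normalization
description denotes. Group comparisons use the classical equal-variance
Student's t (two-sided, α = 0.05), with Welch behind a flag.

## Synthetic data

The generator draws log2 expression as
x = b_g + δ_g·[drought]·(κ_g if mutant else 1) + ε, ε ~ N(0, σ²), with
gene classes dep_pos/dep_neg (δ = ±effect, κ = attenuation < 1),
indep_up/indep_down (δ = ±effect, κ = 1) and null (δ = 0). Defaults encode
the emulated study's design — 3 replicates per cell of the 2×2×2 factorial,
1000 bp promoters — plus free parameters the study does not report and that
were fixed once at values typical for two-channel-free log2 microarray
data: baseline N(8, 2²), effect size δ = 2 (the smallest effect passing the
FC ≥ 2 gate in expectation, making the gate's boundary behavior visible),
noise σ = 0.25, full attenuation κ = 0, class fractions
(0.15, 0.15, 0.10, 0.10, 0.50), promoter GC fraction 0.35 (AT-rich plant
promoters). One seed spawns three independent child streams (expression,
promoters, gene sets) so each generator is reproducible alone.

Promoter backgrounds are rejection-resampled under `clean_background` until
they contain no accidental motif match on either strand, so planted
coordinates are exhaustive ground truth; note a planted word whose reverse
complement is also a motif word legitimately matches both strands at the
same span. Gene sets are Bernoulli samples with per-class inclusion rates
whose defaults give set sizes of the order curated stress/hormone/TF lists
return for a few-thousand-gene universe.

**What passing on synthetic data does not show.** The generator has
homoscedastic Gaussian noise, a common effect size, no probe-level
artifacts, no batch or spatial effects, no correlation between genes, and
attenuation concentrated at a single κ — real arrays have mean–variance
dependence, effect-size spread and correlated nulls, all of which blur the
attenuation column's bimodality. Recovery rates measured here therefore
bound the method's behavior under its own assumptions, not on GEO data;
the published gene counts derive from probe-level processing of the
original CEL files and are out of scope (only their internal arithmetic is
checked).

## Problem sizes and determinism

Simulation-based checks run at 2000 genes × 12 samples (leaf only), the
scale at which binomial error bands on recovery rates and type-I error are
a few tenths of a percent; the scanner oracle uses 1000 random 1 kb
sequences and the enrichment oracle enumerates all tables with N ≤ 12.
Every stochastic component takes an explicit seed (numpy Generator); with
3 vs 3 replicates the permutation null is exhaustive and hence
seed-independent.

## Known limitations

* The attenuation cutoff assumes dependent genes are a sizeable fraction of
  responders; with very few dependent genes the CI-of-the-mean threshold
  approaches the independent mode and specificity degrades — the percentile
  method is the appropriate fallback.
* ρ is unstable for wild-type fold changes near the gate (|log2FC| ≥ 1
  bounds the denominator away from 0, but noise in a borderline denominator
  still inflates |a|).
* The permutation p-value floor is 1/(1 + N_pool); with 19 assignments and
  few genes, very small p-values are unattainable.
* No moderated-variance or interaction-model alternative is provided: the
  genotype×condition ANOVA would be statistically cleaner but is
  deliberately not this pipeline's method.
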