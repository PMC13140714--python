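# Methods

## Scope and model

betacross analyses two-group (control vs. disease) DNA-methylation
studies measured as per-CpG β values (methylated / total intensity,
in [0,1]) on 450K-style arrays. The statistical model operates on
M-values, the base-2 logit M = log₂(β/(1−β)), whose near-Gaussian,
homoscedastic behaviour suits linear modelling; β is retained for all
state calls and visual summaries because it is the interpretable scale.
β values are clamped into [ε, 1−ε] before the logit, ε = 1e-6 by
default, so boundary values stay finite; ε only affects probes that are
fully (un)methylated in some sample and any ε ≪ 0.5 gives identical
downstream calls.

### Merging and filtering

Multiple study matrices are merged on the intersection of probe ids
(probe order follows the first input — the choice is arbitrary but must
be deterministic, and the first-input convention keeps a "reference"
study's ordering). Columns are concatenated in input order and the
sample sheet is kept aligned. Probes with **more than** 80% missing
values across samples are removed; the boundary case (exactly 80%) is
retained, which follows from reading the threshold as strict
exceedance. The filter is idempotent. No normalisation
(quantile/functional/noob) is applied: the pipeline consumes β matrices
as published.

### Differential methylation

Each CpG g is fitted with the two-group linear model on observed M
values: logFC_g = mean(case) − mean(control), pooled residual variance
s²_g with df_g = n_obs − 2, and unscaled coefficient standard deviation
su_g = √(1/n_case + 1/n_control) using per-probe observed counts.
Probes with fewer than two observed values in either group are excluded
(count logged) rather than imputed.

Empirical-Bayes moderation assumes s²_g ~ s₀²·F(df_g, d₀) across CpGs.
Writing e_g = log s²_g − ψ(df_g/2) + log(df_g/2), the model implies
E[e] = log s₀² − ψ(d₀/2) + log(d₀/2) and Var[e] = ψ′(df/2) + ψ′(d₀/2),
so matching the observed mean and variance of e gives d₀ by inverting
the trigamma function (Newton iteration) and s₀² in closed form. When
the observed dispersion of e does not exceed its chi-square sampling
floor, d₀ = ∞ and s₀² is the mean of the s²_g (on the raw scale, which
is exact in the degenerate equal-variance case). The moderated t uses
the posterior variance s̃²_g = (d₀s₀² + df_g s²_g)/(d₀ + df_g) — a convex
combination of shrinkage target and per-probe estimate — and is
referred to t with d₀ + df_g df (standard normal at d₀ = ∞). This
machinery is authored here and is verified in the test suite against
Bioconductor limma on a fixture, where it agrees to machine precision
in logFC, t, p and BH-adjusted p, and to ~1e-6 in (d₀, s₀²).

The B statistic (log posterior odds of differential methylation) uses
the standard closed form in t, its total df, the prior differential
proportion (default 0.01) and the prior logFC variance v₀. v₀ is
estimated by a simple moment rule — the median over the top-|t|
fraction of max(logFC²/s̃² − su², 0) — rather than the reference
implementation's mixture quantile estimator; B is reported for ranking
context only and nothing downstream consumes it.

BH adjustment is the step-up procedure with cumulative-minimum
monotonicity enforcement and cap at 1; significance is adj. p < 0.05
(configurable).

### Directionality

Group-mean β is computed per CpG over observed values only. The state
call is high-methylation iff mean β ≥ 0.5 — the boundary is inclusive
by definition, so (0.5, 0.5) is stable_high. Crossing classes
(low_to_high, high_to_low) and stable classes (stable_high, stable_low)
are exhaustive and mutually exclusive; a CpG with no observed value in
a group is flagged unclassifiable, never dropped silently. State calls
are group-level summaries: no per-sample state is ever assigned.

Top genes are ranked within each crossing direction by |mean logFC|
over the gene's qualifying CpGs (significant + crossing + annotated to
the gene), ties broken lexicographically. Probe-to-gene mappings are
exploded, so a multi-gene probe contributes identical statistics to
each of its genes. The per-gene mean is the primary ranking key because
the reported per-direction ordering follows that aggregate; ranking by
the single largest per-CpG |logFC| is available via `ranking="max"`.

### Annotation and cross-tabulation

The counting unit is the CpG-feature assignment: one count per retained
(gene, gene-structure) mapping of a probe, one count for an unannotated
probe (Unknown group). Probes missing from the manifest get
Unknown/Unknown. Cross-tab rows follow fixed category orders — islands
by genomic proximity (Island, N_Shore, S_Shore, N_Shelf, S_Shelf,
OpenSea, Unknown) and gene-structure groups by TSS proximity (TSS200,
TSS1500, 5'UTR, 1stExon, Body, 3'UTR, Unknown). Each
(island, group, case-state) row carries two counts: `state_count`, all
significant assignments in that state (these partition the assignments
and their percentages sum to 100), and `cpg_count`, the subset whose
change class is the state-consistent crossing (high pairs with
low→high). Percentages use the total number of significant assignments
as denominator; positive values below 0.005% render as "< 0.01" and
exact zeros as "0.00".

### Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with population N (universe), K successes (term ∩ universe)
and n draws (query ∩ universe); query genes outside the universe are
dropped with a logged count and K = 0 terms are skipped. Derived
statistics: GeneRatio k/n, BgRatio K/N, RichFactor k/K, FoldEnrichment
(k/n)/(K/N) (= RichFactor·N/n), and the z-score standardising k by the
hypergeometric mean and variance with finite-population correction.
The q-value column defaults to the BH-adjusted p-value; a separate
q-value estimator is deliberately not implemented, so q is a
conservative stand-in. Reported terms satisfy p.adjust < 0.05 and
q < 0.2; the top 20 per collection are ranked by raw p (ties: adjusted
p, then term id). Gene identifiers are treated as opaque symbols; GO
DAG semantics are out of scope and GMT sets are flat.

### Unsupervised views

Significant CpGs are subsampled (default 10,000, seeded) before
clustering to keep the distance computations tractable; β rows are
standardised with the n−1 sample standard deviation (constant or
single-value rows are dropped with a logged count). Clustering is
complete-linkage on Euclidean distances for both CpGs and samples;
missing entries are mean-imputed per CpG row before distances (the
alternative, pairwise-complete distances, is not metric and breaks
linkage monotonicity). PCA of samples applies centering only, since
rows are already standardised; variance fractions label the axes.
The volcano plot shows all tested CpGs with a dashed line at
−log₁₀(0.05) ≈ 1.301 and deliberately no vertical logFC cutoffs;
adjusted p-values are clipped at 1e-300 before the log transform.

## Synthetic-data generator

The generator emulates the integrated multi-study design the pipeline
targets: 34 control + 31 case samples in 3 dataset blocks (defaults),
20,000 probes. Baseline probe means on the M scale are a three-component
Gaussian mixture (centers −2.5, +2.5, 0 with sd 0.7, weights
0.4/0.4/0.2), i.e. β modes near 0.15 and 0.85 plus a mid component so
boundary crossings are attainable — mirroring empirical 450K
bimodality. 30% of probes carry a planted effect (≈ the significant
fraction in the motivating cohort); 5% + 5% of probes cross the β = 0.5
boundary upward/downward: their control means are drawn close enough to
M = 0 that the planted M-shift (default 2.0) lands the case mean on the
other side, and non-crossing effects are pushed away from the boundary
so planted classes are exact by construction. Noise is Gaussian on the
M scale (sd 0.5 within group — chosen as a testable compromise since
per-group variances were not reported for the cohort), and per-sample β
is the inverse logit, hence always strictly inside (0,1). True group
means on the β scale are the inverse-logit images of the planted M
means (consistent to 1e-12 by construction).

Missingness is Bernoulli at 2% plus 1% of probes engineered to exceed
the 80% filter (a random count strictly above ⌈0.8·n_samples⌉ of their
entries masked, drawn among non-planted probes when possible). Gene
annotation uses synthetic tokens (G000001…, with RefSeq ids mirroring
them); probes map to 0/1/2 genes with probabilities 0.25/0.60/0.15 over
a pool of n_probes/3 genes, producing both multi-gene probes and
multi-probe genes plus unannotated probes. Island categories follow the
observed genome-wide shares (Island 0.20, N_Shore 0.13, S_Shore 0.10,
shelves 0.05 each, OpenSea 0.47). Gene-set generation seeds the first
`enriched_terms` sets with 80% planted-DMP genes. Dataset blocks carry
no batch shift by default (an optional `batch_shift_m` exists for
robustness experiments), matching a design where no batch correction is
applied.

What the generator does **not** emulate: probe type chemistry and
color-channel effects, spatial correlation along the genome, realistic
per-probe variance heterogeneity tied to methylation level,
cell-composition heterogeneity, or real gene identifiers. Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to array artefacts.

## Numerical choices and degenerate inputs

- Trigamma inversion: Newton iteration from y₀ = 0.5 + 1/x, tolerance
  1e-8 relative, with asymptotic shortcuts for x > 1e7 and x < 1e-6.
- d₀ = ∞ is propagated exactly (normal reference distribution) rather
  than capped at a large number.
- All-zero residual variances raise an error with guidance instead of
  producing infinite t statistics.
- Ties in rankings break deterministically (gene symbol, term id,
  stable mergesort) so outputs are permutation-invariant.
- Sampling, simulation and pipeline stages derive independent
  sub-seeds from the single global seed via seed sequences, so stages
  are individually reproducible.

## Problem sizes in the test suite

Validation simulations run at reduced but statistically adequate sizes
chosen for a laptop-class machine: null calibration pools 10 × 20,000
probes at n = 10+10 (rejection rate within [0.045, 0.055]); moderation
recovery uses 50,000 probes (d₀ within 15%, s₀² within 5%); planted
direction recovery pools 20 seeds of 2,000 probes at n = 30+30
(≥ 90% recovered); end-to-end cluster recovery runs 5 seeds of 3,000
probes at the default 34+31 design. The brute-force oracles (BH
step-up, exhaustive hypergeometric enumeration on universes ≤ 12,
cross-tab cell enumeration) are exact.

## Known limitations

- Covariates (age, sex, batch) are not modelled; the design matrix is
  group-only, though the fitting layer is written so an extended design
  would slot into the same moderation path.
- The q-value column approximates rather than reproduces a dedicated
  q-value estimator.
- Real-data logFC reported on other scales cannot be compared directly:
  this pipeline defines logFC on the M scale throughout.
- Gene symbol conversion is an identity mapping; organism annotation
  databases are out of scope.
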