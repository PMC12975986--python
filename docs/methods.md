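# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, and what the synthetic data do and do not emulate.

## Augmented block design

The trial model is the classical augmented RCBD: replicated check varieties
estimate block and error effects; each unreplicated test entry is corrected
by its block's effect. With `b` blocks, `c` checks and `r` check replicates
per block:

* block effect: `b_j = mean(check plot values in block j) − grand check
  mean` (the two replicate plots of a check within a block are averaged
  first, which is equivalent here); effects sum to zero by construction;
* adjusted test value: `observed − b_j`; adjusted check mean: the check's
  raw across-block mean; negative adjusted values are allowed — the
  adjustment is purely arithmetic;
* ANOVA: sequential fit of `value = mean + block + treatment`, blocks first;
  the treatment stratum is partitioned into checks, tests (variation among
  adjusted test values) and the checks-vs-tests contrast. The error SS comes
  entirely from check replication via the additive two-way fit on check
  plots, with `df = (b−1)(c−1) + bc(r−1)` — the classical Federer stratum
  `(b−1)(c−1)` when `r = 1`. Keeping the error stratum at plot level (rather
  than on rep-averaged values) makes the error MS estimate the plot-level
  `Ve`, which is the variance relevant to once-replicated test entries and
  to the critical differences. The ANOVA is verified in the tests against a
  generic least-squares fit of the same linear model.
* critical differences at level α (t on the error df):
  check–check `t·√(2Ve/b)`; test–test same block `t·√(2Ve)`; test–test
  different block `t·√(2Ve(c+1)/c)`; test–check
  `t·√(Ve(1+1/b+1/c+1/(bc)))`. α defaults to 0.05. A promising accession
  beats the best check by more than CD(test–check).
* Bartlett's χ² homogeneity test takes per-environment `(Ve, df)` summaries
  (the form in which multi-environment ANOVAs are available) and is the
  standard screen before pooling environments.

## Genetic variability

For each trait, `Vp` is the variance of the adjusted test means and `Ve`
the ANOVA error MS. An adjusted test mean carries the plot error once *plus*
the noise of its block-effect estimate, `Ve/(r·c)`; by default this term is
removed from `Vp` before decomposing (`Vg = Vp − Ve`, `h² = 100·Vg/Vp`),
which makes `h²` recovery unbiased on simulated trials — the package's
recovery tests hold the median bias under 3 points at true h² of 25/50/75.
`correct_adjustment_variance=False` reproduces the plain field-report
convention; with `c = 5` checks and `r = 2` the difference is small except
for low-heritability traits, where the plain estimator overstates h² by
up to ~5 points. `Vg` is floored at zero (flagged) when `Ve` exceeds `Vp`.

`GCV = 100·√Vg/mean`, `PCV = 100·√Vp/mean`, `GA = k·√Vp·(h²/100)` with
`k = 2.063` (the standard 5%-selection differential; configurable), and
`GG = 100·GA/mean`. The identities `h² = 100·(GCV/PCV)²` and
`GG = 100·GA/mean` hold algebraically and are asserted on all outputs.
Category bands: h² `<30 / 30–60 / >60`; GCV, PCV, GA, GG `<10 / 10–20 / >20`
(Low/Medium/High, boundaries closed on the lower side — a value exactly at
30 is Medium). The GA/GG bands are the ones consistent with how published
mungbean variability tables label their values.

## Distances and core sampling

Gower's coefficient is the default metric (range-normalized absolute
difference for quantitative traits, 0/1 mismatch for qualitative ones,
averaged with pairwise deletion of missing values); it is the standard
choice for mixed germplasm trait data and needs no unit harmonization.
Euclidean-on-standardized-traits is provided for clustering.

The nearest-entry objectives follow the usual core-quality definitions:
`E-NE` (mean distance of each core entry to its nearest other entry;
diversity, larger is better), `A-NE` (mean distance of every accession to
its nearest core entry, zero for entries themselves; representativeness,
smaller is better) and `E-E` (mean pairwise entry distance, reported but not
optimized). Because the two objectives live on different scales, the
weighted score `w_EN·norm(E-NE) − w_AN·norm(A-NE)` normalizes each by its
range over an ensemble of 200 random cores drawn once per optimization; the
normalization is monotone, so single-objective runs (EN100, AN100) are
unaffected by it.

The optimizer is random descent over the single-swap neighborhood: swap a
random non-forced entry with a random outside accession, accept strict
improvements, stop after `budget` consecutive non-improving proposals (or
`max_proposals` in total), keep the best of `restarts` restarts. Defaults
(50,000-proposal budget, 20 restarts) suit collections of a few hundred; the
analysis drivers use budget 1,500 / 12,000 max proposals at n = 1,000, which
is enough for the cores' quality ordering to be stable across seeds. On
every instance small enough to enumerate (n ≤ 12, core ≤ 4), 20 restarts
recover the exhaustive optimum in 100/100 random instances (acceptance
test). Ties everywhere break by ascending accession id for reproducibility.

PowerCore is approximated (the original self-selects its core size, while
this workflow fixes the size at 10%): quantitative traits are discretized
into Sturges-rule classes (`⌈1 + log₂ n⌉` bins over the collection range),
descriptor states are classes as-is, and accessions are added greedily by
most still-uncovered classes (ties toward the accession covering the rarest
class, then lowest id). Once all classes are covered, remaining slots are
filled farthest-point style (each addition maximizes its distance to the
nearest current entry) — a cheap E-NE-raising fill; the exact
marginal-E-NE greedy differs negligibly and costs O(n²k). A size too small
to cover every class is not an error; coverage is reported.

PCSS ranks accessions by their contribution to the retained principal
components (eigenvalue > 1, the usual retention rule): the sum over retained
components of the squared standardized score weighted by the component's
variance share. Deterministic.

`enforce_geography` repairs a core so every geographic group has at least
one entry: for each missing group, all (group member, removable entry) swaps
are scored under the core's own weighted objective and the least-degrading
one applied; forced entries and sole representatives of covered groups are
never removed.

## Core evaluation

Hu indices over quantitative traits: MD% and VD% are the shares of traits
whose core-vs-collection means (Welch t) or variances (two-sided F ratio)
differ at α = 0.05; CR% is the mean core/collection range ratio and VR% the
mean CV ratio, in percent. The F-test convention for VD% follows the index's
original definition; Levene (Brown–Forsythe) is reported separately in the
per-trait battery, so both views are available. The conventional acceptance
rule is MD% < 20 with CR% > 80. Note that diversity-maximizing cores on
strongly *skewed* real collections can shift trait means enough to fail the
MD rule even when range coverage is excellent; on the generator's symmetric
traits the EN100 core passes it comfortably.

Class coverage uses Sturges bins built on the collection; the
phenotype-retained ratio counts qualitative descriptor states present in the
core over those in the collection. Shannon `H′ = −Σ pᵢ ln pᵢ` over observed
states, `H_max = ln k` with `k` taken from the descriptor (not the observed
support), `J′ = H′/H_max`.

Sign tests are exact two-sided binomial tests on the per-trait direction of
the core-minus-collection mean (and variance) differences, ties dropped. The
Mantel test correlates the upper off-diagonals of the two trait-correlation
matrices and permutes row/column labels simultaneously (999 permutations by
default, one-sided, seed required).

Distribution battery per trait: Welch t; Newman–Keuls, which with exactly
two groups degenerates to a single studentized-range comparison on the
pooled variance; Brown–Forsythe Levene; Wilcoxon rank-sum via the normal
approximation with continuity and tie correction (sample sizes in the
intended use are ≫ 20); two-sample KS; Scholz–Stephens k = 2 sample
Anderson–Darling (its p-value is clipped to [0.001, 0.25] by the underlying
implementation; identical samples are reported as the exact null);
symmetrized discrete Kullback–Leibler over shared Sturges bins on the pooled
sample with `ε = 1/(2·n_pooled)` smoothing, so identical samples give
exactly 0. Samples under 5 values yield undefined-flagged results rather
than errors. Q–Q data use plotting positions `(i−0.5)/n` with `n` the
smaller sample.

## Multivariate structure

PCA is computed from the trait correlation matrix (traits standardized), the
right choice for heterogeneous units; eigenvalues then sum to the trait
count and a component's variance share is `100·λ/p`. Loading signs are fixed
so each component's largest-magnitude loading is positive (signs are
otherwise arbitrary). Constant traits are dropped and missing values
mean-imputed, both with warnings. Hierarchical clustering defaults to Ward
on standardized Euclidean distances (the common pairing; average and
complete linkage are available), with flat cuts by cluster count and Newick
export. Pearson correlations carry two-sided t-based p-values.

## Synthetic collections

The generator draws, per quantitative trait, observation = trait mean +
genotypic value + block effect + plot error. Genotypic values are
multivariate normal across traits (configurable correlation matrix;
identical across a check's replicate plots); block effects are one shared
standard-normal draw per block scaled per trait and centered to sum to zero
(they are identifiable only up to a constant); errors are independent
normal. This reproduces exactly the `Vp = Vg + Ve` algebra the variability
module estimates. Qualitative states are accession attributes drawn once
from the configured state-probability vector. A log-normal genotype option
exists for skewed traits but is off by default. Random streams are split by
named substream (layout, genotype, qualitative, block, error) so changing
one component does not perturb the others.

Defaults are the study conditions of the mungbean characterization this
package replicates: 3,903 tests in 50 blocks with 5 named checks sown twice
per block; 21 quantitative traits whose means/SDs come from the published
collection summary and whose Vg/Ve split comes from the published
heritability; 7 qualitative traits with 29 states whose geometric frequency
vectors are calibrated (by root finding at config build) so the collection
Shannon H′ matches the published values; geographic group probabilities from
the published origin counts; block-effect SD = 0.5 × phenotypic SD per trait
(the trials report strong environmental influence but no magnitude — chosen
once as a moderate value).

What the generator does **not** emulate: trait skewness and outliers (real
mungbean yield-component traits are strongly right-skewed, which is why the
real study's chosen core violated the MD% rule while the synthetic default
passes it), genotype-by-environment interaction (the workflow analyses one
environment after the Bartlett screen), spatial field trends, and any
marker data. Passing tests therefore demonstrate correctness of the
estimators and samplers under the stated model, not robustness to every
pathology of real field data.

## Problem sizes and numerical choices

The shipped analyses and the acceptance script run the core-construction
comparison at n = 1,000 accessions with a 100-entry (10%) core and the
heritability recovery at n = 800 × 30–50 replicates; these sizes make the
full suite run in well under a minute per stage on one CPU while leaving all
qualitative conclusions (EN100 superior under the gate-then-E-NE rule,
EN/AN trade-off direction, unbiased h² recovery) stable across seeds. The
`--study-scale` flag of `analysis/01` switches to the full 3,903-accession
layout. Tolerances: identity checks assert to printed precision; Monte-Carlo
checks use bounds derived from repeat simulation (h² median bias < 3
points); the correlation-recovery property uses 0.05 at n ≥ 1,000.

The "best core" verdict formalizes what trial reports argue in prose:
maximize E-NE subject to MD% < 20 and CR% > 80, ties broken by class
coverage then VR%. Reports label it as a codified rule.
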