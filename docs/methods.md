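# Methods

This note documents the models and procedures implemented in `kosynergy`,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not establish about real data.

## Cohort model

Lesion onset in each genotype arm follows a constant (exponential) hazard
λ_g (events/day), so cumulative incidence by day *t* is 1 − exp(−λ_g t).
This is the simplest model in which the Bliss-independence null is exactly
expressible: since

1 − E = (1 − p_A)(1 − p_B) = exp(−(λ_A + λ_B) t),

independence holds at **every** horizon precisely when the double-knockout
hazard equals λ_A + λ_B. The interaction multiplier θ scales that baseline
(λ_AB = θ·(λ_A + λ_B)); θ = 1 is exact independence, θ > 1 synergy. The true
synergy score at horizon *t* is then exp(−(λ_A+λ_B)t) − exp(−θ(λ_A+λ_B)t),
and `theta_for_synergy` inverts this analytically, which is how simulation
studies place the truth at a chosen score.

Default hazards are back-derived from the reference 400-day incidences of
the population the generator emulates: 35.0 % (`SIRT2KO` →
λ = −ln(0.65)/400 ≈ 1.08·10⁻³/day), 4.5 % (`SOD1KO` ≈ 1.15·10⁻⁴/day), a
near-zero wild-type hazard (2·10⁻⁵/day), and θ ≈ 4.04 chosen so the DKO arm
reproduces the reference 85.4 % at 400 days. Cohort size defaults to 40 per
genotype (the reference cohorts span 30–48). Subjects leave observation
through an exponential attrition hazard (default 5·10⁻⁴/day, ~18 % by day
400) or administratively at `followup_days` (default 400); events precede
censoring at tied times. Times are whole days ≥ 1 (event days are rounded
up, which leaves the incidence at integer horizons exactly exponential).

The single attrition hazard is shared across genotypes, so the generator
does not emulate genotype-specific lifespan curves — its target is
lesion-onset synergy, not mortality.

## Incidence at a horizon

`crude` incidence (the default) is the proportion of lesioned-by-*t*
subjects among those either lesioned by *t* or still under observation at
*t*; subjects censored lesion-free before *t* contribute nothing. The
reported reference incidences are consistent with simple proportions of
small integer counts, which is why `crude` is the default;
`km_complement` (1 − S_KM(t) of lesion-free survival) is selectable and the
resampling machinery follows whichever the caller picks. Without censoring
before *t* the two coincide exactly.

## Synergy inference

**Bootstrap CI.** Percentile 95 % interval of the score over `n_boot`
(default 1000) within-genotype resamples. For the crude estimator,
resampling the eligible subjects of an arm with replacement is
distributionally identical to drawing Binomial(n_elig, p̂)/n_elig, which is
what the implementation does (vectorised); the KM path resamples subject
indices and re-estimates the curve. Percentile intervals were chosen as the
simplest defensible method for a bounded score; a degenerate arm (all
identical outcomes) collapses the interval to the point score.

**Independence test.** The null hypothesis is Bliss independence itself, so
the test is a parametric resampling of that null rather than a label
permutation: each replicate draws single-knockout incidences p_A*, p_B* by
resampling those arms, forms E* = p_A* + p_B* − p_A*·p_B*, simulates the DKO
arm as Binomial(n_AB, E*)/n_AB, and scores it against the observed expected
incidence Ê. The p-value is the add-one estimator
(1 + #{S_null ≥ S_obs})/(n_perm + 1), one-sided toward synergy.

Scoring null replicates against Ê (not E*) matters: Var(S_null) =
Ē(1−Ē)/n_AB + Var(E*), which matches Var(S_obs) = E(1−E)/n_AB + Var(Ê); the
alternative (subtracting E* inside each replicate) cancels the
expected-incidence uncertainty and is anti-conservative. Simulation under
θ = 1 (500 datasets, n = 40/genotype, n_perm = 1000) shows the rejection
rate at α = 0.05 within the exact binomial 95 % band, and coverage of the
bootstrap CI at true score 0.3 (n = 45, 300 replicates) is within 95 ± 3
percentage points; both checks live in the acceptance test suite.

**Fisher's exact test** uses the probability-mass two-tailed definition
(sum of same-margin tables whose point probability does not exceed the
observed), the dominant convention; the doubling alternative is not
implemented. The odds ratio is the conditional MLE with 0/∞ conventions on
zero cells.

## Survival statistics

Kaplan–Meier estimation and the log-rank test (hypergeometric variance,
χ² with 1 df) are delegated to `lifelines` behind the module surface; a
label-permutation option exists for tiny cohorts. The median is the smallest
event time with S(t) ≤ 0.5 (`None` if never reached); ties at exactly 0.5
take the first qualifying time. Time is days internally; week/day conversion
only happens at interfaces (`percent_reduction` is unit-agnostic and rounds
to one decimal, the reporting precision used throughout for percentages;
scores are reported to three decimals).

## DE table and count generators

The DE generator plants `frac_up`/`frac_down` (defaults 0.05/0.05 of 8000
genes) true effects of ±`effect_log2fc` (default 2); observed log2 fold
changes add N(0, `noise_sd`²) noise (default 0.3) and p-values are the
two-sided Gaussian test of that estimate, so null genes are exactly uniform.
Transcript lengths are log-normal (median 2 kb, σ_log 0.9); `length_shift`
(default 0.4 log-units, ≈ 33 % shorter) is subtracted from the log-length of
planted up-genes, emulating the aging-associated length imbalance.
The planted truth (which genes are up/down, the decoy set) is drawn from its
own named stream of the seed, so per-tissue tables generated under different
noise-stream names share one truth — the substrate for cross-tissue
signature analyses.

Counts follow a gamma-Poisson model, Var = μ + `dispersion`·μ² (default
dispersion 0.1), log-normal baseline means, with the treated-group mean of
planted genes scaled by 2^±effect. `simple_de_test` (library-size scaling to
the mean library, log2 with pseudo-count 0.5, per-gene Welch t-test, BH) is
a plain two-group screen so synthetic pipelines run end-to-end; it is not a
negative-binomial DE model and should not be used on real counts.

What the generators do **not** emulate: gene–gene correlation, mean-variance
trends fitted from real data, isoform structure (one length per gene),
batch effects, or library-composition bias. Passing the planted-recovery
tests therefore shows the estimators are correct under the stated sampling
models, not that real RNA-seq data meet those models.

## Ranking and pre-ranked GSEA

The ranking score is −log10(padj)·sign(FC); padj = 0 is clamped to 1e-300
(finite scores, order preserved, with a warning) and FC = 0 scores 0 with a
warning. Ties in score break by gene id lexicographically so rankings are
platform-independent.

The enrichment score is the classical weighted Kolmogorov–Smirnov running
sum: walking the ranked list, hits increment by |score|^weight (normalised
over the hit set; weight defaults to 1, weight 0 gives the unweighted
statistic), misses decrement by 1/(N−k); ES is the deviation of largest
magnitude. Numerical choices: magnitude ties between the positive and
negative extremes (within 1e-12) resolve to the deviation reached first
along the list; a hit set whose scores are all exactly zero falls back to
uniform increments. The null is `n_perm` (default 1000) random same-size
gene sets (gene-label permutation); NES divides ES by the mean |null ES| of
the same sign, the permutation p is the add-one one-sided tail among
same-sign nulls, and FDR is BH across the sets tested in one call. Size
gates default to [15, 500] (lower `min_size` for toy inputs). Multilevel
p-value refinement is out of scope, so extremely small enrichment p-values
saturate at 1/(n_perm + 1).

## Rank tests

`wilcoxon_ranksum` is exact (full enumeration over group assignments,
average ranks for ties) for combined n ≤ 12 — the boundary where C(12,6) =
924 assignments is instant and the normal approximation is already within
0.02 — and the continuity-corrected normal approximation above.
The length-imbalance test applies it two-sided to transcript lengths of
up- vs down-DEGs and reports medians plus a direction tag. The paired
fold-change comparison uses the signed-rank test (scipy; exact in tie-free
small samples), with p = 1 by convention when every paired difference is
zero.

## Immune scores

`immune_score` is a deliberately simplified marker-gene analogue of murine
immune deconvolution: per population, the mean log-expression of its marker
genes per sample, z-scored across samples (population SD; constant scores
map to 0). Results are comparative across samples only — no absolute
cell-type proportions — and the marker catalog is user-supplied (GMT).

## Reproducibility

One global seed feeds a named-stream splitter (`stream_rng`): every
stochastic operation draws from its own stream keyed by a CRC of the stream
name, so changing one stage's draws never perturbs another's. Identical
configuration plus seed gives bit-identical outputs, including serialized
artifacts; pipeline bundles are stamped with the package version, a hash of
the analysis configuration (output location excluded) and the seed.

## Problem sizes used in the test suite

Calibration and coverage checks run at the cohort sizes stated above
(500 × n_perm 1000 for type-I error; 300 × n_boot 1000 for coverage; 100
replicates for length-imbalance recovery plus 200 null replicates), which
the vectorised resampling paths complete in seconds. Oracle suites enumerate
exhaustively: all 2×2 tables with total ≤ 30 for Fisher, all assignments for
rank tests at combined n ≤ 12, and every size-2–4 subset of every ranked
list with N ≤ 8 for the GSEA running sum.

## Known limitations

- Constant hazards mean the θ > 1 interaction acts from day 1; real
  late-acting interactions (scores near zero early, large late) need a
  time-varying excess hazard, which the generator does not provide (the test
  suite constructs such a cohort directly where needed).
- The crude-incidence bootstrap resamples the eligible set, ignoring
  uncertainty in *which* subjects are eligible under informative censoring.
- The cohort table carries a single attrition process; death before lesion
  is treated as censoring for lesion-free survival (a preprocessing choice
  the caller can override by editing the table).
- GSEA p-values saturate at the permutation floor; NES values are
  permutation-dependent and not comparable across runs with different
  `n_perm`.
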