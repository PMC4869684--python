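# Methods

## Model

### Cohort-level haplotype regression

For a cohort of n subjects genotyped at q biallelic variants in a region,
let K be the number of haplotypes with posterior support in the sample. The
trait model is

    Y = Xα + Σ_m β_m h_m + b + ε,    b ~ N(0, σa² Φ),   ε ~ N(0, σe² I),

with X an n×p covariate matrix **without intercept** — the expected
haplotype dosages h_m sum to 2 for every subject, so the dosage columns
span the constant vector and absorb the intercept. A consequence worth
being explicit about: the individual β_m are not separately identified
against a mean shift; only contrasts β_m − β_m′ are. All downstream tests
are therefore built on contrasts.

Φ is the relationship matrix (twice the kinship coefficient), built from
the pedigree by the standard recursion with founders assumed unrelated and
non-inbred; individuals referenced by the phenotype but absent from the
pedigree are treated as singleton founders, so cohorts mixing families and
unrelated subjects need no special handling. Only the pedigree route is
implemented; marker-based relationship matrices are out of scope.

Fixed effects are estimated by GLS at the ML variance components:
(XₒᵀΩ̂⁻¹Xₒ)⁻¹XₒᵀΩ̂⁻¹Y with Xₒ = (X, h₁, …, h_K), Ω = σa²Φ + σe²I, and
covariance (XₒᵀΩ̂⁻¹Xₒ)⁻¹. The cohort exports its haplotype labels,
frequencies, β̂ and the haplotype block of the covariance as a JSON
summary — the only object the meta stage ever sees, mirroring consortium
practice where cohorts share summaries, not data.

### Variance-component estimation

ML (not REML), because the effect-covariance contract above is stated at
the ML estimates. The likelihood is profiled: with Ω = σe²(γΦ + I) and
γ = σa²/σe², one eigendecomposition of Φ turns every likelihood evaluation
into diagonally weighted least squares; β and σe² then have closed-form
profiles and the optimization is a bounded scalar search over
log γ ∈ [−12, 12] (tolerance 1e-8 on log γ). The γ = 0 boundary (no
additive variance) is permitted and flagged; a residual variance collapsing
to zero (constant trait) is flagged degenerate. Because Φ is block-diagonal
by family, the simulation engine eigendecomposes one block per family
*shape* (nuclear family with k offspring) and reuses it across the tens of
thousands of fits a simulation study needs; the dense-Φ path and the
block path are algebraically identical and are cross-checked by test.

### EM haplotype inference

Haplotype frequencies are estimated from unphased genotypes by EM on the
multinomial phase-unknown likelihood. A subject heterozygous at H sites is
compatible with 2^(H−1) unordered haplotype pairs; subjects are grouped by
genotype row so the E-step enumerates each distinct row once. Phase
information available in simulation is deliberately ignored — it is not
available in real data. Choices:

* **Initialisation**: product of observed allele frequencies (deterministic);
  a seed feeds optional random restarts only. Likelihoods with flat ridges
  exist (e.g. every subject doubly heterozygous at two sites); the
  deterministic start then sits at the symmetric stationary point, which is
  reproducible, and restarts can reach the boundary maxima.
* **Convergence**: absolute log-likelihood change < 1e-8 (default), cap
  5,000 iterations; non-convergence sets a warning flag rather than raising.
  The log-likelihood is non-decreasing by construction and asserted so in
  tests.
* **Pruning**: haplotypes fitted below half a chromosome's worth of
  support (frequency 0.25/n) are removed and the EM re-converged on the
  reduced support (zeros are absorbing under EM updates, so the result is
  again a fixed point). Such frequencies describe phase configurations
  with essentially no posterior weight; keeping them produces
  all-but-zero dosage columns that make the cohort regression singular. A
  haplotype carried unambiguously by any subject is estimated at
  ≥ 1/(2n) and can never be pruned.
* **Missingness**: subjects with any missing genotype in the region are
  excluded from both EM and regression (`complete_cases`); simulated data
  has none.
* **Rare-haplotype collapsing**: haplotypes below 0.1% frequency are merged
  into a single pooled category with a fixed sentinel label (`_RARE_`),
  identical across cohorts so pooled categories align in the meta stage.
  The pooled column stays in the regression — it is a haplotype column like
  any other and preserves the row-sum-2 structure.
* The EM runs on all subjects, related or not. Treating chromosomes as
  independent draws is wrong in families in principle, but is the standard
  practice the cohort-level tooling follows, and the type-I error
  simulations confirm it does not distort the test.

The EM is intended for a moderate number of variants (q below ~15);
enumeration is exponential in the number of heterozygous sites.

### Meta-analysis and testing

Cohort effect vectors are pooled by generalized weighted least squares over
the union of K′ observed haplotype labels, with block-diagonal Σ̂ (cohorts
independent, off-diagonal blocks exactly zero). Haplotypes observed in a
single cohort are retained. The union is ordered by decreasing
sample-size-weighted mean frequency with lexicographic tie-break, which
fixes output ordering deterministically.

The global test is Wald on the K′−1 contrasts against a baseline:
χ² = γ̂ᵀ[V*]⁻¹γ̂, V*_jj′ = V_jj′ − V_j1 − V_j′1 + V_11, df = K′−1. The
statistic is invariant to the baseline (asserted to 1e-8 in tests); for
reporting, the baseline is the haplotype observed in **every** cohort with
the highest pooled frequency (falling back to the overall most frequent if
none is shared). Per-haplotype contrast rows carry estimate, SE
(sqrt of diag V*) and a two-sided normal p; the baseline row is blank.

Numerics: all solves go through symmetric Cholesky factorizations, never
explicit inversion of stacked systems; the condition number of WᵀΣ̂⁻¹W is
computed and logged as a warning above 1e10. Reported covariances are
symmetrized against solve round-off, and PSD validation uses a tolerance
relative to the largest eigenvalue, since near-rank-deficient cohort
designs legitimately produce very large variances.

## Comparator meta-analyses

* **Single-variant min-P**: per cohort, each variant is fitted in its own
  LMM (intercept, age, sex, allele count, kinship random effect — the
  random effect is kept in family cohorts, consistent with the haplotype
  model); estimates are pooled by inverse-variance weighting, and the
  smallest pooled p-value is Bonferroni-corrected by the effective number
  of tests (simpleM: smallest number of leading eigenvalues of the
  genotype correlation matrix reaching 99.5% of the eigenvalue total). The
  correlation matrix is computed from the pooled genotypes of all cohorts
  in the replicate; variants monomorphic in a cohort are skipped there and
  dropped entirely if monomorphic everywhere.
* **Burden / SKAT**: per-cohort score statistics from the covariates-only
  null LMM, U = GᵀΩ̂⁻¹(Y−Xα̂) and V = GᵀΩ̂⁻¹G − GᵀΩ̂⁻¹X(XᵀΩ̂⁻¹X)⁻¹XᵀΩ̂⁻¹G,
  summed across cohorts. Weights are the Beta(1, 25) density at the MAF
  pooled across cohorts (weighted by 2n). Burden: (wᵀU)²/(wᵀVw) on 1 df.
  SKAT: Q = Σ w_j²U_j² against the eigenvalue mixture of diag(w)·V·diag(w).
* **Mixture tail**: P(Σ λ_k χ²₁ > q) by characteristic-function inversion
  of the Gil-Pelaez integral on a midpoint grid, with three explicit error
  controls at a 1e-9 absolute budget: grid spacing from a Chernoff bound on
  the aliasing mass, truncation once the phase derivative is locked and the
  alternating-tail bound (one half-period of the monotone envelope) is
  below tolerance, plus a first-order Euler step (half of the next
  half-period) to stop early. Eigenvalues below 1e-8 of the largest are
  dropped after rescaling. A moment-matching (Liu-type) approximation is
  the fallback if the inversion fails; tests pin the inversion against an
  independent Ruben-series oracle.

## Simulation engine

The generator reproduces the simulation study's conditions; its defaults
are the study conditions, not tuning knobs.

* **Study designs**: ten registered cohort compositions over three unit
  types — NF2 (nuclear family, 2 offspring), NFv (nuclear family,
  Uniform{1..4} offspring), U (unrelated singleton) — from five cohorts of
  250 NF2 families up to ten-cohort mixtures. One design lists five mixed
  cohorts, each combining a family block and an unrelated block.
* **Ages** are drawn by a constructive sampler that satisfies every
  generation rule exactly and never rejects: unrelated subjects and first
  offspring Uniform(30, 50); later offspring uniform on the ±5-year window
  around the first offspring minus the ±1-year no-twin exclusion zones of
  all existing siblings (the window always retains positive measure);
  mother = oldest offspring + Uniform(20, 45); father uniform on
  [max(mother−5, oldest+20), mother+5]. Sibling gaps are enforced pairwise.
  All constraints are hard-asserted over thousands of families in tests.
* **Sexes**: founders form one father (sex 1) and one mother (sex 2);
  offspring and unrelated subjects are Bernoulli(1/2).
* **Gene dropping**: founders draw two haplotypes iid from the panel
  frequencies; each offspring inherits one uniformly chosen haplotype from
  each parent, no recombination. Panels for *G6PC2* (4 variants,
  8 haplotypes) and *JAZF1* (5 variants, 14 haplotypes) are shipped as TSV
  fixtures; printed frequencies are renormalized to sum to one, with
  sub-threshold entries printed as "<0.001" transcribed as 0.0009. One
  variant's published allele pair is strand-flipped relative to the
  haplotype strings; the panels use the haplotype-table coding so labels
  match the printed strings.
* **Phenotypes**: one multivariate normal draw per cohort with mean
  0.02·age + 0.5·sex (+ genetic terms) and covariance σa²Φ + σe²I,
  σa² = σe² = 0.5, sampled family block by family block with cached
  Cholesky factors.
* **Effect calibration**: a causal variant with minor allele frequency MAF
  gets b_g = sqrt(R²/(4·MAF(1−MAF))); a causal haplotype with mean dosage
  h̄ (twice its frequency) gets b_h = sqrt(R²/(2·h̄(1−h̄/2))); R² = 0.01
  per causal term, relative to the unit residual scale σa²+σe² = 1. When a
  scenario has a single causal term its effect is doubled. The two
  denominators are variance-consistent (2·MAF(1−MAF) = h̄(1−h̄/2) at
  h̄ = 2·MAF). Genetic terms enter the mean through the *true* gene-drop
  counts, while the analysis sees only unphased genotypes.
* **Reproducibility**: every replicate draws from an independent generator
  stream keyed by (seed, design, scenario, replicate); cohorts within a
  replicate consume the stream sequentially. Identical arguments give
  byte-identical results.

What the generator does **not** emulate: recombination and mutation within
the region, genotype missingness, imputation uncertainty (best-guess
genotypes are assumed), population stratification, non-Gaussian traits,
and ascertainment. Passing tests therefore demonstrate correctness of the
estimator and its calibration under a clean additive Gaussian model with
exact pedigrees — not robustness to the messiness of real cohort data.

## Experiments and problem sizes

`run_type1` simulates a design under the null and reports the fraction of
global-test p-values below α; `run_power` runs the haplotype test and the
three comparators on identical replicates; `run_estimate_bias` compares
mean pooled causal contrasts with the generating effects, using the most
frequent non-causal haplotype as baseline so the true contrast equals the
simulated effect. Replicate-level numerical failures (singular designs)
are excluded and counted; more than 1% aborts the experiment. The default
replicate counts are 2,000 for type-I error and 500 for power/bias —
enough for 3-SE Monte-Carlo bands around the published rates — with flags
to raise them to the original 10,000/1,000.

## Known limitations

* Quantitative traits only; no binary-trait (GLMM) stage.
* One additive random effect; no REML, no multiple variance components.
* EM phasing is exponential in heterozygous sites; intended for q < ~15.
* Fixed-effects meta only — no between-cohort heterogeneity model.
* Per-haplotype effects are reported as contrasts against a baseline; they
  are not absolute effects (see the identifiability note above).
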