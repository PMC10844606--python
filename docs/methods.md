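# Methods

This note documents the statistical models, algorithms and design choices
in `opbreed`, in the order the evaluation chain uses them.

## Data model

Three tables drive everything. The **pedigree** (id, dam, sire) is
normalised to a single unknown-parent sentinel (accepting the common
`NA`/`0`/empty dialects) and held in topological order; cycles,
self-parentage and duplicate ids are rejected at read time. The
**genotype matrix** codes each individual × SNP cell as the count of the
alternate allele (0/1/2, NaN for missing); allele frequencies are always
recomputed from the non-missing entries of the matrix at hand, never
stored, so every derived quantity is consistent with whatever SNP subset
is in use. Coding orientation is taken from the file as-is: the genomic
relationship matrix is invariant to flipping any SNP's coding once
frequencies are recomputed, so no ref/alt harmonisation is attempted.
SNPs with more than 50% missing data (configurable) are dropped at read
time because mean imputation degrades beyond that. The **phenotype
table** is long-format (id, site, replication, trait, value) with the
constraint that each individual grows on exactly one site — the
progeny-test design this package targets.

## Relationship matrices

* **A** — numerator relationships by the tabular method over the
  topologically sorted pedigree: founders mutually unrelated and
  non-inbred, `A(i,i) = 1 + F_i` with `F_i` half the parents'
  relationship. Ungenotyped dams stay in A, so pedigree-based fits
  predict their breeding values too.
* **G** — `G = WW′ / (2 Σ_k p_k q_k)` with `W` the 2p-centred codes and
  `p_k` the observed frequency. Monomorphic SNPs contribute zero to both
  numerator and denominator and are dropped with a logged count.
  Missing codes are mean-imputed per SNP first (which leaves `p_k`
  unchanged). Because centring uses the sample's own frequencies, row
  sums of G are ≈0 and within-family means sit slightly below the
  pedigree expectation (by roughly 0.25/n_families for half-sib designs);
  this is a property of the observed-frequency base, not an error.
* **D** — dominance covariates per SNP (−2p², 2pq, −2q² at codes 0/1/2;
  fractional imputed codes are quadratically interpolated through those
  three support points), scaled by `Σ_k (2 p_k q_k)²`.
* **Epistatic** — the Hadamard product `G ∘ D` for additive×dominance
  interaction.
* **Blending** — G (and D, G∘D) is singular whenever n exceeds the marker
  rank, so before any model inverts a genomic matrix it is blended,
  `K ← (1−w)K + wI` with `w = 0.01` by default, and the weight is carried
  in the matrix metadata. Unblended matrices are still accepted wherever
  only products with K are needed.

## Genomic pedigree verification

Three thresholds, all configurable because no principled universal values
exist: individuals with `G(i,i) < 0.6` are removed (failed genotyping /
contaminated samples); individuals whose mean relationship to their
recorded family is `< 0.1` are tested against every other family and
reassigned to the best family whose mean is `≥ 0.15`; leftover outliers
that are mutually related at `≥ 0.15` become new families and the rest are
reported unassigned. The defaults were chosen so that dam mislabels
injected by the simulator at realistic rates are recovered essentially
completely (the test suite requires ≥90% recovery at a 5% error rate);
on real data with shallow marker panels they may need loosening.
Kinship networks (edges where `K(i,j)` exceeds a threshold, typically 0.05
or 0.10, with connected components) visualise the same information.

## Two-stage evaluation

Stage 1 fits, per site and trait, intercept + random replication + random
pedigree additive effect + residual, and subtracts only the predicted
replication effects; site means stay in the data. The additive term is
included by default (`stage1_genetic_term`) so block predictions are not
contaminated by family structure when families are unevenly distributed
over blocks; it can be disabled. A site with a single replication is
passed through unchanged with a warning.

Stage 2 fits individual-tree mixed models on the adjusted data. The
response keys are (trait, site) combinations — three keys for a
single-trait multi-site model, nine for the three-trait model. Fixed
effects are one intercept per key. Each random term (additive, and
optionally dominance and epistatic) has effects for every individual at
every key with covariance `Σ_t ⊗ K_t`, `Σ_t` unstructured across keys.
Residuals are unstructured across traits within a site and structurally
zero across sites (each tree is measured on one site; sites are assessed
separately), and independent across individuals.

## REML estimation

Variance components are estimated by EM-REML with the restricted
likelihood evaluated in observation space: each iteration builds the
phenotypic covariance `V = Σ_t (Σ_t ⊗ K_t gathered) + R`, factorises it
once (Cholesky), forms the REML projection `P`, and applies closed-form EM
updates — for a genetic term,
`Σ⁺[j,l] = (û_j′K⁻¹û_l + n Σ[j,l] − Σ Σ[j,r]Σ[s,l] tr(Z_r′PZ_sK) Σ)/n`,
where the traces reduce to elementwise sums of `P` against the gathered
K, and for the residual the per-individual block analogue. Working in
observation space makes each iteration O(N³) in the number of records
rather than the (much larger) mixed-model-equation dimension, which is
what lets the multi-trait nine-key model fit in seconds to minutes at the
problem sizes used here (hundreds to ~2000 records).

Plain EM is reliable but slow near the optimum, so the fixed-point
iteration is extrapolated with safeguarded SQUAREM steps: two EM updates,
a vector extrapolation, and acceptance only if the restricted likelihood
did not decrease (otherwise the plain EM result is kept). The trace is
therefore monotone and the fixed point identical to EM's;
`accelerate=False` restores plain EM. Convergence is declared on the
relative likelihood change (default tolerance 1e-8, maximum 2000
iterations; the convergence flag reports honestly when the cap is hit).
After convergence one Average-Information round builds the AI matrix over
all (co)variance parameters; its inverse supplies standard errors, and
heritability standard errors follow by the delta method with numerically
differentiated gradients.

Numerical safeguards: every covariance matrix is eigen-clipped to stay
positive definite (floor 1e-8 of the largest eigenvalue) after each
update — unstructured 9×9 matrices drift indefinite on small data
otherwise; initialisation gives half the phenotypic variance to the
genetic terms (split equally when dominance/epistatic terms are present)
and half to the residual, with 0.1·√(v_i v_j) same-trait cross-site
genetic covariances to break symmetry. Records missing a (trait, site)
cell are simply dropped; the residual EM update uses pairwise counts,
which coincides with exact EM when each tree has complete trait records
(the simulator always produces complete records).

## BLUP and prediction-error variances

Breeding values come from Henderson's mixed-model equations assembled at
the converged components: coefficient matrix
`[X′R⁻¹X, X′R⁻¹Z; Z′R⁻¹X, Z′R⁻¹Z + blockdiag(Σ_t⁻¹ ⊗ K_t⁻¹)]`. Terms
cover every individual in their relationship matrix, so dams without
records are predicted through A. PEV_i is the corresponding diagonal
entry of the inverse coefficient matrix; where blending pushes PEV above
the genetic variance it is clamped to it (theoretical accuracy 0 rather
than imaginary), with a logged count. The MME route and an independent
dense GLS/conditional-expectation route agree to 1e-8 on small instances
in the test suite, and the engine is relationship-matrix-agnostic
(identical K gives bit-identical ABLUP and GBLUP output).

## ssGWAS SNP preselection

Because every analysed individual is genotyped after QC, single-step GWAS
reduces to back-solving marker effects from the GBLUP solutions:
`û = W′G⁻¹ĝ / (2 Σ_k p_k q_k)` per site, using the pseudo-inverse so that
rank-deficient unblended G is handled exactly (ĝ lies in the row space of
W, where the solution is unique; this makes back-solved effects equal
direct ridge SNP-BLUP to machine precision, a test-suite invariant). The
per-site GEBVs come from the single-trait multi-site additive GBLUP fit
of each trait. SNPs are ranked by cross-site mean absolute effect
(largest first), by minor allele frequency (rarest first), or by a seeded
shuffle; all ties break by ascending SNP id so every ranking is
deterministic. Subset plans use sizes `round(j·m/steps)`, and the
combined multi-trait panel is the union of each trait's top-k. No
p-values or significance thresholds are involved anywhere — ranking is by
effect magnitude alone — and no LD pruning is attempted.

Preselecting SNPs by their effects estimated on the same data and then
refitting enriches the panel for apparent signal, so heritabilities from
the preselected panel are biased upward relative to the all-SNP panel.
The acceptance run reports both so the contrast is visible; interpreting
the preselected-panel estimates as population parameters requires
independent validation data, which is out of scope here.

## Selection summaries

Heritability per trait averages the genetic and residual variances over
sites before taking the ratio; dominance and epistatic variances join the
denominator when those terms were fitted. Theoretical accuracy is
`TA_i = √(1 − PEV_i/σ̂²_a)` per (individual, trait, site), clamped to 0
when PEV exceeds σ̂²_a. Expected gain of selecting the top N is
`100 · mean(top-N site-averaged BVs) / trait mean`.

## Optimum contribution selection

Candidates are scored by the equally weighted sum of their objective-trait
breeding values scaled to unit variance (no re-centring — BVs are already
deviations from the population mean). The optimiser chooses a subset of
at most `n_max` equally contributing individuals maximising the
**per-slot gain**: the sum of selected scores divided by `n_max`, so
unfilled deployment slots contribute zero. This objective makes the
unconstrained optimum exactly truncation selection of the top `n_max`,
lets the optimiser return fewer individuals when constraints make
low-merit fillers counterproductive, and guarantees that relaxing the
co-ancestry ceiling never lowers the achieved optimum (the feasible set
only grows).

The co-ancestry measure ΔF defaults to the mean pairwise relationship
among the selected (0 for a singleton), because published ceilings like
0.25 (half-sib relatedness) and 0.125 sit naturally on the relationship
scale; classical group co-ancestry `c′Kc/2` is available via
configuration and is always reported alongside. Auxiliary constraints
bound the selected set's mean BV of a trait (e.g. wood density ≥ 0, "no
loss against the base population"). Constraints are checked on candidate
subsets, never used to prune partial sets, because adding an unrelated or
high-density individual can repair a violation.

Two solvers: exact depth-first branch-and-bound over candidates in
descending score order (bound: current sum plus all remaining positive
scores that fit), used up to 25 candidates and returning a certified
optimum; and a greedy-truncation + pairwise-swap local search with seeded
random restarts (default 50) for larger candidate lists. The heuristic
matched the exact optimum in 100/100 seeded trials on 15-candidate
problems in this suite and can never exceed it. Infeasible constraint
systems raise an explicit error rather than returning an empty set.

## The synthetic progeny test

The generator emulates the data structure the framework assumes. Founder
genotypes are drawn per SNP under Hardy–Weinberg equilibrium with allele
frequencies uniform on a configurable band (default 0.05–0.5). Each OP
family's offspring are gene-dropped: one gamete from the dam and one from
a sire whose identity follows the sibship mixture — the dam itself
(selfing), one designated within-family father (full-sibs), or a fresh
unrelated pollen-pool father per offspring (half-sibs). Defaults are
self 0.05 / full-sib 0.25 / half-sib 0.70 — plausible for conifer OP
seedlots, exposed in configuration, and not estimates of any particular
population. SNPs are unlinked; there is no recombination map, no
selection across generations, and no spatial structure within sites.

A single shared QTL set (default 100 of the SNPs) drives all traits.
Per-QTL effects are multivariate normal across traits and sites with
covariance (trait correlation matrix) ⊗ (exchangeable site correlation,
default 0.8), which makes site-specific breeding values the correlated
traits the multi-site models assume, and gives the GWAS ranking a true
causal structure to find. Default trait targets: h² = 0.6/0.4/0.5 and
genetic correlations −0.53 (HT,WD), −0.72 (DBH,WD), +0.5 (HT,DBH); means
15 m, 20 cm, 0.45 g·cm⁻³. Phenotypes are site mean + block effect +
site-specific BV + independent residual, with the phenotypic sd set to
15% of the trait mean, BVs rescaled so site-1 realized additive variance
hits the target h², and the same residual variance at every site.
Recorded pedigrees list all sires unknown; dam mislabelling replaces a
configurable fraction of dams with another family's dam.

What passing tests on this generator do **not** show: robustness to
linked markers and LD structure, to genotyping error, to
genotype-by-environment patterns beyond an exchangeable site correlation,
to spatial field trends, or to selection history in the base population.
One structural consequence matters for interpreting the
optimum-contribution results: with an effectively infinite unrelated
pollen pool there is no ancestral co-ancestry across families, so the
mean kinship of a 30-tree selection from 25 families is tiny (~0.004) and
half-sib-scale ΔF ceilings (0.25, 0.125) cannot bind; the acceptance run
therefore adds a ceiling on the population's own kinship scale to
demonstrate the binding trade-off. Real OP populations with shared
ancestry sit much closer to the published ceilings.

## Problem sizes and determinism

Everything is deterministic given the seeds in configs and function
arguments. The test suite and the acceptance script use simulated
datasets of roughly 450–1500 trees and 200–5000 SNPs — large enough for
the statistical effects (inflation direction, parameter recovery within
±0.1, QTL enrichment) to be stable across the fixed seeds, and small
enough that the whole suite runs in a few minutes on one CPU. The
acceptance run uses 25 families × 30 offspring × 3 sites and 3000 SNPs.

## Known limitations

No single-step H-matrix (ungenotyped individuals with records are not
supported in genomic fits); no Bayesian alternatives to REML; no
spatial/competition effects; exact EM for residuals with partially
missing trait records is approximated by pairwise-count updates; the OCS
contribution scheme is equal-contribution subset selection, not
continuous contribution optimisation or mate allocation.
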