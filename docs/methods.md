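# Methods

## Model and sampler

The trait model is additive: y = b0·1 + X b + e, e ~ N(0, σ² I), where X
holds numeric genotype scores per marker (F2: {1, 0, −1} for A1A1 / A1A2 /
A2A2, so var(X) = 1/2 per locus; two-state designs: {1, 0}). Each effect
carries the hierarchical shrinkage prior b_k | σ_k² ~ N(0, σ_k²),
p(σ_k²) ∝ (σ_k²)^(δ−1) — a scaled inverse chi-square with ν = −2δ and zero
scale. δ must lie in (0, 0.5) for the posterior of σ_k² to be proper; at
δ → 0 the prior approaches the improper 1/σ_k² form, whose posterior places
infinite mass at σ_k² = 0 and makes a Gibbs chain non-ergodic (it absorbs at
zero). The default is δ = 0.05: close enough to the vague prior to shrink
hard, safely inside the proper region.

All full conditionals are conjugate and the sampler is a systematic-scan
Gibbs sweep: b0 (flat prior) → for each locus k in map order, b_k then σ_k²
→ σ² (scale-invariant 1/σ² prior, giving Inv-Gamma(n/2, SSE/2)). The σ_k²
conditional is Inv-Gamma((1−2δ)/2, b_k²/2), drawn through the gamma family;
the shape (1−2δ)/2 < 1/2 is fractional and the generator handles it. b_k²
is floored at 1e−12 in this draw so the chain cannot enter an exactly
absorbing zero state; the floor is far below any effect of practical size.

The default schedule is the study's: 1000 burn-in iterations, then 5000
retained draws thinned by 10 (51 000 total). Initialisation is b0 = mean(y),
b = 0, σ_k² = 1, σ² = var(y); checks showed the retained sample is
insensitive to the σ_k² starting value across 1 to 1e−6. The residual
vector r = y − b0 − Xb is updated incrementally (O(n) per effect update) and
recomputed from scratch every 200 sweeps; observed drift is ~1e−13, and the
kernel reports the maximum drift it saw so tests can bound it.

The hot loop is JIT-compiled (numba). The sampler's own randomness uses the
kernel's seeded stream; within-chain permutation uses a separate
xorshift64*-driven Fisher–Yates stream, so estimates and thresholds are
independently reproducible.

## Permutation thresholds

Between-chain mode runs an independent full chain on each permuted
phenotype vector and records the posterior mean of every effect — one
observation per permutation. Recording the mean (rather than a single
retained draw) is what makes between-chain intervals narrower than
within-chain ones; the final-draw variant is available via `record="last"`.

Within-chain mode permutes the phenotypes once before the first iteration
and again after every h-th full sweep (default h = 1). The initial
permutation matters: it makes h = L (the chain length) collapse exactly to
one between-chain run, which is the defining boundary case. The retained
draws form the per-locus null sample; critical values are the empirical
(α/2, 1 − α/2) percentiles with linear interpolation between order
statistics. Significance uses strict inequality, so a boundary estimate is
not significant. On evenly spaced, fully typed markers the threshold
profile is nearly flat (coefficient of variation ≈ 0.06 in the bundled
study); with uneven real maps it tracks local information content.

## Simulation and variance decomposition

Genotypes are simulated as Markov chains along each chromosome: F2 as two
independent gamete chains (no crossover interference) collapsed to
unordered genotypes, two-state designs as a single chain. Distances map to
recombination fractions through Haldane's function r = (1 − e^(−2d/100))/2
by default (Kosambi optional); selfed RILs use the expected Haldane–
Waddington recombination 2r/(1+2r) between fixed lines. Chromosomes are
unlinked (r = 0.5).

For an F2-coded additive model the genetic variance has the closed form
V_G = V_Q + V_L with V_Q = (1/2)Σ b_k² and V_L = Σ_{k<k'} b_k b_k'(1−2r_kk');
V_P = V_G + σ². The bundled 20-QTL design (single 2400 cM linkage group,
241 markers at 10 cM, b0 = 10, σ² = 10) gives V_Q = 46.7806, V_L = 19.6035,
V_P = 76.3841 under Haldane; the Haldane/single-group convention is adopted
precisely because it reproduces these linkage-covariance values, and distant
pairs contribute negligibly (1 − 2r decays exponentially). Nine of the 20
QTL positions fall between markers; those QTL are simulated on an augmented
map so their genotypes are genuinely linked to the flanking markers, and
only marker columns enter the regression. Genotype and phenotype noise come
from independent streams spawned from one seed, so genotypes can be reused
across phenotype replicates.

## Power and false positive rate

A QTL's detection window is the set of markers within 10 cM of its position
(the covering marker triplet on the 10 cM grid; two markers when the QTL
sits midway between markers; truncated at chromosome ends). A QTL counts
as detected when any window marker is significant, on either tail. Markers
in no window are "false" loci; the windows of the 20 bundled QTL overlap for
closely linked pairs, so their union reserves 44 markers and leaves 197
false loci (the nominal 20 × 3 = 60 double-counts overlaps). A significant
call inside any reserved window is never a false positive. Replicate seeds
are base_seed + replicate index, so aggregates are independent of execution
order. The default study scale here is 20 replicates of n = 500 — large
enough to bound the largest QTL's power and the average false positive rate
while keeping a run under ten minutes on one core.

## Genome-selection cross-validation

Individuals are partitioned into k = 5 folds (sizes within 1). Per fold,
one estimation chain and one within-chain null chain are fitted on the
training 4/5; thresholds at every γ on the grid {0, 0.1, …, 1} come from
that single null sample (identical null draws, large compute saving) and
mask the posterior-mean effects before predicting the held-out 1/5. Δ_s is
the fold's mean squared prediction error — the natural generalisation of
the 5/n normalisation when folds are unequal — and PE(γ) is the mean over
folds. γ = 0 means the (0%, 100%) null interval, which no estimate escapes:
the intercept-only predictor. γ = 1 includes every effect. Ties in the
argmin break toward the larger (more inclusive) γ, since including all
effects is the robust fallback. NaN phenotypes are mean-imputed before
partitioning.

On strong-signal data PE drops steeply from γ = 0 (intercept only) to
γ ≈ 0.1–0.2 and then plateaus; because shrinkage already makes sub-threshold
effects tiny, the plateau is nearly flat and the literal argmin is diffuse
across it (PE differences of ~0.2% against fold noise of similar size), with
PE(1) within a fraction of a percent of the minimum.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions exactly: Mendelian
segregation, Markov linkage along a dense evenly spaced map, fully observed
codominant markers, Gaussian residuals, additive QTL only. It does not
emulate dominance or epistasis, segregation distortion, genotyping error,
missing marker data (supported in analysis via the multipoint HMM, but not
generated), crossover interference, or uneven marker information — so
passing tests demonstrate correctness of the machinery under idealised
conditions, not robustness to the messiness of real crosses. The three
real-data situations the analysis side supports (RIL/DH/F2 maps with
pseudomarkers every 2–5 cM, probability-coded columns, mean-imputed missing
phenotypes) are exercised in unit tests on small synthetic stand-ins.

## Numerical choices and known limitations

* Forward–backward uses per-interval transition matrices and scaled
  recursions; typed loci are exact point masses and conflicting calls at
  zero recombination distance raise an error rather than renormalising.
* Pseudomarker grids anchor at each chromosome's first locus; grid points
  within 1e−6 cM of an existing locus are skipped.
* Equal-tail credible intervals are empirical percentiles of the retained
  draws; with zero-inflated posteriors they are a deliberately weak
  detection criterion — the package's own analyses show them flagging far
  fewer (but, at n = 500, more than one) QTL than permutation thresholds.
* The variance decomposition assumes F2 coding (var(z) = 1/2); other
  designs would need their coding variances substituted and are currently
  rejected.
* Between-chain permutation at realistic scale (1000+ chains) is expensive
  by construction; the within-chain mode is the practical default and is
  slightly conservative (wider intervals, lower false positive rate).
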