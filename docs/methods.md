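# Methods

This note documents the models, estimators, numerical choices and design
decisions behind `campion`, and what the synthetic-data tests do and do not
establish about real data.

## Trait coding

Continuous traits are species-level (min, median, max) ranges in the units
of the source floras: stem length (cm), leaves per node (count), leaf
length, calyx height, calyx width and petal limb length (mm). Analyses use
the medians; the min/max bounds feed the resampling robustness loop.
Ordinal traits get monotone integer codes — inflorescence one/few/many →
1/2/3; tube extension and organ exsertion below/equal/above → −1/0/+1,
with the four-level exsertion trait's "above/equal" at +0.5 (order is what
matters for rank-based statistics; the exact spacing of the four-level
trait is not published, so the half-step preserving order is a package
choice and the encoding map is configurable and serialized with outputs).
Floral color is binned to white/pink/red: white/pink polymorphs code as
pink (the species can make petal anthocyanins), pale yellow as white
(no anthocyanins), orange-pink as pink and orange-red as red; unknown
descriptions are a hard error unless an override is supplied. The CV uses
the sample (n−1) standard deviation, which is what makes the published
summary-table cells internally consistent. Species missing any continuous
trait are kept for univariate summaries but excluded from multivariate
stages.

## Trees and dating

The phylogenetic covariance **C** has C[i,j] = shared root-to-MRCA path
length and depths on the diagonal; Pagel's λ multiplies only the
off-diagonals. λ may exceed 1 up to the largest value keeping **C**λ
positive semidefinite, computed by bisection per tree rather than assumed.

Dating uses penalized likelihood: each branch has its own rate r, a branch
of observed length b over duration t contributes the Poisson-style term
b·log(rt) − rt, and adjacent branches pay a quadratic roughness penalty
weighted by the smoothing parameter (default 0). Node ages are
parameterized as logistic fractions of the parent's age, so the output is
ultrametric with strictly decreasing ages by construction; the root age is
a bounded parameter and internal MRCA bounds enter as quadratic penalties
verified after the fit. With smoothing 0 the likelihood profile over ages
is nearly flat (rates can absorb any age assignment), so the optimizer
effectively refines the proportional-depth initialization — the same
degeneracy the underlying method has at zero smoothing; the returned tree
is always feasible and ultrametric, which is what downstream stages need.
Already-ultrametric inputs whose ages satisfy the bounds are returned
unchanged. Zero-length branches are perturbed by 10⁻⁸ × tree depth before
dating and logged. Two calibration presets ship: the morphospace tree
(root in [15.14, 26.49] Myr) and the ancestral-state tree (root in
[12.39, 31.7] Myr).

## Phylogenetic signal and ANOVA

λ is estimated by profile maximum likelihood (mean and rate profiled out
by GLS) on a 21-point grid over [0, λmax] refined by bounded scalar
minimization; the test against λ = 0 is a 1-df likelihood ratio. Blomberg's
K divides the observed ratio of ordinary to GLS mean squared error by its
Brownian expectation (tr C − n/1ᵀC⁻¹1)/(n−1); the permutation test shuffles
tip labels and counts permutations whose GLS error is at most the observed
(one-tailed for signal, add-one rule). Both statistics are invariant to
affine transforms of the data.

The phylogenetic ANOVA keeps the textbook one-way F but simulates its null
by Brownian motion on the tree at the GLS-estimated rate σ̂²; p is the
plain proportion of simulated F at least the observed (an add-one variant
is available). Post-hoc pairwise t statistics (pooled within-group MSE)
use the same simulations with Holm correction. Degrees of freedom are the
textbook k−1 and n−k. Note the simulated null is *not* invariant to which
tips carry which label on a structured tree — only the star-tree case is
exchangeable — so calibration tests run on star phylogenies.

Spearman correlation matrices use average ranks, pairwise-complete
observations, and Holm correction over each matrix's upper triangle
(constant-trait cells are NA and excluded from the family). Exact
permutation p-values are used for pairs with ≤ 7 complete observations;
larger samples use the t approximation (the error of the approximation at
n = 8–9 is far below the resolution of any downstream decision).

## Mk color evolution

Likelihoods use Felsenstein pruning with per-node rescaling; transition
matrices exp(Qt) come from eigendecomposition with a scaling-and-squaring
(`expm`) fallback when the eigenvector basis is ill-conditioned, and rows
are clipped/renormalized to machine tolerance. The root prior is flat by
default (matching the stochastic-map root choice) and can be stationary.

The seven-model set: ER (1 rate), SYM (3), ARD (6), and four stepwise
models on the ordered chain white ↔ pink ↔ red with the direct white ↔ red
jump forbidden — fully reversible (4), pink-red irreversible (red cannot
revert to pink; 3), red-white irreversible (interpreted as: the pink →
white reversal is forbidden, so whiteness is unrecoverable along the path
toward red; 3), and both irreversibilities combined (a strictly
directional white → pink → red chain; 2). The published source describes
its stepwise constraint matrices only in supplementary material, so the
last two parameterizations are this package's interpretation of the model
names; all constraint matrices are overridable. Rates are fit by
multi-start L-BFGS on log rates with a floor of 10⁻⁸ and a ceiling of 100
expected changes per tree height — beyond that ceiling the likelihood is
flat (tips become independent draws from the prior) and unbounded rates
only destabilize downstream mapping. Models within 2 AIC of the best are
flagged "retained".

Marginal ancestral states use the up-down (outside) algorithm — each
node's subtree-conditional likelihoods times the likelihood of the rest of
the tree given the node's state — which is exact for any root prior and
agrees with brute-force enumeration on small trees. Stochastic maps draw
the root from prior × root partials, descend node states conditioned on
the parent and subtree partials, and fill branch paths by
endpoint-conditioned uniformization: the number of candidate jumps is
sampled from weights Poisson(μt; n)·[Rⁿ]ᵢⱼ with μ = 1.05·max(−Qᵢᵢ),
normalized by the accumulated series itself (robust to truncation and to
under/overflow at large μt), then intermediate states are
backward-filtered and jump times placed uniformly.

## Phylogenetic PCA

Correlation-mode pPCA (the covariance mode is a flag): λ is estimated by
joint ML over all traits under multivariate Brownian motion, the GLS means
and evolutionary covariance P are formed under **C**λ, P is converted to a
correlation matrix and eigendecomposed, and scores project the
standardized, GLS-centered data onto the eigenvectors. Signs follow a
deterministic convention (each component's largest-magnitude loading is
positive) so permutation and resampling runs are comparable. Encoded
ordinal traits enter as numeric columns — the analysis treats coded
categories as points on a line, which is the published design and a known
caveat. On a star tree the procedure reduces exactly to standard PCA.
Group ellipses are 95% normal ellipses: the group's 2×2 score covariance
scaled by the χ²(2) 0.95 quantile (5.991); groups under 3 members get a
mean only.

## Permutation and resampling tests

The two-group statistics are var(A)/var(B) and mean(A) − mean(B) on a
chosen component. The null relabels the full color vector across all
species (group sizes preserved); a mode restricted to the two focal groups
exists and is a documented deviation. Direction is explicit, never
inferred: variance ratios with red in the numerator default to the
one-sided "smaller than expected" alternative, mean differences to a
two-sided exceedance on the absolute value. p is the plain exceedance
count over the number of relabelings (add-one variant available). Whenever
the number of distinct relabelings is ≤ 20 000 the null is enumerated
exhaustively (multiset permutations) instead of sampled; degenerate
relabelings that zero the denominator group's variance count as +∞ in the
null, while a degenerate *observed* denominator is a hard error.

The robustness loop redraws exactly three traits — calyx height, calyx
width, petal limb length — uniformly inside each species' (min, max) and
reruns the pPCA per dataset (other columns stay at their coded/median
values); per-color means and variances of the leading components are
aggregated across datasets. Individual dataset failures are logged and
skipped; more than 5% failures aborts.

## Geography

Cleaning drops (0, 0), out-of-bounds and duplicate coordinates, then thins
greedily (points sorted by latitude, longitude; haversine distances) so no
two retained points are within the thinning distance (default 1 km, the
upstream default being unpublished). Ranges are built in an Albers
equal-area conic projection computed in closed form on the authalic sphere
(R = 6371.0072 km) — exact for areas, which is all the analysis uses —
with standard parallels placed one-sixth in from the pooled data's
latitude extremes; every species being compared shares one projection.
The published buffer is stated as "10 km²", dimensionally a length in a
buffering operation; it is implemented as a 10 km radius (configurable and
flagged to users). The overlap index divides the intersection area by the
sum of the two non-overlapping areas; identical ranges would zero that
denominator and are reported as +∞ with the sympatric flag set. Sympatry
is exactly overlap > 0 — no tolerance band.

Disparity contrasts: Kruskal–Wallis (tie-corrected, via scipy) on pairwise
|ΔpPC| by sympatry; an aligned-rank-transform two-way ANOVA (color-pair ×
sympatry) where each effect is aligned by the cell-mean decomposition,
ranked, and tested by drop-one-term F with sum-to-zero coding; and a
rank-based ANCOVA in the Quade style — response ranks regressed on
covariate ranks, group effect tested by F on the residuals — which is
invariant to monotone rescaling of the covariate and reduces (with a
warning) to a one-way rank test when the covariate is constant. All
pairwise tables treat the n(n−1)/2 species pairs as observations; pairs
are not independent, which the original analysis also accepts, and the
tests should be read with that caveat.

## Synthetic data

The generator mirrors the study design: 47 species (20 white, 18 pink, 9
red), a 43-tip ultrametric tree (four species lack sequences), occurrence
clouds per species. Trees are forward Yule simulations (each lineage
splits at the birth rate; one extra exponential waiting time after the
last split so pendant branches are positive), rescaled to a 20 Myr root —
inside the morphospace calibration window. Continuous trait medians evolve
by correlated Brownian motion at λ = 1 with per-trait means and SDs chosen
to match the study's published summary scales (e.g. calyx height 14 ± 6
mm, petal limb 7 ± 7 mm), a mild 0.4 correlation among the three
flower-size traits, and a floor at 5% of the trait mean (sizes are
positive). Ranges are median ± 25% (|median|). Ordinal traits threshold
latent Brownian variables at empirical quantiles matched to the published
level frequencies, so their phylogenetic signal is controllable. The
red-group contrast pulls red species' trait values and latents toward the
red centroid by a shrink factor, default 0.3 — the value at which the
permutation tests detect the reduced red variance with high power, playing
the role of the study's observed effect; factor 1 is the null fixture.
Every red species is polyploid; other species are diploid with probability
0.10 and diploid/polyploid with 0.05.

Occurrence clouds are truncated (3 SD) Gaussian scatters of 40 points
(plus the range-center point itself) with an 80 km spread. Species are
dealt round-robin into 6 clusters whose anchors sit 2500 km apart; a
member's range center is within 8 km of its anchor. Buffered ranges of
same-cluster species therefore always overlap (centers ≤ 16 km apart with
10 km buffers) and different-cluster ranges never can (truncation bounds
every point within 248 km of its anchor), so the planted
sympatric/allopatric classes are reproduced exactly by construction —
which is what makes the end-to-end geography test sharp.

What passing these tests shows: the estimators recover planted truth under
the model assumptions (Brownian traits, Mk colors, Gaussian ranges). What
they do not show: robustness to real-data features the generator omits —
non-Brownian trait evolution, gene-tree/species-tree discordance,
collection-effort bias and spatial autocorrelation in occurrences,
measurement error in flora-reported ranges, and allopolyploid reticulation.
Published-data percentages (e.g. the exact variance-explained split of the
deposited trait matrix) require the archived dataset and are outside the
test suite.

## Problem sizes and determinism

Default test and pipeline sizes are chosen so the full suite runs in a few
minutes on one CPU: 1000 permutations/simulations for headline tests,
5000 stochastic maps for the consistency check, 200–300-tip trees for
estimator calibration, 20–50 replicate studies for power estimates. Every
stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from one master seed, writes its config (with hash) into
the run directory, and reruns byte-identically. Stage outputs are skipped
on rerun only when the config hash matches.
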