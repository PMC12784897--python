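# Methods

## Scope and data model

`fishdiv` analyses a single-campaign fish survey along a reservoir
gradient. Inputs: a site × species table of counts and biomass (kg),
pooled over gears; a rooted phylogeny with branch lengths covering the
species pool; a site × variable environmental table; per-site river
distance to the dam and pairwise river distances. All site/species label
sets are reconciled up front (`align_inputs`): the default `strict` policy
refuses surveys containing species absent from the tree, because silently
dropping species changes every phylogenetic quantity; `prune` performs the
drop explicitly, with warnings. Ultrametricity of the tree is checked
(root-to-tip spread ≤ 1e-6 × height) and reported but not required — every
metric is defined for arbitrary non-negative branch lengths.

## Taxonomic α-diversity and dominance

Margalef `D = (S−1)/ln N`, Shannon `H′` (natural log, so Pielou
`J = H′/ln S` is bounded by 1), and a divergence measure: counts are
Hellinger-transformed (square root of within-site relative abundance) and
each site's Euclidean distance to the arithmetic centroid of the
transformed profiles is reported. The transform makes the measure
invariant to site totals.

IRI uses proportions in [0, 1]: `IRI = 10000 · Fi · (Ni + Wi)` where `Fi`
is the fraction of sites occupied and `Ni`, `Wi` are pool-wide shares of
individuals and biomass. On the bundled reservoir composition table this
convention reproduces the printed IRI column to within the rounding of the
2-dp printed inputs; percent-scale inputs would inflate values 100-fold.
Classification: strictly above 500 dominant, 100–500 (inclusive) common,
below 100 rare — "between" read as inclusive, "exceeding" as strict.

Sampling completeness is reported two ways, because "accumulation-curve
completeness" admits both readings: the abundance-based coverage estimator
`Ĉ = 1 − (f1/n) · (n−1)f1 / ((n−1)f1 + 2 f2)` from singleton/doubleton
counts, and the exact hypergeometric rarefaction curve
`E[S_m] = Σ_k [1 − C(n−n_k, m)/C(n, m)]` (no extrapolation beyond `n`).
Note the coverage estimator returns exactly 0 when every individual is a
singleton (`f2 = 0` makes the correction factor 1).

## Phylogenetic α-diversity and the null model

Faith PD is the summed branch length of the community's spanning subtree.
`include_root` defaults on — the subtree runs to the root, so the full
pool recovers the whole tree length and a single species retains its
root-ward history; the flag is exposed because both conventions are
current. MPD.abu and VPD.abu are the mean and variance of patristic
distances over **distinct unordered species pairs**, pair (i, j) weighted
by `f_i f_j` (relative abundances); self-pairs are excluded since the
quantities describe distances *among* species. A single-species community
has no pairs: both are reported missing.

The null model shuffles tip labels over the **pooled species list**
(species observed anywhere in the survey, not the full tree tip set if
larger), keeping the community matrix fixed — the standard "taxa labels"
randomization; the pool choice makes SES reflect the sampled pool.
`SES = (obs − mean(null))/sd(null)` with 999 permutations by default
(≥ 99 enforced); the rank p uses the add-one rule
`(count(null ≤ obs)+1)/(n_perm+1)`, which is strictly positive and equals
1 only when the observation tops every null draw. Where the metric is
invariant under the shuffle (null SD = 0: e.g. any metric on a star tree
with equal branches, or PD of the full pool), SES and the rank p are
reported missing with a warning. Calibration is verified in the test
suite: over randomly assembled communities SES is near-standard-normal
(|mean| < 0.15, SD ∈ [0.7, 1.3]).

## β-diversity partition

Pairwise (not multiple-site) Sørensen dissimilarity on incidence data,
Baselga-partitioned: `βsor = (b+c)/(2a+b+c)`,
`βturn = min(b,c)/(a+min(b,c))` (Simpson replacement), `βnes = βsor −
βturn`. Taxonomic (a, b, c) are shared/unique species counts; phylogenetic
(a, b, c) are shared/unique branch lengths of the two spanning subtrees
(PhyloSor construction). Root-path inclusion mirrors the PD flag so that
`a + b = PD(i)` and `a + c = PD(j)` hold exactly under either convention.
The additive identity is exact by construction and asserted to 1e-12.

Summaries use ratios of means over pairs (not means of per-pair ratios):
`turnover_share = 100 · mean(βturn)/mean(βsor)`, so turnover and
nestedness shares add to 100 exactly. The beta deviation
`(βtax − βphy)/βtax` is evaluated on mean total dissimilarities; positive
values mean sites exchange phylogenetically close species. The level
contrast uses Cohen's d on the pooled SD, signed phylogenetic-minus-
taxonomic (taxonomic larger ⇒ negative d), with a normal-approximation 95%
CI and a Welch t-test p. The two-group comparison is implemented as
Welch + Cohen's d; a Tukey HSD across exactly two groups reduces to a
pairwise test.

## Driver attribution

* **Environmental heterogeneity** — variables are z-scored (ddof = 1;
  constant variables dropped with a warning); per-site heterogeneity is
  the Euclidean distance to the profile centroid, the overall value the
  mean. The pairwise decay predictor is the Euclidean distance between
  z-scored profiles — the per-site and pairwise quantities are deliberately
  distinct objects.
* **Correlation screen** — Spearman ρ (average ranks on ties) of each
  α-diversity index against each driver (11 variables + dam distance);
  BH step-up applied per index family. The family structure is a package
  choice; it is the natural "one test family per response" reading.
* **Distance decay** — OLS of each β component on each pairwise distance;
  `adj R² = 1 − (1−R²)(n−1)/(n−2)` over the n = 36 pairs. Pairwise values
  are not independent, so alongside the parametric p a Mantel-style
  permutation p (site-label shuffles, seeded, 999 by default) is emitted
  as a clearly separated robustness column. A Gaussian identity link is
  used; β responses here sit well inside (0, 1), and a logit variant was
  judged not worth the interpretive cost.
* **Hierarchical partitioning** — two-predictor average-shared-variance
  decomposition: `I(X1) = R²(X1)/2 + (R²(X1,X2) − R²(X2))/2`, symmetric in
  X2; contributions sum to the full-model R² identically. The classical
  common fraction `R²(X1)+R²(X2)−R²(full)` and the residual `1 − R²(full)`
  are reported alongside. Near-collinear predictors (|r| > 0.999) warn.
* **Smooth trends** — each environmental variable (and per-site
  heterogeneity) against dam distance. The response is Shapiro–Wilk tested
  at 0.05 and log-transformed if non-normal (shifted first when values
  ≤ 0). The smoother is a cubic B-spline basis (statsmodels `BSplines`,
  df = 5) with a second-difference ridge penalty chosen by GCV over a
  40-point log-spaced grid; the GCV dof charge is inflated by γ = 1.4, the
  standard guard against small-n undersmoothing. The penalty null space
  contains straight lines, so a perfectly linear signal is fit exactly
  (deviance explained = 1). Reported: adjusted R² (penalized by the
  effective dof), an approximate F-test p for the smooth, deviance
  explained, and the EDF. Below 7 points the fit falls back to a straight
  line with a warning.

## Synthetic data

The generator mirrors the magnitudes of the motivating field campaign: 9
sites on a ~30 km river axis, 23 species, ~11 species / ~135 individuals /
~8 kg per site (calibrated loosely, ±30%). Components:

* **Tree** — forward Yule (pure birth) process, all lineages cut at the
  present and rescaled to height 1; ultrametric and binary by
  construction.
* **Layout** — sites evenly spread with jitter, dam distance increasing
  with site index; an optional tributary places the last third of sites on
  a branch departing *below* the upper main-stem sites, so straddling
  pairs travel down to the junction and back up — river distances then
  exceed differences of dam distances.
* **Environment** — 11 variables: four increase away from the dam
  (permanganate index saturating, COD/TN/turbidity linear), two decrease
  (sulfate saturating, water depth linear), five are baseline noise
  (temperature, pH, TP, nitrite, chlorophyll-a); Gaussian noise on all.
* **Survey** — niche assembly with two independent dials. Each species
  draws an optimum on the axis; presence probability is a Gaussian
  response whose width is `0.35/gradient_strength` (no niche filtering at
  0), times a steep logistic retention gate comparing a per-species
  persistence score against a threshold that climbs along the axis with
  `nestedness_strength`. The first dial produces replacement (turnover),
  the second ordered subset loss (nestedness); scenario-recovery tests
  confirm each dial dominates its component at both taxonomic and
  phylogenetic levels. A configurable fraction of species (default 2/23,
  matching the two ubiquitous invaders of the motivating survey) is forced
  present everywhere. Counts are Poisson around a log-normal species
  abundance rescaled to the per-site target; biomass multiplies counts by
  log-normal species body masses (median 44 g). Optional Brownian motion
  on the tree (blended, CDF-mapped) gives optima phylogenetic signal so
  phylogenetic β can track or decouple from taxonomic β; the default is
  no signal, under which turnover swaps species at random with respect to
  the tree and the beta deviation is positive, as in degraded-reservoir
  settings.

What the generator does **not** emulate: gear selectivity, seasonal
dynamics, detection error, abundance distributions beyond the log-normal
assumption (the field data give no distributional detail), or spatial
autocorrelation of the environment beyond the monotone trends. Passing
tests therefore demonstrate correctness of the computations and the
qualitative recoverability of assembly signals — not that any particular
field system satisfies the generator's assumptions.

## Reproducibility and numerics

All randomness flows from one master seed; each stage derives its own seed
from (master seed, stage name) via `numpy.random.SeedSequence`, recorded
in the run log, so stages re-run in isolation reproduce exactly and a full
rerun is byte-identical. Degenerate inputs are handled explicitly: empty
sites give missing α values and missing β pairs (warned); single-species
communities give missing evenness and MPD/VPD; zero-variance predictors
refuse decay fits; constant environmental variables are excluded before
standardization. Identities (β additivity, PD additivity of the
phylogenetic components, partition-sum of hierarchical contributions) are
enforced at 1e-10–1e-12 in the tests rather than assumed.

## Known limitations

* Phylogenetic β here is tip-weighted (terminal branch sharing);
  basal-weighted variants are out of scope, and the two can disagree.
* With 9 sites, GAM fits (including the screen of 12 trend fits) have
  limited power and occasional GCV undersmoothing despite γ = 1.4; the
  per-fit EDF is reported so over-wiggly fits are visible.
* The parametric p of distance-decay fits ignores the non-independence of
  site pairs; use the Mantel column for inference.
* LCBD/SCBD-style local contributions and multiple-site β decompositions
  are not implemented.
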