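# Methods

This note documents the models and procedures implemented in `socialqtl`,
the assumptions they rest on, the defaults and why they were chosen, and
what the bundled synthetic-data generators do and do not emulate.

## Pairwise interaction descriptors

For one co-cultured pair with phenotypes `w_L ≥ w_S > 0` the four
descriptors are

- mutualism `z_mu = w_L·w_S/(w_L − w_S)` (trait units),
- antagonism `z_an = 1/(w_L·w_S·(w_L − w_S))` (trait units⁻³),
- aggression `z_ag = w_L/w_S` (dimensionless, ≥ 1),
- altruism `z_al = 1 − w_S/w_L` (dimensionless, in [0, 1)).

The product of two phenotypes is largest, at fixed sum, when the two are
similar — similarity begets cooperation — so the product (normalised by
the phenotypic difference) proxies mutualism and its inverse antagonism.
The larger-over-smaller ratio proxies dominance of the larger member.
`z_mu` and `z_an` are symmetric in the pair and diverge at an exact tie;
pairs with `|w_L − w_S| ≤ tol·w_L` (default relative tolerance 1e-8) are
flagged, excluded from mutualism/antagonism analyses but retained for the
directional descriptors with `z_ag = 1`, `z_al = 0`. This preserves
sample size for the descriptors that remain well defined at a tie.
Descriptors are computed on raw trait values; an optional pre-scaling by
the population mean is available for cross-unit comparisons but off by
default. Directional descriptors attach to the ordered pair
(larger → smaller), with the ordering recomputed per trait.

When a monoculture arm exists (`u_L`, `u_S`; L/S labelled by the
co-culture phenotypes, so `u_L` may be smaller than `u_S`), the
model-free interaction strengths are `M_u = (w_L/u_L + w_S/u_S)/2`
(above 1: cooperation; below 1: competition),
`A_g = (w_L/w_S)/(u_L/u_S)` and `A_l = 1/A_g`. Correlating the
descriptors against these strengths across pairs — per growth phase for
time-series data — is the package's validation path. Pearson correlation
on raw values is the default; Spearman is available because the
descriptor–strength relations need only be monotone.

## Growth curves and phase partition

Microbial abundance series are fitted by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) to the logistic
`g(t) = a/(1 + b e^{−rt})`; a Gompertz alternative is selectable and
`select_model` picks by AIC. The logistic is the default because it is
the canonical sigmoid and its phase geometry is closed-form: inflection
at `t = ln(b)/r`, and the lag/linear and linear/asymptotic boundaries at
the extrema of the second derivative, `t = ln(b)/r ∓ ln(2+√3)/r`. Fits
use a data-driven start (asymptote from the series maximum, rate from the
observation span, shape from the half-maximum crossing) plus eight seeded
random restarts; a fit whose rate pins at its floor or that does no
better than a constant is flagged degenerate. Phase boundaries are
translation-invariant and scale-equivariant in time by construction.

## Genotypes and segregation

One F1 full-sib family. Testcross markers (informative in one parent)
code offspring 0/1 and segregate 1:1; intercross markers (informative in
both) code 0/1/2 and segregate 1:2:1; the intercross heterozygote is
code 1. Missing genotypes are `-1`; a pair with a missing genotype at
the scanned marker is dropped for that marker only. Monomorphic or
otherwise unclassifiable markers are *uninformative* and excluded from
scans. Segregation distortion is tested per marker by chi-square against
the Mendelian ratio; distorted markers are flagged and reported, never
removed — removal is a study-design decision, not the scan's.

## The genotype-combination scan

A pair carries, at each marker, a genotype combination: unordered
`{g_a, g_b}` for symmetric descriptors (3 testcross / 6 intercross
combinations), ordered `(g_L, g_S)` for directional ones (4 / 9). The
scan statistic compares a saturated one-mean-per-combination normal model
(common variance) against a single-mean null:

    LR = N · ln(RSS0 / RSS1),

N being the usable pairs at the marker. Combinations occupied by fewer
than `min_count = 2` pairs are dropped with the degrees of freedom
adjusted, a single rule applied identically in the observed scan and in
the permutation scan so that the two statistics are exactly the same
function of the data (at the default study sizes — 2,415 pairs from 70
sibs — sparse combinations essentially never occur). A vanishing RSS1 is
floored at `1e-12 · RSS0/N` and the capped LR flagged. The LR is
invariant to affine rescaling of the descriptor.

Pairs share individuals and are therefore strongly dependent; the
working likelihood ignores this deliberately, and **all** error control
is delegated to an individual-level permutation: individual identities
are permuted against the genotype matrix (each individual keeps its
whole-genome genotype vector), pair combinations are rebuilt against the
fixed pair phenotypes, and the genome-wide maximum LR is recorded per
permutation. The threshold is the `ceil((1−α)·n_perm)`-th order
statistic; a marker is declared when its LR strictly exceeds it. Because
the observed assignment is exchangeable with the permuted ones under the
null, the family-wise error rate is ≈ `(n_perm+1−k)/(n_perm+1)` ≈ α by
construction, whatever the dependence between pairs or markers.
Adjacent significant markers within 5 cM merge into one QTL (peak marker
reported) — raw significant-marker counts otherwise inflate with linked
neighbours at sub-cM marker spacing. The scan is marker-based; no
interval mapping is attempted, since the intended marker density
(~1 cM or finer) leaves nothing between markers to map.

Implementation: per-combination sufficient statistics for all markers
(and all permutations, in batches) are quadratic forms
`colsum(E_a ∘ (Y E_b))` of class-indicator matrices against a dense
pair-value matrix, so a 500-permutation genome scan is a handful of
matrix products. A reference per-marker path (`scan_marker`) computes
the identical statistic independently and the two are cross-checked in
the tests.

The *traditional comparator* (`traditional_scan`) is a one-way
genotype-mean ANOVA per marker on individual phenotypes with the same
permutation-threshold machinery; it is the baseline that pair-level
mapping is measured against.

## Effect partition

At a testcross QTL the four ordered combination means m(x_f, x_p), with
`x = ±1` for the focal and partner genotypes, decompose exactly through
orthogonal contrasts into an intercept, a direct effect δ (own genotype
on own phenotype), an indirect effect ι (partner genotype on own
phenotype) and a genome–genome epistatic effect ε. At an intercross QTL,
additive scores `x = g−1` and dominance indicators `z = [g=1]` give the
9-parameter saturated model (a_D, d_D, a_I, d_I, i_aa, i_ad, i_da,
i_dd); the 9×9 design is invertible so the partition reproduces the
combination means to machine precision (a missing cell falls back to
least squares with a rank warning). The ±1/indicator coding was chosen
because it renders the 2×2 partition orthogonal and matches the
additive/dominance vocabulary of quantitative genetics.

Variance attribution reconstructs each component's value per ordered
combination and takes its variance under the *observed* combination
frequencies (not the theoretical 1:1/1:2:1); the three headline shares
are proportions of the sum of the three component variances, with the
covariance cross-term reported separately rather than folded in. Under
equal frequencies the components are orthogonal and the shares reduce to
squared-effect shares. Standard errors come from a nonparametric
bootstrap over individuals — not pairs — because resampling pairs would
pretend away the dependence created by shared membership.

The body-mass dissection accepts either one phenotype per individual or
an (n×n) matrix of pair-context focal phenotypes. With a single shared
phenotype per individual the indirect contrast is structurally zero in a
fully crossed design (every focal meets every partner class in the same
proportions); recovering indirect effects requires phenotypes that vary
with the pair context, which is what the simulator provides.

## Social-network reconstruction

Each individual's *marginal genotypic value* at a QTL is the
frequency-weighted average of the combination means over the partner
genotype, at the individual's own genotype; partner frequencies are the
observed genotype frequencies at the marker. Missing genotypes are
imputed with the individual's row mean and flagged. Laying the detected
QTL (union over the four descriptor scans) along the genome in map order
gives each individual a genotypic profile; the QTL index serves as the
integration axis of a dynamic system

    dG_i/dt = f_i(G_i) + Σ_{j≠i} f_ij(G_j),

with polynomial components (partner components linear by default). The
axis ordering is genomic because it is reproducible and
data-independent.

Estimation proceeds in four steps, each with a reason:

1. **Local polynomial smoothing** (Savitzky–Golay, order `basis_order=4`,
   window ≥ 9). A *global* polynomial basis of that order would project
   every individual's profile into the same 5-dimensional function
   space, leaving the regression design rank-deficient — couplings are
   then unidentifiable no matter the sample. Fitting the same basis in a
   sliding window preserves each profile's identifying structure.
   Derivatives are taken from the smooth.
2. **Sparse selection.** Each node's derivative is regressed on the
   component features of its own and every candidate partner's profile
   with an L1 penalty chosen by BIC along the LARS path (cross-validation
   is available but tends toward prediction-optimal, denser solutions;
   when the axis is shorter than the feature count, blocked — contiguous,
   unshuffled — cross-validated LARS is used instead, since shuffled
   folds leak the axis dependence). Candidates below a relative
   contribution floor (component SD < 0.1 × derivative SD) are dropped
   and the in-degree capped at `max_in_degree = 3`.
3. **Rotation gate.** Profiles are smooth, so they carry far fewer
   effective degrees of freedom than axis points and penalised selection
   alone over-selects: independent smooth profiles can "explain" each
   other's derivatives through chance global correlations. Each
   surviving candidate must therefore beat a rotation null: all
   candidate profiles are circularly shifted along the axis (preserving
   autocorrelation, destroying alignment) and the candidate's partial
   contribution — residualised against the node's own component and its
   other selected partners — must exceed the (1 − 0.1) quantile of the
   *maximum* shifted-candidate contribution (150 shifts, one shared
   offset stream so inference is equivariant under relabelling of
   individuals).
4. **Weights.** Survivors are refit by OLS; the edge weight is the
   average marginal effect of the partner profile on the derivative
   along the axis (the component's constant is absorbed by the
   intercept and therefore not identifiable), and the edge sign is the
   weight's sign.

Pair classification is a pure function of the directed edge signs:
reciprocal positive = mutualism, reciprocal negative = antagonism, a
lone negative edge = aggression by its sender, a lone positive edge =
altruism by its sender. Reciprocal edges of opposite sign fit none of
the four canonical types and are reported separately as
aggression-with-benefit. Hubs are nodes whose total degree exceeds the
mean by `k` SDs (default 1); the hub summary reports a rank-sum
comparison of hub vs marginal phenotypes and the pair-type percentage
breakdowns by hub status. Exclusion experiments drop the QTL detected
*only* for one descriptor class and compare edge counts of the rebuilt
network against the full one.

## QTL DAG

Significant markers sharing an identical genotype vector across the
family (perfect linkage at the sample size) collapse to one
representative (first in map order). Over the unique columns a DAG is
learned by greedy hill-climbing on edge additions, deletions and
reversals, scoring each node's ordinal genotype codes as a conditional
multinomial given its parents' joint configuration with a BIC penalty
`(ln n / 2)·(r_child − 1)·Π r_parents`; acyclicity is enforced at every
move, the score is monotone along each climb, and the best of the
random restarts is kept. Edge orientation inside a Markov-equivalence
class is not identifiable from observational genotype data; orientations
are reported as learned, up to equivalence. Hub QTL are the top-degree
nodes, default count `⌈0.25·nodes⌉`; module annotation labels nodes by
their descriptor-kind memberships (multi-membership = pleiotropy) and
tabulates cross-kind connectivity. The input is ordinal genotype codes,
not genotypic values.

## Synthetic data

`simulate_fullsib_genotypes` draws parental gametes as Markov walks
along each chromosome with recombination fractions from the Haldane map
function `r = (1 − e^{−2d/100})/2` — no crossover interference, which is
second-order at ~1 cM marker spacing. Testcross markers take the
transmitted allele of a randomly chosen informative parent; intercross
markers the summed alleles of both. Default study conditions: n = 70
sibs, 5 chromosomes × 100 cM at 1 cM spacing, an even
testcross/intercross mix, heritability 0.4 (the benchmark grid also uses
n ∈ {100, 200} and h² = 0.1).

`simulate_pair_phenotypes` plants QTL as effect vectors in the partition
parameterization: the genetic value of an ordered pair is the summed
effect-model mean at its genotype combination, Gaussian residual noise
is scaled so the genetic share of pair-phenotype variance equals the
requested h² (computed empirically over pairs), and null mode (no QTL)
yields pure noise. Body mass is the individual's mean genetic value over
partners plus a residual on the *pair-context* noise scale — so a purely
indirect architecture leaves body mass with no detectable own-genotype
signal (the partner average is nearly constant across focals), which is
exactly why the traditional comparator fails on indirect effects while
the pair scan does not. The generator emulates the mapping design, not
the biology it abstracts: no shared environment, no group-size effects,
no non-Gaussian residuals, no linkage between the planted architecture
and unmodelled loci. Passing tests therefore demonstrate statistical
correctness of the machinery under the declared model, not robustness to
real-data pathologies.

`simulate_coupled_profiles` generates the network test bed: a sparse
antisymmetric coupling matrix plus uniform decay drives `dG/dt = AG`,
sampled at 240 axis points, with observation noise at SNR 5. Every
node's derivative is then *exactly* the planted sparse combination of
its neighbours' profiles, and — because an antisymmetric coupling matrix
is normal, with purely imaginary, mutually repelling eigenvalues — all
oscillation modes persist under the uniform decay and the node profiles
stay mutually distinguishable. Alternatives fail structurally, which is
why this design was chosen: a generic random linear system concentrates
its surviving trajectory in a few slow modes (profiles collapse onto a
shared low-dimensional eigenbasis); autonomous sigmoid families are
monotone and hence mutually collinear; and narrowband constructions
alias a child's profile onto its parent's derivative through the 90°
phase shifts of integration and differentiation.

## Monte Carlo harness

`power_fpr_experiment` simulates families per condition, scans each at
the α genome-wide permutation threshold, and reports: under a null
configuration the family-wise false-positive rate (any declared marker);
under planted QTL the power (a declared marker within 10 cM of a true
locus), alongside the traditional own-genotype ANOVA arm on body mass.
The bundled acceptance computation runs 200 null replicates at n = 70
with 500 permutations each; with the threshold convention above the
expected family-wise rate is `26/501 ≈ 0.052`, and a 200-replicate
estimate of it carries a binomial SE of ~0.016.

## Numerical and degenerate-input conventions

- All randomness flows through `numpy.random.default_rng` seeds; every
  public routine with a stochastic step takes a `seed` and is
  reproducible bit-for-bit (the batched permutation engine runs its
  matmuls in float32, which the tests bound against the float64
  reference path at 1e-4).
- Ties: tied pairs (descriptors), identical profiles (network → flagged
  degenerate, no edges), constant abundance series (growth → degenerate
  flag), all-one-combination markers (scan → LR 0, degenerate flag).
- Bootstrap resamples that lose a genotype class are skipped rather than
  patched.
- File formats are plain delimited text with headers (`NA` missing);
  every CLI result file gets a JSON metadata sidecar with the package
  version, parameters and seeds that produced it.

## Known limitations

- The pair likelihood treats dependent pairs as exchangeable
  observations; only the genome-wide threshold, not per-marker p-values,
  is calibrated. Report-worthy inference should rest on the permutation
  threshold alone.
- Effects are per-QTL marginal; no multi-locus joint model is fitted,
  so linked QTL absorb each other's effects within the merge window.
- The network inference assumes the additive component model along the
  QTL axis; the axis itself is an ordering device, and couplings should
  be read as statistical dependence among genotypic profiles, not as
  temporal dynamics.
- The DAG learner requires complete genotype columns and reports one
  member of an equivalence class.
- Families are analysed independently; there is no multi-family joint
  scan.
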