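# Methods

This note records the statistical model behind each component, the
defaults and why they were chosen, the numerical conventions, and the
known limitations.

## Estimators

f2, f3 and f4 are estimated as means of per-SNP terms over the SNPs at
which every population entering the statistic has at least one observed
allele ("complete cases" per statistic; graph fitting and the f4-matrix
tests use the joint complete-case set over all populations in the
model).  With observed allele-1 count and total allele count (c) per
population per SNP, the per-SNP terms are

- f2: (pA − pB)² − hA/cA − hB/cB
- f3: (pX − pA)(pX − pB) − hX/cX
- f4: (pA − pB)(pC − pD)

where h = p(1−p)·c/(c−1) estimates heterozygosity.  The h/c subtractions
remove the upward bias that finite-sample frequency noise adds to
squared terms; f4 is a product of independent contrasts and needs none.
The corrections preserve the linear identities f3(X;A,B) =
(f2(X,A)+f2(X,B)−f2(A,B))/2 and f4(A,B;C,D) =
(f2(A,D)+f2(B,C)−f2(A,C)−f2(B,D))/2 exactly, which the tests assert at
1e-12 relative tolerance.  Bias correction defaults on for f2/f3 and is
not applicable to f4; an inbreeding-aware correction is out of scope.

### Block jackknife

SNPs are grouped into contiguous blocks within chromosomes; a block
opens at its first SNP's genetic position and accepts SNPs within
`block_span` (default 0.05 Morgans) of that anchor.  If genetic
positions are absent the partition falls back to 5 Mb physical spans and
warns.  Uncertainty comes from the weighted delete-one-block jackknife
with block weights equal to SNP counts: the reported mean is the
whole-data estimate and the variance uses the pseudovalue form for
unequal block sizes, which reduces exactly to the textbook delete-one
formula for equal blocks.  Vector statistics use the same pseudovalues
with a scalar 1/(h_j − 1) weight per outer product, so the covariance
diagonal reproduces the univariate formula exactly.

## Rank tests and admixture weights

The matrix X[i,j] = f4(l0, l_i; r0, r_j) over a left set (base l0) and a
right set (base r0) is Gaussian-approximated with the jackknife
covariance Q of vec(X), regularized by adding `diag` (default 1e-4)
times the mean diagonal.  The rank-r hypothesis is fitted by alternating
generalized least squares on the factorization X ≈ AB′ (initialized from
the SVD, converged when the quadratic form improves by < 1e-6, capped at
200 iterations); the test statistic is the fitted quadratic form with
(|left|−1−r)(|right|−1−r) degrees of freedom.

Admixture weights for a target with k sources come from the left null
vector of the rank-(k−1) fitted mean, normalized to sum to one; a single
source returns weight exactly 1.  Negative weights are reported, not
clamped — the plausibility classifier (p ≥ 0.05 and every weight ± 2 SE
inside [0,1]) is the filter, and a model failing a criterion records it
in `failure_reasons`.  Weight standard errors re-run the factorization
and null-vector extraction on each delete-one-block f4 matrix while
keeping Q fixed at its full-data value: re-estimating a g-block
covariance inside each of g deletions is quadratic in g and changes
nothing at first order.  The left base is the target and the right base
the first listed right population; results are base-invariant only in
expectation, so the bases are part of the reported configuration.

Calibration at desk scale: the chi-squared approximation ignores the
sampling noise of Q, which inflates rejection rates when the number of
blocks is not large against the system dimension (a Hotelling-type
effect).  The bundled calibration checks therefore use ~200 blocks
against a 1×5 system, where the measured type-I error of the cladality
test is 5–7%.

## Graph fitting

For a leaf X, a_e(X) is the probability that a lineage from X traverses
drift edge e (products of admixture weights summed over paths).  With
edge lengths ℓ the frequency covariance about the root is C = A diag(ℓ)
A′ and every expected f-statistic is a linear combination of C entries.
The fit minimizes (y − D(w)ℓ)′ Q⁻¹ (y − D(w)ℓ) where y stacks the
observed f2(base,X) and f3(base;X,Y) over all leaves, Q is their
jackknife covariance (regularized as above; `lsq_mode` drops the
off-diagonals), D(w) holds the per-edge coefficients at admixture
weights w, ℓ ≥ 0 is solved by non-negative least squares after Cholesky
whitening, and w is optimized by L-BFGS-B in [0,1] from `n_restarts`
random starts (CLI default 100; the reproduction-scale setting is 1000;
the statistical tests use 2–8 since the preset's weight surfaces are
unimodal).  The score is −½ of the quadratic form: a Gaussian
log-likelihood up to a constant, comparable across models fitted to the
same data.  The score is invariant to the basis population because any
base's basis is an exact linear transform of any other's and the
jackknife covariance transforms consistently.

Residual diagnostics cover every leaf f2, f3 and f4 ("hires" scope):
observed minus expected over the statistic's jackknife SE, with the
worst |Z| reported; `zthresh` (default 0, i.e. report all) filters the
table.  Fixed admixture weights (e.g. an archaic contribution pinned at
3%) are honored by the optimizer.  Edges with zero path support are
reported at length 0 with a warning.

Non-identifiabilities are structural, not numerical: the two root-child
edges carry a single identifiable sum (the root slides along them), and
drift private to one component of an admixed leaf folds into the leaf's
own edge.  Noise-free self-fits recover every identifiable parameter to
1e-4 and the root-pair sum to 1e-6.

### Model comparison

Two fits on the same SNP set are compared by the rules: with different
admixture counts the more complex model is preferred only if it gains
more than 10 log-units of score or reduces the worst residual by more
than 0.5 SE; with equal counts, fits within 3 log-units are ties and
otherwise the higher score wins.  A model with a zero-length (tolerance
1e-7) backbone edge — an internal drift edge excluding the target's
attachment leg and the root-child edges — is a trifurcation and is
discarded before comparison.  When the simpler model wins because
neither cut-off was met, the verdict records the (insufficient)
log-likelihood margin.

## Exhaustive target mapping

A target attaches to an unordered set of 1–3 candidate drift edges: each
chosen edge is split by a new node; one edge hangs the target directly,
two or more feed cascaded two-parent mixture nodes (cascade order fixed
by the edge order; the model space is the unordered edge sets, which is
what makes E candidates give exactly E + C(E,2) + C(E,3) models).  The
root edge is excluded from candidates by default.  All free parameters,
including the skeleton's own lengths and unfixed weights, are refitted
per candidate model.  New legs start unset and are fitted like any
other length.  Selection walks admixture counts in increasing order
applying the comparison rules; `select_from_scores` replays the
decision sequence from the logged score table.  Skeleton construction
adopts the unique best model per added population and raises a tie
error listing the contenders rather than guessing.

## Synthetic data

`simgraph` generates per-SNP root frequencies uniform on (0.05, 0.95),
then drifts them down the graph: a drift edge of length ℓ replaces p by
a Balding–Nichols Beta draw with mean p and variance ℓ·p(1−p) (fixed
sites stay fixed), and an admixture node mixes its parents linearly.
The Beta law was chosen over clamped-normal increments because its
first two conditional moments are exact at every depth; clamping a
normal increment at the [0,1] boundary measurably biases deep
statistics (about 6% on the preset's deepest pair, many SEs at 5×10⁴
SNPs), which would break the estimator-against-truth validation this
module exists for.  The clamped-normal law remains available as
`drift_law="normal"`.

Raw f-statistics are in squared-frequency units while graph lengths are
normalized drift units, so `truth_stats` rescales each edge by the
exact expected heterozygosity of its parent node (computed from the
root law and the accumulated deviation covariances) before delegating
to the closed-form machinery.  Fitted graph lengths are therefore
comparable to the *effective* truth graph; admixture weights are
unit-free and compare directly.

Diploid genotypes are binomial(2, p) with independent per-call
missingness; genetic positions are uniform over `n_chromosomes` ×
`map_length`, so jackknife blocks have near-equal SNP counts.  The
generator deliberately omits linkage disequilibrium, selection,
sequencing error and array ascertainment: passing tests demonstrate
estimator correctness under the drift model, not robustness to those
real-data features, and absolute statistic values are not comparable to
array-ascertained data.

### The bundled preset

An 11-leaf graph shaped like a continental-scale study system: two deep
outgroup-like leaves, an African-like leaf, a West Eurasian-related
leaf, a deeply diverged hunter-gatherer leaf with a Papuan-like
relative, a four-leaf East/Southeast Asian clade, and a South
Asian-like leaf admixed 55/45 between the West Eurasian and
hunter-gatherer lineages.  `preset_graph` adds a target drawing
ancestry from 1–3 named skeleton edges with given fractions;
`preset_spec(sas_fraction)` is the common two-component case (target on
an East Asian edge with an optional South Asian-like fraction).  Drift
lengths are 0.01–0.10, within the Beta model's comfortable range and
large enough that 10⁴–2×10⁴ SNPs resolve the topology.

## Problem sizes used by the bundled checks

Statistical suites run at desk scale, chosen so the whole test run fits
in minutes on one CPU while keeping every check well-powered: 10⁴–2×10⁴
SNPs, 10 diploid samples per population, 20–200 jackknife blocks, 150–
500 replicates for calibration rates, 50 replicates for placement
recovery with an 8-edge candidate subset (the true edges plus
distractors in every major clade) and 2 optimizer restarts.
`scripts/acceptance.py` uses the same conditions with slightly fewer
replicates and derives every stream of randomness from `--seed`.

## Limitations

- The rank-test and graph-fit chi-squared/score calibrations degrade
  when the number of blocks is comparable to the statistic dimension;
  scores remain valid for comparing models on the same data.
- Worst residuals are comparable within this implementation; the
  original tool's likelihood constant and residual scope are not
  published, so absolute score values are not exchangeable with it.
- qpAdm here uses a fixed right set (no rotating protocol) and diploid
  calls only (no pseudo-haploid ancient-DNA handling).
- LD pruning uses pairwise-complete genotype correlation; no haplotype
  phasing or painting is provided.
- Merging drops strand-ambiguous allele-pair mismatches rather than
  attempting strand flips.
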