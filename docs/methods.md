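# Methods

This note records the statistical model behind `poms`, the conventions and
numerical choices the implementation commits to, what the synthetic-data
generator does and does not emulate, and known limitations.

## Balance-tree model

Balances are isometric log-ratio (ILR) coordinates indexed by the internal
nodes of a rooted, strictly bifurcating phylogeny. At node *i* with $n_L$
tips on the left side and $n_R$ on the right,

$$b_i = \sqrt{\tfrac{n_L n_R}{n_L+n_R}} \, \ln \frac{g(y_L)}{g(y_R)},$$

with $g$ the geometric mean of the side's taxon abundances. The coefficient
normalises the coordinate to unit length so balances are comparable across
nodes of different sizes. Balances are compositionally coherent: with
strictly positive abundances and no pseudocount, rescaling a sample's
abundances leaves every balance unchanged, so the method is insensitive to
sequencing depth. Because one zero annihilates a geometric mean, a
pseudocount (default **1**, applied to the raw abundances, whatever their
scale — typically MAG mean read depths) is added before the log-ratio. We
deliberately do not re-normalise to relative abundances before adding the
pseudocount; with the pseudocount in place the Wilcoxon/Spearman node tests
are rank-based, and any common per-sample scale factor shifts all balances
of a sample coherently.

Conventions: the first child in newick order is the "left" side (the choice
only flips signs and is fixed for reproducibility); the natural logarithm is
used (a different base rescales all balances uniformly and cannot change any
rank-based test); multifurcations are rejected unless the caller asks for
arbitrary zero-branch-length resolution, which is logged.

## Node tests

* **Two-group BSNs**: two-sided Wilcoxon rank-sum per node, uncorrected,
  default α = 0.05. The exact null distribution is used when both groups
  have ≤ 25 samples and the pooled balances are tie-free; otherwise the
  normal approximation with tie and continuity correction. The node's
  direction is the side whose balance median is higher in group 1; a node
  with tied medians is declared non-directional, logged, and excluded from
  CEF intersections (counted as a non-BSN).
* **Continuous BSNs**: Spearman correlation between balances and the
  covariate; exact permutation null for n ≤ 9 tie-free samples, otherwise
  the t-approximation with n − 2 degrees of freedom. The sign of ρ is
  discretised into a "high"/"low" direction so the downstream classifier is
  identical to the two-group case.
* **FSNs**: two-sided Fisher's exact test on the 2×2 table of encoding /
  non-encoding tips by node side, at *every* tested node. "Encodes" means
  copy number > 0 (copy numbers may be non-integer). The two-sided p sums
  all tables with the observed margins whose point probability is at most
  the observed one (relative tolerance 1e-7, the scipy convention; equality
  with `scipy.stats.fisher_exact` is asserted in the test suite). The
  implementation sweeps a cached hypergeometric pmf per margin set because a
  single run computes nodes × functions tests.

Node-level p-values are deliberately left uncorrected: multiplicity is
controlled across functions, where the scientific claims are made.

## The multinomial exact test and the mass-action null

For each function the significant FSNs are partitioned into
(non-intersecting, intersecting-toward-group-1, intersecting-toward-group-2)
by whether the node is a directional BSN and whether the function-enriched
side matches the BSN's group-1-higher side. With $T$ tested nodes and $B$
directional BSNs the null probabilities are
$((T-B)/T,\ B/2T,\ B/2T)$: FSNs land on BSNs in proportion to their
frequency (mass action), splitting evenly between directions. The exact
p-value enumerates all $\binom{n+2}{2}$ outcomes of the trinomial with the
observed total $n$, orders them by the log-likelihood-ratio statistic
$G = 2\sum_k k_i \ln(k_i/(n p_i))$ (with $0\ln 0 = 0$), and sums the
probabilities of outcomes with $G \ge G_{obs}$, including ties at relative
tolerance 1e-9. A zero count in a zero-probability category contributes
nothing; a positive count there is an error. When $B = 0$ every test
degenerates to p = 1 and the run emits a warning rather than failing.

Functions with zero significant FSNs are retained with p = 1, so the
Benjamini–Hochberg family equals the full set of tested functions — this
keeps reported proportions of significant functions interpretable.
`direction_summary` is conservative: "groupX-consistent" only when the
opposing intersection count is zero, otherwise "mixed" (a record with no
intersections at all is also labelled "mixed" — it cannot be consistent
toward either group); the raw class counts are always reported for post-hoc
inspection, since a significant "mixed" CEF is a real, interpretable
outcome (depletion of non-intersecting FSNs).

## Pre-filters

Before analysis, taxa absent from every sample are dropped from both
tables; then functions encoded by fewer than 5 taxa or by < 0.1% of the
remaining taxa are dropped (both thresholds configurable). "Present" means
abundance strictly greater than zero. The fraction filter's denominator is
the post-taxa-filter count. After filtering, the tree is sheared to the
surviving taxa (child order preserved) so that tree tips and table rows
always match.

## Phylogenetic regression

Per function, a generalised least-squares fit of a per-taxon response on
the copy-number column under $y \sim \mathcal N(X\beta, \sigma^2 C)$, where
$C_{ij}$ is the root-to-MRCA shared path length (Brownian-motion trait
covariance). The fit whitens through the Cholesky factor of $C$ (no
explicit inversion); $\hat\sigma^2$ is the maximum-likelihood estimate
RSS/n; the slope is tested with a t statistic on n − 2 degrees of freedom.
One shot of diagonal jitter (1e-10 · trace(C)/n) guards against rank
deficiency from zero-length branches; a constant predictor yields a missing
(NaN) result that is excluded from the BH family. The estimates are
invariant to scaling $C$, and on a star tree the fit reduces exactly to
ordinary least squares.

Responses: the **significance indicator** (1 if the taxon's relative
abundance differs between groups by Wilcoxon at uncorrected p < 0.05, or
correlates with the covariate by Spearman; fitted with the Gaussian model —
the standard shortcut of passing an indicator to a linear phylogenetic
model, not a phylogenetic logistic regression); **prevalence** (fraction of
a group's samples where the taxon is present); and **specificity**. For
specificity we use a simple group-affinity score of our own:
$\log[(\bar y_{group} + \epsilon)/(\bar y_{all} + \epsilon)]$ on relative
abundances, with ε defaulting to the smallest non-zero relative abundance.
It preserves the role of the score (positive = concentrated in the group)
with a minimal, transparent definition.

Calibration caveat: the t-test is exactly calibrated when the response is
drawn from the assumed Brownian model (verified in the test suite at ~5%
raw-p rate under the model-matched null). An i.i.d. or permuted response
violates the assumed covariance and empirically inflates the raw-p rate to
roughly double nominal; this is a property of Brownian-motion regression
applied to non-phylogenetic responses, not of this implementation, and is
the reason the balance-tree workflow — not the regression — is the
conservative default for discovery.

## Faith's phylogenetic diversity

Hit summaries report Faith's PD of the taxa encoding each significant
function: the sum of branch lengths of the minimal subtree connecting the
tip set *and the root* (root-inclusive convention — the common default,
and monotone for singletons). High PD indicates phylogenetically broad
support, the signature of a consistently enriched function.

## Synthetic-data generator

`generate_community` emulates the inputs at desk scale. Defaults (chosen
once, with the rationale below, and fixed):

* **300 taxa, 40 + 40 samples, 400 functions** — large enough for ~30
  testable nodes and a meaningful BH family, small enough that
  50-replicate studies run in minutes on one core.
* **Random bifurcating tree** by sequential random pair-joining with
  exponential branch lengths, rescaled to unit maximum depth.
* **Abundances**: zero-inflated log-normal. Each taxon draws an occupancy
  probability (Beta with mean 1 − sparsity; default sparsity 0.7, typical
  of MAG presence matrices) and a log-normal mean depth across taxa
  (heavy tail: a few dominant taxa, many rare ones).
* **Gene presence**: a two-state (absent/present) Markov switching process
  along the tree, per function, with stationary presence frequency drawn
  log-uniformly between 1% and 95% (rare to near-ubiquitous) and switching
  rate 0.5 · 100^(1 − clustering). The default clustering of 0.75 (~1.6
  expected switches per unit depth) makes gene content phylogenetically
  conserved yet multi-lineage, which is how real KEGG-ortholog tables
  behave; clustering 0 approaches independent tips (encoder sets
  indistinguishable from uniform random subsets by Faith's PD, verified in
  the tests). Degenerate all-absent/all-present columns are re-drawn, then
  repaired by one flipped tip if necessary.

What the generator does **not** emulate: read-mapping noise, compositional
closure of sequencing (cells are independent given the taxon parameters),
correlated taxon co-occurrence beyond the tree, copy-number variation
structure, and the empirical depth distribution of any particular dataset.
Passing simulation tests therefore demonstrates the statistical machinery
and its calibration under controlled conditions, not performance on any
specific real dataset.

## Perturbation studies

The three schemes apply `abundance ← (abundance + 1) × 1.5` to target-group
samples only: to all encoders of a randomly chosen focal function
(focal-gene), to a uniformly drawn taxon set of matched size (random-taxa
control), or to all descendants of one internal node with ≥ 5 tips,
root excluded (clade-based). Evaluation ranks the focal function among
significant functions by ascending p (mean rank on ties); replicates where
the focal function is not significant are reported through the detection
fraction and excluded from the median rank, mirroring the convention of
omitting undetected cases from rank plots.

The studies run with **min_tips = 5** rather than the pipeline default
of 10: the default was calibrated for trees of ~1600 taxa, and at 300 taxa
it leaves only ~15 testable nodes, too few for the multinomial test to
resolve small p-values; 5 (matching the clade-size floor used by the
clade-based scheme, and between the package default and the value used in
the worked 60-tip example) yields ~30 nodes. Null-calibration replicates
(unperturbed data, arbitrary group labels) use the same setting; the
per-node BSN rate is additionally pooled over 70 balance-only replicates so
the rate estimate rests on > 2000 node tests.

## Known limitations

* Node balances are treated as independent tests, but nested nodes share
  tips; the clade-based simulations probe exactly this and show that a
  single blooming clade can occasionally produce spurious CEFs.
* CEFs require enough BSNs to intersect: a function cannot be flagged, no
  matter how adaptive, without balance shifts for it to coincide with.
* Functions encoded by very few (or nearly all) taxa cannot produce enough
  directional FSN overlap and are expected to be missed — the
  complementary regression workflow is more sensitive there.
* The exact multinomial enumeration is O(n²) in the FSN count per function;
  this is immaterial at realistic FSN counts (tens).
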