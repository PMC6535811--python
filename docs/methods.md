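# Methods

This note records the models implemented in `paleowgd`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical choices a maintainer would
want to know about.

## Trees, supports, and trait articulation

Trees are rooted `dendropy.Tree` objects with nonnegative branch lengths.
Bootstrap support lives on internal nodes (`node.support`, percent). The
Newick dialect written is the RAxML convention — support in the
internal-label position; a `[&support=…]` comment dialect is read but
never written. Note the usual caveat: support values are properties of
bipartitions, so after rerooting a gene tree the support attached to the
two nodes flanking the new root describes the same bipartition.

Trait tables (`species,value[,source]`) are matched to tips by exact
species id first. When a tip lacks a value and congener fallback is
enabled, the value of a congeneric species (same genus, parsed as the
prefix of the binomial before the first `_`) is substituted and the tip is
flagged `congener`. Ties among several congeners go to the
lexicographically smallest species id — a deterministic rule chosen so
output does not depend on file order. Multiple records per species
default to "first record wins" (curated prime estimates are listed
first); `aggregate="mean"` is available. Tips that still lack data are
pruned; pruning preserves path lengths between retained tips.

## Synthetic data: what it emulates

The generators reproduce the *structure* of a transcriptome-based WGD
study so every downstream stage has ground truth:

* **Species trees** — forward-Gillespie birth–death runs, stopped one
  exponential waiting time after reaching the target tip count so terminal
  branches are strictly positive; extinct lineages pruned; ultrametric by
  construction. Tips `S01…`, internal nodes `N1…` in preorder.
* **Gene families** — one ancestral gene copy evolves inside the species
  tree with per-lineage Poisson duplication and loss. A WGD is one
  synchronous duplication at the stem of a chosen internal node, applied
  per family with probability `retention_prob` — the chance the family
  keeps the duplicate through post-WGD fractionation. Both
  "retained at simulation" and "observable at tips" (both daughter copies
  left survivors) are recorded; surviving duplication nodes carry
  `true_event` tags. Gene-tree branch lengths inherit species-tree
  lengths: the placement algorithm is topology-only, so rate variation
  would be cosmetic. Node supports default to 100; the noise model used to
  exercise the bootstrap filter draws support below 80 (uniform 0–79)
  with probability `p_low_support` and 80–100 otherwise.
* **Chromosome counts** — exact Gillespie simulation of an arbitrary
  generator matrix along each edge, with a per-event log (gain, loss,
  duplication, demiduplication) that serves as the oracle for stochastic
  mapping tests.
* **Continuous traits** — BM by Gaussian increments; λ-BM by sampling the
  covariance-transformed multivariate normal; OU by exact per-edge
  transition moments with regime optima inherited from shift edges.

What the simulations deliberately do **not** emulate: sequence-level
evolution and alignment error, gene-tree estimation error (topological
mistakes, rogue taxa), hidden paralogy from incomplete transcriptome
sampling, allopolyploid network histories, and correlated trait/count
evolution. Passing tests therefore demonstrate correctness of the
algorithms under their own model assumptions, not robustness to every
artifact of real transcriptome data.

## Single-copy reduction

A clade whose tips all belong to one species and whose subtending node
has support ≥ 50 (default) is replaced by its single longest transcript;
ties go to the lexicographically smallest transcript id. The scan runs
preorder (so the first qualifying node on a path is the *maximal*
qualifying clade) and repeats to a fixpoint, which lets a low-support
single-species clade be reduced from the inside out exactly as far as
support allows. Reduction never changes the species set and never
increases any species' copy count; it is idempotent. A family is
single-copy when, after reduction, every species occurs exactly once.
The taxon-occupancy filter keeps families with ≥ `min_taxa` distinct
species (bound inclusive: "fewer than 12" is removed, 12 is kept).

## Duplication placement

Gene trees may first be rerooted on the highest-preference outgroup
species present (root on the midpoint of the edge above that species'
transcripts' MRCA); families containing no outgroup are excluded rather
than guessed at. All C(k,2) same-species transcript pairs are enumerated.
For a pair with gene-tree MRCA *g*:

* *T* = species under *g*; the species tree is first restricted to the
  species present in the family (default; transcriptome sampling is
  incomplete, and against the full tree the composition rule would reject
  nearly everything). The matched node is the one whose descendant
  species set equals *T* exactly — set equality is the only reading that
  makes the node unique. Matching against the unpruned tree is available
  (`prune_species_tree=False`).
* The placement is accepted iff the matched node's sister clade (in the
  pruned species tree) shares at least one species with *g*'s sister
  subtree — the immediate sister only, not any ancestor's sister.
* A pair whose MRCA is the gene-tree root has no sister to check and is
  reported `root-unplaceable` rather than silently dropped; likewise
  `no-matching-clade` and `sister-check-failed` are distinct audit codes.
* A single-species *T* matches that species' terminal branch; such
  tip-level duplications are tallied on the leaf so nothing is lost from
  the audit trail.

The support of a placement is the gene-tree MRCA's bootstrap — the
duplication event *is* that node. Tallying drops records below the
threshold (default 80), then counts each distinct (family, gene-tree
duplication node) once in `unique` mode, or every accepted pair in
`all_pairs` mode. Records are tallied against the *full* species tree's
node labels so counts are comparable across families.

## Chromosome-number CTMC

Data are diploid counts (2n); the model state is haploid n = 2n/2, and odd
2n inputs are rejected with an explicit message rather than rounded.
Outliers can be excluded by species id before fitting (e.g. a count two
orders of magnitude above the family range, which no bounded state space
can accommodate sensibly). The default state space is [1, max observed
n + 10] — wide enough that the absorbing boundary does not distort the
fit, small enough to keep the matrix exponentials cheap; duplication mass
that would overshoot n_max is routed to n_max so Q stays a proper
generator.

The ten-model battery crosses {constant, linear (count-dependent)}
dysploidy with {no duplication, duplication, duplication + tied
demiduplication (μ = ρ), duplication + free demiduplication}, plus a
duplication-only and a gain+duplication-only model. Linear rates are
clamped at zero state-wise.

**Likelihood.** Felsenstein pruning with per-edge exp(Qt). Two
propagation backends are used automatically: the eigendecomposition of Q
when its eigenvector matrix is numerically well-conditioned (verified by
reconstructing the identity to 1e−8), and otherwise a dyadic
repeated-squaring scheme — one Padé exponential of Q·δ with
δ = t_max/2²², then products over the binary expansion of each branch
length. The dyadic path is what makes linear-rate models tractable: their
generators are strongly non-normal and effectively defective, so the
eigenbasis is useless there (naive use produces errors of hundreds of
log-units). Branch lengths are thereby quantized to ≤ δ/2, a relative
perturbation below 3e−7. Root handling: `ml` maximizes over root states;
`uniform` averages. The `uniform` prior is the default recommendation for
fitting — with a free "best root state" the deep drift signal (gain
minus loss) is partly absorbed by the root choice, which measurably
inflates rate errors in recovery experiments.

**Fitting.** Bounded L-BFGS-B on log-rates (slopes on the natural scale),
with one deterministic neutral start (all rates 0.1, slopes 0 — this
keeps nested models comparable run to run) plus seeded log-uniform
restarts over [1e−4, 10]. AIC = 2k − 2logL; Akaike weights
normalize exp(−Δ/2) within a battery; a data fingerprint guards against
comparing fits on different data.

**Ancestral states and event counts.** Marginal posteriors by the
standard two-pass conditioning under a uniform root prior; argmax ties
break toward the smaller count. Expected event counts by stochastic
mapping: joint node states sampled from the conditional distribution,
branch histories by endpoint-conditioned rejection sampling (cap 200
attempts) with a uniformization bridge as fallback; events are classified
gain/loss/duplication/demiduplication by the (i, j) pair.

**Recovery experiment design.** The parameter-recovery and
model-selection experiments use 200-tip pure-birth trees (depth ≈ 5.3),
rates gain 0.5, loss 0.3, duplication 0.08 per unit time, root n = 6 —
about 4.5 events per root-to-tip lineage and ~16 duplication events per
tree. These conditions were chosen by a pre-screen for identifiability:
higher dysploidy rates saturate the tips (multiple hits obscure event
polarity and the gain/loss split degrades sharply), while a much lower
duplication rate leaves too few duplication events to estimate ρ beyond
its Poisson floor. Even so, individual-replicate ML errors of 30–50% on
single rates occur — tips-only data on one shared tree carry limited
information about the gain/loss decomposition — so accuracy is assessed
by the median over 20 replicates.

## Continuous-trait methods

* **BM ancestral states** are GLS best linear unbiased predictions; σ² is
  the quadratic-form estimate whose value equals the mean squared
  standardized contrast (the PIC/REML estimator). The conditional
  variance includes the uncertainty of the phylogenetic mean, so root CIs
  match the standard re-rooting formulations to within the n/(n−1)
  convention. Verified against `phytools::fastAnc` / `ape::ace` on a
  frozen fixture.
* **Pagel's λ** multiplies the off-diagonal covariance; the upper bound
  min_i C_ii/max_{j≠i} C_ij keeps the matrix positive definite. μ and σ²
  are profiled analytically, λ optimized by bounded scalar search, and
  the p-value is a χ²(1) likelihood-ratio test against λ = 0 (a flat
  likelihood reports the λ = 0 boundary with p = 1, which is what a star
  tree produces). Matches `phytools::phylosig` to 1e−4.
* **Blomberg's K** uses the MSE0/MSE ratio standardized by its BM
  expectation from the covariance trace; significance by one-tailed tip
  permutation with the +1 correction, 999 permutations by default
  (seed-controlled; the count is a convention, not a derived quantity).
  Matches `phytools::phylosig(method="K")` to 1e−9.
* **PIC** is the standard pruning recursion; polytomies raise an error
  advising zero-length resolution rather than being resolved silently.
  Trait correlation is regression of y-contrasts on x-contrasts through
  the origin; the F statistic uses (1, n−2) degrees of freedom with n the
  number of contrasts. Type-I error is calibrated at the nominal 5% on
  independent BM traits.
* **OU shift scan.** For each α on a grid (default 10 log-spaced values
  spanning 0.05–20 phylogenetic half-lives per tree depth), tips are
  whitened by the fixed-root OU covariance; a shift on an edge then adds
  a known mean offset, 1 − exp(−α(T − t_start)), to every descendant tip,
  so shift placement is variable selection over edge indicators: forward
  selection on residual sum of squares, backward pruning, every visited
  configuration scored. The score is a Gaussian BIC with k = 2·shifts + 3
  (locations, optima, α, σ²) **plus 2·log(#edges) per shift** — an
  extended-BIC term accounting for the selection of each shift location
  among all edges. Without that term, selection over ~2n candidate edges
  accepts spurious shifts on two thirds of no-shift data sets; with it,
  the false-positive rate on no-shift data is near zero while an
  8-stationary-SD planted shift is still recovered essentially always
  (the same motivation as l1ou's pBIC). This solver is an approximation
  with the same no-prior-locations contract as the lasso-based original;
  its BIC values are not numerically comparable to l1ou's.

Chromosome number *can* be run through the continuous-trait machinery,
but the CTMC module is the appropriate model — a discrete count evolving
by ±1 steps and doublings violates the diffusion assumptions, and the
comparison of the two analyses is itself informative.

## Problem sizes in the shipped experiments

The test suite and `scripts/acceptance.py` run entirely on synthetic
data: 500 six-taxon scenarios for the placement oracle; 1,000 (tests) or
600 (script) gene families on an 8-tip tree for WGD recovery and
bootstrap calibration; 20 (tests) or 10 (script) chromosome-recovery
replicates at 200 tips; 50/20 replicates at 100 tips for λ/K; 500/200
replicate pairs for PIC type-I error; 50/20 replicates at 50 tips for the
OU shift experiments. These sizes were chosen so each experiment's
sampling error is small relative to the property being checked while the
whole suite stays interactive.
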