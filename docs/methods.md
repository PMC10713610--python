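# Methods notes

This note records the models implemented in `montaves`, the assumptions
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Tree model

Trees are rooted and dated in Ma; node ages are measured from the present,
so tips of an ultrametric tree sit at age 0 (tolerance: all root-to-tip
depths equal within a 1e-6 relative band).  Polytomies are accepted on
input; the DEC likelihood and Brownian machinery require strict bifurcation
and raise instead of silently resolving, because a resolution policy would
be a hidden modelling decision.

Pruning returns the induced subtree on the kept tips with unary nodes
suppressed (branch lengths summed) and the root reduced to the kept tips'
MRCA; pairwise divergence ages among kept tips are preserved exactly.
Grafting replaces a backbone tip with a clade, with the connecting branch
chosen so the clade's tips sit at age 0.  How the original analysis
reconciled clade-tree depths with backbone depths is not documented
anywhere we could rely on; this age-preserving rule is this package's own
choice and is visible in the run manifest.

## DEC and DEC+J

State space: all non-empty subsets of the area catalog up to an optional
range-size cap (default: no cap; with the nine-region catalog that is 512
states including the null range), ordered by popcount then bitmask.  The
null (empty) range exists only inside the likelihood machinery: it is
absorbing, contributes nothing to tip data, and is excluded from the root
prior.

Anagenesis: from range R, gain of area a ∉ R at rate d·|R| (each occupied
area is a potential source; no distance scaling), loss of an occupied area
at rate e; single-area ranges extirpate to null.  Units for d and e are
events per Ma.

Cladogenesis: ordered daughter pairs with weights y (sympatric copy,
single-area ancestors only, counted for both orders), s (subset sympatry),
v (vicariance restricted to one single-area daughter — classic DEC), and j
(founder events into any area outside the ancestral range, +J only).
y = s = v = 1 fixed; only j is free, bounded [0, 3].  Probabilities are
weights normalized per ancestor state; a two-area ancestor under plain DEC
therefore has six equiprobable events.

Likelihood: Felsenstein pruning with per-branch actions of exp(Qt); the
root is weighted uniformly over non-null states (recorded in result
metadata; the choice matters little for the nodal contrasts used
downstream but is a genuine free choice).  Marginal nodal probabilities
refer to the state immediately before cladogenesis and come from the
standard down-pass conditional / up-pass outside-weight product.

Numerics: small state spaces (≤ 64 states) use dense transition matrices
from a single spectral decomposition of Q (falling back to `expm` when the
eigenvector matrix is ill-conditioned, condition number ≥ 1e7); large
spaces use uniformization — a Poisson-weighted series of sparse
matrix-vector products truncated at a 1e-14 tail — which is exact to
tolerance and far cheaper per branch than generic exponential-action
routines.  Conditional likelihood vectors are max-rescaled per node with
accumulated log factors.  Both paths agree with a brute-force enumeration
oracle to 1e-8 in the test suite.

Fitting: bounded L-BFGS-B on (log d, log e[, j]) from a fixed small
multi-start grid (optionally seed-jittered), rates bounded to
[1e-9, 2] /Ma — the upper bound is far outside any plausible regime and
exists to keep the series lengths finite.  AIC = 2k − 2 lnL with k = 2
(DEC) or 3 (DEC+J).  When both models are requested the lower-AIC fit is
reported with the rival's lnL/AIC kept in metadata.

Known limitation: with data generated by the full DEC process, maximum
likelihood recovers d well but drives e toward 0, because cladogenetic
subset sympatry and vicariance already supply range contraction at every
node and thereby absorb the anagenetic extirpation signal (survivorship —
observed clades never include lineages that died by losing all areas —
adds a smaller bias).  This is a structural property of DEC ML, not an
implementation artifact: the likelihood itself is verified against
enumeration, and the profile lnL visibly decreases in e at the true d.
Downstream stages use nodal marginals, which are far less sensitive to the
d/e split than the rates themselves.

Elevational range ({Lowland, Montane}) and migratory behavior
({Sedentary, Short, Long}, non-exclusive) are reconstructed with the same
machinery on 2- and 3-area catalogs: those traits gain and lose "areas"
exactly as a geographic range does.  Area lumping (a merge map on the
catalog) is applied by recoding tip bitmasks before state-space
construction.

## Source-node tracing

A species' continental origin is the first ancestor — walking rootward
from the tip's parent, which counts as node 1, since the tip itself is an
observation rather than a reconstruction — whose Eurasian
(Palearctic + Indomalaya) or Australo-Papuan group probability strictly
exceeds 0.75.  Group probability splits each composite state evenly among
its constituent areas: a node that is certainly "Australo-Papua + Wallacea"
is 50% Australo-Papuan.  A tie at exactly 0.75 does not cross the strict
threshold.  Species that reach the root without crossing are labelled
unresolved and excluded from group comparisons.

At the source node identified from the *geographic* reconstruction, the
elevational reconstruction is consulted for montane ancestry
(P(Montane) + 0.5·P(Lowland+Montane)) and the migratory reconstruction for
movement-class ancestry (inclusion sums: P(class) = Σ over states
containing the class).  The two rules are deliberately asymmetric — the
elevational rule allocates composite mass, the migratory rule asks whether
any population showed the behavior — and a regression test guards against
unifying them.

## MIP statistics

An island population is montane (a MIP) iff its minimum elevation is
≥ 100 masl (no record below 100 m above sea level); the exact-100 edge is
montane.  Species present in both archipelagos contribute to both regional
counts.  For the MIP-proportion comparison, species with exactly one MIP
and no LIPs are excluded as uninformative about elevational niche shifts.

Mann-Whitney W is the rank sum of the first-listed group minus
n1(n1+1)/2, midranks for ties; p-values are two-sided, exact (full
permutation distribution) when n1·n2 ≤ 400 and the pooled sample is
tie-free, otherwise a tie- and continuity-corrected normal approximation.
The 2×2 chi-squared uses the Yates correction, Σ (max(|O−E|−0.5, 0))²/E
with df = 1 — the correction is required to reproduce published
contingency values from reconstructed counts, as the acceptance test
verifies.  Medians use midpoint interpolation for even group sizes.

## Phylogenetic null models

For each species-level variable (treated as continuous): joint ML of
Pagel's λ ∈ [0, 1], Brownian rate σ² (variance per Ma), and root state z0
under the multivariate normal whose off-diagonal covariances are scaled by
λ; z0 and σ² are profiled analytically and λ optimized by bounded scalar
search with explicit boundary checks.  The tree is λ-transformed (internal
branches scaled by λ, terminal branches extended so tip depths are
unchanged), 1,000 Brownian datasets are simulated on the transformed tree
with the fitted σ² and root state set to the empirical trait mean (an
undocumented free choice, recorded in the result), a one-way ANOVA F is
computed on each with the same group labels, and
p = (# simulated F strictly greater than empirical F)/n_sim — ties count
as not exceeding.  λ and σ² are fitted once per variable and never refit
inside the null loop.  A constant trait yields σ² = 0 with a
degenerate-fit warning.

The species-level tree is assembled by pruning each clade tree to its
resolved species with MIPs and grafting the pruned clades onto a ladder
backbone whose attachment nodes are spaced 18–40 Ma — a stand-in for a
family-level supertree that any clade younger than 18 Ma can join.

## Synthetic data

The generator states a world with the empirical study's shape: clades
5–15 Ma old (birth–death topologies, birth 0.4, death 0.1 /Ma, rescaled to
a uniformly drawn crown age), 4–185 tips per clade (clipped lognormal,
mean ~30), alternating Eurasian (root range Palearctic+Indomalaya, montane
root, low elevational turnover) and Australo-Papuan pools (Australo-Papua
root, lowland root, faster turnover), nine regions, and an
island-population table targeting ~110 MIP species over 31 islands in two
archipelagos, each listed species carrying at least one MIP.  Effect sizes
are expressed as pool differences in root states, elevational rates, and
the probability that an island population is montane (0.9 Eurasian vs 0.45
Australo-Papuan; the zero-effect configuration equalizes both).

Geographic rates (d = e = 0.08 /Ma) were chosen so tip range sizes match a
realistic regime — median one region, occupancy of remote realms rare —
after observing that unstructured nine-area dispersal lets lineages wander
worldwide and produces biologically meaningless diffuse reconstructions.
For the same reason the study generator modulates dispersal by a
stepping-stone adjacency among the regions; this structure exists only in
the generator.  The fitted model remains plain DEC, so the fit is
deliberately misspecified in exactly the way a real analysis is.  The
forward simulator itself is an independent implementation of the process
(exact event-time CTMC plus direct cladogenetic enumeration over area
sets) sharing no transition code with the likelihood; branches that lose
all areas are resimulated (survival conditioning) with retry counts
recorded.

What a green end-to-end test establishes: that reconstruction, tracing,
and the statistics recover planted source-pool structure through the full
pipeline.  What it does not establish: realism of island geography (random
island assignments, no areas/elevations tied to real islands), taxonomic
structure beyond clade-level genus/family labels, sampling noise in
elevational records, or any clock/topology uncertainty — trees are known
without error.

## Reproducibility

All randomness descends from explicit seeds through numpy's default
(PCG64) generators; the pipeline derives per-stage seeds from one
top-level seed, and identical seed plus config reproduces every output
table byte for byte.  The run manifest stores the seed, a config hash,
package versions, and per-stage status.
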