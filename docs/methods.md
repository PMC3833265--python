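# Methods

## The model

`actichain` tests whether linear chains of genes in a functional network —
ordered simple paths, the backbone shape of canonical signaling pathways —
change their joint expression between two conditions (case/control, or
before/after an intervention).

The expression level of each gene is decomposed into its own *latent
contribution* and the influence of its network neighbours. Writing the
genes × samples expression matrix as **Y** and the influence weights as a
matrix **W** (entry `W[g, h]` = influence of gene *h* on gene *g*), the model
is

    Y = W Y + Γ,        hence        Γ = (I − W) Y,

with the latent contributions Γ assumed independent and normally
distributed. The inversion is exact and needs no iterative fitting: given
**W**, the latent contributions are a linear transform of the observed data.
Under the model assumptions, applying independent per-gene two-sample
contrasts to Γ is the generalized-least-squares solution for the condition
effects, which is why the fit reduces to pooled-variance estimation on
transformed data rather than a full mixed-model optimisation.

### The influence matrix

The literature this model family comes from does not pin down how edge
weights enter **W**, so the construction here is a declared design choice:

- each gene's incoming raw link weights are normalised to sum to a damping
  factor λ ∈ (0, 1) (default **0.5**);
- inhibition links carry sign −1, stimulation and plain interaction +1;
- undirected links influence both endpoints; directed links only
  source → target.

With row sums of |W| at most λ < 1, I − W is strictly diagonally dominant,
so the transform and its generative inverse (used by the simulator) are
always well defined, and the construction is invariant to rescaling all raw
weights. λ is a configuration knob; results in the default unweighted,
undirected regime are insensitive to it because the normalisation fixes the
total incoming influence.

### The chain test

For a chain of *k* genes, per-gene condition effects δ̂ = mean_B(γ) −
mean_A(γ) are combined into a single signed contrast. Signs propagate along
the chain: +1 at the first gene, flipped by every inhibition link — so a
gene that goes *down* behind an inhibiting link counts as consistent signal
flow. The statistic is

    T = Σ_j s_j δ̂_j / sqrt( Σ_j var(δ̂_j) ),

with var(δ̂) = σ̂² (1/n_A + 1/n_B) from the pooled within-condition
variance. Because this is one linear contrast (not a joint multi-degree
test), T follows a t-distribution under the null; degrees of freedom pool
across the chain's genes, df = k (n_A + n_B − 2). When the per-gene
variances are equal this distribution is exact, which the null-calibration
test confirms empirically (type-I error within [0.03, 0.07] at α = 0.05
over 2000 simulated null datasets; Kolmogorov–Smirnov distance from uniform
below 0.05).

p-values are two-sided (activity is change in either direction) and
Benjamini–Hochberg adjusted across *all* scored chains. Ranking, not the
α threshold, drives the output: the results object retains the full ranked
table and displays the top 10 by default. Chains whose summed variance is
exactly zero are handled explicitly — p = 1 when the contrast is also zero,
otherwise the smallest representable p with a `degenerate` flag — rather
than silently dropped.

Per-gene variances are treated as independent across chain genes, which is
model-consistent; covariance induced by model misspecification is ignored.

### Chain enumeration

Enumeration is a lazy depth-first traversal (start genes sorted,
neighbours visited lexicographically) bounded by `max_links` (default
**6**, i.e. 7 genes — one above the upper end of typical average path
lengths in networks of this kind, making the search effectively exhaustive
at pathway scale). A fully undirected chain and its reverse are one
pathway: when both orientations satisfy the start/end query, only the
lexicographically smaller is emitted. When the user's start/end sets
distinguish the orientations, the orientation that matches is reported.
A configurable cap (default 5 × 10⁶) aborts runaway exhaustive runs with
advice to narrow the query.

## The mechanisms database

A database record is a unique (molecule, concentration, cell line,
platform) perturbation experiment. Building a record runs:

1. pooled-t differential-expression ranking (a deliberately plain stand-in;
   externally ranked tables can be substituted),
2. induced subnetwork on the top **2000** genes, keeping links with
   confidence ≥ **0.9** and discarding isolated genes,
3. attaching known targets absent from that subnetwork via one shortest
   reference-network path each (lexicographically smallest on ties —
   deterministic; the minimal reading of "a neighborhood large enough to
   connect"),
4. enumerating and scoring all chains starting at a connected target,
5. storing the **100** lowest-p chains with their p-values.

Queries compare user pathways (AP) to database pathways (DP) with

    score(AP, DP) = overlap(AP, DP) / (p(AP) + p(DP)),
    overlap(AP, DP) = |AP ∩ DP| / |AP|,

p-values floored at 1e−16 so the score stays finite. A record's score is
the maximum over its (AP, DP) pairs — rewarding the single best mechanistic
match — and the top 100 records are returned. Storage is line-delimited
JSON with an explicit `schema_version` header, chosen as a portable,
diff-able replacement for a binary object store.

## Validation statistic

For a reference network and a molecule's target set, each gene's distance
is its shortest direction-blind path length to the nearest target. The
weight of distance *i* is

    weight_i = 1 − ((n_i − 1)/N)³,

where n_i counts genes at distance ≤ i and N is the node count: weights are
high exactly when a gene is close to a sparsely surrounded target, and the
weighting is monotone non-increasing in distance. The statistic for a gene
set is the weighted mean of member distances. Its null distribution comes
from B (default **10,000**) uniform same-size gene-set draws over all nodes
— deliberately not degree-matched, since the weighting already compensates
topological bias — and the one-sided p-value is add-one smoothed,
p = (1 + #{stat_b ≤ stat_obs}) / (B + 1), so p is never zero and the
−log10 transform is always defined. Ties count against the observation
(conservative). Unreachable genes get the maximum finite distance + 1 and
are flagged. Fractional requested set sizes (an average pathway size) round
half-up.

## The simulator

`simulate` draws an Erdős–Rényi network (topology matters little to the
weighted-distance statistic, which is the main consumer of structure), then
embeds one planted simple chain, marks its first gene as a target, and
samples expression from the *same* latent model the scorer assumes:
γ ~ Normal(μ_g + 1[B]·Δ_g, σ²) with Δ = ±δ sign-propagated along the
planted chain, then Y = (I − W)⁻¹ γ. Planting the effect on latent means
(not on expression directly) is what makes parameter recovery a fair test
of the scorer.

Default conditions: 150 genes, edge probability 0.03 (mean degree ≈ 4.5,
typical of high-confidence functional subnetworks), 3 + 3 replicates,
σ = 1, δ = 2, 4-link planted chain, λ = 0.5, undirected links with 25%
inhibitions, 3 targets. These defaults are the reference conditions of the
whole test suite: at them, the planted chain (or a chain sharing ≥ 3 of its
genes) lands in the top-10 output in well over 90 of 100 replicates.

What the simulator does **not** emulate: microarray noise structure (probe
effects, batches, normalisation artifacts), hub-dominated degree
distributions, and mismatch between the assumed and true influence
structure. Passing tests therefore demonstrate correctness and calibration
*under the model*, not robustness to real-data violations of it.

## Numerical and interface choices

- Zero-variance genes in the DE ranking: t = ±∞ for a nonzero mean
  difference (ranked first), t = 0 otherwise; ties break by gene id.
- Result ordering: ascending p, then descending |T|, then canonical chain
  string — fully deterministic, byte-reproducible output.
- Duplicate network links collapse to the maximum-confidence entry; gene
  identifiers are opaque, case-sensitive strings (ID mapping is upstream
  curation).
- Expression TSVs are written with 17 significant digits and parsed with
  correctly-rounded float conversion, so fixture bundles round-trip
  bit-exactly.
- BH adjustment is implemented in-package (four lines of numpy) and
  cross-checked against `statsmodels.stats.multitest` in the tests.

## Problem sizes

The default test and acceptance runs use 100-gene networks for transform
checks, ≤ 12-node graphs (100 of them) for enumeration-oracle equivalence,
2000 null replicates for calibration, 100 end-to-end replicates for
planted-chain recovery, and B = 10,000 bootstrap draws — sizes at which
every statistical bound tested has comfortable Monte-Carlo margin.

## Known limitations

- The latent-variable framework this adapts is usually presented as a
  mixed linear model without a closed-form two-condition recipe; the
  contrast-based reduction here is exact under the stated assumptions but
  other implementations of the same idea may parameterise the test
  differently and produce different numbers.
- Sign propagation across inhibition links is a modelling choice of this
  package; it strictly helps anti-correlated cascades and is always on.
- Time-course designs are out of scope; the model is the two-condition
  simplification only, and **W** is constructed from the network, never
  estimated from data.
- Chains are linear; branched active subnetworks are a different problem
  class served by other tools.
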