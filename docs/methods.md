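# Methods

## Potency read-outs

A dose-response series is a set of (dose, viability) points for one drug on
one biological sample, doses in nM, viability on the control scale
(1 = untreated, 0 = total kill). Replicates are aggregated by the mean
response per dose before any summary — the usual screening convention.
Viability outside \[0, 10\] is treated as corrupt, clipped and logged.

* **Median viability** — the middle order statistic of the responses. It is
  the pipeline's default edge-weight read-out: robust to single-dose
  outliers, unimodal in practice, and no curve fit can fail on it.
* **4PL fit** — y = lower + (upper − lower)/(1 + (x/ec50)^slope), fitted by
  least squares on log-dose with data-driven bounds. Fewer than four
  distinct doses pin the slope at 1; a near-constant series returns a
  flagged degenerate fit; non-convergence falls back to monotone
  interpolation rather than raising. An increasing curve (stimulation) is
  flagged non-inhibitory via the slope sign.
* **IC50** — relative = EC50 (midpoint of the fitted plateaus); absolute =
  the dose where the fitted curve crosses viability 0.5 on the control
  scale, declared undefined when that crossing lies outside 10× the tested
  dose range (we do not extrapolate a read-out the experiment cannot
  support).
* **AUC** — trapezoidal area under viability vs log₁₀(dose), normalised by
  the log-dose span so that constant viability *v* gives AUC = *v*. The
  log-dose domain makes AUC comparable across drugs with different tested
  ranges and puts it on the same scale as the median. A linear-dose variant
  is deliberately not offered; the half-log design makes log spacing the
  natural measure.
* **Relative inhibition** — RI = 100 × (1 − AUC), the percent area under
  the inhibition curve. The literature formula this approximates is not
  restated in our sources, so RI here is *defined* as the AUC complement
  and documented as such; stimulation gives negative RI.
* **MIC / MAS / MEV** — approximate MINE statistics over equal-frequency
  grids with a·b ≤ B(n) = n^0.6 cells, axes capped at 15 bins. The
  characteristic matrix M\[a,b\] is mutual information normalised by
  log₂ min(a,b); MIC is its maximum, MAS the largest asymmetry
  |M\[a,b\] − M\[b,a\]|, MEV the maximum over 2-row/2-column grids (hence
  MEV ≤ MIC structurally). We equipartition rather than optimise cut
  positions: this is a lower bound on the exact statistic, adequate for
  ranking measure pairs; tests compare it against an exhaustive small-grid
  oracle at n ≤ 30.

## Network construction

Missing cells are removed by list-wise deletion: iteratively drop the row or
column with the highest missing fraction (ties: the larger axis first, then
lexicographic id) until the matrix is complete. The retained matrix of
median viabilities is transformed to edge weights by the reciprocal
transform — min–max normalisation (Eq: (v − min)/(max − min)) of 1/median —
so that potent (low-median) interactions get weight near 1. A complement
variant (1 − min–max of the median) is switchable; both are strictly
decreasing in the median, so rankings agree. An all-equal input maps to 0.5
with a warning. Medians are clipped at 1e−6 before reciprocation.

Drug and sample node ids are namespaced (`drug:`/`sample:`) to make
cross-side id collisions harmless. The one-mode projections use plain
product-sum weights — edge(i,j) = Σₖ wᵢₖwⱼₖ, the off-diagonal of W Wᵀ —
computed by dense matrix product (screens of this size are a few hundred
nodes; the contract is identical for any backend). Exact-zero projected
weights are dropped from edge lists; the C(n,2) edge-count identity is
asserted only for strictly positive incidence.

Network statistics: degree heterogeneity sd(k)/mean(k), Freeman degree
centralisation Σ(k_max − kᵢ)/((n−1)(n−2)), and the Barrat weighted local
clustering coefficient averaged over nodes (degree-<2 nodes contribute 0).

## Community detection

Weighted Newman–Girvan modularity is the objective and the selection
criterion. The reference algorithm (`fastgreedy`) is deterministic:
CNM agglomeration from singletons — merge the pair with maximal
ΔQ = 2(eᵢⱼ − aᵢaⱼ), ties to the smallest label pair — with the dendrogram
cut at maximal Q, followed by seed-free refinement (greedy single-node
moves, whole-community merges, and Kernighan–Lin passes of forced moves
with locking, iterated to a fixed point). Plain agglomeration can stall
several percent below the optimum on small dense graphs; the refinement
brings it within 5% of the exhaustive optimum on every random ≤8-node graph
in the test sweep. Cross-component merges always have ΔQ < 0, so
disconnected components are clustered independently by construction.

`best_partition` may additionally run infomap, spinglass or leiden through
python-igraph (seeded; skipped with a warning when the backend or the
graph's structure does not allow them) and returns the partition with
maximal Q — ties to fewer clusters, then algorithm order.

## Homogeneity validation

Within-cluster pairwise statistics are compared against a random-grouping
null: permute the items, regroup at the observed cluster sizes, pool the
within-group pair values; the null is reproducible by seed, and defaults to
the order of 10⁴ pooled values. Metrics:

* Dice 2c/(a+b) on hashed circular fingerprints (radius 2, 2048 bits via
  rdkit when SMILES are supplied, or read precomputed from bitstring CSV —
  the statistics stay testable without a chemistry dependency).
* Target-set intersections, optionally after 2-hop directed expansion in a
  signalling network ("secondary targets"; absent targets are kept and
  contribute no neighbours).
* Shared-pathway counts: a drug's profile is every pathway hit by ≥1
  target.
* Harmonic expression similarity 2·Σ PᵢQᵢ/(Pᵢ+Qᵢ): genes with Pᵢ+Qᵢ = 0 are
  dropped pairwise and counted, since signed (log-scale) expression makes
  the term singular; this is a documented convention, not a claim about
  the metric's behaviour on negative data.
* Continuous Jaccard distance. Two forms ship: the **standard** Tanimoto
  form 1 − ΣPQ/(ΣP² + ΣQ² − ΣPQ) (default — zero self-distance, as a
  distance should have) and an **as-printed** variant with +ΣPQ in the
  denominator whose self-distance is 2/3 for any nonzero vector, kept
  selectable for literal reproduction of the published formula.

Testing: Kruskal–Wallis across {cluster groups, null} plus pairwise
two-sample Wilcoxon rank-sum of each cluster against the null, all
Benjamini–Hochberg adjusted (the adjustment method is our choice; only
"adjusted" is specified upstream). Fully tied inputs yield p = 1 with a tie
warning.

**A caveat the test suite quantifies.** Pairwise similarity values within a
group share samples, so they are not independent observations; applying
rank tests to all pairs is anti-conservative under the null (we measure
~25% of p-values below 0.05 at zero planted effect). This is a property of
the all-pairs design, common to this kind of analysis, and is acceptable
when effects are enormous (the planted-structure tests report p-values
hundreds of orders of magnitude below any threshold) but matters near the
margin. The type-I calibration test therefore evaluates the procedure in a
regime where its assumptions hold: disjoint pairs (each sample used once)
and a null drawn from held-out samples, under which the p-value is uniform
(KS test over 200 repeats). Users testing subtle effects should prefer the
disjoint-pair design.

Mutation profiling filters to damaging mutations (damage probability
strictly > 0.5), computes the fraction of each cluster's samples carrying
each gene, ranks genes per cluster (dense, descending) and reports the rank
shift across clusters.

## Combination design

Drugs are ranked within each community by median viability ascending (most
potent first, ties by id). For two communities and top-k lists the positive
(cross-cluster) set has k² pairs and the negative (within-cluster) set
2·C(k,2); with c cell lines the experiment plan has (k² + 2·C(k,2))·c
triplets. More than two communities generalise to the union of cross
products over community pairs. Undersized communities shrink their own k
with a warning. The positive-vs-negative synergy comparison offers
Student's t (Welch) and Wilcoxon rank-sum, two-sided by default with
one-sided available — both sidedness conventions appear in practice.

## Synergy models

Effects are handled internally as inhibition fractions (viability inputs
convert as 1 − viability); surfaces and means are reported in percentage
points. δ = observed − expected over the positive-dose grid.

* **HSA**: y_e = max(y₁, y₂).
* **Bliss**: y_e = y₁ + y₂ − y₁y₂ with margins clipped to \[0, 1\], as the
  probabilistic reading requires.
* **Loewe**: y_e solves d₁/D₁(y) + d₂/D₂(y) = 1, with D from the inverted
  monotherapy logistic fits, by bisection to 1e−6. The equation has a root
  only inside the effect range achievable by both drugs; cells outside are
  clamped to the nearest achievable effect, flagged, and excluded from the
  mean.
* **ZIP**: the reference is Bliss-type independence of the two *fitted*
  monotherapy logistics; the potentiated response averages two
  partner-conditioned logistic refits (the combination row/column at
  positive own-doses). The conditional refits use a full free-parameter
  logistic rather than pinning the minimum to the partner's fitted effect:
  on an exactly-independent surface the conditional curve *is* a logistic
  with minimum y₂ and the free fit recovers it (δ ≡ 0), and a constant
  synergy offset shifts that minimum, which a pinned fit cannot represent —
  the free fit keeps the estimator unbiased for both regimes. Failed
  conditional fits fall back to the raw observed values, flagged. Means are
  unweighted over the positive-dose grid.

Sensitivity-type scores (CSS/S) are not computed; ingestion tolerates their
columns for comparison workflows.

## Synthetic cohorts

The generator's defaults are the package's study conditions: 88 drugs × 88
samples, two drug and two sample clusters (round-robin assignment), seven
half-log doses spanning a 1000-fold range (10 nM – 10 µM), matched
drug/sample blocks sensitive (median viability 0.2) and crossed blocks
resistant (0.8), Gaussian response noise sd 0.05, no missing cells by
default (the complete-case step is exercised with explicit missing rates in
tests). Viability curves run from the control plateau (1) to full kill (0)
with per-pair slopes jittered in \[1.2, 1.8\] and the EC50 placed so the
curve passes the block mean at the middle tested dose — making the 7-dose
median equal the block mean exactly in the noiseless limit, whatever the
slope.

Annotations plant the same cluster structure: fingerprints resampled from
cluster prototypes (within-similarity 0.85 vs between 0.30), target sets
drawn mostly from disjoint per-cluster cores over a 200-protein universe, a
sparse random directed signalling graph containing all targets, per-cluster
pathways over the cores plus random decoys, expression with an additive
shift (default 2.0) on per-cluster signature gene blocks, and cluster
marker mutations at frequencies 0.38/0.30/0.25/0.20/0.15 with damage
probabilities in (0.6, 0.95) over a low uniform background. Combination
surfaces are the Bliss expectation of the true monotherapies plus a +10
percentage-point offset on inter-cluster pairs (none within), with 1%
Gaussian cell noise.

All substreams derive from one seed via (seed, purpose) keys, so any
artefact regenerates independently and identically.

What the generator does **not** emulate: real screens' heavy-tailed weight
distributions beyond mild positive skew, dose-dependent noise, plate
effects, partially overlapping cluster structure, or correlated annotation
errors. Passing tests therefore demonstrate that the machinery recovers
structure it is designed to represent — not that real cohorts contain such
clean structure.

## Numerical conventions

* Min–max of an all-equal vector → 0.5 with a warning (keeps the graph
  connected rather than erroring an entire screen).
* Curve fits clip exponents at ±500, bound parameters by the data range,
  and never raise: degeneracy and non-convergence are flags.
* Community ties break lexicographically; node order is fixed by sorted id
  before agglomeration, making every partition reproducible bit-for-bit.
* Projection weights are exact dense products; the matrix-product oracle is
  asserted to 1e−12 in tests.
* Edge-list TSV weights round-trip at 6 significant digits; GraphML
  preserves full doubles.

## Problem sizes used in the checks

The shipped verification suite runs the full pipeline at the default 88×88
scale, structural identities additionally at 266×266, oracle sweeps on 100
random ≤10×10 matrices and 100 random ≤8-node graphs, synergy calibration
on 7×7 dose grids, detection power over 100 seeded repeats of a 12-drug
cohort, and type-I calibration over 200 repeats of a 40-sample zero-effect
cohort — sizes chosen so the whole suite completes in a few minutes on one
core while keeping every estimate's Monte-Carlo error far below the margins
being asserted.

## Known limitations

* The RI definition is an AUC complement, not the original cited formula.
* The approximate MIC underestimates the exact statistic on adversarial
  relationships (it never optimises cut positions).
* Loewe is undefined where monotherapy plateaus exclude the observed
  effect; heavily clamped matrices yield means over few cells (the count
  is reported).
* The all-pairs homogeneity test is anti-conservative under dependence
  (see above).
* Spinglass requires a connected graph and is skipped otherwise.
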