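# Methods

This note records the models behind each stage, the defaults that matter and
why they hold their values, what the synthetic designs do and do not emulate,
and the numerical choices a maintainer would want written down.

## Data model

A study is a set of omics blocks: samples × features tables with per-sample
metadata (subject, replicate, time). Networks are undirected multi-layer
graphs. Nodes carry a layer (`gene`, `tf`, `protein`, `metabolite`, `otu`,
`clinical`, `go_term`, `disease`), a `measured` flag separating profiled
molecules from knowledge-database extensions, and an optional kinetic-cluster
label. Edges carry a provenance (`inferred_mi`, `knowledge_ppi`,
`knowledge_reaction`, `coding`, `tf_target`, `correlation`, `annotation`) and
a non-negative weight; several provenances may connect the same pair.
Directed inputs (TF→target, enzyme→compound, term→member) are stored
undirected — the propagation model assumes an undirected graph — with the
originating endpoint kept in `source_role`. Node ids live in one flat
namespace; the assembler prefixes ids (`rna:`, `prot:`, `met:`, `otu:`,
`clin:`, `go:`, `dis:`) to avoid cross-layer symbol collisions.

Merging layers resolves shared nodes by rule (`measured=True` wins;
disagreeing cluster labels accumulate into a set) and duplicate
(pair, provenance) edges by maximum weight, which makes the merge
order-independent.

## Pre-processing and trajectory modelling

**Fold-change filter.** The per-time summary is the mean across replicates
and subjects. Linear scale keeps a feature iff max/min ≥ threshold; log
scale iff max − min ≥ log_base(threshold). Non-positive linear minima
receive a pseudocount of half the smallest positive value in the block,
recorded in the report. Thresholds are per block (platforms differ in
dynamic range); the synthetic default is 1.5.

**Model hierarchy.** Four candidates per feature: constant mean; straight
line; cubic smoothing spline of the per-time group mean; the same spline
plus per-subject random intercepts estimated by method-of-moments variance
components and shrunk toward zero (weight σ²_b / (σ²_b + σ²_e/n_s)). This
approximates linear-mixed-model splines; full per-subject random spline
terms are deliberately out of scope. With ≤ 5 distinct timepoints the spline
is a natural cubic interpolant through the group means (df = number of
timepoints); with more, the smoothing level is chosen by generalized
cross-validation over a wide λ grid using the explicit smoother matrix, and
the model's df is that matrix's trace. Selection is by BIC
(n·ln(RSS/n) + k·ln n) with the mean squared error floored at 10⁻¹² of the
signal scale, so exact fits are compared by parameter count alone — a
noiseless constant feature selects `constant`, a noiseless line `linear`.
The winning curve is evaluated on a common grid restricted to the observed
time range (interpolation only; no extrapolation).

**Noise filter.** A feature is noisy when its selected model is constant or
the winning model's R² against the observations falls below 0.5 — i.e. the
curve must explain at least half the observed variance. The floor was
calibrated on the null: at the default design (3 subjects × 6 timepoints,
18 observations) a trend-free Gaussian feature beats the constant model by
BIC with R² up to ~0.7 a few percent of the time, and any floor below ~0.15
is vacuous because a BIC win already implies R² above it. At 0.5 roughly 2%
of pure-noise features survive while modelled signals (fixture R² ≈ 0.9)
are untouched. Configurable per run.

## Kinetic clustering

**Pattern route.** Each fitted profile maps to the sign pattern of its
consecutive differences, one symbol per interval in {−, 0, +}, with a zero
band of 1% of the profile's range (making labels invariant under positive
affine transforms). Every distinct pattern is a cluster.

**Multi-block PLS route.** Blocks are row-scaled fitted profiles
(features × grid). Components are extracted by an alternating scheme whose
fixed point maximises Σ_b cov(X_b w_b, t)² — block weights w_b = X_bᵀt,
consensus score the normalised sum of block scores. The composite update is
applied through the small grid × grid cross-product matrix, with deflation
X_b ← X_b − t tᵀ X_b between components; non-convergence raises an error
naming the component. The per-iteration *weight-normalised*
"sum of covariances" variant oscillates when two archetypes carry similar
variance, so the squared-covariance criterion (consensus-PCA family) is
used; exact numerical agreement with other multiblock implementations is not
promised — cluster-label agreement on designs with known truth is the
contract. Features join cluster (component of max |loading|, sign), so
ncomp components yield ≤ 2·ncomp clusters.

**Silhouette and k selection.** Distance is d(i,j) = 1 − Pearson r of scaled
profiles — profiles cluster by shape, not magnitude. Silhouette
s(i) = (b−a)/max(a,b) with singletons contributing 0; `choose_k` scans a
component-count grid and keeps the clustering with the highest average
silhouette, ties toward fewer clusters. Sparse signatures soft-threshold
loadings to the `keepX` largest |loadings| per block per component and
re-derive assignments from the thresholded loadings, mapped back to the
original cluster numbering.

## Network construction

**MI inference.** Pairwise mutual information on equal-frequency bins,
default bins = ⌊n^(1/3)⌋. The common ⌊√n⌋ rule produces severe upward bias
at desk-scale n (the plug-in bias grows as (bins−1)²/(2n ln 2): ~0.6 bits at
n = 200 with 14 bins), which compresses the MI ratios the pruning step
relies on; cube-root binning keeps the bias an order of magnitude below the
signal MIs. The edge floor is the 1 − 0.05/n_pairs quantile of a permutation
null (20 per-feature shuffles): a Bonferroni-style choice so the *network*
carries ≈ 0.05 expected false edges rather than 5% of all pairs — triangle-
free false edges can never be removed by DPI, so per-pair error control is
the wrong scale. DPI pruning then marks edge (i,j) in any triangle where
MI(i,j) < (1 − ε)·min(MI(i,k), MI(j,k)), ε = 0.15, and removes all marked
edges simultaneously. All three knobs are configurable.

**SparCC-style compositional correlation.** With fractions x_i and
t_ij = var(log(x_i/x_j)), sparsity lets the basis variances solve
Σ_j t_ij = (D−1)ω_i² + Σ_{j≠i} ω_j², and
ρ_ij = (ω_i² + ω_j² − t_ij)/(2 ω_i ω_j), clipped to [−1, 1]. This is the
single-pass estimator — no iterative strong-pair exclusion — which suffices
at the default |ρ| ≥ 0.3 threshold; fewer than 4 taxa leave the system
underdetermined and raise an error. In the noiseless closed system the
estimate equals the Pearson correlation of log basis abundances.

**Knowledge layers.** Rows below a confidence threshold are dropped
(unscored rows pass); nodes are the measured molecules present in the table
plus, when extension is on, their direct interactors flagged unmeasured.
Extension is strictly first-degree: an unmeasured node never sits at graph
distance > 1 from a measured one. Reaction tables produce clique edges among
co-occurring compounds and enzyme–compound edges, with unmeasured compounds
admitted only alongside a measured one. Cross-layer Spearman links use the
modelled profiles on the common grid (the natural shared observation space)
at |ρ| ≥ 0.99 by default.

**Assembly.** The entire network merges all layers plus cross-links, nodes
stamped with cluster labels. Per-cluster networks are *rebuilt from scratch*
on each cluster's measured features — inference re-run, knowledge extension
re-applied — so knowledge nodes may appear in several cluster networks;
building per cluster keeps molecules connected that a network-first cut
would strand. Measured features without a label stay in the entire network
only, with a warning.

## Enrichment

ORA uses the upper-tail hypergeometric probability P(X ≥ overlap) with term
memberships intersected with the universe, Benjamini–Hochberg adjustment per
ontology, and significance at adjusted p < 0.05. BH replaces
web-service-specific multiple-testing schemes; the substitution is recorded
in the result metadata. The universe is either the measured molecules
(default) or measured + knowledge-extended nodes; both are supported and the
choice is echoed in the output, since enrichment against an extended
background asks a different question. The entire network receives the union
of terms found significant in any query (per cluster or entire) as its term
layer; the entire-set query itself is degenerate when the universe equals
the query (p = 1 throughout), so cluster queries drive the term layer under
the default universe. Disease annotations are consumed as generic term sets.
Fisher's combination uses X² = −2 Σ ln pᵢ against χ² with 2k df; p = 0 is
rejected rather than silently clamped.

## Random walk with restart

Transition matrix: column x distributes 1/d(x) over neighbours (weighted
mode normalises max-collapsed edge weights per column); isolated nodes get a
self-loop so columns stay stochastic. Iteration p ← (1−r)Wp + r·p₀ runs to
L1 change < 10⁻¹⁰ (the fixed point solves (I − (1−r)W)p = r·p₀; the
iterative result matches a dense solve to < 10⁻¹² in tests). Restart
defaults to r = 0.7, the convention of monoplex RWR toolkits, and is
recorded in every output. The walk is unweighted by default, matching the
degree-based transition model; the merged graph is monoplex — multiplex
inter-layer jump tuning is out of scope. Ranking excludes seeds and breaks
score ties lexicographically for deterministic output.

One caution: strict "closer in hops ⇒ higher score" holds only when the
restart term dominates. As r → 0 scores approach the degree-proportional
stationary law, so at small r (≲ 0.25 on a path graph) a degree-2 neighbour
outscores a degree-1 seed; beyond the seed's immediate neighbour the decay
is monotone for any r. At the default r = 0.7 the strict ordering holds.

Interpretation defaults: mechanism sub-networks take the top 25 nodes per
term seed (screens: reaches genes+proteins, reaches
genes+proteins+metabolites, counting `gene` and `tf` layers together);
function prediction assigns the highest-scoring term node per ontology to
each molecule lacking an annotation edge (annotation edges are not masked
during the walk — the predicted term may therefore be reinforced by existing
annotations of neighbours, which is the guilt-by-association intent);
the cluster-intersection screen takes the top 10 nodes per measured seed and
retains seeds whose sub-network holds both a foreign cluster label and a
term node.

## Synthetic designs and what they show

The generators draw all randomness from one integer seed through named
sub-streams, so every fixture is reproducible independently.

* **Kinetic blocks** — 3 blocks × 20 features, 6 timepoints, 3 subjects,
  log2-scale baseline 8, noise σ = 0.2, subject intercepts σ/2, plus 2
  trend-free noise features per block. Archetypes are ⌈k/2⌉ z-scored cosine
  half-waves; clusters are (archetype, sign) pairs with skewed sizes
  (weights descending k, k−1, …, 1). The skew mirrors reported kinetic
  clusterings, whose sizes are strongly unequal; a perfectly balanced design
  would tie the leading eigenvalues and make the component plane an
  arbitrary rotation that no loadings-based method could label correctly.
* **Regulatory designs** — a 3-gene chain X→Y→Z (Z touches X only through
  Y) and a 50-node forest (10 regulators × 4 targets, target = parent +
  N(0, 0.75²), n = 200 samples) whose only indirect correlations run
  through shared parents — exactly what DPI should discard.
* **Knowledge tables** — random interactions among measured molecules,
  unmeasured first-degree partners, and deliberate second-degree decoy rows
  that a correct extension must not pull in.
* **Annotations** — one term per cluster drawn wholly from that cluster's
  members, plus background terms sampled from the whole universe.
* **Compositional counts** — multivariate-normal log bases with requested
  pairwise correlations, closed to fractions, multinomially sampled at
  fixed depth.

These designs validate *mechanics* — recovery of planted structure under
known noise — not realism: real data have heavier tails, batch structure,
missing values, uneven sampling, and far weaker signal-to-noise. Passing
tests show the algorithms do what they claim under their stated model, not
that any particular biological dataset will yield clean clusters or
networks.

## Problem sizes and numerical choices

Default fixture sizes (60 measured features across 3 blocks, ~70-node
networks, 500-sample compositional tables, 200-sample regulatory designs)
were chosen so that a full pipeline run completes in seconds and the whole
validation suite in minutes on a single CPU, while keeping every recovery
property measurably non-trivial. Other numerics worth recording: MI uses
mergesort-stable rank binning (ties broken by input order, deterministic);
the block-PLS consensus starts from the normalised column-mean direction and
fixes each component's sign by its largest-magnitude coordinate;
equal-BIC candidates resolve to the simpler model; silhouette clips
correlation distances to [0, 2]; GraphML round-trips preserve string/int
attributes exactly and floats to full repr precision; pipeline artifacts are
written with fixed float formats and sorted JSON keys, so a rerun with the
same config and seed is byte-identical, and stage caches are invalidated by
a hash chained through every upstream stage's configuration.

## Known limitations

* The trajectory hierarchy is an approximation to full mixed-model splines:
  subject effects are intercept-only, and the spline df is a smoother-trace
  estimate.
* The MI estimator is the binned plug-in; no kernel or adaptive-partition
  estimators, no bias correction beyond the binning choice.
* SparCC is single-pass; strongly coupled taxa pairs bias the basis
  variances slightly (visible as ±0.02 background correlation).
* Propagation is monoplex and unweighted by default; no multiplex
  transition tuning, no diffusion kernels.
* No platform normalisation, no differential-expression pre-filters, no GO
  DAG traversal or term-redundancy reduction, no database download clients.
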