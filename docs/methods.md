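# Methods

## Model

All computations operate on a set *S* of m aligned sequences of common
length n over a finite alphabet 𝒮 (DNA, binary presence/absence, or any
declared symbol set). Characters are unordered, multistate and reversible;
the distance is Hamming, d_H(x, y) = |{i : x_i ≠ y_i}|, kept as an exact
integer throughout. Gap and ambiguity symbols are ordinary states — there
is no missing-data semantics — and sequences are upper-cased on input so
comparisons are case-insensitive. A *cladogram* is a rooted tree with
leaves in bijection with *S* and every node labeled by a sequence in 𝒮ⁿ;
its parsimony length is the sum of edge-wise distances between labels. A
*dendrogram* is the merge history of an agglomerative clustering, with one
height per merge.

## MST-based parsimonious construction

The complete graph G(S) has an edge of weight d_H(x, y) for every pair. Its
minimum spanning tree T₁ already connects *S* at minimal total cost among
trees without extra nodes, and ½·w(T₁) ≤ w(T\*) ≤ w(T₁) for the optimal
cladogram T\* (the upper bound by construction below, the lower bound by
the Euler-tour/triangle-inequality argument standard for such
2-approximations). The conversion to a cladogram peels T₁ in leaf layers
under a fixed root orientation: each peeled vertex u attaches below the
internal copy of its parent v with edge weight d_H(u, v), and each vertex
that ever serves as a parent receives, once, a zero-weight pendant leaf
carrying its own sequence. Every vertex of T₁ therefore ends up as a leaf
of the output, internal labels all lie in *S*, every T₁ edge appears
exactly once and pendants cost nothing, so w(T₂) = w(T₁) exactly — an
integer identity, not an approximation. With an explicit root the
"both-remaining-vertices-are-leaves" terminal special case of the
layer-peeling scheme never arises (the root is never peeled), which is how
this implementation handles it. The output is multifurcating wherever an
MST vertex has degree > 2; no binarization is applied, since nothing in the
weight definition requires binary trees.

Determinism: MSTs are not unique, so Kruskal examines edges sorted by
(weight, lexicographically sorted id pair), and the spanning tree is rooted
at the lexicographically smallest id. Two runs on the same input produce
identical trees.

## Small parsimony (fixed topology)

For a fixed leaf-labeled topology the optimal internal labeling decomposes
exactly per site under Hamming distance. Each site is solved by
uniform-cost dynamic programming,
cost(v, s) = Σ_children c min(cost(c, s), min_s′ cost(c, s′) + 1),
which reduces to the classical two-pass set method on binary nodes and
handles multifurcations (needed because the MST conversion can emit them).
All sites are processed simultaneously as (|𝒮| × n) integer matrices.
The traceback is deterministic: the root takes the lexicographically
smallest optimal state; every other node keeps its parent's state whenever
that is optimal for its subtree, else the lexicographically smallest
optimal state. For a cherry this makes the root label the site-wise
minimum of the two leaf sequences. Any optimal labeling is equally valid
scientifically; the rule only pins down which one is returned.

## Single-linkage clustering, plain and label-assigning

Agglomeration is the naive O(m³) loop over active cluster pairs — adequate
at the scales this package targets, and the simplest to make deterministic:
ties between cluster pairs at equal linkage distance, and between member
pairs at equal distance, are broken by the lexicographically smallest
sorted id pair. Merge heights are emitted in the scipy linkage-matrix
convention and are provably non-decreasing; the test suite cross-checks
them against scipy's independent implementation and against the sorted MST
edge weights, which they equal for single linkage.

The label-assigning variant gives the merge tree a full labeling from *S*
itself: when clusters Ĉᵢ and Ĉⱼ merge, the member pair (x ∈ Ĉᵢ, y ∈ Ĉⱼ)
realizing the single-linkage minimum labels the two merged nodes — a
singleton keeps its own point, a composite node takes its member of the
pair. The final cluster is never itself merged, so the loop leaves the
root unlabeled; as a design choice the root inherits the label of its
larger child (label id breaking ties lexicographically), and every label
choice including this one is recorded in the output's provenance. The
result is a cladogram with all labels in *S*, so its parsimony weight is
well defined; it is a heuristic labeling, bounded below by the exact
small-parsimony minimum of the same topology, which the linkage-tree
command reports alongside it.

On chain-plus-outlier inputs the merge tree is *provably* bad: the best
labeling of the single-linkage topology of {1111111, 1110000, 1100000,
0000000} weighs 8 while the MST weighs 7. The simulator generalizes this
family (ones-prefix chains of configurable length plus the all-ones
outlier), and the exact DP confirms the strict gap across the family.

## Cluster extraction and F-score

Threshold cuts join everything merged at height ≤ t and coincide with the
connected components of the MST after deleting edges heavier than t (a
cross-module property test). Count cuts undo the last k−1 merges of a
dendrogram; a cladogram is truncated by removing its k−1 heaviest edges
(ties broken by the cut subtree's smallest leaf id), with a depth-based
alternative (`cut_cladogram_by_depth`) cutting all edges that cross a given
cumulative root distance. When a tree's structure cannot yield exactly k
non-empty leaf clusters the closest achievable number is returned with a
warning.

Two partitions are compared by F-score. The default is the pair-counting
F1 — precision/recall over unordered co-clustered item pairs — which is
symmetric, invariant to cluster relabeling, and equals 1 iff the partitions
coincide; two all-singleton partitions (no pairs on either side) are
defined to score 1 since they are identical. The cluster-matching variant
Σᵢ (|cᵢ|/N)·maxⱼ F1(cᵢ, c′ⱼ), symmetrized by averaging both directions, is
available behind a flag. External definitions of "the F-score of two
clusterings" vary; exposing both symmetric variants covers the common
readings.

## Brute-force oracles

`most_parsimonious_tree` enumerates all (2m−3)!! rooted binary leaf-labeled
topologies by stepwise leaf addition and optimizes each with the exact DP;
restricting to binary topologies is lossless because contracting an edge
never lowers the weight, so any multifurcating optimum is matched by a
binary tree with a zero-cost edge. `exhaustive_min_labeling` re-derives the
small-parsimony minimum by literally enumerating internal-state
assignments per site, checking the DP itself. Both refuse oversized
instances with explicit errors (default bounds: 8 leaves; 2²⁴ enumerated
assignments). The site-wise lower bound Σ_sites (#distinct states − 1)
certifies oracle optima that attain it.

## Synthetic data

`simulate_tree_sequences` grows a topology by uniform stepwise leaf
addition, draws a root sequence uniformly, and mutates each site
independently on each edge with probability p, jumping to a uniformly
chosen different symbol. Defaults (DNA alphabet, p = 0.1 per edge) produce
short homoplasy-rich alignments appropriate for exercising the bounds; the
test sweeps use 4–7 leaves, 5–10 sites and p between 0.1 and 0.35 so that
exhaustive oracles stay cheap while weights remain non-trivial. A fixed
seed makes output bit-for-bit reproducible. The generator does not model
indels, rate heterogeneity across sites, or realistic substitution
processes (no transition/transversion bias), and simulated leaves can
contain duplicate sequences; what passing property tests establish are the
exact combinatorial claims (weight preservation, the sandwich bound, cut
equivalences) on such data — not statistical performance on real
alignments, for which the exact worked examples and the proved bounds are
the relevant evidence.

## Numerical and degenerate-input choices

Distances and parsimony weights are integers end to end; normalized heights
are computed on demand only. A single-vertex input yields a one-leaf
cladogram with no edges and weight 0; clustering requires ≥ 2 points. The
demarcation-instance generator requires n ≥ chain_length + 2 so the outlier
is genuinely distant and distinct from the chain head. CLI exit codes
separate usage errors (2), data errors (3) and size-guard refusals (4).

## Known limitations

Only single linkage is implemented (no complete/average/Ward); only
unordered reversible characters (no Wagner/Dollo/Camin-Sokal costs, no
perfect-phylogeny reasoning); no substitution-model distances; no tree
search beyond the exhaustive oracle — heuristic search (NNI) and
neighbor-joining are deliberately out of scope, as is any alignment step:
inputs must already be aligned and equal-length.
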