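# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `cliquecav`.

## Networks and thresholding

A network is a symmetric non-negative n×n matrix with zero diagonal; an
edge exists iff its weight is positive. Asymmetry beyond 1e−9 is an error
rather than being silently averaged, because an asymmetric input to an
undirected analysis usually signals an upstream bug. Edge density always
uses the all-pairs denominator n(n−1)/2 — including pairs that never carry
an edge — so the density of an incomplete network tops out below 1 and
thresholds at different n are comparable. `threshold_by_density(net, rho)`
keeps the ⌊ρ·n(n−1)/2⌋ strongest edges (capped at the number of present
edges); the default ρ = 0.25 removes spurious weak connections at the
density conventional for structural connectomes.

Weight ties are broken deterministically by lexicographic node-pair order.
The alternative, adding independent Uniform[0, 1e−4] noise to every
positive weight (`add_tiebreak_noise`, seeded), is provided because
persistence is stable under small filtration perturbations; the
deterministic default makes runs reproducible without a seed. Group
averaging is the element-wise mean with absent edges entering as zeros,
matching a group-averaged connectome where each edge is the mean
streamline density over scans; averaging before thresholding is the
default order, with the other order available by thresholding each input
first.

## Filtration and persistent homology

The weight-rank clique filtration adds edges in strictly decreasing weight
order starting from the empty graph on all nodes. Every clique of the
growing graph is a simplex of the flag complex and is stamped with the
step of its latest edge. Homology is computed over Z2 in dimensions 1–2 by
standard boundary-matrix column reduction: simplices are ordered by
(stamp, dimension, node tuple) — which places faces before cofaces —
columns are stored as integer bitmasks, and each column is reduced by XOR
against earlier columns with the same low entry. A zero column creates a
class; a pivot column kills the class created by its low. Classes never
filled (possible only when the input network is incomplete, since absent
edges are never added) are reported with death = +∞ and excluded from π
rankings. Zero-lifetime pairs — a clique and its killer arriving on the
same edge, e.g. an edge that simultaneously closes a cycle and completes a
triangle — are retained in the raw output for completeness but excluded by
`Diagram.positive()`, which is what plots and downstream stages consume.

The dimension cap defaults to 2 (cliques up to 4 nodes are enumerated, so
dimension-2 deaths are paired correctly); it can be raised at cost.
Persistence runs on the full weighted network by default; reproducing a
thresholded run is a matter of thresholding first (`--rho` on the CLI).

An independent oracle computes Betti numbers at any step directly from
GF(2) ranks of freshly built boundary matrices
(β_k = n_k − rank ∂_k − rank ∂_{k+1}). The binding correctness contract —
enforced by the test suite on randomized ensembles — is that the number of
alive bars at every step equals the oracle's β_1 and β_2, and that the
alternating clique-count sum equals the alternating Betti sum when the
complex is truncated consistently at dimension 3.

## Minimal cycle representatives

"Minimal" means minimum node count (topological hop length); minimum total
edge weight would be an alternative definition and is not implemented.
For a dimension-1 class, the graph is thresholded at the step immediately
preceding the birth edge (the graph containing all strictly earlier
edges); every minimum-length path between the birth edge's endpoints
closes a candidate cycle. Candidates that bound at the birth step are
discarded, and the survivors — all recorded, since any could be the
class's generator — are grouped into Z2 equivalence classes by solving
membership of their pairwise sums in the boundary image. Dimension-2
representatives are found by exhaustive search over connected node subsets
containing the birth triangle, in increasing size: on each subset the
affine system "closed 2-chain containing the birth triangle" is solved
over GF(2) and solutions spanning exactly the subset are kept if
non-bounding in the full slice. The search is capped (default 12 nodes;
100 representatives per class; kernel dimension 20): hitting any cap is a
diagnostic error, never a silent truncation.

## Graph statistics

Communicability uses the exact matrix exponential of the
strength-normalised adjacency D^{−1/2} A D^{−1/2}, making it invariant to
global weight rescaling; isolated nodes are an error naming the node.
The weighted rich-club curve φ^w(k) divides the summed weight among nodes
of degree > k by the sum of the equally many globally largest weights, so
φ ≤ 1 wherever defined; degrees whose subgraph has no edges are flagged
NaN. Null networks are built by degree-preserving double edge swaps
(10·|E| attempted swaps) followed by reassigning the original weight
multiset to the new edge set in rank order of the product of the original
endpoint strengths. This preserves the degree sequence exactly and node
strengths approximately (rank correlation > 0.95 on 50-node geometric
networks); an exact strength-preserving rewire is not uniquely defined and
the approximation is deliberate, with the swap count exposed. Significance
per k is a one-sample, one-sided t-test of the null sample against the
observed φ (α = 0.05, no multiplicity correction); when the null sample is
constant the p-value degenerates to 0/1 by direct comparison. The k-core
uses the standard definition (all subgraph degrees ≥ k, by iterative
pruning); a strict greater-than variant is available behind
`paper_strict`. s-core levels are produced by the degeneracy-style
weighted pruning of Eidsaa–Almaas type, scanning only strengths actually
observed during pruning rather than a continuous grid.

## Synthetic data

The minimally wired model links every pair of nodes with weight equal to
the inverse Euclidean distance between them; only relative distances
matter after rank filtration, so coordinate units are arbitrary. Random
geometric networks place n i.i.d. uniform points in a cube (n and the box
are free; tests use n up to 83, the size of a standard cortical+subcortical
parcellation).

Planted-cavity networks assign strictly decreasing integer weights by
explicit rank so births and deaths are exact by construction: shell edges
occupy the top ranks with the designated last shell edge exactly at the
target birth index, fill edges start at the target death index, and any
gaps are occupied by inert padding edges chosen so that they close no
cycle once the shell nodes are contracted to a single supernode — a
union-find argument that guarantees padding creates neither independent
cycles nor triangles at any stage. The realised homology is verified with
the rank oracle; a shell that bounds before completion (e.g. a tetrahedron
boundary, instantly filled in a flag complex) is rejected.

Scan ensembles multiply each present weight by exp(σZ) with Z standard
normal (default σ = 0.05, a mild re-scan variability), delete present
edges and insert absent pairs with a common Bernoulli flip rate (default
0), inserting at weights between the template's minimum and median so new
edges arrive late in the filtration. This generative model is the
package's own choice; it emulates test–retest variability in edge weights
and marginal edge detection, but not the spatially correlated errors,
distance-dependent false positives or region-size effects of real
tractography — so passing matching tests demonstrates the heuristic's
mechanics, not its field performance on imaging data.

## Cavity matching across scans

Rule 1 runs the filtration of the subgraph induced on each reference node
set N_i, on the subgraph's own density scale (the natural choice given
that only the induced edges exist there), and reports the first step
carrying precisely one non-trivial class of the reference dimension.
Rule 2 scans the target's positive-lifetime classes of that dimension in
increasing birth density, skipping any whose birth clique contains no
reference node — reproducing, deliberately, the heuristic's documented
false-negative mode. Subrule 2a compares the scan's minimal generators to
the reference representatives by equality or Z2 equivalence (testable only
when the reference cycle's cliques all exist in the scan's slice); 2b
accepts a generator using all but at most one node of some N_i with at
most two extra nodes, requiring the shared nodes to appear in the
reference's cyclic order up to rotation and reflection (vacuous for
dimension 2, where no canonical order exists); 2c re-runs both tests at
each step within [ρ_birth, ρ_death) at which the class's minimal
generators change, where generators at a later step are BFS candidates
filtered to those still equivalent to a birth representative. For
dimension-2 classes 2c falls back to the birth density only, since
tracking 2-dimensional generator evolution would require the exhaustive
search at every step for little benefit at the scales considered.

## Pipeline

`run_full_analysis` composes the stages (load/average → optional
tie-break noise → threshold → cliques/participation → communicability,
rich club, cores → persistence for the empirical and minimally wired
networks → minimal cycles for the longest-lived classes → per-scan
matching) under a flat INI config whose defaults are ρ = 0.25, dimensions
1–2, 1000 rich-club nulls and noise bound 1e−4. Every output is listed in
a JSON manifest with parameters, seeds and input fingerprints; all
randomness flows from the configured seed, and two runs with the same
config are byte-identical.

## Problem sizes and limitations

The reduction and oracle are exact but dense-bitset based: they are
designed for parcellation-scale networks (tens to low hundreds of nodes)
and desk-scale validation ensembles (randomized suites use n ≤ 12–15 where
an exhaustive or rank oracle is feasible), not for voxel-scale complexes.
The acceptance script's ensemble of 200 random graphs with n ≤ 12 was
chosen to exercise every pairing case (births, finite and infinite deaths
in both dimensions) while completing in seconds. Other known limitations:
the rewiring null preserves strengths only approximately; the 2-cycle
search cost grows combinatorially with the node cap; the matching
heuristic inherits the false negatives discussed above; and homology in
dimension ≥ 3 is supported by the engine (raise `max_dim`) but untested
beyond the Euler identity's truncation logic.
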