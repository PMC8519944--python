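# Methods

This note documents the models and procedures `mechnet` implements, the
choices made where the design was genuinely open, and what the test suite
does and does not establish.

## Mechanism simulators

All simulators emit binary, self-loop-free adjacencies and are fully
deterministic given a seeded generator.

* **ER** — every off-diagonal (ordered, if directed) pair carries an edge
  independently with probability *p*.
* **PA** — growth from a single node (an *m*-clique for *m* > 1); each
  arrival attaches *m* edges to distinct existing nodes with probability
  ∝ (degree + 1)^α. The +1 keeps zero-degree nodes reachable at every α;
  the directed variant points the arrival's arcs at targets chosen by
  in-degree. Default *m* = 1.
* **DD** — growth from a connected pair; each arrival copies a uniformly
  chosen template's neighbourhood, deletes each copy independently with the
  divergence probability, and links to the template with the parent-link
  probability (default 1, which guarantees connectivity). Undirected. With
  divergence 0 the graph stays complete; with divergence 1 it is a tree.
* **NM** — niche model: ηᵢ ~ U(0,1) (resampled until distinct to guard float
  ties), diet range rᵢ = ηᵢ·x with x ~ Beta(1, (1−2C)/(2C)), diet centre
  cᵢ ~ U(rᵢ/2, ηᵢ); i consumes every j with ηⱼ in [cᵢ−rᵢ/2, cᵢ+rᵢ/2].
  Directed only. Cannibalism links fall on the forbidden diagonal and are
  dropped, which biases realized connectance down by O(1/n).
* **SW** — ring lattice with k neighbours per side (default k = 2, the
  smallest radius with nonzero lattice clustering); each lattice edge is
  rewired with the rewiring probability to a uniform non-duplicate target
  (skipped if the node is saturated), so the edge count is exactly n·k.

DD and SW have no native directed form; their "directed" variant is the same
symmetric adjacency flagged directed (reciprocal arcs). NM has no undirected
form and is skipped when testing undirected targets.

Grid-search ranges: p ∈ [0.01, 0.99], divergence ∈ [0.01, 0.99],
C ∈ [0.01, 0.49] (the beta shape is undefined at C ≥ 0.5), α ∈ [0, 4],
rewiring ∈ [0.01, 0.99]; all config-overridable.

### The standardized growth form

`grow_network` builds any mechanism one node at a time with per-arrival
rules (the homogeneous case of a mixture). PA and DD are inherently growth
processes and delegate to their canonical simulators. For the others the
arrival acts locally: ER draws an out-arc to each existing node w.p. *p*
(making grown directed ER a random DAG — growth itself imposes structure,
and grown ER is measurably distinct from canonical ER in the state space);
NM consumes in-range existing nodes; SW links to its k most recent
predecessors and rewires each w.p. *p*. These per-arrival rules are this
package's definitions, chosen to reduce to each mechanism's canonical
structure in the homogeneous limit where one exists.

## Property profile (18 components)

Nine properties on the raw network, the same nine on its Markov transform:

1–2. in-/out-degree vectors, descending-sorted (strengths for weighted
input; identical for undirected networks);
3–4. Shannon entropies (nats) of the empirical distribution over distinct
degree values — parameter-free, stable at n = 20; float degrees are grouped
after rounding to 9 decimals;
5. global transitivity 3·triangles/triples on the symmetrized graph;
6. PageRank distribution (power iteration, damping 0.85, tolerance 1e−10,
≤ 200 iterations; dangling rows redistribute uniformly over the *other*
nodes, keeping the diagonal zero);
7. community count by greedy modularity maximization. Greedy merging breaks
ties by vertex and edge order, so the graph is first brought to BLISS
canonical form and rebuilt from its sorted edge list — the count is then a
true graph invariant, which the relabeling-invariance of the whole profile
requires;
8–9. exact censuses of connected induced 3- and 4-node subgraphs by
isomorphism class (igraph RAND-ESU with no sampling): 2 and 6 classes for
undirected networks, 13 and 199 for directed ones, in igraph's canonical
class order.

**Markov transform.** P = row-normalized adjacency (zero rows become
uniform over the other nodes, mirroring the PageRank dangling convention),
raised to the 5th power. Degree and PageRank components use the weights of
P⁵ directly; transitivity, communities and motifs operate on P⁵ binarized
at 1/(2n) — half the uniform-row mass scale — because motif isomorphism
classes are defined on binary graphs. The binarized transform is treated as
directed even for undirected inputs (P⁵ of a symmetric adjacency is not
symmetric in general). One consequence: the Markov out-strengths are
identically 1, so the Markov out-degree entropy is constant and calibration
assigns it weight 0.

## Distances, stacking weights, ordination

Scalar components compare as |x−y|; sorted vectors are zero-padded to equal
length (label-invariant, size-tolerant); motif counts are first divided by
C(n,3) or C(n,4) so differently sized networks are commensurable. The
network distance is the weighted average of the 18 component distances — a
symmetric, nonnegative, relabeling-invariant pseudo-metric (the triangle
inequality is not asserted).

Weights are calibrated by PCA *on pair distances*, not raw profiles
(distribution-valued components have no single raw scalar): compute all 18
component distances for every pair in a calibration panel, z-score each
component, take |PC1 loadings| normalized to sum 1; constant components get
weight 0. The shipped default was calibrated once on a seeded systematic
panel of 300 twenty-node networks spanning all mechanism–orientation
combinations (`calibrate_default_weights(seed=0)` reproduces it exactly;
provenance is embedded in the JSON).

Ordination is nonmetric MDS initialized from the classical MDS solution
(deterministic given the seed), returning coordinates and normalized
stress.

## The classification test

Per candidate mechanism, independently: (i) grid-search `grid_size` evenly
spaced parameter values, `reps` simulations each, matched to the target's
node count and directedness; keep the value minimizing mean distance to the
target, ties toward the smaller value. (ii) Simulate `n_null` networks at
that value; each null's score is its mean distance to the *other* nulls
(the target is excluded from the cloud's internal averages so the null
distribution is target-independent); the target's score is its mean
distance to all nulls; p = fraction of null scores ≥ the target's score
(ties count toward non-rejection; they have probability zero off the fully
degenerate case). Verdict at level α (default 0.05): the mechanism survives
iff p ≥ α. p-values are not normalized across candidates — a network can
pass several mechanisms or none.

Full-scale defaults are grid 100 / reps 50 / null 500; the desk-scale
settings used throughout the test suite and the acceptance script are
grid 25 / reps 10 / null 100 with 20-node networks, which keep a full
panel evaluation in minutes on one CPU while leaving the SW classifier's
AUC above 0.97. Under the exact null (target drawn from the tested
mechanism and parameter) the p-value distribution is approximately uniform
(KS-checked in the suite).

Each candidate runs on an RNG substream keyed by the mechanism's fixed
index, so adding or removing one candidate never changes another's
p-value.

Parameter estimation against a labelled panel uses inverse-distance
weights 1/(d + ε), ε = 1e−9, with an exact-zero-distance short-circuit.

## Mixtures

A mixture assigns each node a mechanism and parameter. Growth mode: a
connected pair seeds the network and arrivals wire per their own
mechanism's rule (directionality fixed per mechanism: ER/PA/NM act as
directed rules, DD/SW as undirected rules stored symmetrically). Rewiring
mode: an undirected ER network (density 0.2 by default) is swept
(default 10 passes) in fresh random node order, each node redrawing its
incident edges per its fixed rule; an all-ER assignment is stationary at
density p. `random_mixture` draws proportions uniformly on the simplex,
one parameter per mechanism uniformly in its range, shuffles the
assignment, and records the seed so the spec reproduces the network
bit-for-bit.

Identifiability behaves as expected from theory: a two-mechanism
proportion sweep lays out as a monotone gradient in the ordination,
while five-mechanism mixtures largely collapse — in this implementation a
weak residual signal remains (leave-one-out R² of proportions on 2-d NMDS
position ≈ 0.1, against ≈ 0 for label-permuted baselines), so the suite
asserts the collapse (R² < 0.3) rather than exact indistinguishability.

## Function: ascendency

Treating the (binary networks: unit-flow) adjacency as a flow matrix T with
total throughput T··: A = Σ Tᵢⱼ·ln(Tᵢⱼ·T··/(Tᵢ·T·ⱼ)) and
C = −Σ Tᵢⱼ·ln(Tᵢⱼ/T··), natural log, sums over positive entries; A/C ∈
[0, 1], undefined when C = 0. A/C = 1 exactly for permutation-structured
flows and is invariant to flow rescaling.

Leave-one-out prediction of A/C uses the same inverse-distance weighting as
parameter estimation over *all* other panel members (a k-nearest variant is
available via `k=`). The global kernel is deliberately conservative: with
~150 panel members at broadly similar distances it shrinks predictions
toward the panel mean, so its R² understates what the nearest neighbours
alone achieve (small-k variants score far higher on the same panels). The
headline R² reported by the acceptance script uses the default predictor.

## Evaluation

ROC/AUC uses the mechanism-test p-value as the score (higher = more
consistent with the candidate) and the rank (Mann–Whitney) formulation with
tie mid-ranks, which equals trapezoidal integration of the tie-aware curve;
−target_mean_distance is available as an alternative score. Panel
evaluation simulates labelled targets per mechanism–orientation (parameters
swept evenly across each range) and classifies every target against every
candidate with independently simulated nulls. `bayes_ppv(a, f)` treats a as
both sensitivity and specificity of the test and f as mechanism prevalence:
P(true|positive) = a·f / (a·f + (1−a)(1−f)).

## What the synthetic panels do and do not show

Every number in the test suite and acceptance script comes from networks
this package simulated itself: small (default 20 nodes), binary, connected
to the extent the mechanisms make them, with parameters swept or drawn
uniformly. Passing tests establish internal correctness and desk-scale
discriminability under exactly these conditions. They do not establish
behaviour on empirical networks — real data are larger, weighted, noisy,
possibly sampled, and drawn from unknown mechanism prevalences (the Bayes
analysis shows how quickly positive calls degrade when a mechanism is
rare). Motif censuses are exact, not sampled, so profile cost grows
combinatorially; the implementation is practical to a few hundred nodes.

## Known limitations

* One governing parameter per mechanism is searched; secondary settings
  (k, m, parent-link probability) are fixed.
* The stacked distance is a pseudo-metric; NMDS stress at small panel sizes
  can be substantial.
* The attachment power is only coarsely identifiable from 20-node networks
  (estimates track the truth monotonically but with errors up to a fifth of
  the range near α ≈ 2).
* Directed DD/SW are conventions (reciprocal arcs), not native directed
  processes.
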