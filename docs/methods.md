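# Methods

This note documents the models and procedures implemented in `oascreen`,
the defaults that matter, and the choices made where the design was
genuinely open.

## Molecular graphs and descriptors

Molecules are hydrogen-suppressed RDKit graphs; implicit hydrogen counts
enter as an atom descriptor.  Atom indices are the stable 0-based RDKit
indices of the parsed heavy-atom graph and are preserved across all
operations of a run, so a weight vector indexed by query atoms stays
meaningful from optimization through visualization.

Each atom carries a k_a = 10 descriptor vector: Pauling
electronegativity, atomic mass, heavy-atom degree, total hydrogen count,
formal charge, aromaticity flag, ring-membership flag, hybridization
code, Gasteiger partial charge, and a conjugation flag.  Each bond
carries k_b = 4 values: bond order, aromaticity, ring membership,
conjugation.  The set is configurable (`DescriptorConfig`); the default
trades the large descriptor battery of chemical expert systems for a
compact, dependency-free set that captures the same physico-chemical
intent.

Every descriptor is standardized by a **fixed affine range** declared in
the configuration (e.g. electronegativity over [0.7, 4.0], mass over
[1, 130]), never by data-dependent statistics.  This keeps atom
similarities identical across libraries and runs.  If a descriptor is
undefined for an atom (the Gasteiger model can fail on exotic atoms),
its neutral raw value (0) is imputed and a warning emitted.

## Pairwise atom similarity

The similarity of atom *i* of molecule A and atom *j* of B combines an
RBF over the standardized atom descriptors with a recursive comparison
of the topological neighborhoods up to depth 2:

```
S_0(i,j) = exp(-gamma ||x_i - x_j||^2)

S_r(i,j) = (S_0(i,j) + d(1) * M_r(i,j)) / (1 + d(1) * max(|N_i|, |N_j|))
```

where `M_r(i,j)` is the value of a small optimal assignment between the
neighbors of *i* and the neighbors of *j*, with pair scores
`rbf(bond descriptors) * S_{r-1}(a,b)`, and `d(dist) = (1 - dist/3)^2`
is the decay that down-weights the environment relative to the center
(d(0) = 1, d(1) = 4/9, d(2) = 1/9, 0 at distance 3 — just beyond the
depth-2 cutoff).  Two levels of the recursion are applied (depth 2).

Design choices in this combination, made where a single canonical rule
does not exist:

* **Decay-normalized weighted mean.**  Center and matched neighbors are
  combined as a weighted mean with weights 1 and d(1); unmatched
  neighbors (degree mismatch) keep their weight but contribute zero
  similarity, so missing neighbors are penalized.  This form makes the
  decay parameter operative, keeps results in [0, 1], and — important
  for the normalization below — gives *exactly* 1 for identical atoms in
  identical environments.  Through the recursion, atoms two bonds away
  are effectively damped by d(1)^2 ≈ 0.20, close to the nominal
  d(2) = 1/9.
* **RBF width** gamma = 4.0 on the standardized descriptors (bond RBF
  width 1/k_b).  With all descriptors scaled to ~[0, 1], widths of order
  1/k_a leave cross-element similarities above 0.97 and the ranking
  nearly blind; gamma = 4 places two different first-row heavy atoms at
  ~0.5.  Configurable per `VirtualScreen`/`pairwise_matrix`.

## Optimal assignment and weighting

`optimal_assignment` maximizes the summed mapped similarities over
injective mappings of the smaller molecule onto the larger
(`scipy.optimize.linear_sum_assignment`, O(max(m,n)^3)); the score is
normalized as S(A,B)/sqrt(S(A,A) S(B,B)).  Since the pairwise matrix has
a unit diagonal, S(A,A) equals the heavy-atom count m.

A query weight vector w (w_i >= 0, sum w_i = m) scales row i of the
similarity matrix, so the weighted OA is the plain OA of diag(w)·S; the
weight always sits on the query side of an assignment edge.  With
uniform weights (w = 1) the weighted pipeline reproduces the unweighted
one bit-for-bit.  Two conventions had to be fixed:

* **Weighted self-similarity.**  The normalization of the weighted score
  uses S_w(Q,Q) = sum_i w_i S_ii = m (the identity self-assignment), so
  the weighted normalized score is raw / sqrt(m * S(B,B)).  Strongly
  concentrated weights can push individual scores above 1; scores are
  used for ranking only, so they are not clamped.
* **Search-space mapping.**  Optimizers work in the box [-0.5, 0.5]^m.
  `normalize_weights` clips to the box, shifts by +0.5 into [0, 1]^m and
  rescales to sum m; the all-zero degenerate case maps to the uniform
  vector.

## Virtual-screening metrics

`RankedList` canonicalizes results by descending score with **decoys
before actives at equal score** (then by id) — a pessimistic,
deterministic tie policy.  On top of it:

* **AUC** via the Mann-Whitney identity with average ranks (tied
  active/decoy pairs count 1/2); identical to the trapezoidal area under
  the tie-grouped ROC curve.
* **BEDROC** (default alpha = 53.6) as the exponentially rank-weighted
  robust initial enhancement, min-max rescaled to [0, 1] with its exact
  attainable extremes; at alpha = 53.6 the weight function places 80% of
  its mass on the top 3% of the list.
* **ROCE_x%**: sensitivity at the rank of the ceil(x/100 · N_decoys)-th
  decoy divided by the realized false-positive rate k/N_decoys.  Actives
  strictly above that decoy in the canonical order count as found; an
  active tied with the boundary decoy does not (pessimistic).
* **awROCE_x%**: each active weighted by 1/(its chemotype-cluster size),
  averaged over clusters before dividing by the FPR — retrieving many
  distinct scaffolds early scores higher than piling up one cluster.
  With singleton clusters it reduces exactly to ROCE.
* **Chemotype discovery curve**: fraction of clusters first seen as a
  function of the decoy fraction.

## Weight optimization

The fitness of a raw vector is `1 - metric` (AUC or BEDROC) of the
weighted ranking on the optimization set; optimizers minimize.  The
pairwise matrices and library self-similarities do not depend on the
weights, so `VirtualScreen` precomputes them once and each fitness
evaluation costs one row-scaling plus one Hungarian solve per library
molecule (~milliseconds for a 240-compound library).

* **PSO (constriction).**  phi1 = phi2 = 2.05, chi from
  2/|2 - phi - sqrt(phi^2 - 4 phi)| ≈ 0.7298, population 30, synchronous
  updates, positions clipped to the box, initial positions uniform in
  the box and initial velocity components uniform in [-0.2, 0.2].
  Neighborhood: 2D grid on the most-square factorization of the
  population (5 x 6 for 30), torus wrap, Manhattan range 2, each
  particle included in its own neighborhood.
* **DE variants** (binomial recombination, forced crossover index,
  mutually exclusive donors, F = 0.8, CR = 0.6, population 30):
  DE/rand/1 (random base, one difference pair), DE/best/2 (best base,
  two pairs), DE/current-to-best/1 (arithmetic base
  x_i + lambda (x_best - x_i), lambda = 0.6, then binomial crossover
  against x_i).  Selection is greedy one-to-one replacement, applied
  immediately, with ties resolved in favor of the candidate.
* Runs stop after exactly `budget` fitness evaluations (a generation may
  be truncated); the best-so-far trace has one entry per evaluation and
  is monotone.  A single seeded NumPy generator drives each run, so runs
  are exactly reproducible from (seed, config).

## Evaluation protocol

`make_splits` draws label-stratified randomized 50/50 splits (default
10); with an odd label count the optimization half receives the floor
share.  For each split x multirun, weights are optimized on the
optimization half only; the best multirun is selected by its
*optimization-split* fitness (never test performance, avoiding selection
bias) and scored on the held-out half.  External-test ids are disjoint
from optimization ids by construction and by test.

Multirun stability is the per-split sample standard deviation (ddof = 1)
of the optimized metric, averaged over splits; %RSD divides by the
per-split mean.  The convergence point of a monotone best-so-far
performance trace is the first evaluation within a band of the final
best — relative 1% by default, or a fixed 0.01; a zero final best falls
back to the fixed band.  `average_ranks` summarizes methods across
datasets with average ranks (ties averaged).

## Synthetic planted-pharmacophore benchmark

The fixture generator emulates a small target-focused screening library:
actives embed an indole-carbonyl motif (an indol-3-yl ketone) in one of
up to seven chemotype scaffolds plus random decorations; decoys combine
the same scaffolds/decorations with non-pharmacophore caps.  Half of the
decoy caps (default `hard_decoy_fraction = 0.5`) are deliberate near
misses — benzoyl (carbonyl, no indole), 2- or 3-substituted indoles (no
carbonyl), a methylene-spaced indole ketone — so the unweighted OA
ranking is good but imperfect (external AUC ~0.78–0.84 at the default
40 actives / 200 decoys / 5 clusters), leaving real headroom for the
weight optimization.  Every active substructure-matches the motif and no
decoy does (verified at generation); an optional label-noise rate flips
labels to degrade attainable performance in a controlled way.  The query
embeds the motif in a short propyl tail (14 heavy atoms).

What the fixture does **not** emulate: property-matched decoy selection
as in curated decoy databases, conformational flexibility, activity
cliffs, or assay noise.  Passing the optimization-recovery tests shows
the machinery can find and exploit a genuine substructure signal at
desk scale; it does not certify performance on real screening decks.

Problem sizes used by the test suite and `scripts/acceptance.py` (the
package's own desk-scale defaults): 10 seeds, one stratified split per
seed, population 30, 1500 fitness evaluations per run — against the
full protocol defaults of 10 splits x 10 multiruns x 15000 evaluations
that `ExperimentConfig` ships with.

## Numerical choices and degenerate inputs

* Similarities are clipped to [0, 1] after the recursion; the canonical
  sort makes all metrics invariant to permuting tied entries.
* Assignment ties: any optimal mapping may be returned; tests assert
  scores, not mappings, whenever ties are possible.
* Weight redistribution (visualization) spreads w_i over the depth-2
  neighborhood *including the center* proportionally to the decay;
  pre-normalization totals are conserved exactly and the transform is
  linear.  Per-molecule min-max normalization maps an all-equal vector
  to 1.0 (within 1e-9) to avoid amplifying float noise; ball radii are
  r_min + w' (r_max - r_min), defaults 0.2–0.8 Å.
* Disconnected atom pairs have infinite topological distance; the
  depth-2 machinery never sees them.
* Empty molecules, datasets without both labels, single-multirun
  stability, and zero-decoy cutoffs raise `ValueError` rather than
  returning silent defaults.

## Known limitations

* The descriptor set is deliberately small; it does not reproduce any
  specific expert-system descriptor battery, and stereochemistry and 3D
  conformations are ignored.
* The recursive environment term is one of several defensible readings
  of a neighborhood-aware atom kernel; alternatives (fixed 0.5 mixing,
  different decays) are reachable through the configuration but not
  exhaustively benchmarked.
* Weighted normalized scores are comparable within one screening run
  (fixed query and weights), not across different weight vectors.
* On easy landscapes the convergence-speed ranking of the optimizers is
  sensitive to the convergence-band definition (relative 1% vs fixed
  0.01); both are implemented and reported.
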