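# Methods

## Overview

`danemda` predicts candidate miRNA–disease associations from three inputs:
a table of known associations, miRNA sequences, and a disease hierarchy
(a MeSH-style directed acyclic graph). The method treats the data as an
*attributed network*: the bipartite association graph supplies structure,
and per-node similarity profiles supply attributes. Four stages follow.

1. **Channels.** The structure channel `S` is the row-normalized adjacency
   of the bipartite graph (miRNA and disease nodes, an edge per known
   association). The attribute channel `Z` is the row-normalized
   block-diagonal matrix whose miRNA block is k-mer cosine sequence
   similarity and whose disease block is hierarchy-based semantic
   similarity. Node order is miRNAs sorted lexicographically, then
   diseases sorted lexicographically, so runs are independent of input
   line order.
2. **Fusion and multi-order proximity.** The channels are fused into one
   transition matrix `P = α·S + (1−α)·Z` and expanded into the enhanced
   matrix `M = Σ_{l=1..t} β^{l−1} P^l`. Fusion happens *before* powering,
   so structure–attribute cross-terms appear from order 2 on. The damping
   exponent is `β^{l−1}`: the first-order term carries full weight and
   `β = 1` degenerates to an unweighted sum. For fully stochastic `P`
   every row of `M` sums to `(1−β^t)/(1−β)` (or `t` when `β = 1`), which
   the tests verify to 1e−9.
3. **Compression.** Each node's row of `M` is compressed to a
   low-dimensional code by a stacked auto-encoder (below).
4. **Classification.** A pair (miRNA `i`, disease `j`) is represented by
   the concatenation of the two codes; a Random Forest (scikit-learn
   defaults, seeded) scores the probability of association. Balanced
   negatives are drawn uniformly from the unlabeled complement of the
   association matrix.

## Disease semantic similarity

Each disease `d` receives a contribution map over its ancestors:
`D_d(d) = 1` and `D_d(t) = max{Δ·D_d(t′) : t′ a child of t on a path from
d}`, i.e. the contribution decays by `Δ` per edge along the best path
(equivalently `Δ^dist` with `dist` the minimum edge distance, computed by
BFS along child→parent links). The semantic value is `DV(d) = Σ_t D_d(t)`
and two diseases are compared by shared contribution mass:

    DSS(d1, d2) = Σ_{t ∈ T1 ∩ T2} (D_d1(t) + D_d2(t)) / (DV(d1) + DV(d2))

`Δ` defaults to 0.5, the conventional value for this family of hierarchy
measures; it is exposed as `delta` everywhere. Contributions are combined
across multiple parents by `max`, not by sum, which keeps every
contribution in (0, 1] and makes `DSS(d, d) = 1` exact. A brute-force
path-enumeration oracle on random DAGs of ≤ 8 nodes backs the
implementation in the tests.

## miRNA sequence similarity

Cosine similarity of k-mer count vectors (`k = 3` by default, 64
dimensions over the ACGU alphabet). Alignment-free, deterministic, O(n)
per sequence, entries guaranteed in [0, 1] with exact 1 on identical
sequences. DNA-coded input (T) is normalized to U on loading. A
normalized-alignment similarity would be a drop-in replacement behind the
same operation but is out of scope.

## Stacked auto-encoder

Architecture: input width `n = m + d`, hidden widths `(256, 64)` by
default, logistic-sigmoid activations on hidden layers and a linear
reconstruction output, untied encoder/decoder weights, Glorot-style
initialization. Requested hidden widths are capped below the input width
so the layer chain stays strictly decreasing on narrow inputs. Training is
greedy layer-wise pretraining (each layer reconstructs the previous
layer's activations through its own code; 50 epochs per layer by default)
followed by end-to-end fine-tuning of the full stack on mean squared
reconstruction error (100 epochs by default), mini-batches of 32.

Updates use Adam-style adaptive moments (β₁ = 0.9, β₂ = 0.999) at a
nominal learning rate of 1e−3. This is a deliberate numerical choice:
enhanced-matrix entries are small (row sums ≈ 4.47 at the default β and t,
spread over hundreds of columns), and plain constant-step gradient descent
at any single default step size either diverges or leaves the code
activations nearly constant, destroying the planted-group separability the
embedding must preserve. Adaptive per-parameter scaling removes that
dataset-dependent tuning while remaining seeded, deterministic, mini-batch
gradient descent: the batch order is drawn from the spec seed, so
identical input + spec + seed reproduces the weights bit for bit.

No denoising or sparsity penalties are applied; the model is a plain
stacked auto-encoder.

## Evaluation protocol

Cross-validation folds positives and negatives independently into `k = 5`
seed-deterministic folds. Two feature-construction modes exist:

* **masked** (default): the adjacency is rebuilt from training-fold
  positives only before the proximity and embedding stages, so test edges
  never leak into the features. This is the honest protocol and the one
  all reported numbers use.
* **paper**: the full adjacency is embedded once and reused across folds
  (the classifier still sees only training pairs). Provided as a
  reproducibility switch for comparison with published protocols that do
  not state masking; expect optimistic numbers from it.

Metrics are computed from first principles: confusion counts at a fixed
0.5 threshold (classes are balanced by construction), MCC by its standard
formula (0 when the denominator vanishes), AUC as the Mann–Whitney rank
statistic with ties credited 0.5, and AUPR as non-interpolated step-wise
area. The rank AUC equals the trapezoidal area under the stored ROC points
to 1e−12, and all three summary statistics are cross-checked against
scikit-learn in the tests. Report means and standard deviations (ddof = 1)
are recomputable from the per-fold values.

Candidate ranking for a disease scores every miRNA not already known for
it, sorts by descending score and breaks ties by miRNA id ascending, so
top-50 lists are reproducible.

## Synthetic data

The generator plants a shared group structure in all three inputs:
miRNAs and diseases are assigned to `n_groups` round-robin; association
(i, j) is Bernoulli with probability `p_in` within a group and `p_out`
across; each group has a random `motif_len`-mer implanted (per-base
mutation at `mutation_rate`) into otherwise random `seq_len`-nt sequences;
and the disease hierarchy is a rooted `dag_branching`-ary tree in which
same-group diseases coalesce below a strictly deeper ancestor than
cross-group pairs. Defaults: 200 miRNAs, 100 diseases, 5 groups,
`p_in = 0.3`, `p_out = 0.01`, 22-nt sequences with 8-nt motifs mutated at
0.1, ternary hierarchy, seed 7 — miRNA-realistic lengths and sparse
association density at a scale where five-fold masked cross-validation
with per-fold re-embedding runs in a few minutes on one CPU. Randomness is
split into per-component sub-streams spawned from the single seed, so
changing one parameter perturbs only its component.

What the generator does **not** emulate: the heavy-tailed degree
distribution of curated association databases, literature/ascertainment
bias, sequence families with shared precursors, or diseases annotated at
multiple hierarchy positions. Passing tests therefore demonstrate that the
pipeline recovers a planted structure–attribute signal, not that it
attains any particular accuracy on curated human data.

A note on the attainable ceiling: under the generator's model the label of
a held-out pair is conditionally independent of every observable feature
given the two nodes' group memberships, so the Bayes-optimal masked AUC is
about 0.87 at the default densities (the group-truth oracle measures
0.85–0.88 per fold). The pipeline's mean masked AUC of ≈ 0.86 is therefore
near-optimal for these conditions; the fused, structure-only and
attribute-only variants differ by design only in how reliably they recover
the groups, which is why their ordering (fusion ≥ structure ≥ attribute)
is the meaningful comparison rather than the absolute values.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.85 | fusion weight: fraction of structure information in `P` |
| `beta` | 0.94 | per-order damping of higher-order walk terms |
| `t` | 5 | maximum walk order accumulated into `M` |
| `delta` | 0.5 | per-edge decay of ancestor contributions |
| `kmer_k` | 3 | k-mer length for sequence similarity |
| hidden dims | (256, 64) | auto-encoder widths; code dimension 64 → 128-dim pair features |
| learning rate | 1e−3 | Adam step size |
| epochs | 50/layer + 100 | pretraining / fine-tuning |
| classifier | random_forest | scikit-learn defaults, seeded |
| threshold | 0.5 | operating point for thresholded metrics |

`alpha`, `beta` and `t` follow the tuned operating point of the method
this package implements; the auto-encoder architecture is configuration,
and none of the pipeline's qualitative behavior depends on it.

## Degenerate inputs and tie-breaking

* Isolated nodes produce zero rows in `S`; they are left zero (no
  fabricated uniform jump), so their fused rows sum to `1 − α` and the
  attribute channel still supplies signal through the unit diagonal of
  `Z`.
* Duplicate association lines are collapsed with a logged count; ids
  missing from the FASTA/DAG error by default and can be dropped
  explicitly (`--allow-missing-attributes`).
* All randomized steps (negative sampling, folding, batch order, forest
  construction) derive independent sub-seeds from one user seed.

## Known limitations

* Only sequence and hierarchy attributes are implemented; interaction
  profile kernels and functional similarity are out of scope.
* The auto-encoder is CPU-only and dense; networks beyond ~10⁴ nodes
  would need a sparse or mini-batched proximity stage.
* `paper`-mode evaluation is intentionally leak-prone and should not be
  used for honest performance claims.
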