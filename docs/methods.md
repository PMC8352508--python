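# Methods

## Problem

Structure-based virtual screening benchmarks pair known binders (*actives*)
with presumed non-binders (*decoys*). If decoys differ from actives in bulk
physicochemical properties — molecular weight, logP, hydrogen-bond counts
and so on — a scoring method can separate the classes from those properties
alone (*artificial enrichment*) and its apparent performance says little
about molecular recognition. Conversely, decoys that are too structurally
similar to the actives risk being binders themselves (*false-negative
bias*). decoykit generates decoys tailored to each active — matched in
property space, dissimilar in structure — and quantifies the residual bias
of any active/decoy set.

## Generative model

The generator is a graph-to-graph variational autoencoder over heavy-atom
molecular graphs.

**Encoder.** A gated-graph neural network: per-atom one-hot type embeddings
are refined by `mp_rounds` rounds of bond-order-specific message passing
with a GRU-style node update, pooled through a sigmoid-gated sum into a
graph vector, and projected to the mean and log-scale of a diagonal
Gaussian latent of dimension `latent_size`.

**Decoder.** Molecules are built bond by bond, breadth first, from a pool
of typed atoms (by default the exact heavy-atom composition of the input
active, so composition is matched by construction; a partial substructure
can seed the graph instead). At each step the focus atom — head of the BFS
queue — chooses among *permitted* actions: form a bond of order 1, 2 or 3
to a placed atom or to one representative unplaced pool atom per type, or
close the focus atom and advance the queue. An action is permitted only if
both endpoints have sufficient remaining valence under the atom vocabulary,
so every intermediate and final graph is chemically valid; validity is a
structural guarantee, not a learned behaviour. Node states are recomputed
from the partial graph (conditioned on the latent sample) before each
action and scored by a small MLP; generation samples from the masked
softmax with a seeded RNG (greedy mode exists for tests).

**Training.** Supervision comes from molecule pairs (see below): the first
molecule is encoded, a latent sample drawn, and the decoder teacher-forced
through a canonical BFS construction trace of the second. The objective is

    L_total = L_recon + lambda_KL * L_KL

where `L_KL` is the standard Gaussian KL and `L_recon` is the sum of an
atom-type term (cross-entropy of a type head against the target pool's
type distribution) and the action-sequence term, averaged over steps.

**Reweighted action loss.** Instead of plain cross-entropy over permitted
actions, each action is weighted by the reciprocal frequency `f(x)` of the
local subgraph it would create, counted over the training molecules:

    L = -fbar * log( p(x_j) f(x_j) / sum_i p(x_i) f(x_i) )

with `fbar` the mean of `f` over permitted actions. With all weights equal
this is exactly `-log p(x_j)` (asserted numerically over 10^4 random
distributions). Since rare subgraphs carry large `f`, the fit forces the
model probability `p` of rare local chemistry *below* its data frequency,
suppressing unusual motifs in generated molecules. Design choices the
formula leaves open, decided here:

* the *induced local subgraph* of a bond action is the radius-1 environment
  of the new bond — the order of the bond plus, for each endpoint, its
  element, charge and the sorted orders of all incident bonds; counts are
  tabulated over (kekulized) training molecules with add-one smoothing so
  `f` is finite for unseen keys;
* the stop action induces no subgraph; it receives the mean weight of the
  competing bond actions, which leaves it neutral under the reweighting
  (a constant weight of 1 was observed to systematically inflate the
  trained stop probability and truncate generated molecules);
* the atom-type and action terms of `L_recon` are weighted equally.

The model works on kekulé graphs (bond orders 1/2/3 only) so valence
masking is exact; aromaticity is re-perceived by RDKit on output.

Optimisation is Adam, one pair per step, with a linear KL warm-up over
`kl_warmup` epochs. Defaults (`hidden_size=24`, `latent_size=8`,
`mp_rounds=2`, `epochs=30`, `learning_rate=0.01`, `lambda_kl=1.0`) are
desk-scale: they train in seconds-to-minutes on a CPU and are meant for
small-molecule libraries, not for full benchmark-scale runs. Training and
inference are NumPy throughout, gradients by the in-repo reverse-mode tape
(`decoykit.nn.autodiff`), checked against finite differences.

## Training pairs

Pairs are mined from a library so that both molecules (i) have identical
heavy-atom totals and identical C/N/O/S/Cl/F counts, (ii) lie within
`max_property_distance` in z-scored property space (z-scoring fitted on the
library itself), and (iii) have Morgan (radius 2, 1024-bit) Tanimoto
similarity at most `max_structural_sim` (default 0.15). Criterion (i) is an
exact equality, so the library is partitioned into composition buckets and
only within-bucket pairs are scanned — lossless and verified against the
O(N²) scan. Both orientations of each accepted pair are training examples.
A per-molecule pair cap (off by default) prunes by largest property
distance first. Published full-scale pair counts are not a target here:
they depend on multiplicity and normalisation conventions that are not
part of this package's contract.

## Selection pipeline

For each active, `candidates_per_active` (default 1000) molecules are
sampled, deduplicated by canonical SMILES, and filtered by an iterative
relaxation: starting from heavy-atom-count difference 0 and doppelganger
score ≤ 0.25, the atom-count allowance (+1) and the doppelganger threshold
(+0.05) are relaxed alternately until at least `min_pool` (default 100)
candidates survive; the whole schedule is logged so a user can audit or
override it. Final decoys (default 30/active) are the survivors with the
smallest sum of (a) normalised Euclidean property difference to their
active — normalisation fitted on the target's actives plus all candidates —
and (b) the LADS score. Ties break on canonical SMILES, making selection
order-independent and deterministic.

**LADS.** The latent-actives-in-decoy-set penalty is implemented as the
mean, over the decoy's functional-fingerprint bits, of the fraction of
actives containing that bit: 0 when no environment is shared, 1 when every
environment occurs in every active. The exact weighting is this package's
documented choice (validated against a hand-computed toy case); it rises
monotonically with active-like substructure content, which is the property
the greedy objective needs.

## Bias metrics

All metrics z-score properties on the union of the target's actives and
decoys, assessing each target in isolation.

**DOE score.** For each active, all other actives (positives) and all
decoys (negatives) are ranked by ascending property-space distance to it
and a ROC curve built; tied distances contribute a single linear segment.
The per-active score is the exact area between the curve and the diagonal
(trapezoid over breakpoints, split at sign crossings); the DOE score is the
mean over actives. 0 iff actives and decoys are co-embedded, 0.5 at
complete separation — both limits hold analytically under tie
interpolation and are asserted exactly. Distances are rounded to 9 decimals
before ranking so mathematically tied values are not split by last-bit
float noise; the implementation is equivalence-tested against an
exact-rational brute-force enumeration. Decoys of all actives are pooled
per target.

**Doppelganger score.** Per decoy, the maximum Tanimoto similarity to any
active over functional fingerprints (Morgan radius 3 on pharmacophoric
feature invariants — FCFP6-like — folded to 1024 bits); reported per decoy
with set mean and maximum.

**AVE.** Asymmetric validation embedding: over stratified folds,
`(H(VA,TA) − H(VA,TD)) + (H(VD,TD) − H(VD,TA))`, where `H(V,T)` averages,
over validation points and a uniform threshold grid on [0, 1], the
indicator that the nearest-training-point distance falls under the
threshold. Property distances are unbounded, so they are squashed by
`d/(1+d)` before thresholding; the grid density (default 50) is
configurable. Values lie in [−2, 2]; ≈0 for co-distributed classes.

**ML bias.** For every non-empty subset of the property set (2^k − 1
subsets), a classifier is assessed by pooled out-of-fold AUC under
stratified 10-fold cross-validation. 1NN uses a continuous score (distance
to nearest training decoy minus distance to nearest training active), which
yields a proper ROC; the random forest (50 trees, unlimited depth, pinned
seed) uses class probabilities. On permuted labels the mean AUC sits at
0.5 within Monte-Carlo noise.

## Synthetic fixtures

`make_library` grows connected, valence-valid heavy-atom graphs by seeded
random tree growth with occasional double bonds and one optional ring
closure, over a configurable element palette. These molecules exercise
every code path with realistic graph and descriptor diversity, but they
are not drug-like and carry no bioactivity: tests that pass on them
demonstrate correctness of the algorithms and contracts, not chemical
plausibility or screening performance on real benchmarks. A curated list
of ~110 well-known public-domain drug structures is bundled for realistic
descriptor values. `make_separable_sets` emits two Gaussian property
populations with controlled centre separation (`spread=0` collapses each
to a point), driving the DOE limit checks.

Desk-scale problem sizes used by the test suite — libraries of 120–500
fixture molecules, models of hidden size 24 trained ~12 epochs on ~30
pairs, 100–1000 candidates per active over 8 actives — were chosen so the
full pipeline runs on one CPU in minutes while still exhibiting the
qualitative behaviours of interest (loss decrease, valid and diverse
generation, DOE improving with candidate count). One small-sample caveat
is documented in the monotonicity test itself: with only a handful of
actives per target, each active's own property-hugging decoys dominate the
negatives of its ROC and the DOE score loses its meaning; eight or more
actives restore the intended behaviour.

## Known limitations

* The generator is desk-scale: no mini-batching, no GPU, modest capacity.
  Reproducing published full-benchmark decoy sets would require
  library-scale training outside this package's scope.
* Stereochemistry, tautomers, protonation states and 3D conformers are out
  of scope; formal charge is read from the input structure as drawn.
* The default atom vocabulary covers C, N (0/±1), O (0/−1), F, S, Cl, Br,
  I; rarer elements (e.g. phosphorus) must be admitted explicitly via a
  custom `AtomVocabulary`.
* The 27-descriptor extended property set is a reasonable default, not a
  canonical list; it is user-overridable via a property-set config file.
* Greedy selection is deliberately simple; it is not an optimal subset
  choice.
* Docking-based evaluation and CNN scoring-function training are out of
  scope; the bias metrics operate purely on properties and fingerprints.
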