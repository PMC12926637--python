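# Methods

`algddi` predicts drug–drug interactions (DDIs) by fusing three per-drug
representations of width *d* and scoring drug pairs with a fully connected
head. This note records the model, its assumptions, the synthetic protocol,
and the numerical choices, in the order the pipeline runs.

## Attribute scale: masked-attribute molecular GNN

A SMILES string is parsed (RDKit) into a heavy-atom graph; hydrogens stay
implicit. Node features are categorical codes for atom type, degree and
formal charge; bonds carry a bond-type code. Node states are updated for
K layers as

    h_v(k) = ReLU( MLP_k( Σ_{u∈N(v)∪{v}} h_u(k−1) + Σ_{e=(v,u)} h_e ) )

where each `MLP_k` is two affine maps with a rectifier between them, and
the molecule embedding is the mean over final node states. The summand
over neighbours is read as the neighbours' states h_u (summing the centre's
own state |N(v)|+1 times has no precedent and would break the pretext
task). Bond embeddings are computed once from the bond-type table and
reused at every layer; no edge-state update is defined for this
architecture. The encoder is pretrained by attribute masking: per epoch,
max(1, round-half-up(0.15·|V|)) nodes per molecule are replaced by a
dedicated mask row in the atom-type table (degree/charge features zeroed),
and a linear head must recover the original atom type from the final node
state, trained with cross-entropy. The minimum-one rule guarantees a
training signal on tiny graphs.

Defaults: pretraining width 300, K = 5 layers, mask rate 0.15, 100 epochs
of full-batch Adam at 5·10⁻³ (all molecules are batched into one
block-diagonal graph per epoch), with a fixed seeded linear map projecting
the pretraining width to the common *d* at export. One hundred epochs is
the point at which masked-atom reconstruction accuracy saturates on the
synthetic corpus; shorter schedules underfit.

## Local scale: relational propagation on the association graph

Drugs connect to side effects, proteins and diseases in an undirected
typed graph. Per relation r and layer k:

    E_v(k,r) = σ( W(k,r) · Concat(E_v(k−1), mean_{u∈N_r(v)} E_u(k−1)) )
    E_v(k)   = Σ_r E_v(k,r)

with σ the logistic function and the aggregate defined as the zero vector
for empty neighbourhoods, so isolated nodes stay well-defined. Initial
node states are a learned lookup table (seeded normal, scale 1/√d) — the
inputs carry no node features. K = 2 by default: two hops reach
entity-of-entity structure without oversmoothing at this scale.

No training objective is prescribed for this stage by the architecture
alone; the package pretrains it by per-relation link reconstruction:
observed drug–entity edges against 1:1 uniformly resampled non-edges,
scored by a dot product of the final-layer states with binary
cross-entropy. Because σ keeps every coordinate strictly positive, raw
dot products cannot express "non-edge"; the states are therefore centred
by their batch mean (not back-propagated) inside the scorer and a
trainable scalar bias is added. Without this conditioning the stage
collapses to the constant-probability solution. Sixty epochs of
full-batch Adam at 10⁻².

Drugs absent from the association graph receive the cold-start path:
their lookup row propagated through all-empty neighbourhoods (with a
warning).

## Global scale: ComplEx factorization of the knowledge graph

Entities and relations carry complex vectors of rank K. Triple
plausibility is the Hermitian trilinear form

    φ(r,h,t) = Re( Σ_k w_rk · e_hk · conj(e_tk) )

whose imaginary parts break head/tail symmetry (DistMult is the
imaginary-zero special case and is necessarily symmetric). Parameters
minimise the regularized logistic loss Σ log(1+exp(−Y φ)) + λ‖Θ‖²₂ over
observed positives plus uniform head-or-tail corruptions (10 per positive
by default; collisions with observed positives are rejected and resampled,
at most 100 rounds). λ = 10⁻³ as a plain L2 penalty on all four tables.

Optimization is full-batch Adam at learning rate 0.1 for 300 epochs by
default; at these problem sizes smaller rates leave the ranking of
held-out triples visibly unconverged. For larger graphs the trainer can
subsample a fixed number of positives per epoch (`batch_positives`),
which the stagewise pipeline uses. A drug's global embedding g is the
real part of its entity vector, passed through a fixed seeded linear map
when the rank differs from *d*. The real-part readout is lossy and
gauge-dependent — per-dimension complex rotations reallocate information
between real and imaginary parts — which matters for what the synthetic
protocol can plant (below). The KG supplied to this stage must already
exclude DDI edges; the package does not filter them.

## Fusion

The three width-*d* vectors (a, l, g) form a 3-token sequence processed by
a pre-norm transformer encoder block: multi-head self-attention (m = 4
heads, d_k = d/m) and a position-wise feed-forward (d→4d→d, ReLU), each
wrapped in a residual connection with layer normalisation applied before
the sub-layer (ε = 10⁻⁵). No positional encoding is used — scale identity
is carried by the learned projections — so the token stream is
permutation-equivariant by construction. The block output is flattened
(3d) and linearly projected to *d*; flatten-then-project preserves
per-scale information, unlike a token mean. One block by default,
configurable. Baselines: concatenation (3d→d linear), Hadamard product
and average (d→d linear).

## Pair head and training

For a pair (i, j), Concat(x_i, x_j) passes through a three-layer fully
connected network (hidden 256 and 128, ReLU) ending in a sigmoid (binary)
or softmax over event classes. Concatenation is order-sensitive while DDI
is undirected, so training uses both orderings of every pair and inference
averages score(i,j) and score(j,i).

Binary mode minimises binary cross-entropy (computed in logit space for
stability; the probability-space form clips at 10⁻⁷). Event mode uses the
phased schedule: standard cross-entropy while epoch t < T/2 (0-based
epochs make the inequality unambiguous), then focal loss
−Σ (1−p)^γ y log p with γ = 2, which down-weights easy examples in favour
of rare classes. Event classes with strictly fewer than 10 instances are
removed before training, and stratified K-fold splits deal each class's
shuffled indices round-robin so per-fold class counts deviate from
proportionality by at most one.

The default regime is stage-wise: encoders pretrained and frozen, fusion
and head trained jointly (full-batch Adam, 10⁻³, 300 epochs). Each scale
matrix is column-standardized before fusion so no scale dominates by raw
magnitude. The `fine_tune_encoders` flag additionally updates the
per-drug scale embedding matrices during pair training; the upstream
encoder weights themselves stay fixed (embedding-level fine-tuning).

All trainable components run on a small in-repo reverse-mode autodiff
core (`algddi.autodiff`) over float64 NumPy arrays with hand-written
vector-Jacobian products; training is full-batch (or seeded-subsample)
Adam throughout, so runs are exactly reproducible for a given seed.

## Synthetic protocol

The generators produce, from one master seed (expanded into independent
streams via `SeedSequence.spawn`: molecules 0, associations 1, knowledge
graph 2, pairs 3):

* **Molecules** — single-bond SMILES over C/N/O/S from chain, branched
  and ring topologies. The element of each atom is a deterministic
  function of local topology (terminal atoms from the neighbour's degree;
  two-connected atoms from the parity of their neighbours' degree sum;
  branching atoms N or C), respecting valence. This makes the masked-atom
  pretext task exactly solvable from context while keeping the four
  element marginals near-balanced (all between ~0.20 and ~0.29), so
  chance-level accuracy is interpretable against 1/4.
* **Associations** — a stochastic block model per relation: drugs carry a
  latent community, entities are split into contiguous blocks, and edges
  appear with probability p_in = 0.3 inside the matched block and
  p_out = 0.02 elsewhere.
* **Knowledge graph** — planted complex embeddings (standard normal real
  and imaginary parts, rank 8). Drug entities mix a community centroid
  with drug-specific noise at equal variance, mirroring how drugs of one
  pharmacological class occupy nearby KG regions. Per relation, all
  ordered entity pairs are scored with the ComplEx form; the top 5% are
  positives and an equal count of sampled non-positives are emitted as
  held-out negatives.
* **Pair labels** — a planted bilinear rule over per-drug latents
  u = [heavy-atom count, heteroatom fraction, community one-hot, first
  two complex KG coordinates (real and imaginary)], each column z-scored.
  P(y=1) = σ(gain · q(u_i' M u_j)) with a seeded random symmetric M.
  Three calibrations keep the rule recoverable at desk scale, chosen
  during generator design and then frozen: (1) the score is
  quantile-normalized (q, a monotone rank-to-Gaussian map) because raw
  bilinear scores are heavy-tailed and would otherwise concentrate most
  labels near the decision boundary for some seeds; (2) M is
  block-diagonal with the KG block's variance share pinned at 0.02 —
  the real-part KG readout is lossy, so a rule leaning heavily on planted
  complex coordinates is unrecoverable by construction; (3) gain = 20
  makes labels nearly deterministic in the latents (the label noise,
  not model capacity, would otherwise bound every downstream check).
  Median-centring puts positives at ~50%. Event mode draws classes from
  softmax(Zipf(1.5) prior + w_c'(u_i + u_j)), giving a long-tailed but
  feature-dependent class distribution. Default 20 sampled pairs per drug
  (capped at the number of distinct pairs).

What the generators do **not** emulate: real chemistry (no aromaticity,
charges, stereochemistry, or realistic functional groups), ontology
semantics, degree heterogeneity of curated KGs, or dosage/severity
structure in DDI labels. Passing tests therefore demonstrate that each
stage recovers the statistical structure it is designed for — not
clinical-grade accuracy on real pharmacological data.

## Problem sizes

The test suite and the acceptance script run the protocol at: 300 drugs,
400 KG entities, 3 relations, 50 entities per association relation,
6000 pairs (end-to-end); 200 entities/rank 8 (KG recovery); 200 molecules
(attribute pretraining); 150 drugs (community probe); and a 5-seed
ablation at 150 drugs/2000 pairs with shortened schedules. These sizes
were chosen so every planted signal is comfortably recoverable on a
single CPU; the model itself has no scale-specific logic.

## Numerical choices and conventions

* float64 everywhere; seeded `numpy.random.Generator` streams; full-batch
  or seeded-subsample optimization — bitwise-reproducible runs.
* Initialisation: embedding tables and weights at scale 1/√fan-in; the
  attribute reconstruction head small random; fusion layer-norm at
  (γ=1, β=0).
* Probability clipping 10⁻⁷ in probability-space losses; softplus-based
  logit-space forms inside training loops.
* Zero denominators in precision/recall report 0 with a warning (keeps
  macro averages defined for rare classes); binary confusion metrics
  threshold at 0.5.
* AUROC is the Mann–Whitney rank statistic with tied scores counted ½;
  AUPR integrates the precision–recall step curve over distinct score
  thresholds (ties grouped). Multi-class AUROC/AUPR are macro one-vs-rest
  over classes present in the labels, matching the macro-P/R/F1 choice.
* Stratified folds deal each class from fold 0; per-class deviation from
  proportionality is ≤ 1 by construction.
* Empty relation neighbourhoods aggregate to zero; unknown drugs get
  documented cold-start embeddings with warnings, never errors.

## Known limitations

* The local encoder's sigmoid-and-sum update bounds each coordinate by
  the relation count and saturates under large inputs; the encoder is
  sensitive to initialisation scale (documented above) and is not suited
  to deep stacking.
* The real-part global readout discards the imaginary half of the learned
  factorization; asymmetric-relation information is only partially
  carried into fusion.
* Pair scoring is transductive: drugs present at training time are
  scored well, but there is no inductive path for entirely unseen drugs
  beyond the cold-start conventions.
* The event head treats classes as unordered; no hierarchy or severity
  structure.
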