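# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Encoders

**Graph side.** Molecules are attributed graphs: integer node attributes
(atom-type index first; extra categorical attributes allowed) and integer
bond attributes, every undirected bond stored as two inverse directed arcs.
The encoder is a GIN with edge features. Node state is initialized as the
sum of per-attribute embedding-table rows; layer *l* computes for node *v*

    h_v ← MLP_l( h_v + Σ_{u∈N(v)} (h_u + e_uv) )

where `e_uv` embeds the bond attributes and the MLP has one hidden layer of
width 2·d with ReLU. The aggregation/update forms are not pinned down by the
encoder's usual citation chain, so this standard edge-featured GIN reading
(messages are neighbor state plus embedded edge attributes; sum
aggregation; no learnable ε) is a documented assumption. The graph
embedding z_G is the **sum** of final node states (mean available via
config). Reference-scale defaults are 5 layers × 300 hidden; tests and
desk-scale experiments use 2 × 16.

*Exact permutation invariance.* Floating-point addition is commutative but
not associative, so a naive scatter-add readout is only invariant to node
relabeling up to round-off. All segment sums (message aggregation and
readout) therefore sort rows value-lexicographically within each segment
before accumulating, making isomorphic graphs produce **bit-identical**
embeddings.

**Image side.** The image encoder is a contract: anything mapping a
C×H×W stack to a fixed-dimension vector. The default is a from-scratch
stack of stride-2 valid 3×3 convolutions (widths 8, 16, 32) with ReLU,
global average pooling, and an affine output. As many conv layers are
instantiated as the configured image size supports (each layer must see at
least a 3-pixel extent), so 8-px test images get two layers and 128-px
images all three. No pretrained weights are used anywhere: heavyweight
backbones can be plugged in behind the same contract, but the package is
self-contained and CPU-sized by design.

**Projections.** One affine head per modality maps embeddings into a shared
space (default 256 at reference scale, 16 in tests) where cosine similarity
(Euclidean available) is computed.

## Objectives

All four losses are pure functions built on the package's reverse-mode
autodiff (float64 throughout), so their analytic gradients are checked
against central finite differences (relative error < 1e-4) in the suite.

**GIC.** Symmetric InfoNCE with temperature τ (default 0.1). The
implemented form scales every similarity by τ and keeps the positive pair
in the softmax normalizer, making the loss nonnegative and exactly log K at
uniform similarity; the variant that drops τ from the denominator and
excludes the matched pair is available as `literal_denominator=True` for
compatibility.

**MGM.** Each node, and each bond (both arcs together), is masked
independently at rate 0.15 (configurable) with a reserved mask token; this
simple Bernoulli attribute masking is the implemented reading of "randomly
masked", and the observed remainder of the graph plays the role of the
context — no explicit k-hop context subgraphs are extracted. The masked
graph is re-encoded; each masked position's final-layer representation
(bond positions use the sum of endpoint states) is concatenated with the
paired image embedding and scored by a one-hidden-layer perceptron per
attribute vocabulary; the loss is the mean categorical cross-entropy over
masked positions.

**GIM.** Match probabilities come from a fusion MLP over the concatenated
projected embeddings with a 2-way softmax. Positives are the K matched
batch pairs; negatives (default P:N = 1:1) alternate between (graph_i,
hard-negative image) and (hard-negative graph, image_i), where the hard
negative for row i is drawn with probability ∝ softmax of that row's
off-diagonal contrastive similarities. Probabilities are clamped at 1e-7
before the logs.

**GM.** Two cross-modal VAEs: q(z_I | z_G) is a diagonal Gaussian whose
mean/log-variance come from an MLP on z_G; a reparameterized sample (one
per step) is decoded back to a reconstruction of z_G, and symmetrically in
the other direction. The loss is the negative ELBO: 0.5·‖ẑ − z‖² (unit
variance Gaussian decoder ⇒ MSE) plus λ_kl times the closed-form KL to a
standard-normal prior, averaged over the two directions. λ_kl defaults to
0.1 (no reference value exists). GM consumes the raw encoder embeddings,
not the projected ones, and only the matched pairs of the batch; the
hard-negative subset feeds GIM alone. A margin parameter γ (default 4) is
accepted in the training config for compatibility but no margin term exists
in any of the four losses, so it is unused.

**Total.** L = Σ w_c L_c with all weights defaulting to 1. A component with
weight 0 is skipped entirely, and every stochastic choice (view sampling,
masking, hard negatives, VAE noise) draws from its own seed-derived stream,
so zeroing one component provably leaves the other components' step-0
values untouched (tested).

## Training

Mini-batch Adam with decoupled weight decay. Reference-scale defaults (lr
3e-4, weight decay 0.02, batch 1024) are kept as `TrainConfig` defaults;
the desk-scale experiments use batch 32 and lr 3e-3 because a ~300-step
schedule barely moves at 3e-4. Each epoch shuffles molecules and samples
one image view per molecule, keeping batches i.i.d. and views balanced.
A non-finite loss aborts with the offending component named. Checkpoints
are NPZ files with every float64 parameter plus a JSON config echo;
save → load → encode is bit-exact. The trainer is a scikit-learn-style
estimator (`GraphImagePretrainer`): constructor parameters, `fit`,
trailing-underscore fitted attributes, `get_params`/`set_params`.

## Retrieval evaluation

Queries are ranked by L2 (or cosine) distance, ties broken by candidate id
so rankings are deterministic. With several ground-truth images per
molecule the best (minimum) rank is scored. Metrics: MRR = mean 1/rank;
Hit@k; and AUC defined as the per-query normalized rank
(pool − rank)/(pool − 1) — the Mann–Whitney probability that the positive
outranks a random negative, the only definition consistent with a ranking
task whose random value is 0.500. AUC averages over queries (molecules),
not views. Negative pools are drawn per query from a seed derived as
(seed, query index), so reports are reproducible and invariant to candidate
order; candidates are canonicalized (molecule id, then embedding content)
before sampling to guarantee that invariance.

The synthetic-data experiments evaluate in the **projected** common space.
The contrastive objective aligns the modalities only after projection; at
desk scale the raw embedding spaces never co-align (retrieval there stays
at chance), so raw-space evaluation — the sensible choice for a fully
trained large model whose embedding spaces are tied by long joint
training — is kept behind a flag (`projected=False`, the default for the
generic `evaluate_pairs`).

Closed forms used as analytic floors, for a pool of size P with one
positive under uniform random ranking: E[MRR] = H_P/P, E[Hit@k] = k/P,
E[AUC] = 1/2; for the zero-shot pool, E[Recall@N] = N/(pool size). Note
that with 1 positive + 100 negatives the pool has 101 items, so the random
Hit@10 is 10/101 = 0.0990, conventionally printed as 0.100.

## Synthetic paired data

The generator emulates the statistical structure of a high-content
screen: many views per molecule, view-level noise, plate/batch intensity
offsets, and a tunable molecule → phenotype signal.

1. **Molecules** are random connected graphs (random tree + ring-closing
   edges) with degree ≤ 4, atom types from a 12-symbol desk vocabulary,
   8–24 atoms.
2. **Phenotype** is a 7-vector of interpretable factors — cell count
   (1–14), five channel intensities (0.3–1.0), blob width ("texture",
   1.2–2.8 px at 32 px) — computed as tanh of a seeded linear map of
   permutation-invariant graph descriptors (atom-type fractions, log atom
   count, bonds per atom, degree histogram), blended with a fixed baseline
   by the signal strength α. Descriptors are standardized against a seeded
   reference sample of molecules before the map; without this, descriptor
   variance (~1/√n per fraction) would collapse all phenotypes onto nearly
   one point and α would carry almost no signal. α = 0 therefore yields
   identical factors for every molecule, and isomorphic graphs always share
   a phenotype.
3. **Rendering** draws Poisson(cell count) Gaussian-blob cells with
   best-effort minimum separation, per-channel intensities and widths from
   the phenotype, pixel noise N(0, σ²) (σ = 0.05) and an additive
   per-(batch, channel) offset (scale 0.1, 3 batches round-robin over
   views).
4. All randomness descends from the single config seed via a
   `SeedSequence` hierarchy (phenotype-map / per-molecule / per-view
   streams), so datasets are byte-reproducible.

What it does **not** emulate: real microscopy texture, segmentation
artifacts, cell-cell interaction, dose, assay chemistry, multiplicative or
spatially structured batch effects. Passing the signal-recovery tests shows
the *pipeline* can align modalities when a recoverable signal exists and
does not hallucinate one when it does not; it says nothing about absolute
performance on real screens.

## Desk-scale experiment sizes

Chosen once as the package's standard CPU protocol: 420 generated
molecules — 300 for training, 120 held-out query molecules with one view
each in the candidate pool so the protocol is exactly 1 positive + 100
sampled negatives — 4 views, 32×32 px, 30 epochs. The ablation
(GIC vs GIC+MGM) runs 5 paired training seeds on one fixed dataset; with
five pairs a one-sided sign test only reaches significance at 5/5, so the
suite asserts the qualitative ordering (mean improvement, majority wins,
reverse direction not significant). The α-monotonicity check compares
held-out Hit@10 across α ∈ {0, 0.5, 0.9}.

## Known limitations

- The image encoder's global average pooling reads intensity-like features
  well but localized morphology only weakly; the synthetic phenotype is
  deliberately intensity-dominated.
- GM's reconstruction target (raw embeddings) and single-sample ELBO are
  assumptions where no reference pins them down; both are config-exposed.
- Cross-validated R² of the generator's linear signal probe treats a
  zero-variance factor as 0, so the no-signal case scores 0 by construction.
- The literal InfoNCE variant can be negative; it exists for comparison,
  not training.
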