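# molimage

Cross-modal contrastive pre-training of **molecular graphs** and
**five-channel cell-painting images**, with retrieval evaluation and a
synthetic paired-data generator — all runnable on one CPU.

## The problem

High-content imaging screens photograph cells after perturbation by a small
molecule, staining five compartments (DNA, ER, RNA, AGP, Mito). The images
encode what the molecule *does*; the molecular graph encodes what it *is*.
Learning a joint embedding space in which a molecule sits next to the images
of the cells it perturbed enables phenotypic retrieval: find the images
matching a query structure, or — given an image produced by a genetic
intervention — rank candidate molecules that produce the same phenotype
(zero-shot functional screening / scaffold hopping).

## The model

A Graph Isomorphism Network (GIN) with edge features encodes the attributed
graph *G* into *z_G* (node states are summed — exactly
permutation-invariant); a convolutional encoder maps the image stack *I* to
*z_I*. Affine heads *f_v*, *f_w* project both into a common space, where
four objectives are minimized jointly:

- **GIC** — symmetric InfoNCE: the matched pair (G_i, I_i) is the positive
  class of a temperature-τ softmax over the batch, averaged over both
  retrieval directions;
- **MGM** — masked graph modeling: atom/bond attributes are masked at rate
  0.15 and predicted from the observed graph context fused with *z_I*
  (categorical cross-entropy);
- **GIM** — graph-image matching: a fusion MLP classifies pairs as
  matched/unmatched with in-batch *hard negatives* sampled in proportion to
  contrastive similarity (binary cross-entropy, P:N = 1:1);
- **GM** — generative matching: two cross-modal variational autoencoders
  reconstruct each modality's embedding from the other's; the loss is the
  negative ELBO (unit-variance Gaussian reconstruction + λ_kl · closed-form
  diagonal-Gaussian KL).

The total loss is the (weighted, default unweighted) sum
L = L_GIC + L_MGM + L_GIM + L_GM. Everything — encoders, heads, Adam — runs
on a small reverse-mode autodiff over numpy float64 arrays, so training is
deterministic to the bit given a seed and analytic gradients are verified
against finite differences in the test suite.

Evaluation ranks candidates by embedding distance and reports **MRR**,
**Hit@k**, **AUC** (mean normalized rank = Mann–Whitney probability) and,
for the zero-shot protocol, **Recall@N**.

Because real screen-scale corpora are huge, the package ships a synthetic
generator that emulates their statistical structure: each random molecule
determines an interpretable phenotype (cell count, channel intensities,
texture) through a seeded linear map blended with a molecule-independent
baseline by a signal strength α; views add placement randomness, pixel
noise and per-batch intensity offsets. α = 0 means images carry no molecule
information, so any retrieval skill above chance would indicate leakage.

## Worked example

```bash
molimage generate --out data --n-molecules 100 --views 4 --alpha 0.9 --seed 1
molimage pretrain --data data --out ck.npz --epochs 10 --seed 0
molimage eval-retrieval --checkpoint ck.npz --data data --neg 50 --seed 0
```

or in Python:

```python
from molimage import SynthConfig, generate_dataset, GraphImagePretrainer

ds = generate_dataset(SynthConfig(n_molecules=100, views_per_molecule=4,
                                  signal_strength=0.9, image_size=24, seed=21))
est = GraphImagePretrainer(epochs=20, learning_rate=3e-3, seed=0,
                           val_fraction=0.0).fit(ds.graphs, ds.images)
report = est.evaluate(ds.graphs, [im for im in ds.images if im.view_id == 0],
                      neg_per_pos=50, seed=0, projected=True)
print(report.to_dict())
```

```
{'n_queries': 100, 'mrr': 0.1580278572190928, 'auc': 0.6738, 'hit@1': 0.05, 'hit@5': 0.23, 'hit@10': 0.4}
```

Each of the 100 molecules queries a pool of one of its own images plus 50
images of other molecules. After just 20 epochs on this small set the
matched image lands in the top 10 of 51 candidates 40% of the time, twice
the random rate of 10/51 ≈ 0.196, and the mean reciprocal rank 0.158 is
well above the random floor H_51/51 ≈ 0.088 — the planted
molecule→phenotype signal is being recovered by the joint embedding.
Longer schedules and more molecules push the margin much higher (see the
signal-recovery numbers written by the acceptance script).

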