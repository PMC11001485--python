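# Methods

## The model

`molemcl` pre-trains a molecular graph encoder with two complementary
self-supervised objectives and then evaluates the learned representation
by scaffold-split fine-tuning and embedding-based retrieval.

A molecule is an attributed graph `G = (V, E)`: nodes carry two
categorical attributes (atom type, i.e. atomic number, and chirality
tag), and each chemical bond is stored as two directed arcs carrying a
bond type (single / double / triple / aromatic) and a bond direction.
Hydrogens are implicit.  The encoder `f(.; θ)` is a message-passing
network; with the default GIN backbone each of the `L` layers computes

    h_v  <-  MLP( h_v + Σ_{u ∈ N(v)} (h_u + e_uv) )

followed by batch normalisation and (except after the last layer) a
ReLU, where `e_uv` is a learned embedding of the arc's bond attributes.
A mean readout over nodes gives the graph embedding `h_G`, and a
two-layer MLP projection head `g` maps `h_G` to the projection `z_G`
used by the contrastive losses.  GCN and GraphSAGE backbones are
provided for the backbone-sensitivity study; all backbones share the
featurisation, readout and head.

### Masking objective (MaskGCL)

For each graph, a fraction `mask_rate` of nodes (at least one) is chosen
uniformly; their attributes are replaced by a dedicated mask token
(chirality zeroed).  Two terms are computed:

* **Reconstruction** `L_Mask`: a single affine head predicts the atom
  type of each masked node from its contextual embedding in the masked
  view; the loss is the mean cross-entropy.  The mask token is excluded
  from the label space.
* **Contrast** `L_CL1`: NT-Xent between the projections of the original
  graphs and of their masked views.  For anchor `i` the positive is its
  own masked view and the negatives are the *partner views of the other
  graphs in the batch*; the positive term is excluded from the
  denominator, so the loss is `mean_i [ log Σ_{j≠i} exp(s_ij/τ) − s_ii/τ ]`
  with `s_ij` the cosine similarity.  It can be negative; with all
  projections identical it equals `ln(B−1)`.

These combine as `L_MaskGCL = α·L_Mask + (1−α)·L_CL1`.

### Perturbation objective (PPGCL)

The second positive view perturbs the *encoder* rather than the input.
The gradient of `L_CL1` with respect to the encoder layer weights is
snapshotted (from the very masked views of the same step, before the
optimiser update), and a perturbed registry is built:

    θ'_l = θ_l + η · ∇_{θ_l} L_CL1

Feature-embedding tables, the projection head and the reconstruction
head are not perturbed; the batch-norm affine parameters of each layer
are, since they are layer weights through which the gradient flows.
The perturbed encoder re-embeds the unchanged graphs (through the
unperturbed projection head), and `L_PPGCL` is the same NT-Xent form
with the perturbed view as partner.  The perturbed branch is a constant
during optimisation: differentiating through `θ'` would require
second-order terms, so gradient flows only through the original branch.
A Gaussian mode (`θ'_l = θ_l + ε`, `ε ~ N(0, σ²)` elementwise)
reproduces the random-perturbation baseline for the ablation study, and
`mode=none` reduces the objective exactly to MaskGCL alone.

The sign of the perturbation is gradient *ascent* on the contrastive
loss, producing a "hard" positive; a negative `η` would give the descent
variant without code changes.

### Joint objective

One optimiser step per batch on `L = L_MaskGCL + L_PPGCL` (ablation arms
drop terms).  The printed per-dataset sums are realised as per-batch
means, so learning-rate semantics do not depend on batch size.

## Numerical core

No deep-learning framework is used: `autodiff.py` is a small
reverse-mode automatic-differentiation engine over float64 NumPy arrays
providing the dozen primitives the encoders need (broadcasting
arithmetic, matmul, gather/scatter for message passing and pooling, a
fused batch-norm, log-softmax, row normalisation).  Every primitive's
backward rule is checked against central finite differences in the test
suite, and the full contrastive-loss gradient is additionally checked by
directional derivatives (step 1e-4, relative tolerance 1e-3 — the
residual is dominated by the O(h²) truncation of the difference
quotient, observed at ~1e-8).  The optimiser is plain Adam
(β₁ 0.9, β₂ 0.999, ε 1e-8, no weight decay, no schedule).

Batch normalisation uses batch statistics in training mode and running
statistics (momentum 0.1) at inference, so `encode()` is independent of
batch composition; batched and per-molecule encoding agree to float
round-off (tolerance 1e-5 in the tests, covering reduction-order
differences).  Gradient snapshots run batch-norm on batch statistics
without touching the running buffers, so snapshotting is pure.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| backbone / layers / width | GIN, 5, 300 | evaluation-protocol encoder |
| readout | mean | permutation-invariant pooling |
| projection head | 300→300→300, ReLU | contrastive space |
| α | 0.5 | midpoint of the search grid {0.3, 0.5, 0.7} |
| η | 2.0 | smallest value of the grid {2, 4, 6, 8, 10} |
| τ | 0.1 | NT-Xent temperature (graph-contrastive convention) |
| mask_rate | 0.15 | attribute-masking convention |
| pre-training | 100 epochs, batch 256, lr 1e-3 | protocol defaults |
| fine-tuning | 100 epochs, batch 32, lr 1e-3, 10 seeds | protocol defaults |
| vocabulary | 118 atom types + mask; 4 chirality; 4 bond types + mask; 3 bond directions | configurable in `FeatureVocab` |

Dropout defaults to 0 in the contrastive branches: a stochastic encoder
would blur what "the same encoder on two views" means.  The
fine-tuning learning rate (unspecified by the protocol) defaults to the
pre-training value; fine-tuning updates the whole encoder plus a fresh
linear head (`head_only=True` freezes the encoder).

## Synthetic data

`generate_fixture_molecules` draws from a deterministic pool of ~350
small organic molecules built from ring cores (benzene, pyridine,
naphthalene, furan, thiophene, pyrrole, indole, piperidine, cyclohexane,
tetrahydrofuran) with common substituents, plus acyclic alkanes, ethers,
amines, alcohols, ketones, nitriles and halides.  Any sample of ≥64
molecules covers eight heavy-atom elements (C, N, O, S, F, Cl, Br, I)
and at least five Bemis–Murcko scaffolds.  The pool emulates the size
range and functional-group diversity of a screening corpus at desk
scale; it does **not** emulate the scale (millions of molecules), the
structural complexity (macrocycles, stereo-rich natural products,
charged species) or the label correlations of real assay data, so
passing tests demonstrate correctness and qualitative behaviour of the
training machinery, not chemistry-scale transfer performance.

`make_synthetic_labels` labels molecules by a SMARTS substructure match,
then flips labels with probability `noise_rate` and masks them to
missing with probability `missing_rate`.  The downstream task used in
the end-to-end checks labels **halogen presence** (`[F,Cl,Br,I]`) with
10% label noise.  A substituent property is deliberately chosen over a
ring property: under scaffold splitting a ring-based label is a property
of the scaffold itself, so the split concentrates positives in the train
partition and leaves the validation partition nearly single-class, and
early stopping then selects noise.  Halogenation is expressed inside
every scaffold group, giving all three partitions both classes — the
structure real scaffold-split benchmarks have.

## Evaluation protocol

The scaffold split is deterministic: molecules are grouped by canonical
Bemis–Murcko scaffold (acyclic molecules share the empty scaffold),
groups are ordered by size descending (ties by scaffold string) and
placed whole — train until it reaches 80% of the data, then validation
until 90%, remainder test.  A group larger than the remaining train
budget still goes entirely to train (logged).  No scaffold ever spans
two partitions.

Fine-tuning trains with sigmoid cross-entropy summed over non-missing
labels only; tasks whose observed test labels are single-class are
excluded from the ROC-AUC mean and reported as NaN.  "Early stopping"
keeps the test score of the epoch with the best validation mean-AUC (no
patience-based halt).  Results aggregate as mean (sd) over seeds.

Retrieval embeds a corpus with the (eval-mode) encoder, ranks by cosine
similarity to a query (ties by corpus index) and annotates each hit with
the Tanimoto similarity of 2048-bit radius-2 Morgan fingerprints.

## Desk-scale problem sizes

The acceptance checks exercise the real pipeline at sizes a laptop CPU
handles: pre-training uses 256 generated molecules for 30 epochs at the
default hyper-parameters (one 256-graph batch per epoch, i.e. 30
optimiser steps); the transfer comparison fine-tunes on 300 molecules
for 15 epochs with 3 seeds per arm.  At these sizes the reconstruction
accuracy reaches roughly the majority-class (carbon) rate while the
reconstruction cross-entropy falls by an order of magnitude — the model
is learning atom-type structure, but 30 updates are far too few for the
heteroatom accuracy a full-scale run attains.  Small-molecule corpora
are inherently carbon-dominated (~0.8 of heavy atoms here), which bounds
how impressive raw masked-atom accuracy can look at any scale.

## Degenerate inputs and tie-breaks

* Cosine similarity of a zero vector is defined as 0 (avoids NaN in the
  NT-Xent denominator; unreachable for trained encoders).
* NT-Xent requires batch size ≥ 2 — with one graph there are no
  negatives; the training loop uses drop-last batching so this holds.
* `mask_rate = 0` masks nothing; `k` clamps to `|V|`; the masked-node
  count is `max(min_masked, floor(rate·|V| + 0.5))`.
* Zero masked nodes make the reconstruction loss 0 with a warning.
* Tanimoto of two empty fingerprints is 1 by convention (logged).
* Unparseable SMILES raise in `smiles_to_graph`; bulk loaders drop and
  count them instead, surfacing the count in logs and metadata.

## Known limitations

* CPU-only and float64: a 2M-molecule pre-training run is supported in
  principle but not practical in this implementation; the design target
  is correctness and auditability at fixture scale.
* Edge-attribute masking exists behind a flag but edge attributes are
  never reconstructed; only node-level reconstruction is part of the
  objective.
* Whether the printed contrastive denominator should also include
  same-view negatives is ambiguous; the partner-view reading is
  implemented as printed, and the symmetric two-sided variant is
  deliberately not offered.
* The perturbation magnitude η and the trade-off α interact with batch
  size through gradient norms; the defaults are grid midpoints/endpoints
  from the evaluation protocol, not re-tuned values.
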