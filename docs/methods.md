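# Methods

## Problem and model

`bchem` predicts disease–drug resistance associations. The data is a
bipartite network: disease and drug nodes, with labeled records saying that
a disease either *resists* a drug (positive class) or is *sensitive* to it
(negative class). Only resistance records become graph edges; sensitivity
records are negative labels, never structure. Negatives are recorded
sensitivity associations by default; an optional sampler can augment them
with unobserved pairs for settings that treat "no association" as absence
of resistance. The prediction task is binary
link classification on (disease, drug) pairs, and, downstream, ranking
candidate diseases for a drug of interest.

The model has three stages.

**1. Initial node attributes.** Three interchangeable backends produce the
per-node feature matrix H⁰:

* `encoder` — externally computed vectors, typically the [CLS]-pooled output
  of a pre-trained text encoder on disease descriptions and of a chemical
  sequence encoder on drug SMILES. The library deliberately does not ship
  model weights: encoders are reached through an adapter contract
  (`encode(texts) -> token vectors + pooled vector`), precomputed matrices
  load from delimited files, and a deterministic hash-seeded mock adapter
  exercises the contract offline.
* `svd` — rows of U·diag(σ) from the truncated SVD of the adjacency matrix
  (topology only). Signs are fixed by forcing each singular vector's
  largest-magnitude entry positive so features are reproducible across
  LAPACK builds. During cross-validation the SVD uses the **training-fold**
  adjacency, never the full graph, to avoid leaking held-out edges into the
  features.
* `random` — seeded i.i.d. standard-normal vectors, the uninformative
  baseline.

When disease and drug vectors differ in dimension, each modality passes
through a seeded Gaussian projection to a common width; the graph model's
own trainable per-modality input maps then continue adapting them.

**2. Graph encoder.** The normalized symmetric Laplacian
L = I − D^{−1/2} A D^{−1/2} (isolated nodes use d^{−1/2} := 0) is shifted to
the Chebyshev-stable interval via 2L/λ_max − I with λ_max taken as its
bound 2 (the raw Laplacian is available via `scale=False`). Each
convolution layer computes Σ_{k=0..K} T_k(L̃) H W_k with the polynomial
recurrence applied to matrix–feature products (T₀H = H, T₁H = L̃H,
T_kH = 2L̃(T_{k−1}H) − T_{k−2}H), so nothing beyond L̃ is ever
materialized. After the convolution stack, a dense multi-head scaled
dot-product attention block — per head, softmax(QKᵀ/√d_k)V over **all**
node pairs, d_k = C/H — is applied with a residual connection.

Defaults: K = 2, two convolution layers, ReLU, H = 2 heads, C = 32. Two
heads and 32 dimensions are the configuration that performed best in the
ablations this architecture family reports; both are plain constructor
arguments.

**3. Training and classification.** The original description of this
architecture does not state a training objective for the graph module, so
the package makes one explicit: end-to-end supervised link prediction.
A bilinear head scores each training pair (z = e_dᵀ B e_r + b), binary
cross-entropy is minimized with Adam (lr 1e−3) for 200 full-batch epochs
over the whole graph. Gradients come from a small in-package reverse-mode
autodiff over numpy arrays (`bchem._autodiff`); full-graph training at a
few thousand nodes needs nothing heavier. Longer budgets were not adopted:
on the planted benchmark, 400–800 epochs visibly overfit (held-out AUC
drops while training loss keeps falling).

Node embeddings then feed an AdaBoost ensemble of depth-1 decision stumps
(50 rounds, learning rate 1.0 — the conventional defaults), after the
training fold's minority class is randomly oversampled to parity.
Oversampling happens strictly inside each training fold.

### Pair descriptors

Three descriptor modes combine a pair's two embeddings:

* `concat` — [e_d ‖ e_r], 2C columns;
* `hadamard` — e_d ∘ e_r, C columns;
* `bilinear` (pipeline default) — (e_d B) ∘ e_r, the per-dimension
  contributions of the trained link head; their sum is exactly the link
  logit.

The pipeline defaults to `bilinear` for a structural reason: depth-1 stumps
are axis-aligned, so a stump ensemble on concatenated embeddings can only
express *additive* per-node effects — it cannot represent "this disease
matched to this drug", which is precisely the signal in interaction-driven
data. On the planted benchmark (whose class marginals are flat by
construction) concatenation caps test AUC near chance, while the product
modes restore the interaction; the bilinear weighting additionally reuses
the metric B the encoder already learned. On datasets with strong per-node
marginals, `concat` remains available and useful.

## Evaluation

Stratified k-fold cross-validation (k = 5 default) over records. Per fold,
the training adjacency contains training resistance edges only; held-out
edges are masked from both the Laplacian and the SVD features. Metrics:
accuracy, precision, recall and F1 at a fixed 0.5 score threshold, plus
ROC AUC (Mann–Whitney convention, ties counted one half) and area under
the precision–recall curve by step integration. Aggregation reports the
arithmetic mean and the **population** standard deviation (ddof = 0) over
folds — the convention that exactly reproduces published per-fold → summary
arithmetic in this line of work (the sample convention does not). Values
are reported rounded to 4 decimals alongside full precision.

Every stochastic stage — fold assignment, parameter initialization,
oversampling, classifier seeding — derives its seed from one master seed
through `numpy.random.SeedSequence`, so a report is reproducible bit for
bit.

## Synthetic benchmark

The generator plants a latent-class model: each disease and drug gets one
of `n_classes` hidden classes; matched-class pairs become resistance
records with probability p_in, unmatched with p_out; sensitivity records
are sampled uniformly from the remaining pairs at `sens_ratio` per
resistance record (0.6, mirroring the ~2:1 imbalance of curated resistance
data). Attributes are β·(class one-hot through a fixed random projection) +
(1−β)·noise, row-standardized; β dials how informative the "encoder"
backend is.

The canonical fixture is 100 diseases × 150 drugs, 4 classes, p_in = 0.30,
p_out = 0.01, β = 0.9, attr_dim = 32, seed = 1 — about 1,300 resistance and
790 sensitivity records, sized so a full 5-fold evaluation takes well under
a minute on one CPU.

What the benchmark does *not* emulate: real attribute semantics (text or
chemistry), degree heterogeneity beyond binomial noise, correlated label
errors, and out-of-class mechanisms of resistance. Passing on it shows the
pipeline recovers planted low-rank block structure from attributes and
topology under class imbalance — not that any particular clinical
performance level would be reached on curated data.

A useful calibration point: on this fixture an oracle that knows every
node's class perfectly (scoring only class match) achieves AUC ≈ 0.86,
because matched non-edges also occur among sensitivity records. Observed
pipeline AUCs around 0.85–0.87 with β = 0.9 therefore sit near the
information ceiling; SVD-topology attributes reach ≈ 0.82 and random
initialization ≈ 0.71, reproducing the expected backend ordering.

## Numerical choices and edge cases

* Laplacian of an empty graph is I (isolated-node convention); asymmetric
  adjacency is an error, not silently symmetrized.
* Zero-denominator metric cases (no predicted positives, etc.) return 0
  with a logged warning rather than NaN.
* Equal scores across all pairs give AUC exactly 0.5 (tie convention).
* Duplicate association rows collapse; the same pair with conflicting
  labels is a hard `ConflictingLabelError` — silent overwrites hide data
  corruption.
* Candidate rankings break score ties alphabetically by disease id so
  output order is deterministic.
* Dense matrices up to 5,000 nodes; sparse storage above.

## Known limitations

* Dense all-pairs attention is O(n²); the intended regime is ≤ a few
  thousand nodes.
* The link-prediction training objective is this package's choice; other
  objectives (contrastive, reconstruction) may behave differently.
* Oversampling duplicates minority pairs; it does not synthesize new ones.
* The mock encoder adapter is a contract test double — its vectors carry no
  semantic signal, and real encoder embeddings must be supplied externally
  for attribute-informed prediction on real data.
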