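# bchem

Bipartite disease–drug **resistance** link prediction.

Clinicians and drug-repurposing researchers want to know, before treatment
or screening, which diseases are likely to *resist* which drugs. Curated
drug-response catalogs record a few thousand experimentally supported
resistance/sensitivity associations between hundreds of diseases and over a
thousand drugs — a sparse bipartite network with roughly two resistance
records per sensitivity record. `bchem` learns from that network plus
per-node molecular attributes (language-model embeddings of disease
descriptions, chemical-encoder embeddings of drug SMILES) and predicts the
response label of unobserved pairs.

## Model

1. **Attributes.** Per-node features H⁰ from one of three backends:
   pooled external-encoder embeddings (loaded from file or via an adapter
   interface with [CLS] pooling), truncated SVD of the network topology
   (U·diag(σ)), or seeded random vectors.
2. **Graph encoder.** Chebyshev spectral graph convolution on the
   normalized symmetric Laplacian L = I − D^{−1/2}AD^{−1/2},

       H^(l+1) = Σ_{k=0..K} T_k(L̃) H^(l) W_k,   T_k(x) = 2x·T_{k−1}(x) − T_{k−2}(x),

   followed by dense multi-head scaled dot-product attention over all node
   pairs (softmax(QKᵀ/√d_k)V per head, d_k = C/H, residual connection).
   Defaults: K = 2, 2 layers, H = 2 heads, C = 32. Trained end-to-end on
   training-fold link labels with a bilinear scoring head (binary
   cross-entropy, Adam, 200 epochs), via a small built-in reverse-mode
   autodiff over numpy.
3. **Classifier.** Pair descriptors from the two embeddings feed an
   AdaBoost ensemble of decision stumps after random oversampling of the
   training fold's minority class. Evaluation is stratified 5-fold
   cross-validation with Acc/Prec/Rec/F1 (0.5 threshold), ROC AUC and AUPR,
   aggregated as mean ± population std.

A planted-block-model generator ships as first-class code: hidden latent
classes drive resistance probabilities (p_in for matched classes, p_out
otherwise) and attribute informativeness is a dial β ∈ [0, 1], so every
stage is testable offline with recoverable ground truth.

## Worked example

```python
from bchem import (AttributeConfig, generate_attributes, generate_network,
                   run_cross_validation)

network, classes = generate_network()          # planted benchmark, seed 1
attrs = generate_attributes(network, classes)  # informative attributes (β=0.9)
order = network.diseases + network.drugs
vectors = {n: attrs.values[i] for i, n in enumerate(order)}

report = run_cross_validation(
    network, AttributeConfig(backend="encoder", node_vectors=vectors),
    k=5, seed=1,
)
print(report.mean_rounded)
```

prints

```
{'Acc': 0.8289, 'Prec': 0.8838, 'Rec': 0.8365, 'F1': 0.8592, 'AUC': 0.8693, 'AUPR': 0.8878}
```

— the pipeline recovers the planted structure well above chance (AUC 0.87
against a class-match information ceiling of ≈ 0.86–0.90 on this fixture);
with topology-only SVD attributes the same run gives AUC ≈ 0.82, and with
random attributes ≈ 0.71, showing what the attribute signal adds. The
`examples/` scripts walk through simulation, cross-validation, the
attribute ablation, candidate ranking and the encoder-adapter contract.

A thin CLI wraps the same calls:

```bash
bchem simulate --out-dir bench
bchem evaluate --associations bench/associations.tsv \
               --attributes encoder --embeddings-file bench/attributes.tsv \
               --seed 1 --out-dir results
bchem rank --associations bench/associations.tsv \
           --attributes encoder --embeddings-file bench/attributes.tsv DRG000
```

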