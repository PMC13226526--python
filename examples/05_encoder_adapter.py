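"""Feed external encoder embeddings through the adapter contract.

Real deployments encode disease descriptions with a biomedical language
model and drug SMILES with a chemical language model, pooling the [CLS]
position of each sequence.  Any object with an ``encode(texts)`` method
returning token vectors plus a pooled vector plugs in; here the
deterministic hash-seeded mock adapter stands in so the demo runs offline.
"""

from bchem import (
    AssociationRecord,
    HashEncoderAdapter,
    Label,
    build_network,
    encode_node_attributes,
    pool_cls_embedding,
)

network = build_network(
    [
        AssociationRecord("gastric cancer", "fluorouracil", Label.RESISTANCE),
        AssociationRecord("breast cancer", "doxorubicin", Label.RESISTANCE),
        AssociationRecord("breast cancer", "fluorouracil", Label.SENSITIVITY),
    ]
)

adapter = HashEncoderAdapter(dim=16, seed=0)
out = adapter.encode(["a malignant tumor of the stomach lining"])[0]
print(f"tokens encoded: {out.token_vectors.shape[0]}, encoder dim: {out.encoder_dim}")
print(f"[CLS] pooled vector (first 4 dims): {pool_cls_embedding(out)[:4].round(3)}")

attrs = encode_node_attributes(
    network,
    disease_texts={d: f"semantic description of {d}" for d in network.diseases},
    drug_smiles={"fluorouracil": "C1=C(C(=O)NC(=O)N1)F", "doxorubicin": "CC1C(C(CC(O1)O)N)O"},
    adapter=adapter,
)
print(f"assembled attribute matrix: {attrs.values.shape} (rows follow node index)")
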