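"""Train on all known associations, then rank resistance candidates.

After fitting the full pipeline, every unobserved (disease, drug) pair can
be scored.  On the planted benchmark the top-ranked diseases for a drug
should share its hidden latent class — printed alongside each score so the
recovery is visible.
"""

from bchem import (
    AttributeConfig,
    fit_pipeline,
    generate_attributes,
    generate_network,
    rank_candidates,
)

network, classes = generate_network()
attrs = generate_attributes(network, classes)
order = network.diseases + network.drugs
vectors = {n: attrs.values[i] for i, n in enumerate(order)}

fitted = fit_pipeline(
    network, AttributeConfig(backend="encoder", node_vectors=vectors), seed=1
)

drug = network.drugs[0]
print(f"drug {drug} (latent class {classes[drug]}) — top 10 predicted resistant diseases:")
for disease, score in rank_candidates(fitted, drug, exclude_known=True)[:10]:
    marker = "match" if classes[disease] == classes[drug] else "     "
    print(f"  {disease}  score={score:.4f}  class={classes[disease]}  {marker}")
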