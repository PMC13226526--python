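"""Generate a planted disease-drug resistance benchmark and inspect it.

Samples a bipartite network in which hidden latent classes drive resistance
(matched disease/drug classes link with probability p_in = 0.30, unmatched
with p_out = 0.01), then writes the fixture bundle to disk.  The printed
counts show the ~2:1 resistance:sensitivity imbalance that curated drug
response data exhibits.
"""

from bchem import PLANTED_BENCHMARK, generate_network, write_fixture_bundle

network, classes = generate_network(PLANTED_BENCHMARK)
labels = network.labels()
print(f"diseases: {network.n_diseases}, drugs: {network.n_drugs}")
print(f"records: {len(network.records)} "
      f"({int(labels.sum())} resistance, {int(len(labels) - labels.sum())} sensitivity)")
print(f"resistance:sensitivity ratio = {labels.sum() / (len(labels) - labels.sum()):.2f}")

paths = write_fixture_bundle(PLANTED_BENCHMARK, "scratch/planted_benchmark")
print("\nfixture bundle written:")
for name, path in paths.items():
    print(f"  {name}: {path}")
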