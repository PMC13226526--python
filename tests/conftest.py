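"""Shared fixtures: the planted benchmark and its cross-validated reports.

Heavy computations (full 5-fold CV per attribute backend, the shuffled-label
null) are session-scoped so the pipeline tests and the end-to-end checks
share one run each.
"""

import numpy as np
import pytest

from bchem import (
    AssociationRecord,
    AttributeConfig,
    Label,
    ModelConfig,
    build_network,
    generate_attributes,
    generate_network,
    run_cross_validation,
)


@pytest.fixture(scope="session")
def planted():
    """The canonical fixed-seed planted benchmark: network, classes, attrs."""
    network, classes = generate_network()
    attrs = generate_attributes(network, classes)
    order = network.diseases + network.drugs
    vectors = {n: attrs.values[i] for i, n in enumerate(order)}
    return {
        "network": network,
        "classes": classes,
        "attrs": attrs,
        "vectors": vectors,
    }


@pytest.fixture(scope="session")
def benchmark_reports(planted):
    """5-fold CV reports on the planted benchmark for all three backends."""
    reports = {}
    for backend in ("encoder", "svd", "random"):
        config = AttributeConfig(
            backend=backend,
            node_vectors=planted["vectors"] if backend == "encoder" else None,
            seed=7,
        )
        reports[backend] = run_cross_validation(
            planted["network"], config, model_config=ModelConfig(), k=5, seed=1
        )
    return reports


@pytest.fixture(scope="session")
def null_report(planted):
    """CV report after shuffling all record labels (no learnable signal)."""
    network = planted["network"]
    rng = np.random.default_rng(1)
    shuffled = rng.permutation(network.labels())
    records = [
        AssociationRecord(
            r.disease_id,
            r.drug_id,
            Label.RESISTANCE if keep else Label.SENSITIVITY,
        )
        for r, keep in zip(network.records, shuffled)
    ]
    null_net = build_network(records)
    vectors = {
        n: planted["vectors"][n] for n in null_net.diseases + null_net.drugs
    }
    return run_cross_validation(
        null_net,
        AttributeConfig(backend="encoder", node_vectors=vectors),
        model_config=ModelConfig(),
        k=5,
        seed=1,
    )


@pytest.fixture()
def toy_network():
    """2 diseases x 2 drugs with one resistance edge (d0, r0)."""
    return build_network(
        [
            AssociationRecord("d0", "r0", Label.RESISTANCE),
            AssociationRecord("d0", "r1", Label.SENSITIVITY),
            AssociationRecord("d1", "r0", Label.SENSITIVITY),
            AssociationRecord("d1", "r1", Label.SENSITIVITY),
        ]
    )
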