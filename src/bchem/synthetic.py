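"""Planted-block-model generator for offline benchmarking.

Real disease-drug resistance data is a sparse bipartite network with roughly
two resistance records per sensitivity record.  The generator emulates that
shape with a planted latent-class model: every disease and drug carries a
hidden class; matched-class pairs gain a resistance edge with probability
``p_in``, unmatched with ``p_out`` (p_out << p_in), and sensitivity records
are sampled uniformly from the remaining pairs to hit the configured class
imbalance.  Node attributes mix a class-indicator signal with Gaussian noise
under a weight ``attr_informativeness``, giving a dial from pure noise
(beta = 0) to clean class indicators (beta = 1) — the axis along which the
encoder / SVD / random attribute backends separate.

The fixed default spec is the repository's canonical "planted benchmark":
100 diseases x 150 drugs, 4 classes, p_in = 0.30, p_out = 0.01, ~2:1
resistance:sensitivity, attr_dim = 32, beta = 0.9, seed = 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .attributes import AttributeMatrix, save_embedding_file
from .data import AssociationRecord, DDRNetwork, Label, build_network, save_associations


@dataclass
class PlantedModelSpec:
    """Parameters of the planted latent-class bipartite model.

    ``sens_ratio`` is the target number of sensitivity records per resistance
    record (0.6 mirrors the ~2:1 imbalance of curated resistance data).
    """

    n_diseases: int = 100
    n_drugs: int = 150
    n_classes: int = 4
    p_in: float = 0.30
    p_out: float = 0.01
    sens_ratio: float = 0.6
    attr_dim: int = 32
    attr_informativeness: float = 0.9
    seed: int = 1

    def validate(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError(f"need 0 <= p_out < p_in <= 1, got ({self.p_out}, {self.p_in})")
        if not (0.0 <= self.attr_informativeness <= 1.0):
            raise ValueError("attr_informativeness must be in [0, 1]")
        if min(self.n_diseases, self.n_drugs) < self.n_classes:
            raise ValueError("need at least n_classes nodes on each side")
        if self.sens_ratio < 0:
            raise ValueError("sens_ratio must be nonnegative")


#: the canonical fixed-seed test fixture
PLANTED_BENCHMARK = PlantedModelSpec()


def _node_ids(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_network(
    spec: PlantedModelSpec | None = None,
) -> tuple[DDRNetwork, dict[str, int]]:
    """Sample a labeled bipartite network with planted latent classes.

    Returns the network plus the ground-truth ``{node_id: class}`` map.
    Matched-class (disease, drug) pairs become resistance records with
    probability ``p_in``, unmatched with ``p_out``; sensitivity records are
    then drawn uniformly from the non-resistant pairs.  Deterministic given
    ``spec.seed``.
    """
    spec = spec or PLANTED_BENCHMARK
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    d_ids = _node_ids("DIS", spec.n_diseases)
    r_ids = _node_ids("DRG", spec.n_drugs)
    d_cls = rng.integers(0, spec.n_classes, size=spec.n_diseases)
    r_cls = rng.integers(0, spec.n_classes, size=spec.n_drugs)

    match = d_cls[:, None] == r_cls[None, :]
    prob = np.where(match, spec.p_in, spec.p_out)
    resist = rng.random(prob.shape) < prob

    records = [
        AssociationRecord(d_ids[i], r_ids[j], Label.RESISTANCE)
        for i, j in zip(*np.nonzero(resist))
    ]
    n_res = len(records)
    free_i, free_j = np.nonzero(~resist)
    n_sens = min(int(round(spec.sens_ratio * n_res)), len(free_i))
    pick = rng.choice(len(free_i), size=n_sens, replace=False)
    records += [
        AssociationRecord(d_ids[free_i[p]], r_ids[free_j[p]], Label.SENSITIVITY)
        for p in pick
    ]
    network = build_network(records)
    classes = {**dict(zip(d_ids, d_cls.tolist())), **dict(zip(r_ids, r_cls.tolist()))}
    return network, classes


def generate_attributes(
    network: DDRNetwork,
    classes: dict[str, int],
    spec: PlantedModelSpec | None = None,
) -> AttributeMatrix:
    """Class-informed node attributes with tunable informativeness.

    Each row is ``beta * (one-hot class through a fixed seeded projection)
    + (1 - beta) * N(0, I)``, then row-standardized (zero mean, unit std per
    row).  At beta = 1 same-class rows are identical before standardization;
    at beta = 0 attributes carry no class signal.
    """
    spec = spec or PLANTED_BENCHMARK
    spec.validate()
    if spec.attr_dim < spec.n_classes:
        raise ValueError(
            f"attr_dim ({spec.attr_dim}) must be >= n_classes ({spec.n_classes})"
        )
    rng = np.random.default_rng(spec.seed + 101)
    beta = spec.attr_informativeness
    proj = rng.standard_normal((spec.n_classes, spec.attr_dim))
    node_order = network.diseases + network.drugs
    cls = np.array([classes[n] for n in node_order])
    signal = proj[cls]
    noise = rng.standard_normal((len(node_order), spec.attr_dim))
    X = beta * signal + (1.0 - beta) * noise
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    X = X / np.where(sd > 0, sd, 1.0)
    return AttributeMatrix(values=X, backend="encoder")


def write_fixture_bundle(spec: PlantedModelSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the association table, attributes, classes and spec to disk.

    The bundle round-trips through :func:`bchem.data.load_associations` and
    :func:`bchem.attributes.load_embedding_file`; file bytes are
    deterministic given the spec's seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network, classes = generate_network(spec)
    attrs = generate_attributes(network, classes, spec)

    paths = {
        "associations": out_dir / "associations.tsv",
        "attributes": out_dir / "attributes.tsv",
        "classes": out_dir / "classes.tsv",
        "spec": out_dir / "spec.json",
    }
    save_associations(network, paths["associations"])
    node_order = network.diseases + network.drugs
    save_embedding_file(
        {n: attrs.values[i] for i, n in enumerate(node_order)}, paths["attributes"]
    )
    with open(paths["classes"], "w") as fh:
        fh.write("node_id\tclass\n")
        for n in node_order:
            fh.write(f"{n}\t{classes[n]}\n")
    with open(paths["spec"], "w") as fh:
        json.dump(asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
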