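"""Cross-validated resistance prediction: balancing, boosting, metrics, ranking.

Given node embeddings from the graph encoder, each (disease, drug) pair gets
a descriptor (concatenated embeddings by default), the minority class of the
training fold is randomly oversampled to parity, and an AdaBoost ensemble of
decision stumps learns the binary resistance/sensitivity task.  Evaluation is
stratified k-fold cross-validation with Acc/Prec/Rec/F1 at a 0.5 threshold
plus AUC and AUPR, aggregated as mean and population standard deviation.

Anti-leakage discipline: for every fold the graph adjacency fed to the
encoder and the classifier's training set are built strictly from training
records; held-out pairs never contribute edges or labels to fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.tree import DecisionTreeClassifier

from .attributes import (
    AttributeMatrix,
    random_features,
    svd_topology_features,
)
from .data import (
    AdjacencyMatrix,
    AssociationRecord,
    CVFoldPlan,
    DDRNetwork,
    Label,
    build_adjacency,
    make_cv_folds,
)
from .errors import SingleClassError, UnknownNodeError
from .gnn import (
    ChebAttnModel,
    ModelConfig,
    init_model,
    model_forward,
    normalized_laplacian,
    train_model,
)

logger = logging.getLogger(__name__)

METRIC_KEYS = ("Acc", "Prec", "Rec", "F1", "AUC", "AUPR")


@dataclass
class PairDataset:
    """(disease position, drug position) pairs with labels and descriptors."""

    pairs: np.ndarray  # (n, 2) int
    labels: np.ndarray  # (n,) in {0, 1}; 1 = resistance
    descriptors: np.ndarray | None = None
    fold_tag: str = "train"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        if self.descriptors is not None and len(self.descriptors) != len(self.pairs):
            raise ValueError("descriptor rows must align with pairs")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Per-fold and aggregated CV metrics with serialized curves."""

    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    std: dict[str, float]
    mean_rounded: dict[str, float] = field(default_factory=dict)
    std_rounded: dict[str, float] = field(default_factory=dict)
    curves: list[dict] = field(default_factory=list)
    predictions: list[dict] = field(default_factory=list)


@dataclass
class AttributeConfig:
    """Which attribute backend feeds the encoder, and at what dimension.

    ``encoder`` uses externally supplied per-node vectors (pooled encoder
    embeddings or any precomputed matrix); ``svd`` factorizes the
    training-fold adjacency; ``random`` draws seeded Gaussian features.
    """

    backend: str = "encoder"
    dim: int = 32
    node_vectors: dict[str, np.ndarray] | None = None
    seed: int = 0

    def build(
        self, network: DDRNetwork, train_adjacency: AdjacencyMatrix
    ) -> AttributeMatrix:
        if self.backend == "encoder":
            if self.node_vectors is None:
                raise ValueError("encoder backend requires node_vectors")
            order = network.diseases + network.drugs
            missing = [n for n in order if n not in self.node_vectors]
            if missing:
                raise UnknownNodeError(f"missing embeddings for nodes: {missing[:5]}")
            X = np.stack([np.asarray(self.node_vectors[n], float) for n in order])
            return AttributeMatrix(values=X, backend="encoder")
        if self.backend == "svd":
            return svd_topology_features(train_adjacency, self.dim)
        if self.backend == "random":
            return random_features(network.n_nodes, self.dim, self.seed)
        raise ValueError(f"unknown attribute backend: {self.backend!r}")


def network_pairs(network: DDRNetwork, record_indices=None) -> PairDataset:
    """Record subset as (disease position, drug position) pairs + labels."""
    recs = network.records
    idx = range(len(recs)) if record_indices is None else record_indices
    d_pos = {d: i for i, d in enumerate(network.diseases)}
    r_pos = {r: i for i, r in enumerate(network.drugs)}
    pairs = np.array(
        [[d_pos[recs[i].disease_id], r_pos[recs[i].drug_id]] for i in idx], int
    ).reshape(-1, 2)
    labels = np.array(
        [1 if recs[i].label is Label.RESISTANCE else 0 for i in idx], int
    )
    return PairDataset(pairs=pairs, labels=labels)


def sample_unobserved_negatives(
    network: DDRNetwork, n_samples: int, seed: int
) -> PairDataset:
    """Sample unobserved (disease, drug) pairs as extra negative examples.

    By default only recorded sensitivity associations serve as negatives;
    this optional augmentation draws pairs with no record of either kind and
    labels them 0, for settings where "no association" is treated as absence
    of resistance.
    """
    observed = {
        (network.diseases.index(r.disease_id), network.drugs.index(r.drug_id))
        for r in network.records
    }
    free = [
        (i, j)
        for i in range(network.n_diseases)
        for j in range(network.n_drugs)
        if (i, j) not in observed
    ]
    if n_samples > len(free):
        raise ValueError(
            f"requested {n_samples} unobserved pairs but only {len(free)} exist"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(free), size=n_samples, replace=False)
    pairs = np.array([free[p] for p in pick], dtype=int).reshape(-1, 2)
    return PairDataset(pairs=pairs, labels=np.zeros(n_samples, dtype=int))


def oversample_minority(train: PairDataset, seed: int) -> PairDataset:
    """Duplicate minority-class pairs at random until the classes balance.

    All original pairs are retained; only training-tagged datasets may be
    balanced (balancing a test fold would corrupt evaluation).
    """
    if train.fold_tag != "train":
        raise ValueError("oversampling is only valid on a training dataset")
    y = train.labels
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("training set must contain both classes")
    if n_pos == n_neg:
        return train
    minority = 1 if n_pos < n_neg else 0
    deficit = abs(n_pos - n_neg)
    pool = np.flatnonzero(y == minority)
    rng = np.random.default_rng(seed)
    extra = rng.choice(pool, size=deficit, replace=True)
    order = np.concatenate([np.arange(len(y)), extra])
    return PairDataset(
        pairs=train.pairs[order],
        labels=y[order],
        descriptors=None if train.descriptors is None else train.descriptors[order],
        fold_tag="train",
    )


def pair_descriptors(
    embeddings: np.ndarray,
    pairs: np.ndarray,
    n_diseases: int,
    mode: str = "concat",
    bilinear: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pair descriptors from node embeddings.

    ``concat`` (default) gives [disease embedding || drug embedding], i.e.
    2C columns; ``hadamard`` gives the elementwise product (C columns);
    ``bilinear`` gives (e_d B) * e_r, the per-dimension contributions of the
    trained bilinear link head (its row sum is exactly the link logit), and
    requires the head's ``bilinear`` matrix.

    Concatenation only exposes per-node effects to an additive classifier,
    so interaction-driven tasks (is this disease matched to this drug?) need
    one of the product modes.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    n_drugs = embeddings.shape[0] - n_diseases
    if len(pairs) and (
        pairs[:, 0].min() < 0
        or pairs[:, 0].max() >= n_diseases
        or pairs[:, 1].min() < 0
        or pairs[:, 1].max() >= n_drugs
    ):
        raise IndexError("pair index out of range")
    Ed = embeddings[pairs[:, 0]]
    Er = embeddings[n_diseases + pairs[:, 1]]
    if mode == "concat":
        return np.hstack([Ed, Er])
    if mode == "hadamard":
        return Ed * Er
    if mode == "bilinear":
        if bilinear is None:
            raise ValueError("bilinear descriptor mode needs the link-head matrix")
        return (Ed @ bilinear) * Er
    raise ValueError(f"unknown descriptor mode: {mode!r}")


def fit_classifier(
    train: PairDataset,
    n_estimators: int = 50,
    learning_rate: float = 1.0,
    seed: int = 0,
) -> AdaBoostClassifier:
    """AdaBoost over depth-1 decision stumps on the pair descriptors.

    Returns the fitted ensemble; ``predict_proba(...)[:, 1]`` is the
    resistance score in [0, 1].  Deterministic given ``seed``.
    """
    if train.descriptors is None:
        raise ValueError("training dataset has no descriptors")
    if len(np.unique(train.labels)) < 2:
        raise SingleClassError("classifier training requires both classes")
    clf = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1),
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        random_state=seed,
    )
    clf.fit(train.descriptors, train.labels)
    return clf


def compute_confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Zero-denominator cases (no predicted positives, no true positives, or a
    zero precision+recall sum) return 0 for the affected metric with a
    logged warning.
    """
    if counts.total <= 0:
        raise ValueError("confusion counts sum to zero")

    def _ratio(num, den, name):
        if den == 0:
            logger.warning("%s denominator is zero; reporting 0", name)
            return 0.0
        return num / den

    acc = (counts.TP + counts.TN) / counts.total
    prec = _ratio(counts.TP, counts.TP + counts.FP, "precision")
    rec = _ratio(counts.TP, counts.TP + counts.FN, "recall")
    f1 = _ratio(2 * prec * rec, prec + rec, "F1")
    return {"Acc": acc, "Prec": prec, "Rec": rec, "F1": f1}


def confusion_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    pred = (np.asarray(scores) >= threshold).astype(int)
    y = np.asarray(labels, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )


def compute_curve_metrics(scores: np.ndarray, labels: np.ndarray) -> dict:
    """AUC (Mann-Whitney, ties counted half) and AUPR with curve points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise SingleClassError("curve metrics require both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return {
        "AUC": float(roc_auc_score(labels, scores)),
        "AUPR": float(average_precision_score(labels, scores)),
        "roc_points": np.column_stack([fpr, tpr]),
        "pr_points": np.column_stack([rec, prec]),
    }


def aggregate_cv_report(per_fold: list[dict[str, float]]) -> MetricsReport:
    """Aggregate per-fold metrics into mean and population std (ddof = 0).

    Rounded-to-4-decimals values are reported alongside full precision.
    """
    if len(per_fold) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    keys = list(per_fold[0].keys())
    for fold in per_fold[1:]:
        if list(fold.keys()) != keys:
            raise ValueError("inconsistent metric keys across folds")
    mean = {k: float(np.mean([f[k] for f in per_fold])) for k in keys}
    std = {k: float(np.std([f[k] for f in per_fold], ddof=0)) for k in keys}
    return MetricsReport(
        per_fold=per_fold,
        mean=mean,
        std=std,
        mean_rounded={k: round(v, 4) for k, v in mean.items()},
        std_rounded={k: round(v, 4) for k, v in std.items()},
    )


def _fold_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _run_single_fold(
    network: DDRNetwork,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    attributes_config: AttributeConfig,
    model_config: ModelConfig,
    seed: int,
    descriptor_mode: str = "bilinear",
) -> tuple[dict[str, float], dict, np.ndarray]:
    train_records = [network.records[i] for i in train_idx]
    A_train = build_adjacency(network, include_records=train_records)
    L = normalized_laplacian(A_train, scale=model_config.scaled_laplacian)
    attrs = attributes_config.build(network, A_train)

    train_ds = network_pairs(network, train_idx)
    test_ds = network_pairs(network, test_idx)
    test_ds.fold_tag = "test"

    model = init_model(attrs.attr_dim, network.n_diseases, model_config, seed=seed)
    train_model(model, attrs, L, train_ds.pairs, train_ds.labels, seed=seed)
    emb = model_forward(model, attrs, L)

    train_ds.descriptors = pair_descriptors(
        emb, train_ds.pairs, network.n_diseases, mode=descriptor_mode,
        bilinear=model.link_bilinear,
    )
    balanced = oversample_minority(train_ds, seed=seed)
    clf = fit_classifier(balanced, seed=seed)

    test_ds.descriptors = pair_descriptors(
        emb, test_ds.pairs, network.n_diseases, mode=descriptor_mode,
        bilinear=model.link_bilinear,
    )
    scores = clf.predict_proba(test_ds.descriptors)[:, 1]
    metrics = compute_confusion_metrics(confusion_from_scores(scores, test_ds.labels))
    curves = compute_curve_metrics(scores, test_ds.labels)
    metrics["AUC"] = curves["AUC"]
    metrics["AUPR"] = curves["AUPR"]
    return metrics, curves, scores


def run_cross_validation(
    network: DDRNetwork,
    attributes_config: AttributeConfig,
    model_config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
    descriptor_mode: str = "bilinear",
    fold_plan: CVFoldPlan | None = None,
) -> MetricsReport:
    """Full stratified k-fold evaluation of the prediction pipeline.

    Per fold: training-fold resistance edges build the adjacency (held-out
    edges are masked), attributes are derived, the graph encoder trains on
    training-fold link labels, pair descriptors feed the balanced AdaBoost
    classifier, and the held-out fold is scored.  Every stochastic stage is
    seeded from the master seed, so the whole report is reproducible.
    """
    model_config = model_config or ModelConfig()
    plan = fold_plan or make_cv_folds(network, k=k, seed=seed)
    seeds = _fold_seeds(seed, plan.k)
    per_fold, all_curves, predictions = [], [], []
    for fold in range(plan.k):
        train_idx, test_idx = plan.train_test_indices(fold)
        try:
            metrics, curves, scores = _run_single_fold(
                network, train_idx, test_idx, attributes_config,
                model_config, seeds[fold], descriptor_mode,
            )
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        per_fold.append(metrics)
        all_curves.append({"fold": fold, **{k_: curves[k_] for k_ in ("roc_points", "pr_points")}})
        for i, s in zip(test_idx, scores):
            rec = network.records[i]
            predictions.append(
                {
                    "disease_id": rec.disease_id,
                    "drug_id": rec.drug_id,
                    "label": 1 if rec.label is Label.RESISTANCE else 0,
                    "score": float(s),
                    "fold": fold,
                }
            )
        logger.info("fold %d: %s", fold, {k_: round(v, 4) for k_, v in metrics.items()})
    report = aggregate_cv_report(per_fold)
    report.curves = all_curves
    report.predictions = predictions
    return report


@dataclass
class FittedPipeline:
    """End state of training on the full record set, ready for ranking."""

    network: DDRNetwork
    model: ChebAttnModel
    embeddings: np.ndarray
    classifier: AdaBoostClassifier
    descriptor_mode: str = "bilinear"


def fit_pipeline(
    network: DDRNetwork,
    attributes_config: AttributeConfig,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    descriptor_mode: str = "bilinear",
) -> FittedPipeline:
    """Train encoder + classifier on all records (for candidate ranking)."""
    model_config = model_config or ModelConfig()
    A = build_adjacency(network)
    L = normalized_laplacian(A, scale=model_config.scaled_laplacian)
    attrs = attributes_config.build(network, A)
    ds = network_pairs(network)
    model = init_model(attrs.attr_dim, network.n_diseases, model_config, seed=seed)
    train_model(model, attrs, L, ds.pairs, ds.labels, seed=seed)
    emb = model_forward(model, attrs, L)
    ds.descriptors = pair_descriptors(
        emb, ds.pairs, network.n_diseases, mode=descriptor_mode,
        bilinear=model.link_bilinear,
    )
    balanced = oversample_minority(ds, seed=seed)
    clf = fit_classifier(balanced, seed=seed)
    return FittedPipeline(
        network=network, model=model, embeddings=emb,
        classifier=clf, descriptor_mode=descriptor_mode,
    )


def rank_candidates(
    fitted: FittedPipeline, drug_id: str, exclude_known: bool = True
) -> list[tuple[str, float]]:
    """Rank all diseases by predicted resistance likelihood for one drug.

    Scores every (disease, drug) pair with the fitted classifier and sorts
    descending; ties break alphabetically by disease id.  With
    ``exclude_known`` the drug's training resistance partners are dropped.
    """
    net = fitted.network
    if ("drug", drug_id) not in net.node_index:
        raise UnknownNodeError(f"unknown drug id: {drug_id!r}")
    r_pos = net.drugs.index(drug_id)
    known = {
        rec.disease_id
        for rec in net.records
        if rec.drug_id == drug_id and rec.label is Label.RESISTANCE
    }
    diseases = [
        d for d in net.diseases if not (exclude_known and d in known)
    ]
    if not diseases:
        return []
    pairs = np.array(
        [[net.diseases.index(d), r_pos] for d in diseases], dtype=int
    )
    desc = pair_descriptors(
        fitted.embeddings, pairs, net.n_diseases, mode=fitted.descriptor_mode,
        bilinear=fitted.model.link_bilinear,
    )
    scores = fitted.classifier.predict_proba(desc)[:, 1]
    ranked = sorted(zip(diseases, scores), key=lambda t: (-t[1], t[0]))
    return [(d, float(s)) for d, s in ranked]
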