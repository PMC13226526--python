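"""Disease-drug resistance network (DDRN) construction and cross-validation planning.

The ground-truth data is a table of experimentally supported disease-drug
response records.  A record's label is either ``resistance`` (the positive
class: the disease shows decreased responsiveness to the drug) or
``sensitivity`` (the negative class).  Only resistance records become edges of
the bipartite graph; sensitivity records supply negative training labels but
never graph structure.

Node indexing convention: all diseases precede all drugs, each block sorted
alphabetically by id, giving a reproducible contiguous 0-based index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold

from .errors import (
    ConflictingLabelError,
    EmptyAssociationFileError,
    FoldCountError,
    UnknownLabelError,
    UnknownNodeError,
)

logger = logging.getLogger(__name__)

#: above this node count adjacency matrices are stored sparse
DENSE_NODE_LIMIT = 5000

REQUIRED_COLUMNS = ("disease_id", "drug_id", "label")
OPTIONAL_COLUMNS = ("smiles", "evidence")


class Label(str, Enum):
    """Binary drug-response label; resistance is the positive class."""

    RESISTANCE = "resistance"
    SENSITIVITY = "sensitivity"


@dataclass(frozen=True)
class AssociationRecord:
    """One curated disease-drug response observation."""

    disease_id: str
    drug_id: str
    label: Label
    smiles: str | None = None
    evidence: str | None = None


@dataclass
class DDRNetwork:
    """Indexed bipartite disease-drug network with labeled associations.

    ``node_index`` maps ``("disease", id)`` / ``("drug", id)`` to a contiguous
    integer with all diseases indexed before all drugs.
    """

    diseases: list[str]
    drugs: list[str]
    records: list[AssociationRecord]
    node_index: dict[tuple[str, str], int] = field(init=False)

    def __post_init__(self) -> None:
        self.node_index = {("disease", d): i for i, d in enumerate(self.diseases)}
        nd = len(self.diseases)
        self.node_index.update(
            {("drug", r): nd + j for j, r in enumerate(self.drugs)}
        )

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_nodes(self) -> int:
        return len(self.diseases) + len(self.drugs)

    def record_node_indices(self, record: AssociationRecord) -> tuple[int, int]:
        """Return (disease node index, drug node index) for a record."""
        try:
            i = self.node_index[("disease", record.disease_id)]
            j = self.node_index[("drug", record.drug_id)]
        except KeyError as exc:  # pragma: no cover - guarded by construction
            raise UnknownNodeError(f"record references unregistered node: {exc}")
        return i, j

    def labels(self) -> np.ndarray:
        """Binary label vector over records (1 = resistance)."""
        return np.array(
            [1 if r.label is Label.RESISTANCE else 0 for r in self.records],
            dtype=int,
        )


@dataclass
class AdjacencyMatrix:
    """Symmetric bipartite adjacency over the full node set.

    Edges come from resistance records only (``edge_source='resistance_only'``);
    sensitivity records are negative labels, not graph structure.
    """

    values: np.ndarray | sp.spmatrix
    edge_source: str = "resistance_only"

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class CVFoldPlan:
    """Stratified fold assignment: one fold index in 0..k-1 per record."""

    k: int
    assignments: np.ndarray
    seed: int

    def train_test_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def _normalize_label(token: str) -> Label:
    t = str(token).strip().lower()
    try:
        return Label(t)
    except ValueError:
        raise UnknownLabelError(f"unknown label token: {token!r}")


def build_network(records: Iterable[AssociationRecord]) -> DDRNetwork:
    """Index a deduplicated record list into a DDRNetwork.

    Exact duplicate (disease, drug) rows with identical labels collapse to
    one; the same pair with conflicting labels raises ConflictingLabelError.
    """
    seen: dict[tuple[str, str], AssociationRecord] = {}
    for rec in records:
        key = (rec.disease_id, rec.drug_id)
        if key in seen:
            if seen[key].label is not rec.label:
                raise ConflictingLabelError(
                    f"pair ({rec.disease_id}, {rec.drug_id}) carries both "
                    f"'{seen[key].label.value}' and '{rec.label.value}'"
                )
            continue
        seen[key] = rec
    deduped = list(seen.values())
    diseases = sorted({r.disease_id for r in deduped})
    drugs = sorted({r.drug_id for r in deduped})
    return DDRNetwork(diseases=diseases, drugs=drugs, records=deduped)


def load_associations(path: str | Path, sep: str | None = None) -> DDRNetwork:
    """Read a delimited association table and build an indexed network.

    The header must declare ``disease_id``, ``drug_id`` and ``label``
    columns; ``smiles`` and ``evidence`` are optional.  TSV is the default
    dialect, comma-delimited files are accepted (``sep=None`` sniffs the
    delimiter from the header line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "," if ("," in header and "\t" not in header) else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyAssociationFileError(f"{path} is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association table missing required columns: {missing}")
    if len(df) == 0:
        raise EmptyAssociationFileError(f"{path} declares a header but no records")

    records = [
        AssociationRecord(
            disease_id=row["disease_id"],
            drug_id=row["drug_id"],
            label=_normalize_label(row["label"]),
            smiles=row.get("smiles") or None,
            evidence=row.get("evidence") or None,
        )
        for row in df.to_dict(orient="records")
    ]
    net = build_network(records)
    y = net.labels()
    logger.info(
        "loaded %d diseases, %d drugs, %d records (%d resistance, %d sensitivity)",
        net.n_diseases, net.n_drugs, len(net.records), int(y.sum()), int((1 - y).sum()),
    )
    return net


def save_associations(network: DDRNetwork, path: str | Path, sep: str = "\t") -> None:
    """Write the network back to the delimited association format."""
    rows = [
        {
            "disease_id": r.disease_id,
            "drug_id": r.drug_id,
            "label": r.label.value,
            "smiles": r.smiles or "",
            "evidence": r.evidence or "",
        }
        for r in network.records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def build_adjacency(
    network: DDRNetwork,
    include_records: Sequence[AssociationRecord] | None = None,
) -> AdjacencyMatrix:
    """Build the symmetric bipartite adjacency from resistance records.

    Parameters
    ----------
    include_records
        Subset of ``network.records`` to draw edges from (e.g. the training
        folds during cross-validation).  Defaults to all records.
        Sensitivity records never create edges.
    """
    if include_records is None:
        include_records = network.records
    n = network.n_nodes
    rows, cols = [], []
    for rec in include_records:
        if ("disease", rec.disease_id) not in network.node_index or (
            "drug", rec.drug_id
        ) not in network.node_index:
            raise UnknownNodeError(
                f"record ({rec.disease_id}, {rec.drug_id}) references an unindexed node"
            )
        if rec.label is Label.RESISTANCE:
            i, j = network.record_node_indices(rec)
            rows += [i, j]
            cols += [j, i]
    data = np.ones(len(rows), dtype=float)
    mat = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    # duplicates cannot occur post-dedup, but tocsr sums defensively
    mat.data[:] = np.minimum(mat.data, 1.0)
    if n <= DENSE_NODE_LIMIT:
        return AdjacencyMatrix(values=np.asarray(mat.todense(), dtype=float))
    return AdjacencyMatrix(values=mat)


def make_cv_folds(network: DDRNetwork, k: int, seed: int) -> CVFoldPlan:
    """Plan a label-stratified k-fold partition of the records.

    Fold sizes differ by at most one record and per-fold class ratios track
    the global ~2:1 resistance:sensitivity imbalance.  Deterministic given
    ``seed``.
    """
    if k < 2:
        raise FoldCountError(f"k must be >= 2, got {k}")
    y = network.labels()
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if k > min(n_pos, n_neg):
        raise FoldCountError(
            f"k={k} exceeds the smaller class count ({min(n_pos, n_neg)})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignments[test_idx] = fold
    return CVFoldPlan(k=k, assignments=assignments, seed=seed)


def save_fold_plan(plan: CVFoldPlan, path: str | Path, sep: str = "\t") -> None:
    """Export the fold plan as ``record_index<sep>fold`` delimited text."""
    pd.DataFrame(
        {"record_index": np.arange(len(plan.assignments)), "fold": plan.assignments}
    ).to_csv(path, sep=sep, index=False)
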