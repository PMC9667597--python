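"""Cross-validation schemes for the three prediction settings, and metrics.

Three evaluation settings of increasing difficulty are standard for
multi-type DDI prediction:

* **Task 1** — unobserved interaction types between *known* drugs: 5-fold CV
  over the DDI records themselves (both drugs of a test pair may appear in
  training pairs).
* **Task 2** — interactions between known drugs and *new* drugs: 5-fold CV
  over drugs; a fold trains on pairs of training drugs and tests on pairs
  with exactly one held-out drug.
* **Task 3** — interactions between two new drugs: same drug folds, but test
  pairs have both drugs held out.

Metrics follow the field's convention for these benchmarks: accuracy from
the argmax, macro-averaged F1/precision/recall over classes present in the
test labels, and micro-averaged (one-vs-rest pooled) AUPR and AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

__all__ = [
    "DDIDataset",
    "Fold",
    "SplitPlan",
    "MetricReport",
    "split_task1",
    "split_task2",
    "split_task3",
    "split_for_task",
    "compute_metrics",
    "N_FOLDS",
]

N_FOLDS = 5


@dataclass
class DDIDataset:
    """DDI records: (drugA, drugB, integer type label), one label per
    unordered pair."""

    records: list[tuple[str, str, int]]
    n_classes: int
    drug_universe: set[str]

    def __post_init__(self):
        self.records = [(str(a), str(b), int(y)) for a, b, y in self.records]
        self.drug_universe = set(map(str, self.drug_universe))
        seen: set[frozenset] = set()
        for a, b, y in self.records:
            if a == b:
                raise ValueError(f"self-pair ({a}, {a}) not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate unordered pair ({a}, {b})")
            seen.add(key)
            if not 0 <= y < self.n_classes:
                raise ValueError(f"label {y} outside [0, {self.n_classes})")
            if a not in self.drug_universe or b not in self.drug_universe:
                raise ValueError(f"pair ({a}, {b}) references unknown drug")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.records], dtype=np.intp)


@dataclass
class Fold:
    train_idx: np.ndarray
    test_idx: np.ndarray
    heldout_drugs: set[str] = field(default_factory=set)


@dataclass
class SplitPlan:
    task: int
    folds: list[Fold]
    seed: int

    def to_json(self) -> str:
        payload = {
            "task": self.task,
            "seed": self.seed,
            "folds": [
                {
                    "train": f.train_idx.tolist(),
                    "test": f.test_idx.tolist(),
                    "heldout_drugs": sorted(f.heldout_drugs),
                }
                for f in self.folds
            ],
        }
        return json.dumps(payload)

    @staticmethod
    def from_json(text: str) -> "SplitPlan":
        payload = json.loads(text)
        return SplitPlan(
            task=payload["task"],
            seed=payload["seed"],
            folds=[
                Fold(
                    train_idx=np.array(f["train"], dtype=np.intp),
                    test_idx=np.array(f["test"], dtype=np.intp),
                    heldout_drugs=set(f["heldout_drugs"]),
                )
                for f in payload["folds"]
            ],
        )


def split_task1(ds: DDIDataset, seed: int = 0, n_folds: int = N_FOLDS) -> SplitPlan:
    """Partition the records into folds, stratified by class wherever the
    class has at least ``n_folds`` records; rarer classes are dealt
    round-robin so no fold hoards them."""
    if len(ds) < n_folds:
        raise ValueError(f"need at least {n_folds} records, got {len(ds)}")
    rng = np.random.default_rng(seed)
    labels = ds.labels
    fold_of = np.empty(len(ds), dtype=np.intp)
    loads = np.zeros(n_folds, dtype=np.intp)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        base = len(idx) // n_folds
        pos = 0
        for k in range(n_folds):  # each fold gets `base` records of class c
            fold_of[idx[pos:pos + base]] = k
            pos += base
        loads += base
        rem = idx[pos:]
        if len(rem):
            # leftovers go to the least-loaded folds (random tie-break),
            # keeping fold sizes within +-1 overall
            perm = rng.permutation(n_folds)
            order = perm[np.argsort(loads[perm], kind="stable")]
            for i, k in zip(rem, order[: len(rem)]):
                fold_of[i] = k
                loads[k] += 1
    folds = []
    for k in range(n_folds):
        test = np.flatnonzero(fold_of == k)
        train = np.flatnonzero(fold_of != k)
        folds.append(Fold(train_idx=train, test_idx=test))
    return SplitPlan(task=1, folds=folds, seed=seed)


def _drug_folds(ds: DDIDataset, seed: int, n_folds: int) -> list[set[str]]:
    drugs = sorted(ds.drug_universe)
    if len(drugs) < n_folds:
        raise ValueError(f"need at least {n_folds} drugs, got {len(drugs)}")
    rng = np.random.default_rng(seed)
    order = np.array(drugs, dtype=object)
    rng.shuffle(order)
    return [set(order[k::n_folds]) for k in range(n_folds)]


def _split_by_drugs(ds: DDIDataset, seed: int, n_folds: int, task: int) -> SplitPlan:
    folds = []
    for heldout in _drug_folds(ds, seed, n_folds):
        train, test = [], []
        for i, (a, b, _) in enumerate(ds.records):
            n_out = (a in heldout) + (b in heldout)
            if n_out == 0:
                train.append(i)
            elif n_out == 1 and task == 2:
                test.append(i)
            elif n_out == 2 and task == 3:
                test.append(i)
            # pairs in the "other" cold-start regime are dropped for this fold
        folds.append(
            Fold(
                train_idx=np.array(train, dtype=np.intp),
                test_idx=np.array(test, dtype=np.intp),
                heldout_drugs=heldout,
            )
        )
    return SplitPlan(task=task, folds=folds, seed=seed)


def split_task2(ds: DDIDataset, seed: int = 0, n_folds: int = N_FOLDS) -> SplitPlan:
    """Cold-start over one drug: test pairs have exactly one held-out drug."""
    return _split_by_drugs(ds, seed, n_folds, task=2)


def split_task3(ds: DDIDataset, seed: int = 0, n_folds: int = N_FOLDS) -> SplitPlan:
    """Cold-start over both drugs: test pairs have both drugs held out."""
    return _split_by_drugs(ds, seed, n_folds, task=3)


def split_for_task(task: int, ds: DDIDataset, seed: int = 0,
                   n_folds: int = N_FOLDS) -> SplitPlan:
    try:
        fn = {1: split_task1, 2: split_task2, 3: split_task3}[task]
    except KeyError:
        raise ValueError(f"task must be 1, 2 or 3, got {task}") from None
    return fn(ds, seed=seed, n_folds=n_folds)


@dataclass
class MetricReport:
    """Six-metric evaluation summary plus a per-class breakdown."""

    acc: float
    aupr: float
    auc: float
    f1: float
    precision: float
    recall: float
    per_class: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in
                ("acc", "aupr", "auc", "f1", "precision", "recall")}


def compute_metrics(y_true, y_prob, average: str = "paper") -> MetricReport:
    """Evaluate multi-class probabilistic predictions.

    ``average='paper'`` (default) uses macro averaging for F1/precision/
    recall over classes present in ``y_true`` and micro (one-vs-rest pooled)
    for AUPR/AUC; ``'macro'``/``'micro'`` force one mode for everything.
    """
    y_true = np.asarray(y_true, dtype=np.intp)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_prob.ndim != 2 or y_prob.shape[0] != y_true.shape[0]:
        raise ValueError("y_prob must be (N, C) aligned with y_true")
    n, c = y_prob.shape
    if y_true.min() < 0 or y_true.max() >= c:
        raise ValueError(
            f"labels span [{y_true.min()}, {y_true.max()}] but y_prob has {c} columns"
        )
    row_sums = y_prob.sum(axis=1)
    if np.abs(row_sums - 1.0).max() > 1e-4:
        raise ValueError("probability rows must sum to 1 within 1e-4")

    y_pred = y_prob.argmax(axis=1)
    acc = float((y_pred == y_true).mean())

    present = np.unique(y_true)
    prf_avg = "micro" if average == "micro" else "macro"
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average=prf_avg, zero_division=0
    )

    onehot = np.zeros((n, c))
    onehot[np.arange(n), y_true] = 1.0
    rank_avg = "macro" if average == "macro" else "micro"
    if rank_avg == "macro":
        # restrict to present classes: AP/AUC undefined without positives
        aupr = float(average_precision_score(
            onehot[:, present], y_prob[:, present], average="macro"))
        auc = float(roc_auc_score(
            onehot[:, present], y_prob[:, present], average="macro"))
    else:
        aupr = float(average_precision_score(onehot, y_prob, average="micro"))
        auc = float(roc_auc_score(onehot, y_prob, average="micro"))

    per_class = []
    p_c, r_c, f_c, support = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average=None, zero_division=0
    )
    for cls, sup, f1c in zip(present, support, f_c):
        ap = float(average_precision_score(onehot[:, cls], y_prob[:, cls]))
        per_class.append(
            {"class": int(cls), "support": int(sup), "f1": float(f1c), "aupr": ap}
        )

    return MetricReport(
        acc=acc, aupr=aupr, auc=auc,
        f1=float(f1), precision=float(precision), recall=float(recall),
        per_class=per_class,
    )
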