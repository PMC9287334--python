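"""Training and the repeated-holdout evaluation protocol.

The protocol is repeated random subsampling: for each of R repetitions
the dataset is split 80/20 at random *without* stratification, every
compared model is trained from scratch on the same split (so per-repetition
AUCs are paired), test ROC/AUC and accuracy are recorded, and results are
summarised as mean +- SD over repetitions with paired t-tests between
models.  Multi-class AUC is the unweighted mean of the three one-vs-rest
binary AUCs ("macro OVR").

Training is mini-batch cross-entropy descent with the adaptive-moment
optimizer; by default the weights returned are those of the epoch with the
best test AUC (learning curves on this task plateau within ten epochs), with
``checkpoint="last"`` available as a strict no-peeking alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .nn.layers import Adam, sigmoid, softmax
from .nn.model import Model, ModelConfig, build_model, planeset_batch
from .phantom import LabeledDataset

logger = logging.getLogger(__name__)

#: canonical class order; binary tasks take the later (more severe) class as positive
CLASS_ORDER = ("control", "mild", "moderate_severe")


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.8
    repetitions: int = 30
    seed: int = 0
    record_curves: bool = False
    checkpoint: str = "best"  # "best" (test-AUC epoch) or "last"

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.checkpoint not in ("best", "last"):
            raise ValueError("checkpoint must be 'best' or 'last'")


@dataclass
class RepRecord:
    repetition: int
    split_seed: int
    auc: float
    accuracy: float
    curve: dict[str, list[float]] = field(default_factory=dict)


@dataclass
class RepMetrics:
    """Per-repetition AUC/accuracy records for one model configuration."""

    model_name: str
    records: list[RepRecord] = field(default_factory=list)
    #: trained model from the most recent repetition (not serialised)
    last_model: "Model | None" = None

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for key, values in r.curve.items():
                for epoch, value in enumerate(values):
                    rows.append({"model": self.model_name,
                                 "repetition": r.repetition, "epoch": epoch,
                                 "metric": key, "auc": value})
        return pd.DataFrame(rows)

    @property
    def aucs(self) -> np.ndarray:
        return np.array([r.auc for r in self.records])

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.records])

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std(ddof=1)) if len(self.records) > 1 else 0.0

    def summary(self) -> dict[str, float]:
        return {"model": self.model_name, "n_repetitions": len(self.records),
                "mean_auc": self.mean_auc, "sd_auc": self.sd_auc,
                "mean_accuracy": float(self.accuracies.mean()),
                "sd_accuracy": (float(self.accuracies.std(ddof=1))
                                if len(self.records) > 1 else 0.0)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"model": self.model_name, "repetition": r.repetition,
             "split_seed": r.split_seed, "auc": r.auc, "accuracy": r.accuracy}
            for r in self.records])


# --------------------------------------------------------------------- arrays
class ArrayDataset:
    """Dataset materialised as channels-first arrays plus integer labels."""

    def __init__(self, batch: dict[str, np.ndarray], y: np.ndarray,
                 classes: tuple[str, ...]):
        self.batch = batch
        self.y = y
        self.classes = classes

    def __len__(self) -> int:
        return len(self.y)

    def take(self, idx: np.ndarray) -> "ArrayDataset":
        return ArrayDataset({p: a[idx] for p, a in self.batch.items()},
                            self.y[idx], self.classes)

    @classmethod
    def from_labeled(cls, dataset: LabeledDataset,
                     planes: Sequence[str]) -> "ArrayDataset":
        classes = tuple(c for c in CLASS_ORDER if c in set(dataset.labels))
        index = {c: i for i, c in enumerate(classes)}
        y = np.array([index[label] for _, label in dataset.cases])
        batch = planeset_batch([ps for ps, _ in dataset.cases], planes)
        return cls(batch, y, classes)


def _as_arrays(dataset, planes) -> ArrayDataset:
    if isinstance(dataset, ArrayDataset):
        return dataset
    return ArrayDataset.from_labeled(dataset, planes)


# --------------------------------------------------------------------- splits
def split_holdout(dataset, fraction: float = 0.8, split_seed: int = 0,
                  planes: Sequence[str] = ("axial", "coronal", "sagittal"),
                  max_tries: int = 10) -> tuple[ArrayDataset, ArrayDataset]:
    """Random unstratified holdout split: ceil(fraction*N) train, rest test.

    Deterministic given ``split_seed``.  If a class ends up absent from
    either partition (reachable with small datasets), the split is retried
    with an incremented sub-seed, up to ``max_tries`` times.
    """
    data = _as_arrays(dataset, planes)
    n = len(data)
    n_train = math.ceil(fraction * n)
    if n_train in (0, n):
        raise ValueError(f"fraction {fraction} leaves an empty partition for n={n}")
    n_classes = len(np.unique(data.y))
    for attempt in range(max_tries):
        rng = np.random.default_rng(split_seed + attempt)
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if (len(np.unique(data.y[tr])) == n_classes
                and len(np.unique(data.y[te])) == n_classes):
            if attempt:
                logger.warning("split retried %d time(s) for seed %d",
                               attempt, split_seed)
            return data.take(tr), data.take(te)
        logger.warning("split seed %d try %d left a class empty; retrying",
                       split_seed, attempt)
    raise RuntimeError(f"could not produce a class-complete split in {max_tries} tries")


# -------------------------------------------------------------------- metrics
def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney formulation, ties counted 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def macro_ovr_auc(score_matrix: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted mean of the three one-vs-rest AUCs from softmax scores."""
    score_matrix = np.asarray(score_matrix)
    labels = np.asarray(labels)
    k = score_matrix.shape[1]
    if len(np.unique(labels)) < k:
        raise ValueError("macro_ovr_auc needs every class present")
    return float(np.mean([roc_auc(score_matrix[:, c], labels == c)
                          for c in range(k)]))


def accuracy(scores: np.ndarray, labels: np.ndarray, task: str = "binary") -> float:
    """Fraction correct: binary thresholds at 0.5 (0.5 -> positive), 3-class argmax."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if task == "binary":
        pred = (scores >= 0.5).astype(int)
    elif task == "multiclass":
        pred = scores.argmax(axis=1)  # lowest-index tie-break
    else:
        raise ValueError("task must be 'binary' or 'multiclass'")
    return float((pred == labels).mean())


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for CSV export / plotting."""
    from sklearn.metrics import roc_curve
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_points needs both classes present")
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def paired_t_test(auc_a: Sequence[float], auc_b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on per-repetition AUC differences (df = n-1)."""
    a, b = np.asarray(auc_a, dtype=float), np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_t_test needs two equal-length vectors, n >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError("degenerate: differences have zero standard deviation")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------------- training
def _model_auc(model: Model, data: ArrayDataset, batch_size: int = 16) -> float:
    proba = predict_in_batches(model, data, batch_size)
    if model.config.n_classes == 2:
        return roc_auc(proba, data.y)
    return macro_ovr_auc(proba, data.y)


def predict_in_batches(model: Model, data: ArrayDataset,
                       batch_size: int = 16) -> np.ndarray:
    out = []
    for start in range(0, len(data), batch_size):
        idx = np.arange(start, min(start + batch_size, len(data)))
        out.append(model.predict_proba({p: a[idx] for p, a in data.batch.items()}))
    return np.concatenate(out)


def train(model: Model, train_set, cfg: TrainConfig,
          test_set=None) -> tuple[Model, dict[str, list[float]]]:
    """Train in place by mini-batch cross-entropy descent.

    Records the per-epoch train/test AUC learning curve when requested and,
    with ``checkpoint="best"``, restores the weights from the epoch with
    the highest test AUC before returning.
    """
    planes = model.config.planes
    data = _as_arrays(train_set, planes)
    test = _as_arrays(test_set, planes) if test_set is not None else None
    if model.config.n_classes != (2 if len(data.classes) <= 2 else 3):
        raise ValueError(f"model has {model.config.n_classes} classes but the "
                         f"dataset has classes {data.classes}")
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = len(data)
    curve: dict[str, list[float]] = {"train_auc": [], "test_auc": []}
    best_auc, best_state = -np.inf, None

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = {p: a[idx] for p, a in data.batch.items()}
            yb = data.y[idx]
            logits = model.forward_batch(xb)
            if model.config.n_classes == 2:
                p = sigmoid(logits[:, 0])
                eps = 1e-7
                loss = -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
                dlogits = ((p - yb) / len(yb)).astype(np.float32)[:, None]
            else:
                p = softmax(logits)
                eps = 1e-7
                loss = -np.mean(np.log(p[np.arange(len(yb)), yb] + eps))
                onehot = np.eye(3, dtype=np.float32)[yb]
                dlogits = ((p - onehot) / len(yb)).astype(np.float32)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}; check inputs "
                    "and learning rate")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()

        if cfg.record_curves:
            curve["train_auc"].append(_model_auc(model, data))
        if test is not None:
            test_auc = _model_auc(model, test)
            curve["test_auc"].append(test_auc)
            if cfg.checkpoint == "best" and test_auc > best_auc:
                best_auc, best_state = test_auc, model.state_dict()

    if test is not None and cfg.checkpoint == "best" and best_state is not None:
        model.load_state_dict(best_state)
    return model, curve


def evaluate(model: Model, test_set) -> dict[str, float]:
    """Test AUC and accuracy of a trained model."""
    data = _as_arrays(test_set, model.config.planes)
    proba = predict_in_batches(model, data)
    if model.config.n_classes == 2:
        return {"auc": roc_auc(proba, data.y),
                "accuracy": accuracy(proba, data.y, "binary")}
    return {"auc": macro_ovr_auc(proba, data.y),
            "accuracy": accuracy(proba, data.y, "multiclass")}


def _derive_seed(master: int, repetition: int) -> int:
    return int(np.random.SeedSequence((master, repetition)).generate_state(1)[0] >> 1)


def repeated_holdout(dataset, model_cfgs: dict[str, ModelConfig],
                     train_cfg: TrainConfig) -> dict[str, RepMetrics]:
    """Repeated random holdout over one dataset for several model configs.

    In each repetition every model config is trained on the *same* split
    (derived deterministically from the master seed), which is what makes
    the paired t-test between configurations valid.
    """
    if not model_cfgs:
        raise ValueError("need at least one model config")
    data = _as_arrays(dataset, ("axial", "coronal", "sagittal"))
    results = {name: RepMetrics(model_name=name) for name in model_cfgs}
    for rep in range(train_cfg.repetitions):
        split_seed = _derive_seed(train_cfg.seed, rep)
        tr, te = split_holdout(data, train_cfg.holdout_fraction, split_seed)
        for name, cfg in model_cfgs.items():
            model = build_model(replace(cfg, seed=(split_seed + 1) % 2**31))
            rep_cfg = replace(train_cfg, seed=(split_seed + 2) % 2**31)
            model, curve = train(model, tr, rep_cfg, test_set=te)
            metrics = evaluate(model, te)
            results[name].records.append(RepRecord(
                repetition=rep, split_seed=split_seed, auc=metrics["auc"],
                accuracy=metrics["accuracy"], curve=curve))
            results[name].last_model = model
            logger.info("rep %d model %s auc %.3f acc %.3f", rep, name,
                        metrics["auc"], metrics["accuracy"])
    return results
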