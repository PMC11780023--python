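"""Stratified splitting, the four-classifier bank, and multiclass evaluation.

Evaluation reports the 3x3 confusion matrix, accuracy, macro precision/
recall/F1, per-class one-vs-rest ROC AUC, their unweighted mean
(macro-AUC), the pooled-indicator micro-AUC, and a stratified case-level
bootstrap percentile 95% CI for the macro-AUC.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SplitAssignment",
    "ModelSpec",
    "EvalReport",
    "stratified_split",
    "train_model",
    "evaluate",
    "compare_models",
]

CLASSIFIERS = ("svm", "lr", "rf", "dt")


@dataclasses.dataclass(frozen=True)
class SplitAssignment:
    """case_id -> {train, internal_test, external_test}; externals never mix."""

    assignment: dict[str, str]
    ratio: tuple[float, float]
    seed: int

    def ids(self, role: str) -> list[str]:
        return [k for k, v in self.assignment.items() if v == role]


def stratified_split(
    case_ids: list[str],
    labels: np.ndarray | list[int],
    cohort_tags: list[str] | None = None,
    test_frac: float = 0.2,
    seed: int = 0,
) -> SplitAssignment:
    """Stratified train / internal-test split; external cases pass through.

    The internal test size is ceil(test_frac * n); slots are apportioned
    across classes by largest remainder of the class-proportional quotas,
    and membership within a class is a seeded shuffle.
    """
    case_ids = list(case_ids)
    labels = np.asarray(labels)
    if cohort_tags is None:
        cohort_tags = ["train_pool"] * len(case_ids)
    assignment: dict[str, str] = {}
    pool_idx = [i for i, t in enumerate(cohort_tags) if t != "external"]
    for i, t in enumerate(cohort_tags):
        if t == "external":
            assignment[case_ids[i]] = "external_test"

    pool_labels = labels[pool_idx]
    n = len(pool_idx)
    classes, counts = np.unique(pool_labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 cases to split")
    n_test = int(np.ceil(test_frac * n))
    quotas = counts * n_test / n
    alloc = np.floor(quotas).astype(int)
    rem = quotas - alloc
    for idx in np.argsort(-rem)[: n_test - alloc.sum()]:
        alloc[idx] += 1

    rng = np.random.default_rng(seed)
    for cls, k in zip(classes, alloc):
        members = [pool_idx[j] for j in np.flatnonzero(pool_labels == cls)]
        members = list(np.asarray(members)[rng.permutation(len(members))])
        for j, m in enumerate(members):
            role = "internal_test" if j < k else "train"
            assignment[case_ids[m]] = role
    return SplitAssignment(assignment, (1 - test_frac, test_frac), seed)


# ---------------------------------------------------------------------------
# classifier bank


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One model slot of the inventory: modality x phase (x backend) x classifier."""

    modality: str  # radiomics | dtl | fusion
    phase: str  # AP | PP | combined
    classifier: str = "svm"
    backend: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("radiomics", "dtl", "fusion"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.phase not in ("AP", "PP", "combined"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; choose from {CLASSIFIERS}"
            )
        if self.modality in ("dtl", "fusion") and not self.backend:
            raise ValueError(f"{self.modality} models require a backend name")

    @property
    def name(self) -> str:
        parts = [self.modality]
        if self.backend:
            parts.append(self.backend)
        parts.extend([self.phase, self.classifier])
        return "-".join(parts)


def make_classifier(name: str, seed: int = 0):
    """Pinned classifier defaults; all expose per-class probabilities."""
    if name == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if name == "lr":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def train_model(spec: ModelSpec, train_features: pd.DataFrame, train_labels):
    """Fit the classifier named by the spec on selected/standardised features."""
    est = make_classifier(spec.classifier, spec.seed)
    est.fit(train_features.to_numpy(dtype=np.float64), np.asarray(train_labels))
    return est


# ---------------------------------------------------------------------------
# evaluation


@dataclasses.dataclass(frozen=True)
class EvalReport:
    model_name: str
    split_name: str
    n: int
    confusion: np.ndarray  # rows = true class
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class_auc: dict[int, float]
    macro_auc: float
    micro_auc: float
    ci_95: tuple[float, float]
    n_bootstrap: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confusion"] = self.confusion.tolist()
        d["per_class_auc"] = {str(k): v for k, v in self.per_class_auc.items()}
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _macro_prf(conf: np.ndarray) -> tuple[float, float, float]:
    tp = np.diag(conf).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(conf.sum(axis=0) > 0, tp / conf.sum(axis=0), 0.0)
        rec = np.where(conf.sum(axis=1) > 0, tp / conf.sum(axis=1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    present = conf.sum(axis=1) > 0
    return (
        float(prec[present].mean()),
        float(rec[present].mean()),
        float(f1[present].mean()),
    )


def _auc_metrics(y: np.ndarray, prob: np.ndarray, n_classes: int = 3):
    per_class: dict[int, float] = {}
    for c in range(n_classes):
        pos = y == c
        if pos.any() and (~pos).any():
            per_class[c] = float(roc_auc_score(pos.astype(int), prob[:, c]))
    if not per_class:
        return per_class, float("nan"), float("nan")
    macro = float(np.mean(list(per_class.values())))
    onehot = np.zeros_like(prob)
    onehot[np.arange(len(y)), y] = 1.0
    micro = float(roc_auc_score(onehot.ravel(), prob.ravel()))
    return per_class, macro, micro


def evaluate(
    model,
    features: pd.DataFrame,
    labels,
    n_bootstrap: int = 2000,
    seed: int = 0,
    model_name: str = "model",
    split_name: str = "test",
) -> EvalReport:
    """Full multiclass evaluation of a fitted model on one data split."""
    y = np.asarray(labels)
    X = features.to_numpy(dtype=np.float64)
    prob = model.predict_proba(X)
    pred = np.asarray(model.classes_)[np.argmax(prob, axis=1)]

    conf = confusion_matrix(y, pred, labels=[0, 1, 2])
    acc = float(np.trace(conf) / conf.sum())
    prec, rec, f1 = _macro_prf(conf)

    # align probability columns to classes 0..2 (absent classes scored 0)
    full_prob = np.zeros((len(y), 3))
    for j, c in enumerate(model.classes_):
        full_prob[:, int(c)] = prob[:, j]
    per_class, macro, micro = _auc_metrics(y, full_prob)
    if len(per_class) < 3:
        warnings.warn(
            "some classes are absent from the evaluation set; macro-AUC "
            "averages the present classes only",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    boots = []
    class_idx = [np.flatnonzero(y == c) for c in np.unique(y)]
    for _ in range(n_bootstrap):
        idx = np.concatenate([rng.choice(ci, size=len(ci), replace=True) for ci in class_idx])
        _, m, _ = _auc_metrics(y[idx], full_prob[idx])
        if np.isfinite(m):
            boots.append(m)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")

    return EvalReport(
        model_name=model_name,
        split_name=split_name,
        n=len(y),
        confusion=conf,
        accuracy=acc,
        precision_macro=prec,
        recall_macro=rec,
        f1_macro=f1,
        per_class_auc=per_class,
        macro_auc=macro,
        micro_auc=micro,
        ci_95=(float(lo), float(hi)),
        n_bootstrap=n_bootstrap,
    )


def compare_models(reports: list[EvalReport]) -> pd.DataFrame:
    """Rank reports from one split by macro-AUC (ties: accuracy, then F1)."""
    if not reports:
        raise ValueError("no reports to compare")
    splits = {r.split_name for r in reports}
    if len(splits) > 1:
        raise ValueError(f"reports come from different splits: {sorted(splits)}")
    rows = [
        {
            "model": r.model_name,
            "macro_auc": r.macro_auc,
            "ci_low": r.ci_95[0],
            "ci_high": r.ci_95[1],
            "micro_auc": r.micro_auc,
            "accuracy": r.accuracy,
            "precision": r.precision_macro,
            "recall": r.recall_macro,
            "f1": r.f1_macro,
            "n": r.n,
        }
        for r in reports
    ]
    table = pd.DataFrame(rows).sort_values(
        by=["macro_auc", "accuracy", "f1"], ascending=False, kind="mergesort"
    )
    return table.reset_index(drop=True)
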