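"""Model/Results interface over the classifier bank.

``LesionClassifier`` wraps one model slot (modality, phase, classifier)
around a feature table; ``fit`` returns a ``LesionClassifierResults``
carrying the fitted estimator, which evaluates itself on held-out tables
and renders a summary table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import EvalReport, ModelSpec, evaluate, train_model

__all__ = ["LesionClassifier", "LesionClassifierResults"]


class LesionClassifier:
    """A three-class lesion classifier on a selected feature table.

    Parameters
    ----------
    features : DataFrame
        Training rows (cases) by selected, standardised feature columns.
    labels : array-like
        Class labels coded 0 = HCC, 1 = DPHCC, 2 = ICC.
    spec : ModelSpec
        The model-slot description (modality/phase/classifier/backend).
    """

    def __init__(self, features: pd.DataFrame, labels, spec: ModelSpec):
        if len(features) != len(labels):
            raise ValueError("features and labels disagree in length")
        self.features = features
        self.labels = np.asarray(labels)
        self.spec = spec

    @classmethod
    def from_feature_table(
        cls,
        table: pd.DataFrame,
        labels,
        selected: list[str],
        spec: ModelSpec,
    ) -> "LesionClassifier":
        return cls(table.loc[:, selected], labels, spec)

    def fit(self) -> "LesionClassifierResults":
        est = train_model(self.spec, self.features, self.labels)
        return LesionClassifierResults(self, est)


class LesionClassifierResults:
    """Fitted classifier plus its evaluation reports."""

    def __init__(self, model: LesionClassifier, estimator):
        self.model = model
        self.estimator = estimator
        self.reports: dict[str, EvalReport] = {}

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(features.to_numpy(dtype=np.float64))

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(features.to_numpy(dtype=np.float64))

    def evaluate(
        self,
        features: pd.DataFrame,
        labels,
        split_name: str = "test",
        n_bootstrap: int = 2000,
        seed: int = 0,
    ) -> EvalReport:
        rep = evaluate(
            self.estimator,
            features.loc[:, self.model.features.columns],
            labels,
            n_bootstrap=n_bootstrap,
            seed=seed,
            model_name=self.model.spec.name,
            split_name=split_name,
        )
        self.reports[split_name] = rep
        return rep

    def summary(self) -> pd.DataFrame:
        """One row per evaluated split with the headline metrics."""
        rows = []
        for split, r in self.reports.items():
            rows.append(
                {
                    "model": r.model_name,
                    "split": split,
                    "n": r.n,
                    "macro_auc": r.macro_auc,
                    "ci_low": r.ci_95[0],
                    "ci_high": r.ci_95[1],
                    "micro_auc": r.micro_auc,
                    "accuracy": r.accuracy,
                    "precision": r.precision_macro,
                    "recall": r.recall_macro,
                    "f1": r.f1_macro,
                }
            )
        return pd.DataFrame(rows)
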