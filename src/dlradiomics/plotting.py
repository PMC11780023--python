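"""Diagnostic plots: LASSO cross-validation path and one-vs-rest ROC curves."""

from __future__ import annotations

import numpy as np

from .selection import SelectionResult

CLASS_NAMES = {0: "HCC", 1: "DPHCC", 2: "ICC"}


def plot_cv_path(sel: SelectionResult, ax=None):
    """Cross-validated deviance against log10(lambda), with the one-SE band
    and the chosen lambda_1se / lambda_min marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.log10(sel.lambda_grid)
    ax.errorbar(x, sel.cv_loss_mean, yerr=sel.cv_loss_se, fmt="o-", ms=3, lw=1)
    ax.axvline(np.log10(sel.lambda_min), ls=":", color="gray", label=r"$\lambda_{min}$")
    ax.axvline(np.log10(sel.lambda_1se), ls="--", color="red", label=r"$\lambda_{1se}$")
    ax.set_xlabel(r"$\log_{10}\lambda$")
    ax.set_ylabel("CV multinomial deviance")
    ax.legend()
    return ax


def plot_roc(results, features, labels, ax=None):
    """Per-class one-vs-rest ROC curves for a fitted LesionClassifierResults."""
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve, roc_auc_score

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    prob = results.predict_proba(features)
    y = np.asarray(labels)
    classes = np.asarray(results.estimator.classes_)
    for j, c in enumerate(classes):
        pos = (y == c).astype(int)
        if pos.sum() in (0, len(y)):
            continue
        fpr, tpr, _ = roc_curve(pos, prob[:, j])
        auc = roc_auc_score(pos, prob[:, j])
        name = CLASS_NAMES.get(int(c), str(c))
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], ls=":", color="gray", lw=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    return ax
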