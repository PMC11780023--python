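"""Feature reproducibility filtering, standardisation, LASSO selection, fusion.

* ICC(2,1) — two-way random-effects, absolute-agreement, single-rater
  intraclass correlation — screens features for stability across readers
  (inter) and re-delineation (intra); both must reach the threshold
  (default 0.8).
* Z-score standardisation is fitted on training rows only (sample sd,
  ddof=1) and applied unchanged to test rows.
* LASSO: an L1-penalised multinomial logistic path over a descending
  log-spaced lambda grid; five-fold stratified cross-validated multinomial
  deviance picks lambda_1se, the largest lambda within one standard error
  of the minimum mean loss (the sparsest acceptable model).
* Fusion: selected radiomics and deep features are concatenated and pruned
  greedily in fixed order so that no retained pair has |Spearman rho|
  above the threshold (default 0.9) on the training rows.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ICCResult",
    "SelectionResult",
    "FusionSet",
    "icc_21",
    "icc_filter",
    "zscore",
    "lasso_select",
    "fuse_and_prune",
]


# ---------------------------------------------------------------------------
# ICC


@dataclasses.dataclass(frozen=True)
class ICCResult:
    """Per-feature inter/intra-reader ICC and the retention decision."""

    inter_reader_icc: pd.Series
    intra_reader_icc: pd.Series
    retained: pd.Series  # bool per feature
    threshold: float

    @property
    def retained_names(self) -> list[str]:
        return self.retained.index[self.retained].tolist()


def icc_21(ratings: np.ndarray) -> np.ndarray:
    """Vectorised ICC(2,1) over feature columns.

    ``ratings`` has shape (n_targets, k_raters) or (n_targets, k_raters,
    n_features).  Two-way random effects, absolute agreement, single rater:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Zero-variance features yield NaN.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim == 2:
        x = x[..., None]
    n, k, _ = x.shape
    mean_r = x.mean(axis=1, keepdims=True)  # per target
    mean_c = x.mean(axis=0, keepdims=True)  # per rater
    grand = x.mean(axis=(0, 1), keepdims=True)
    ssr = k * ((mean_r - grand) ** 2).sum(axis=(0, 1))
    ssc = n * ((mean_c - grand) ** 2).sum(axis=(0, 1))
    sse = ((x - mean_r - mean_c + grand) ** 2).sum(axis=(0, 1))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(np.abs(denom) > 1e-300, (msr - mse) / denom, np.nan)
    total_var = x.reshape(n * k, -1).var(axis=0)
    icc[total_var <= 1e-300] = np.nan
    return icc


def icc_filter(
    reader1: pd.DataFrame,
    reader2: pd.DataFrame,
    reader1_repeat: pd.DataFrame,
    threshold: float = 0.8,
) -> ICCResult:
    """Retain features whose inter- and intra-reader ICC both reach threshold.

    Inputs are aligned case-by-feature tables from the three delineations
    of the same ~30 cases.  Features with undefined ICC (zero variance)
    are dropped with a warning.
    """
    if not (reader1.columns.equals(reader2.columns) and reader1.columns.equals(reader1_repeat.columns)):
        raise ValueError("feature name mismatch between reader tables")
    if len(reader1) < 10:
        raise ValueError("ICC analysis needs at least 10 cases")
    inter = icc_21(np.stack([reader1.to_numpy(), reader2.to_numpy()], axis=1))
    intra = icc_21(np.stack([reader1.to_numpy(), reader1_repeat.to_numpy()], axis=1))
    inter_s = pd.Series(inter, index=reader1.columns)
    intra_s = pd.Series(intra, index=reader1.columns)
    undefined = inter_s.isna() | intra_s.isna()
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} features have undefined ICC "
            "(zero variance) and were dropped",
            stacklevel=2,
        )
    retained = (inter_s >= threshold) & (intra_s >= threshold) & ~undefined
    return ICCResult(inter_s, intra_s, retained, threshold)


# ---------------------------------------------------------------------------
# z-score


def zscore(
    train: pd.DataFrame, apply: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Standardise columns on training statistics (sample sd, ddof=1).

    Zero-variance training columns are dropped (with a warning) from both
    outputs.  Test-set columns are transformed with the training mean/sd
    and need not have mean 0.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance features before scaling",
            stacklevel=2,
        )
    train_z = (train.loc[:, keep] - mean[keep]) / sd[keep]
    apply_z = None
    if apply is not None:
        apply_z = (apply.loc[:, keep.index[keep]] - mean[keep]) / sd[keep]
    return train_z, apply_z


# ---------------------------------------------------------------------------
# LASSO one-SE selection


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    lambda_grid: np.ndarray  # descending
    cv_loss_mean: np.ndarray
    cv_loss_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    selected_names: list[str]
    coefficients: pd.DataFrame  # class x feature at lambda_1se


def _lambda_max(X: np.ndarray, y: np.ndarray, n_classes: int) -> float:
    """Smallest penalty that zeroes every multinomial coefficient."""
    n = len(y)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    resid = onehot - onehot.mean(axis=0, keepdims=True)
    grad = X.T @ resid / n
    return float(np.abs(grad).max())


def _multinomial_deviance(prob: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.clip(prob[np.arange(len(y)), y], 1e-12, 1.0)
    return -2.0 * np.log(p)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _spectral_norm_sq(X: np.ndarray, n_iter: int = 30) -> float:
    """Largest squared singular value by power iteration (deterministic init)."""
    v = np.ones(X.shape[1]) / np.sqrt(X.shape[1])
    s = 1.0
    for _ in range(n_iter):
        u = X @ v
        v = X.T @ u
        s = np.linalg.norm(v)
        if s == 0:
            return 1.0
        v /= s
    return float(s)


def _fit_multinomial_l1(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    W0: np.ndarray,
    b0: np.ndarray,
    L: float,
    max_iter: int = 400,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """One lambda of the L1 multinomial logistic problem via FISTA.

    Minimises (1/n) sum cross-entropy + lam * ||W||_1 (intercept b
    unpenalised).  ``L`` is the gradient Lipschitz bound 0.5 * sigma_max^2
    (X) / n; the same step serves the intercept (its curvature bound 0.5
    is smaller whenever n <= sigma_max^2).
    """
    n = X.shape[0]
    W, b = W0.copy(), b0.copy()
    Wy, by = W.copy(), b.copy()
    t = 1.0
    step = 1.0 / L
    thresh = lam * step
    for _ in range(max_iter):
        P = _softmax(X @ Wy + by)
        R = (P - Y) / n
        gW = X.T @ R
        gb = R.sum(axis=0)
        Z = Wy - step * gW
        W_new = np.sign(Z) * np.maximum(np.abs(Z) - thresh, 0.0)
        b_new = by - step * gb
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        beta = (t - 1.0) / t_new
        Wy = W_new + beta * (W_new - W)
        by = b_new + beta * (b_new - b)
        delta = max(np.abs(W_new - W).max(initial=0.0), np.abs(b_new - b).max())
        W, b, t = W_new, b_new, t_new
        if delta < tol * max(1.0, np.abs(W).max(initial=1.0)):
            break
    return W, b


def _path_fit(X, y_enc, n_classes, lambdas):
    """Warm-started descending-lambda path; returns per-lambda (W, b)."""
    n, p = X.shape
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), y_enc] = 1.0
    L = 0.5 * _spectral_norm_sq(X) / n + 1e-12
    props = np.clip(Y.mean(axis=0), 1e-9, 1.0)
    W = np.zeros((p, n_classes))
    b = np.log(props)
    out = []
    for lam in lambdas:
        W, b = _fit_multinomial_l1(X, Y, lam, W, b, L)
        out.append((W.copy(), b.copy()))
    return out


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 25,
    lambda_min_ratio: float = 0.01,
) -> SelectionResult:
    """L1 multinomial logistic path with the cross-validated one-SE rule."""
    y = np.asarray(y)
    classes, y_enc = np.unique(y, return_inverse=True)
    n_classes = len(classes)
    counts = np.bincount(y_enc)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold CV needs >= {n_folds} cases per class "
            f"(smallest class has {counts.min()})"
        )
    Xv = X.to_numpy(dtype=np.float64)
    lam_max = _lambda_max(Xv, y_enc, n_classes)
    if lam_max <= 0:
        lam_max = 1e-3
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_losses = np.zeros((n_folds, len(lambdas)))
    for f, (tr, va) in enumerate(skf.split(Xv, y_enc)):
        path = _path_fit(Xv[tr], y_enc[tr], n_classes, lambdas)
        for li, (coef, intercept) in enumerate(path):
            prob = _softmax(Xv[va] @ coef + intercept)
            fold_losses[f, li] = _multinomial_deviance(prob, y_enc[va]).mean()

    cv_mean = fold_losses.mean(axis=0)
    cv_se = fold_losses.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    lam_min = float(lambdas[i_min])
    cutoff = cv_mean[i_min] + cv_se[i_min]
    i_1se = int(np.flatnonzero(cv_mean <= cutoff)[0])  # largest lambda (grid descends)
    lam_1se = float(lambdas[i_1se])

    # refit on the full training table along the path down to lambda_1se
    full_path = _path_fit(Xv, y_enc, n_classes, lambdas[: i_1se + 1])
    W_1se, _ = full_path[-1]
    nonzero = np.any(np.abs(W_1se) > 1e-8, axis=1)
    selected = X.columns[nonzero].tolist()
    if not selected:
        warnings.warn("LASSO selected no features at lambda_1se", stacklevel=2)
    coefs = pd.DataFrame(W_1se.T, index=classes, columns=X.columns)
    return SelectionResult(
        lambda_grid=lambdas,
        cv_loss_mean=cv_mean,
        cv_loss_se=cv_se,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        selected_names=selected,
        coefficients=coefs,
    )


# ---------------------------------------------------------------------------
# fusion with Spearman pruning


@dataclasses.dataclass(frozen=True)
class FusionSet:
    members: list[str]
    dropped_pairs: list[tuple[str, str, float]]  # (kept, dropped, rho)
    rho_max: float


def fuse_and_prune(
    selected_radiomics: list[str],
    selected_deep: list[str],
    train_table: pd.DataFrame,
    rho_max: float = 0.9,
) -> FusionSet:
    """Concatenate selections and greedily drop |Spearman rho| > rho_max pairs.

    Features are scanned in the fixed order radiomics-then-deep; a feature
    is dropped if it correlates beyond the threshold with any already-kept
    feature (ties resolved in favour of the earlier name).
    """
    overlap = set(selected_radiomics) & set(selected_deep)
    if overlap:
        raise ValueError(f"radiomics and deep name spaces overlap: {sorted(overlap)[:3]}")
    order = list(selected_radiomics) + list(selected_deep)
    if not order:
        return FusionSet([], [], rho_max)
    data = train_table.loc[:, order].to_numpy(dtype=np.float64)
    if len(order) == 1:
        rho = np.ones((1, 1))
    else:
        r = stats.spearmanr(data).statistic
        if np.ndim(r) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, float(r)], [float(r), 1.0]])
        else:
            rho = np.asarray(r)
    kept: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(order)):
        conflict = None
        for i in kept:
            if abs(rho[i, j]) > rho_max:
                conflict = i
                break
        if conflict is None:
            kept.append(j)
        else:
            dropped.append((order[conflict], order[j], float(rho[conflict, j])))
    return FusionSet([order[j] for j in kept], dropped, rho_max)
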