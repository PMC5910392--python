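"""Bootstrap-enhanced LASSO-penalized logistic signature selection.

The classifier distinguishes cancer (SCC + AD, encoded 1) from non-cancer
(HD + EB, encoded 0) from miRNA-ratio features.  The stages are:

1. per-feature AUC pre-filter (keep ratios with oriented AUC > 0.7),
2. L1-penalized logistic regression; the penalty weight lambda is chosen
   by stratified 5-fold cross-validation minimizing the out-of-fold
   Brier score over a geometric lambda path,
3. bootstrap enhancement: many stratified 2:1 train/test splits, each
   re-optimizing lambda on its training part, recording the test AUC and
   the set of features with nonzero coefficients,
4. variable importance = selection frequency across iterations (ties
   broken by mean absolute coefficient), and
5. a final model fitted on all data at the CV-optimal lambda, evaluated
   by resubstitution ROC/AUC (no independent validation cohort exists at
   this stage of a biomarker study).

The penalized fit minimizes ``(1/n) * sum log-loss + lambda * ||beta||_1``
with an unpenalized intercept over features standardized to mean 0 / SD 1.
It is solved by FISTA (accelerated proximal gradient with adaptive
restart); soft-thresholding yields *exact* zeros, so "selected" is
well defined, and for lambda >= lambda_max = max|X'(y - ybar)|/n the
solution is exactly the null model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "auc",
    "auc_prefilter",
    "brier",
    "logistic_lasso_fit",
    "lambda_max",
    "cv_lambda",
    "bootstrap_lasso",
    "variable_importance",
    "final_model_and_roc",
    "SignatureModel",
    "BootstrapSummary",
    "CvLambdaResult",
]


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------


def auc(scores, labels) -> float:
    """Area under the ROC curve in its Mann-Whitney form.

    The probability that a random positive outranks a random negative,
    with ties counted 1/2.  ``labels`` must contain both classes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(s)
    rank_sum = float(np.sum(ranks[y == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_prefilter(
    X: pd.DataFrame, y, min_auc: float = 0.7
) -> tuple[list[str], pd.Series]:
    """Keep features whose single-feature AUC exceeds ``min_auc``.

    Each feature is oriented first (AUC mapped to max(a, 1-a)), so the
    filter is direction-agnostic.  Returns the retained feature names and
    the oriented AUC of every feature.
    """
    y = np.asarray(y).astype(int)
    oriented = {}
    for feat in X.columns:
        v = X[feat].to_numpy(dtype=float)
        ok = np.isfinite(v)
        a = auc(v[ok], y[ok])
        oriented[feat] = max(a, 1.0 - a)
    ser = pd.Series(oriented, name="auc")
    keep = [f for f in X.columns if ser[f] > min_auc]
    return keep, ser


def brier(probabilities, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(float)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


# ---------------------------------------------------------------------------
# penalized logistic regression (FISTA)
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    # tolerance absorbs cancellation error when a column is constant
    kept = scale > 1e-10 * np.maximum(1.0, np.abs(center))
    safe = np.where(kept, scale, 1.0)
    return (X - center) / safe, center, safe, kept


def lambda_max(Xs: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the LASSO solution is the null model:
    ``max_j |Xs_j'(y - ybar)| / n`` for standardized features."""
    n = len(y)
    r = y - y.mean()
    return float(np.max(np.abs(Xs.T @ r)) / n)


def _fit_path(
    Xs: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Solutions along a lambda path on standardized features.

    All path points are solved simultaneously: one batched FISTA run in
    which each column of the iterate matrix is one lambda (momentum,
    adaptive restart and convergence are tracked per column).  Returns
    (intercepts, coefficients).
    """
    n, p = Xs.shape
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("labels must contain both classes")
    Xt = np.column_stack([np.ones(n), Xs])
    # Lipschitz constant of the logistic gradient: ||Xt||_2^2 / (4n)
    L = float(np.linalg.norm(Xt, 2)) ** 2 / (4.0 * n)
    step = 1.0 / L
    n_lam = len(lambdas)
    lam_row = np.asarray(lambdas, dtype=float)[None, :]

    x = np.zeros((p + 1, n_lam))
    x[0, :] = np.log(ybar / (1.0 - ybar))
    z = x.copy()
    t = np.ones(n_lam)
    thr = step * lam_row
    yv = y[:, None]
    for _ in range(max_iter):
        g = Xt.T @ (expit(Xt @ z) - yv) / n
        x_new = z - step * g
        x_new[1:] = np.sign(x_new[1:]) * np.maximum(np.abs(x_new[1:]) - thr, 0.0)
        restart = np.einsum("ij,ij->j", z - x_new, x_new - x) > 0.0
        t_new = np.where(restart, 1.0, 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t)))
        mom = np.where(restart, 0.0, (t - 1.0) / t_new)
        z = x_new + mom[None, :] * (x_new - x)
        delta = np.max(np.abs(x_new - x), axis=0)
        x = x_new
        t = t_new
        if np.max(delta) < tol:
            break
    return x[0, :].copy(), x[1:, :].T.copy()


@dataclass
class SignatureModel:
    """Penalized logistic signature with its preprocessing parameters.

    Coefficients are on the standardized-feature scale; ``center`` and
    ``scale`` reproduce the standardization at prediction time.  Features
    that were constant at fit time are recorded in ``dropped`` and carry
    coefficient 0 / scale 1.
    """

    features: list[str]
    center: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    lambda_: float
    dropped: list[str] = field(default_factory=list)
    positive_class: str = "cancer"

    def _design(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.features].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        return (X - self.center) / self.scale

    def decision(self, X) -> np.ndarray:
        return self._design(X) @ self.coef + self.intercept

    def predict_proba(self, X) -> np.ndarray:
        """P(cancer) for each row; strictly inside (0, 1)."""
        return expit(self.decision(X))

    def nonzero_features(self) -> list[str]:
        return [f for f, c in zip(self.features, self.coef) if c != 0.0]

    # -- serialization (human-readable JSON) ---------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "positive_class": self.positive_class,
            "lambda": self.lambda_,
            "intercept": self.intercept,
            "dropped": self.dropped,
            "features": [
                {
                    "name": f,
                    "center": float(c),
                    "scale": float(s),
                    "coef": float(b),
                }
                for f, c, s, b in zip(self.features, self.center, self.scale, self.coef)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        payload = json.loads(Path(path).read_text())
        feats = payload["features"]
        return cls(
            features=[f["name"] for f in feats],
            center=np.array([f["center"] for f in feats]),
            scale=np.array([f["scale"] for f in feats]),
            coef=np.array([f["coef"] for f in feats]),
            intercept=float(payload["intercept"]),
            lambda_=float(payload["lambda"]),
            dropped=list(payload.get("dropped", [])),
            positive_class=payload.get("positive_class", "cancer"),
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def logistic_lasso_fit(
    X,
    y,
    lambda_: float,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> SignatureModel:
    """Fit the L1-penalized logistic model at a fixed penalty.

    Minimizes ``(1/n) sum log-loss + lambda * ||beta||_1`` with an
    unpenalized intercept; features are standardized internally.  Constant
    features are dropped with a warning.  Deterministic given inputs.
    """
    mat, names = _as_matrix(X)
    y = np.asarray(y).astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if not np.all(np.isfinite(mat)):
        raise ValueError("feature matrix must be complete (no missing values)")
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    Xs, center, scale, kept = _standardize(mat)
    dropped = [n for n, k in zip(names, kept) if not k]
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    inter, coefs = _fit_path(Xs[:, kept], y, np.array([lambda_]), tol=tol, max_iter=max_iter)
    coef_full = np.zeros(len(names))
    coef_full[kept] = coefs[0]
    return SignatureModel(
        features=names,
        center=center,
        scale=scale,
        coef=coef_full,
        intercept=float(inter[0]),
        lambda_=float(lambda_),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# lambda selection by cross-validated Brier score
# ---------------------------------------------------------------------------


@dataclass
class CvLambdaResult:
    lambdas: np.ndarray
    cv_brier: np.ndarray
    lambda_min: float

    @property
    def index_min(self) -> int:
        return int(np.argmin(self.cv_brier))


def _lambda_grid(lmax: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def cv_lambda(
    X,
    y,
    n_folds: int = 5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> CvLambdaResult:
    """Choose lambda by stratified k-fold CV minimizing the Brier score.

    The grid is geometric over ``[lambda_max, lambda_min_ratio *
    lambda_max]`` with the all-zero boundary computed on the full data.
    Out-of-fold probabilities are pooled before scoring; ties on the
    minimum resolve to the largest (most parsimonious) lambda.
    """
    mat, _ = _as_matrix(X)
    y = np.asarray(y).astype(float)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold CV impossible with class counts {counts.tolist()}"
        )
    Xs_full, _, _, kept_full = _standardize(mat)
    if not kept_full.any():
        raise ValueError("all features are constant")
    lmax = lambda_max(Xs_full[:, kept_full], y)
    lambdas = _lambda_grid(lmax, n_lambda, lambda_min_ratio)

    oof = np.full((len(y), n_lambda), np.nan)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    for tr, te in skf.split(mat, y):
        Xs_tr, center, scale, kept = _standardize(mat[tr])
        inter, coefs = _fit_path(Xs_tr[:, kept], y[tr], lambdas, tol=tol, max_iter=max_iter)
        Xs_te = ((mat[te] - center) / scale)[:, kept]
        oof[te, :] = expit(Xs_te @ coefs.T + inter[None, :])
    cv_brier = np.mean((oof - y[:, None]) ** 2, axis=0)
    return CvLambdaResult(
        lambdas=lambdas,
        cv_brier=cv_brier,
        lambda_min=float(lambdas[int(np.argmin(cv_brier))]),
    )


# ---------------------------------------------------------------------------
# bootstrap enhancement
# ---------------------------------------------------------------------------


@dataclass
class BootstrapSummary:
    """Aggregate over resampling iterations.

    ``coef_matrix`` holds one row per iteration (standardized-scale
    coefficients, exact zeros for unselected features).  The AUC CI is a
    normal-theory 95% CI *of the mean* over iterations.
    """

    features: list[str]
    auc_values: np.ndarray
    coef_matrix: np.ndarray
    lambda_values: np.ndarray
    seed: int
    n_iter: int

    @property
    def selection_freq(self) -> pd.Series:
        freq = np.mean(self.coef_matrix != 0.0, axis=0)
        return pd.Series(freq, index=self.features, name="selection_freq")

    @property
    def mean_abs_coef(self) -> pd.Series:
        m = np.mean(np.abs(self.coef_matrix), axis=0)
        return pd.Series(m, index=self.features, name="mean_abs_coef")

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def auc_ci(self) -> tuple[float, float]:
        se = float(np.std(self.auc_values, ddof=1) / np.sqrt(len(self.auc_values)))
        m = self.mean_auc
        return (m - 1.96 * se, m + 1.96 * se)

    @property
    def auc_quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.auc_values, [25, 75])
        return (float(q1), float(q3))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "selection_freq": self.selection_freq,
                "mean_abs_coef": self.mean_abs_coef,
            }
        )


def bootstrap_lasso(
    X,
    y,
    n_iter: int = 2000,
    test_fraction: float = 1.0 / 3.0,
    n_folds: int = 5,
    seed: int = 0,
    resample_first: bool = False,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    fixed_lambda: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 2000,
    max_retries: int = 100,
) -> BootstrapSummary:
    """Repeated stratified 2:1 train/test resampling of the LASSO model.

    Each iteration draws a stratified random 2:1 split of the samples
    (with ``resample_first=True``, a bootstrap resample with replacement
    is drawn before splitting), re-optimizes lambda by CV on the training
    part (unless ``fixed_lambda`` is given), fits at the optimum, and
    records the test-set AUC and the coefficient vector.  Deterministic
    given ``seed``.
    """
    mat, names = _as_matrix(X)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(int(seed))
    n = len(y)
    p = mat.shape[1]
    aucs = np.empty(n_iter)
    lams = np.empty(n_iter)
    coefs = np.zeros((n_iter, p))
    for it in range(n_iter):
        for attempt in range(max_retries):
            it_seed = int(rng.integers(2**31 - 1))
            idx = np.arange(n)
            if resample_first:
                idx = rng.integers(0, n, size=n)
            try:
                tr, te = train_test_split(
                    idx,
                    test_size=test_fraction,
                    stratify=y[idx],
                    random_state=it_seed,
                )
            except ValueError:
                continue  # degenerate resample; redraw
            y_tr, y_te = y[tr], y[te]
            if len(np.unique(y_te)) < 2 or np.bincount(y_tr, minlength=2).min() < n_folds:
                continue
            break
        else:
            raise ValueError("could not draw a usable stratified split")
        X_tr, X_te = mat[tr], mat[te]
        if fixed_lambda is None:
            cv = cv_lambda(
                X_tr, y_tr, n_folds=n_folds, n_lambda=n_lambda,
                lambda_min_ratio=lambda_min_ratio, seed=it_seed,
                tol=tol, max_iter=max_iter,
            )
            lam = cv.lambda_min
        else:
            lam = float(fixed_lambda)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-in-split features
            model = logistic_lasso_fit(
                pd.DataFrame(X_tr, columns=names), y_tr, lam, tol=tol, max_iter=max_iter
            )
        probs = model.predict_proba(pd.DataFrame(X_te, columns=names))
        aucs[it] = auc(probs, y_te)
        lams[it] = lam
        coefs[it] = model.coef
    return BootstrapSummary(
        features=names,
        auc_values=aucs,
        coef_matrix=coefs,
        lambda_values=lams,
        seed=int(seed),
        n_iter=n_iter,
    )


def variable_importance(summary: BootstrapSummary, top_k: int | None = None) -> pd.DataFrame:
    """Rank features by selection frequency; ties broken by mean |coef|."""
    df = summary.to_frame()
    if len(df) == 0:
        raise ValueError("empty bootstrap summary")
    df = df.sort_values(
        by=["selection_freq", "mean_abs_coef"], ascending=[False, False], kind="mergesort"
    )
    if top_k is None:
        return df
    if top_k > len(df):
        warnings.warn(
            f"top_k={top_k} exceeds feature count {len(df)}; truncating", stacklevel=2
        )
        top_k = len(df)
    return df.head(max(top_k, 0))


def final_model_and_roc(
    X,
    y,
    lambda_: float | None = None,
    n_folds: int = 5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> tuple[SignatureModel, pd.DataFrame, float]:
    """Fit the final signature on all data and evaluate by resubstitution.

    If ``lambda_`` is None it is chosen by :func:`cv_lambda` on the full
    data.  Returns (model, ROC coordinate table, AUC); the ROC is computed
    from in-sample predicted probabilities, which is optimistic and is
    reported as such in the absence of an independent validation cohort.
    """
    y = np.asarray(y).astype(int)
    if lambda_ is None:
        lambda_ = cv_lambda(
            X, y, n_folds=n_folds, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio, seed=seed,
        ).lambda_min
    model = logistic_lasso_fit(X, y, lambda_, tol=tol, max_iter=max_iter)
    probs = model.predict_proba(X)
    fpr, tpr, thr = roc_curve(y, probs)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return model, roc, auc(probs, y)
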