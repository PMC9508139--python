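"""Variance of each metabolite explained by the species matrix.

Nested 10-fold cross-validated ridge regression: each outer fold is held out
once; the remaining nine folds are split into ten inner folds over which a
penalty grid is searched for the lambda with lowest mean inner validation MSE;
the model is refit on the nine folds at that lambda and scored on the hold-out
fold.  The reported "variance explained" is the mean hold-out r-squared,
r2 = 1 - SSE / SST with SST around the hold-out mean, so values can be
negative for metabolites the microbiota does not predict.

Predictors are standardized and the response centered with training-fold
statistics only (no leakage into validation or hold-out data).  The ridge
solution itself is the closed form on the standardized scale,
beta = (X'X + lambda I)^{-1} X'y with an unpenalized intercept; the grid
search evaluates all lambdas from one eigendecomposition of X'X per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RidgeGrid:
    """Penalty grid and fold counts for the nested search."""

    lambdas: tuple[float, ...] = tuple(np.logspace(-3, 5, 100))
    outer_folds: int = 10
    inner_folds: int = 10

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.size == 0 or np.any(lam <= 0):
            raise ValueError("penalty grid must be strictly positive")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("penalty grid must be strictly increasing")


@dataclass
class RidgeModel:
    coef: np.ndarray
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.x_mean) / self.x_scale
        return Xs @ self.coef + self.intercept


def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> RidgeModel:
    """Closed-form ridge fit with internal standardization.

    Columns of ``X`` are scaled to mean 0 / SD 1 (constant columns get unit
    scale and a zero coefficient) and ``y`` is centered, which makes the
    intercept unpenalized; coefficients solve (X'X + lambda I) beta = X'y on
    the standardized scale.
    """
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=0)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    Xs = (X - x_mean) / x_scale
    y_mean = y.mean()
    G = Xs.T @ Xs + lam * np.eye(X.shape[1])
    b = Xs.T @ (y - y_mean)
    coef = np.linalg.solve(G, b) if lam > 0 else np.linalg.lstsq(Xs, y - y_mean, rcond=None)[0]
    return RidgeModel(coef=coef, intercept=float(y_mean), x_mean=x_mean, x_scale=x_scale)


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, n_folds)]


def _grid_val_mse(
    X_tr: np.ndarray, y_tr: np.ndarray, X_va: np.ndarray, y_va: np.ndarray,
    lambdas: np.ndarray,
) -> np.ndarray:
    """Validation MSE for every lambda from one eigendecomposition.

    With X'X = V diag(d) V', the ridge coefficients for all lambdas are
    V diag(1/(d+lambda)) V' X'y, evaluated in one vectorized sweep.
    """
    x_mean = X_tr.mean(axis=0)
    x_scale = X_tr.std(axis=0, ddof=0)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    Xs = (X_tr - x_mean) / x_scale
    y_mean = y_tr.mean()
    d, V = np.linalg.eigh(Xs.T @ Xs)
    b = V.T @ (Xs.T @ (y_tr - y_mean))
    # coefficients for all lambdas: p x L
    B = V @ (b[:, None] / (d[:, None] + lambdas[None, :]))
    pred = ((X_va - x_mean) / x_scale) @ B + y_mean
    resid = pred - y_va[:, None]
    return np.mean(resid**2, axis=0)


@dataclass
class VarianceExplainedResult:
    """Nested-CV summary for one metabolite."""

    metabolite_id: str
    mse_train: float
    mse_test: float
    r2: float
    fold_lambdas: list[float] = field(default_factory=list)
    fold_r2: list[float] = field(default_factory=list)
    seed: int = 0


def nested_cv_r2(
    X: np.ndarray,
    y: np.ndarray,
    grid: RidgeGrid | None = None,
    seed: int = 0,
    metabolite_id: str = "",
    r2_kind: str = "one_minus_sse",
) -> VarianceExplainedResult:
    """Nested cross-validated ridge r-squared for one response.

    ``r2_kind`` selects the hold-out statistic: ``one_minus_sse`` (default,
    1 - SSE/SST on the hold-out fold) or ``squared_correlation`` (squared
    Pearson correlation of predictions and hold-out values).
    """
    grid = grid or RidgeGrid()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[mask], y[mask]
    n = y.shape[0]
    if n < 30:
        raise ValueError("nested CV requires at least 30 complete cases")
    if np.ptp(y) == 0:
        raise ValueError("constant response: variance explained undefined")
    lambdas = np.asarray(grid.lambdas, dtype=float)
    rng = np.random.default_rng(seed)
    outer = _fold_indices(n, grid.outer_folds, rng)

    mse_tr, mse_te, r2s, lam_stars = [], [], [], []
    for f, hold in enumerate(outer):
        train = np.concatenate([outer[g] for g in range(len(outer)) if g != f])
        Xt, yt = X[train], y[train]
        inner = _fold_indices(len(train), grid.inner_folds, rng)
        inner_mse = np.zeros(lambdas.shape[0])
        for g, val in enumerate(inner):
            tr = np.concatenate([inner[h] for h in range(len(inner)) if h != g])
            inner_mse += _grid_val_mse(Xt[tr], yt[tr], Xt[val], yt[val], lambdas)
        lam_star = float(lambdas[int(np.argmin(inner_mse / len(inner)))])
        lam_stars.append(lam_star)

        model = ridge_fit(Xt, yt, lam_star)
        pred_tr = model.predict(Xt)
        pred_ho = model.predict(X[hold])
        y_ho = y[hold]
        mse_tr.append(float(np.mean((pred_tr - yt) ** 2)))
        mse_te.append(float(np.mean((pred_ho - y_ho) ** 2)))
        sst = float(np.sum((y_ho - y_ho.mean()) ** 2))
        if r2_kind == "one_minus_sse":
            r2s.append(1.0 - float(np.sum((pred_ho - y_ho) ** 2)) / sst)
        elif r2_kind == "squared_correlation":
            c = np.corrcoef(pred_ho, y_ho)[0, 1]
            r2s.append(float(c**2) if np.isfinite(c) else 0.0)
        else:
            raise ValueError(f"unknown r2_kind {r2_kind!r}")

    return VarianceExplainedResult(
        metabolite_id=metabolite_id,
        mse_train=float(np.mean(mse_tr)),
        mse_test=float(np.mean(mse_te)),
        r2=float(np.mean(r2s)),
        fold_lambdas=lam_stars,
        fold_r2=r2s,
        seed=seed,
    )


def variance_explained_screen(
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    grid: RidgeGrid | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Nested-CV variance explained for every (non-constant) outcome column."""
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(outcomes.shape[1])
    Xv = X.to_numpy(dtype=float)
    for j, m in enumerate(outcomes.columns):
        y = outcomes[m].to_numpy(dtype=float)
        try:
            res = nested_cv_r2(
                Xv, y, grid=grid, seed=int(child_seeds[j] % (2**31)), metabolite_id=m
            )
        except ValueError:
            continue
        rows.append(
            {
                "metabolite_id": m,
                "mse_train": res.mse_train,
                "mse_test": res.mse_test,
                "r2": res.r2,
                **{f"lambda_fold{i + 1}": l for i, l in enumerate(res.fold_lambdas)},
                "seed": res.seed,
            }
        )
    return pd.DataFrame(rows)
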