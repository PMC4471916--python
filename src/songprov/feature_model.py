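"""Feature selection and leave-one-out prediction of feeding rates.

The statistical chain: standardize the per-male predictor table (nine song
measures plus number of hatchlings and study year), shrink with an
L1-penalized least-squares path solved by cyclic coordinate descent, choose
the penalty by k-fold cross-validation, then predict each male's feeding
rate by epsilon-insensitive support-vector regression trained on the other
n-1 males, and evaluate predicted against observed rates with a
tie-corrected Spearman rank correlation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVR

from .errors import ConvergenceError, StatisticsError

#: The nine per-male song measures used as candidate predictors.
SONG_MEASURES = (
    "repertoire_size",
    "whistle_repertoire",
    "whistle_occurrence",
    "trill_repertoire",
    "trill_occurrence",
    "buzz_repertoire",
    "buzz_occurrence",
    "average_shortest_path",
    "transitivity",
)
COVARIATES = ("n_hatchlings", "year")
RESPONSE = "median_feeding_rate"


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingRecord:
    """Per-column centre/scale used to standardize; allows back-transform."""

    center: dict[str, float]
    scale: dict[str, float]
    ddof: int
    dummy_columns: tuple[str, ...] = ()

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, c in self.center.items():
            out[col] = (out[col] - c) / self.scale[col]
        return out


def expand_year(df: pd.DataFrame, column: str = "year") -> pd.DataFrame:
    """Reference-coded indicator columns for the year factor.

    The first (sorted) level is the reference; each remaining level gets a
    0/1 column ``year_<level>``.
    """
    if column not in df.columns:
        return df.copy()
    levels = sorted(pd.unique(df[column]))
    out = df.drop(columns=[column]).copy()
    for lev in levels[1:]:
        out[f"{column}_{lev}"] = (df[column] == lev).astype(float)
    return out


def standardize(
    df: pd.DataFrame,
    columns: Sequence[str] | None = None,
    ddof: int = 1,
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Centre to mean 0 and scale to SD 1 (sample SD by default).

    A categorical ``year`` column is first expanded into reference-coded
    indicators, which are then standardized and penalized like any other
    predictor.  A zero-variance column raises an error naming it.
    """
    if len(df) < 2:
        raise StatisticsError("standardize needs >= 2 rows")
    dummies: tuple[str, ...] = ()
    if "year" in df.columns and (columns is None or "year" in columns):
        before = set(df.columns)
        df = expand_year(df)
        dummies = tuple(sorted(set(df.columns) - before))
        if columns is not None:
            columns = [c for c in columns if c != "year"] + list(dummies)
    cols = list(columns) if columns is not None else [
        c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
    ]
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    out = df.copy()
    for col in cols:
        x = df[col].to_numpy(dtype=float)
        mu = float(x.mean())
        sd = float(x.std(ddof=ddof))
        if sd == 0.0:
            raise StatisticsError(f"predictor {col!r} has zero variance")
        center[col] = mu
        scale[col] = sd
        out[col] = (x - mu) / sd
    return out, ScalingRecord(center=center, scale=scale, ddof=ddof, dummy_columns=dummies)


# ---------------------------------------------------------------------------
# LASSO by cyclic coordinate descent
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LassoFit:
    lam: float
    coef: dict[str, float]
    intercept: float
    n_iter: int

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.coef.items() if v != 0.0)


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _cd_sweeps(Xc, yc, col_sq, beta, lam, tol, max_iter):
    """Cyclic soft-threshold sweeps on centred data; mutates ``beta`` in place.

    Returns the sweep count on convergence, -1 on failure.  Kept free of
    Python objects so it can be numba-compiled (see below).
    """
    n, p = Xc.shape
    r = yc - Xc @ beta
    for sweep in range(1, max_iter + 1):
        delta = 0.0
        for j in range(p):
            cj = col_sq[j]
            if cj == 0.0:
                continue
            b_old = beta[j]
            rho = 0.0
            for i in range(n):
                rho += Xc[i, j] * r[i]
            rho = rho / n + cj * b_old
            if rho > lam:
                b_new = (rho - lam) / cj
            elif rho < -lam:
                b_new = (rho + lam) / cj
            else:
                b_new = 0.0
            if b_new != b_old:
                d = b_old - b_new
                for i in range(n):
                    r[i] += Xc[i, j] * d
                beta[j] = b_new
                change = b_new - b_old
                if change < 0.0:
                    change = -change
                if change > delta:
                    delta = change
        if delta < tol:
            return sweep
    return -1


try:  # the jitted kernel cuts path solves from seconds to milliseconds
    from numba import njit

    _cd_sweeps = njit(cache=False)(_cd_sweeps)  # type: ignore[assignment]
except ImportError:  # pragma: no cover - numba is normally available
    pass


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with an all-zero solution: max_j |x_j' (y - ybar)| / n."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)) / n)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta_init: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, float, int]:
    """Solve min_b (1/2n)||y - b0 - X b||^2 + lam * ||b||_1.

    Cyclic soft-threshold coordinate updates on mean-centred data until the
    largest coefficient change in a sweep falls below ``tol``.  The
    intercept is unpenalized.  Returns (beta, intercept, sweeps).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    col_sq = (Xc ** 2).sum(axis=0) / n

    beta = np.zeros(p) if beta_init is None else beta_init.astype(float).copy()
    sweeps = _cd_sweeps(
        np.ascontiguousarray(Xc), yc, col_sq, beta, float(lam), tol, max_iter
    )
    if sweeps < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge at lambda={lam:g} "
            f"after {max_iter} sweeps"
        )
    intercept = float(y_mean - x_mean @ beta)
    return beta, intercept, int(sweeps)


def default_lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_lambdas: int = 100,
    min_ratio: float = 1e-4,
) -> np.ndarray:
    """Log-spaced grid from lambda_max down to lambda_max * min_ratio."""
    lmax = lambda_max(X, y)
    if lmax == 0.0:
        return np.zeros(1)
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: Sequence[float] | None = None,
    feature_names: Sequence[str] | None = None,
    n_lambdas: int = 100,
    min_ratio: float = 1e-4,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> list[LassoFit]:
    """Solution path along a decreasing lambda grid with warm starts."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if lambdas is None:
        lambdas = default_lambda_grid(X, y, n_lambdas=n_lambdas, min_ratio=min_ratio)
    lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=float)
    fits: list[LassoFit] = []
    beta = np.zeros(p)
    for lam in lambdas:
        beta, intercept, n_iter = lasso_fit(
            X, y, float(lam), beta_init=beta, tol=tol, max_iter=max_iter
        )
        fits.append(
            LassoFit(
                lam=float(lam),
                coef={name: float(b) for name, b in zip(feature_names, beta)},
                intercept=intercept,
                n_iter=n_iter,
            )
        )
    return fits


def lasso_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, intercept: float, lam: float) -> float:
    n = X.shape[0]
    resid = y - intercept - X @ beta
    return float(resid @ resid / (2 * n) + lam * np.abs(beta).sum())


# ---------------------------------------------------------------------------
# penalty selection by cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    lam: float
    rule: str
    selected: tuple[str, ...]  # ordered by |coefficient| descending
    coef: dict[str, float]
    intercept: float
    cv_table: pd.DataFrame = field(repr=False)


def _cv_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [fold for fold in np.array_split(idx, n_folds)]


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    rule: str = "min",
    n_folds: int = 5,
    seed: int | np.random.Generator = 0,
    n_lambdas: int = 100,
    min_ratio: float = 1e-4,
) -> SelectionResult:
    """Choose lambda by k-fold CV mean squared error and return the non-zero set.

    ``rule="min"`` takes the lambda minimising mean CV error; ``rule="1se"``
    the largest lambda within one standard error of that minimum.  Selected
    predictors are ordered by absolute coefficient, descending.  An empty
    selection is a valid outcome (warned, not an error).
    """
    if rule not in ("min", "1se"):
        raise ValueError(f"unknown rule {rule!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    lambdas = default_lambda_grid(X, y, n_lambdas=n_lambdas, min_ratio=min_ratio)
    folds = _cv_folds(n, n_folds, rng)
    errors = np.full((len(folds), len(lambdas)), np.nan)
    for i, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            continue
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        fits = lasso_path(X[mask], y[mask], lambdas=lambdas, feature_names=feature_names)
        for k, fit in enumerate(fits):
            beta = np.array([fit.coef[name] for name in feature_names])
            pred = fit.intercept + X[test_idx] @ beta
            errors[i, k] = float(np.mean((y[test_idx] - pred) ** 2))
    mean_err = np.nanmean(errors, axis=0)
    k_folds_eff = np.sum(~np.isnan(errors), axis=0)
    se_err = np.nanstd(errors, axis=0, ddof=1) / np.sqrt(k_folds_eff)
    k_min = int(np.argmin(mean_err))
    if rule == "min":
        k_best = k_min
    else:
        threshold = mean_err[k_min] + se_err[k_min]
        # lambdas are sorted decreasing: first index within threshold
        k_best = int(np.nonzero(mean_err <= threshold)[0][0])
    lam = float(lambdas[k_best])
    beta, intercept, _ = lasso_fit(X, y, lam)
    coef = {name: float(b) for name, b in zip(feature_names, beta)}
    selected = tuple(
        sorted((k for k, v in coef.items() if v != 0.0), key=lambda k: -abs(coef[k]))
    )
    if not selected:
        warnings.warn("LASSO selected no predictors at the CV-chosen lambda", stacklevel=2)
    cv_table = pd.DataFrame(
        {"lambda": lambdas, "cv_mse": mean_err, "cv_se": se_err}
    )
    return SelectionResult(
        lam=lam,
        rule=rule,
        selected=selected,
        coef=coef,
        intercept=intercept,
        cv_table=cv_table,
    )


# ---------------------------------------------------------------------------
# support-vector regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SvmParams:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | None = None  # None -> 1 / n_predictors
    epsilon: float = 0.1

    def make(self, n_features: int) -> SVR:
        gamma = self.gamma if self.gamma is not None else 1.0 / n_features
        return SVR(kernel=self.kernel, C=self.C, gamma=gamma, epsilon=self.epsilon)


def svm_regress(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    params: SvmParams = SvmParams(),
) -> np.ndarray:
    """Epsilon-insensitive SVR prediction for ``X_test``.

    Inputs are used as-is; standardize predictors (and, in the LOO driver,
    the response) before calling.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    model = params.make(X_train.shape[1])
    model.fit(X_train, np.asarray(y_train, dtype=float))
    return model.predict(X_test)


# ---------------------------------------------------------------------------
# leave-one-out prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LooPrediction:
    table: pd.DataFrame  # index: male id; columns: observed, predicted
    predictors: tuple[str, ...] | None
    params: SvmParams
    mode: str

    @property
    def observed(self) -> np.ndarray:
        return self.table["observed"].to_numpy()

    @property
    def predicted(self) -> np.ndarray:
        return self.table["predicted"].to_numpy()


def loo_predict(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str = RESPONSE,
    params: SvmParams = SvmParams(),
    selector: Callable[[pd.DataFrame], Sequence[str]] | None = None,
) -> LooPrediction:
    """Predict each row's response from a model trained on the other rows.

    For every round: the held-out row is removed, predictors and the
    response are re-standardized on the remaining rows only, an SVR is
    fitted and the held-out male's rate predicted on the original scale.
    If ``selector`` is given it is called on each round's training table to
    re-select predictors inside the round (full refit, no leakage);
    otherwise the fixed ``predictors`` are used in every round.
    """
    if len(table) < 3:
        raise StatisticsError("leave-one-out prediction needs >= 3 rows")
    preds_out = []
    for i in range(len(table)):
        train = table.drop(table.index[i])
        test = table.iloc[[i]]
        cols = list(selector(train)) if selector is not None else list(predictors)
        if not cols:
            # no predictors survive selection: fall back to the train mean
            preds_out.append(float(train[response].mean()))
            continue
        std_train, scaling = standardize(train[cols], columns=cols)
        y = train[response].to_numpy(dtype=float)
        y_mu, y_sd = float(y.mean()), float(y.std(ddof=1))
        if y_sd == 0.0:
            preds_out.append(y_mu)
            continue
        x_test = scaling.transform(test[cols])[list(scaling.center)].to_numpy(dtype=float)
        z = svm_regress(
            std_train[list(scaling.center)].to_numpy(dtype=float),
            (y - y_mu) / y_sd,
            x_test,
            params=params,
        )
        preds_out.append(float(z[0]) * y_sd + y_mu)
    out = pd.DataFrame(
        {"observed": table[response].to_numpy(dtype=float), "predicted": preds_out},
        index=table.index,
    )
    return LooPrediction(
        table=out,
        predictors=None if selector is not None else tuple(predictors),
        params=params,
        mode="refit" if selector is not None else "fixed",
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationResult:
    spearman_rho: float
    p_value: float
    n: int
    method: str


def spearman(
    predicted: Sequence[float],
    observed: Sequence[float],
    method: str = "t",
) -> EvaluationResult:
    """Tie-corrected Spearman rank correlation with a two-tailed p-value.

    ``method="t"`` uses the t approximation on n-2 df; ``method="exact"``
    enumerates all rank permutations (only feasible for n <= 8).
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise StatisticsError("Spearman correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatisticsError("Spearman correlation undefined for a constant vector")
    rx = sps.rankdata(x)  # midranks for ties
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 8:
            raise StatisticsError("exact permutation p-value limited to n <= 8")
        count = 0
        total = 0
        target = abs(rho)
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            if abs(r) >= target - 1e-12:
                count += 1
            total += 1
        p = count / total
    elif method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = float(2 * sps.t.sf(abs(t), n - 2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return EvaluationResult(spearman_rho=rho, p_value=p, n=n, method=method)
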