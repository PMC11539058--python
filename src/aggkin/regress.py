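"""Regression model building for aggregation kinetics.

Two model families are implemented from first principles behind a
statsmodels-style interface: ordinary least squares (multiple linear
regression, MLR) and NIPALS partial least squares (PLS).  A model object is
constructed from the response and the feature matrix; ``fit()`` returns a
results object carrying coefficients on the original feature scale,
training diagnostics, prediction, and a ``summary()`` table.

Cross-validation utilities (seeded k-fold splitting, per-fold refitting
with leakage-free standardization, fold-number sensitivity against the
LOOCV baseline) and a stability-aware model-selection rule complete the
model-building stage.

Features are z-scored internally before fitting; in cross-validation the
standardization parameters are learned on each training fold only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MLRModel",
    "PLSModel",
    "RegressionResults",
    "CVReport",
    "ModelSpec",
    "ModelSelectionReport",
    "metrics",
    "kfold_split",
    "cross_validate",
    "k_sensitivity",
    "select_model",
    "loocv_ols_closed_form",
    "SKLEARN_CANDIDATES",
]


def metrics(y, y_pred) -> dict[str, float]:
    """Mean squared error and coefficient of determination.

    R^2 = 1 - SS_res / SS_tot; MSE is the mean (not sum) of squared
    residuals.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    resid = y - y_pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return {"mse": float(np.mean(resid ** 2)), "r2": r2}


def _as_matrix(X, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(X.shape[1])]
    return X, list(feature_names)


class _BaseModel:
    """Shared construction and standardization for the regression models."""

    kind = "base"

    def __init__(self, endog, exog, feature_names=None):
        self.exog, self.feature_names = _as_matrix(exog, feature_names)
        self.endog = np.asarray(endog, dtype=float).ravel()
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        self.nobs, self.nfeat = self.exog.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       features: list[str] | None = None, **kwargs):
        """Build a model from a tidy table with a named response column."""
        if features is None:
            features = [c for c in df.columns if c != response]
        return cls(df[response], df[features], **kwargs)

    def _standardize(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mu = self.exog.mean(axis=0)
        sd = self.exog.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [n for n, s in zip(self.feature_names, sd) if s == 0]
            raise ValueError(f"zero-variance feature columns: {bad}")
        return (self.exog - mu) / sd, mu, sd


@dataclass
class RegressionResults:
    """Fitted-model container: coefficients on the original feature scale,
    standardization metadata, and training diagnostics."""

    kind: str
    params: pd.Series               # per-feature coefficients, original scale
    intercept: float
    feature_names: list[str]
    nobs: int
    rsquared: float
    mse: float
    standardization: dict           # {"mean": [...], "scale": [...]}
    n_components: int | None = None
    extra: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        """Predict the response for new rows (DataFrame columns are aligned
        to the training feature names; a plain array must match the order)."""
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, got "
                    f"{X.shape[1]}"
                )
        return X @ self.params.to_numpy() + self.intercept

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.extra["fittedvalues"]

    @property
    def resid(self) -> np.ndarray:
        return self.extra["resid"]

    def summary(self) -> str:
        lines = [
            f"{'PLS' if self.kind == 'pls' else 'MLR'} regression results",
            "=" * 46,
            f"{'No. observations:':<24}{self.nobs:>22}",
            f"{'No. features:':<24}{len(self.feature_names):>22}",
        ]
        if self.kind == "pls":
            lines.append(f"{'No. components:':<24}{self.n_components:>22}")
        lines += [
            f"{'R-squared (train):':<24}{self.rsquared:>22.4f}",
            f"{'MSE (train):':<24}{self.mse:>22.4f}",
            "-" * 46,
            f"{'feature':<30}{'coef':>16}",
            "-" * 46,
            f"{'(intercept)':<30}{self.intercept:>16.4f}",
        ]
        for name, c in self.params.items():
            lines.append(f"{name:<30}{c:>16.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "coefficients": self.params.to_dict(),
            "intercept": self.intercept,
            "nobs": self.nobs,
            "rsquared": self.rsquared,
            "mse": self.mse,
            "standardization": self.standardization,
            "n_components": self.n_components,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RegressionResults":
        d = json.loads(text)
        params = pd.Series({k: d["coefficients"][k]
                            for k in d["feature_names"]})
        return cls(kind=d["kind"], params=params, intercept=d["intercept"],
                   feature_names=d["feature_names"], nobs=d["nobs"],
                   rsquared=d["rsquared"], mse=d["mse"],
                   standardization=d["standardization"],
                   n_components=d.get("n_components"))


class MLRModel(_BaseModel):
    """Multiple linear regression fitted by a QR decomposition.

    Requires more observations than features and a full-column-rank design;
    collinear columns are reported by name.
    """

    kind = "ols"

    def fit(self) -> RegressionResults:
        if self.nobs <= self.nfeat:
            raise ValueError(
                f"OLS needs n > p (n={self.nobs}, p={self.nfeat})"
            )
        Z, mu, sd = self._standardize()
        y = self.endog
        A = np.column_stack([np.ones(self.nobs), Z])
        q, r = np.linalg.qr(A)
        diag = np.abs(np.diag(r))
        tol = max(A.shape) * np.finfo(float).eps * diag.max()
        if np.any(diag < tol):
            bad_idx = [i - 1 for i in np.nonzero(diag < tol)[0] if i > 0]
            bad = [self.feature_names[i] for i in bad_idx]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")
        beta = np.linalg.solve(r, q.T @ y)
        coef_std = beta[1:]
        coef = coef_std / sd
        intercept = float(beta[0] - np.sum(coef * mu))
        fitted = A @ beta
        m = metrics(y, fitted)
        return RegressionResults(
            kind=self.kind,
            params=pd.Series(coef, index=self.feature_names),
            intercept=intercept,
            feature_names=self.feature_names,
            nobs=self.nobs,
            rsquared=m["r2"],
            mse=m["mse"],
            standardization={"mean": mu.tolist(), "scale": sd.tolist()},
            extra={"fittedvalues": fitted, "resid": y - fitted},
        )


class PLSModel(_BaseModel):
    """Partial least squares regression fitted by the NIPALS algorithm.

    Per component: weight w proportional to X'y (unit norm), score t = Xw,
    X-loading p = X't/(t't), y-loading q = y't/(t't), then X and y are
    deflated.  X is z-scored and y centred internally; coefficients are
    back-transformed to the original scale.  When ``n_components`` is None
    it is chosen by an inner 5-fold cross-validation minimising MSE.
    """

    kind = "pls"

    def __init__(self, endog, exog, feature_names=None,
                 n_components: int | None = None,
                 inner_cv_seed: int = 0):
        super().__init__(endog, exog, feature_names)
        self.n_components = n_components
        self.inner_cv_seed = inner_cv_seed

    def _max_components(self) -> int:
        return max(1, min(self.nobs - 1, self.nfeat))

    def fit(self) -> RegressionResults:
        n_comp = self.n_components
        if n_comp is None:
            n_comp = self._choose_components()
        if not 1 <= n_comp <= self._max_components():
            raise ValueError(
                f"n_components must be in [1, {self._max_components()}], "
                f"got {n_comp}"
            )
        Z, mu, sd = self._standardize()
        y = self.endog
        y_mean = y.mean()
        coef_std, W, P, Q, used = _nipals(Z, y - y_mean, n_comp)
        coef = coef_std / sd
        intercept = float(y_mean - np.sum(coef * mu))
        fitted = self.exog @ coef + intercept
        m = metrics(y, fitted)
        return RegressionResults(
            kind=self.kind,
            params=pd.Series(coef, index=self.feature_names),
            intercept=intercept,
            feature_names=self.feature_names,
            nobs=self.nobs,
            rsquared=m["r2"],
            mse=m["mse"],
            standardization={"mean": mu.tolist(), "scale": sd.tolist()},
            n_components=used,
            extra={"fittedvalues": fitted, "resid": y - fitted,
                   "weights": W, "x_loadings": P, "y_loadings": Q},
        )

    def _choose_components(self) -> int:
        """Inner 5-fold CV over 1..max components, minimising mean MSE."""
        kmax = self._max_components()
        k_inner = min(5, self.nobs)
        folds = kfold_split(self.nobs, k_inner, seed=self.inner_cv_seed)
        best, best_mse = 1, np.inf
        for nc in range(1, kmax + 1):
            errs = []
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(self.nobs), test_idx)
                if train_idx.size <= nc:
                    errs.append(np.inf)
                    continue
                try:
                    res = PLSModel(self.endog[train_idx],
                                   self.exog[train_idx],
                                   self.feature_names,
                                   n_components=nc).fit()
                except ValueError:
                    errs.append(np.inf)
                    continue
                pred = res.predict(self.exog[test_idx])
                errs.append(metrics(self.endog[test_idx], pred)["mse"])
            mse = float(np.mean(errs))
            if mse < best_mse - 1e-12:
                best, best_mse = nc, mse
        logger.info("inner CV selected %d PLS component(s)", best)
        return best


def _nipals(X: np.ndarray, y: np.ndarray, n_components: int,
            tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                         np.ndarray, int]:
    """NIPALS PLS1.  Returns (coefficients on the standardized scale,
    weights W, X-loadings P, y-loadings q, components actually used)."""
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    used = 0
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < tol:
            logger.info("NIPALS: X'y vanished after %d component(s)", a)
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < tol:
            break
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p_a)
        yd = yd - q_a * t
        W[:, a] = w
        P[:, a] = p_a
        q[a] = q_a
        used = a + 1
    if used == 0:
        raise ValueError("degenerate PLS: X'y is zero at the first component")
    W, P, q = W[:, :used], P[:, :used], q[:used]
    # beta = W (P'W)^-1 q  maps standardized X to centred y
    beta = W @ np.linalg.solve(P.T @ W, q)
    return beta, W, P, q, used


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVReport:
    """Per-fold test MSEs and their summary statistics for one model/k."""

    model: str
    k: int
    seed: int
    fold_mses: list[float]
    evaluation_r2: float

    def __post_init__(self) -> None:
        if len(self.fold_mses) != self.k:
            raise ValueError("one MSE per fold required")

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.fold_mses))

    @property
    def max_mse(self) -> float:
        return float(np.max(self.fold_mses))

    @property
    def std_mse(self) -> float:
        """Sample standard deviation (ddof=1) of the fold MSEs."""
        if len(self.fold_mses) < 2:
            return 0.0
        return float(np.std(self.fold_mses, ddof=1))

    def to_dict(self) -> dict:
        return {
            "model": self.model, "k": self.k, "seed": self.seed,
            "fold_mses": [float(m) for m in self.fold_mses],
            "mean_mse": self.mean_mse, "max_mse": self.max_mse,
            "std_mse": self.std_mse, "evaluation_r2": self.evaluation_r2,
        }


@dataclass(frozen=True)
class ModelSpec:
    """A fit-from-scratch recipe used inside cross-validation folds."""

    kind: str                      # "ols" | "pls" | sklearn candidate name
    name: str | None = None
    kwargs: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.name or self.kind

    def build(self, y: np.ndarray, X: np.ndarray,
              feature_names: list[str]):
        if self.kind == "ols":
            return MLRModel(y, X, feature_names, **self.kwargs)
        if self.kind == "pls":
            return PLSModel(y, X, feature_names, **self.kwargs)
        if self.kind == "mean":
            return _MeanModel(y)
        if self.kind in SKLEARN_CANDIDATES:
            return _SklearnAdapter(self.kind, y, X, feature_names,
                                   **self.kwargs)
        raise ValueError(f"unknown model kind {self.kind!r}")


#: Comparison candidates delegated to scikit-learn (no from-scratch
#: guarantee; surfaced in CV reports only).
SKLEARN_CANDIDATES = ("svr", "tree", "forest")


class _MeanModel:
    """Intercept-only baseline: predicts the training mean everywhere."""

    def __init__(self, endog):
        self.endog = np.asarray(endog, dtype=float).ravel()

    def fit(self):
        mean = float(self.endog.mean())

        class _Res:
            def predict(self, X):
                X = np.asarray(X, dtype=float)
                n = X.shape[0] if X.ndim > 1 else 1
                return np.full(n, mean)

        return _Res()


class _SklearnAdapter:
    """Thin adapter so established SVR/tree/forest implementations can enter
    the CV comparison alongside the native models."""

    def __init__(self, kind: str, endog, exog, feature_names=None, seed=0,
                 **kwargs):
        self.kind = kind
        self.exog, self.feature_names = _as_matrix(exog, feature_names)
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.seed = seed
        self.kwargs = kwargs

    def fit(self):
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVR
        from sklearn.tree import DecisionTreeRegressor

        if self.kind == "svr":
            est = make_pipeline(StandardScaler(), SVR(**self.kwargs))
        elif self.kind == "tree":
            est = DecisionTreeRegressor(random_state=self.seed, **self.kwargs)
        else:
            est = RandomForestRegressor(random_state=self.seed, **self.kwargs)
        est.fit(self.exog, self.endog)

        class _Res:
            def __init__(self, est, names):
                self._est = est
                self.feature_names = names

            def predict(self, X):
                if isinstance(X, pd.DataFrame):
                    X = X[self.feature_names].to_numpy(dtype=float)
                return self._est.predict(np.asarray(X, dtype=float))

        return _Res(est, self.feature_names)


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded partition of ``range(n)`` into k disjoint exhaustive folds with
    sizes differing by at most one.  ``k = n`` gives leave-one-out."""
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def cross_validate(spec: ModelSpec, X, y, k: int, seed: int) -> CVReport:
    """k-fold cross-validation with the model refitted from scratch per fold.

    Standardization (and any other fitted state) is learned on the training
    fold only.  ``evaluation_r2`` is the R^2 of the pooled out-of-fold
    predictions against the full response.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    folds = kfold_split(n, k, seed)
    oof = np.full(n, np.nan)
    fold_mses = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = spec.build(yv[train_idx], Xm[train_idx], names)
        res = model.fit()
        pred = res.predict(Xm[test_idx])
        oof[test_idx] = pred
        fold_mses.append(metrics(yv[test_idx], pred)["mse"])
    r2 = metrics(yv, oof)["r2"]
    return CVReport(model=spec.label, k=k, seed=seed,
                    fold_mses=fold_mses, evaluation_r2=r2)


def k_sensitivity(spec: ModelSpec, X, y, k_range=range(2, 32),
                  seed: int = 0) -> tuple[pd.DataFrame, int]:
    """Mean CV MSE as a function of the fold number, against the LOOCV
    baseline.

    Returns the table (one row per k plus a LOOCV row) and the recommended
    k: the one whose mean MSE lies closest to the LOOCV baseline (ties go
    to the smaller k).  k values exceeding n are skipped.
    """
    Xm, _ = _as_matrix(X)
    n = Xm.shape[0]
    loocv = cross_validate(spec, X, y, n, seed)
    rows = []
    for k in k_range:
        if k > n:
            continue
        rep = cross_validate(spec, X, y, k, seed)
        rows.append({"k": k, "mean_mse": rep.mean_mse,
                     "max_mse": rep.max_mse, "std_mse": rep.std_mse,
                     "evaluation_r2": rep.evaluation_r2})
    if not rows:
        raise ValueError("k_range contains no feasible fold numbers")
    table = pd.DataFrame(rows)
    table["abs_diff_to_loocv"] = (table["mean_mse"] - loocv.mean_mse).abs()
    # smallest k among those within numerical noise of the best agreement
    min_diff = table["abs_diff_to_loocv"].min()
    near = table[table["abs_diff_to_loocv"] <= min_diff + 1e-12]
    best = int(near["k"].min())
    loocv_row = pd.DataFrame(
        [{"k": n, "mean_mse": loocv.mean_mse, "max_mse": loocv.max_mse,
          "std_mse": loocv.std_mse, "evaluation_r2": loocv.evaluation_r2,
          "abs_diff_to_loocv": 0.0}]
    )
    loocv_row.index = ["loocv"]
    table.index = [str(k) for k in table["k"]]
    return pd.concat([table, loocv_row]), best


def loocv_ols_closed_form(X, y) -> float:
    """Leave-one-out mean squared error of OLS via the hat-matrix identity.

    e_i / (1 - h_ii) gives the deleted residual without refitting; used as
    the independent check of fold-based LOOCV.  Standardization of X does
    not change OLS predictions, so the identity applies directly on the
    intercept-augmented design.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    A = np.column_stack([np.ones(Xm.shape[0]), Xm])
    H = A @ np.linalg.solve(A.T @ A, A.T)
    resid = yv - H @ yv
    h = np.diag(H)
    loo = resid / (1.0 - h)
    return float(np.mean(loo ** 2))


# ---------------------------------------------------------------------------
# model selection

@dataclass
class ModelSelectionReport:
    """Ranking of CV candidates under the stability-aware default rule."""

    selected: str
    ranking: pd.DataFrame
    excluded_for_instability: list[str]
    rule: str


def select_model(cv_reports: list[CVReport],
                 rule=None) -> ModelSelectionReport:
    """Select a model from cross-validation reports.

    Default rule: candidates whose fold-MSE standard deviation exceeds the
    median across candidates are excluded as unstable; among the remainder
    the lowest mean MSE wins (ties resolved by input order, logged).  A
    custom ``rule`` callable taking the ranking DataFrame and returning a
    model label may be supplied.
    """
    if not cv_reports:
        raise ValueError("empty candidate set")
    rows = [{"model": r.model, "k": r.k, "mean_mse": r.mean_mse,
             "max_mse": r.max_mse, "std_mse": r.std_mse,
             "evaluation_r2": r.evaluation_r2} for r in cv_reports]
    ranking = pd.DataFrame(rows)
    if rule is not None:
        return ModelSelectionReport(selected=rule(ranking), ranking=ranking,
                                    excluded_for_instability=[],
                                    rule="custom")
    med = ranking["std_mse"].median()
    stable = ranking[ranking["std_mse"] <= med]
    excluded = ranking.loc[~ranking.index.isin(stable.index), "model"].tolist()
    if stable.empty:
        stable = ranking
        excluded = []
    best_mse = stable["mean_mse"].min()
    winners = stable[stable["mean_mse"] == best_mse]
    if len(winners) > 1:
        logger.info("model-selection tie between %s; taking the first",
                    winners["model"].tolist())
    selected = str(winners.iloc[0]["model"])
    return ModelSelectionReport(
        selected=selected, ranking=ranking,
        excluded_for_instability=excluded,
        rule="std_mse <= median(std_mse), then min mean_mse",
    )
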