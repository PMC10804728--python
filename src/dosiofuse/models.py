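"""Six time-to-event models behind one fit/predict-risk contract.

Estimator classes follow scikit-learn conventions: hyperparameters are
constructor arguments, ``fit(X, y)`` learns from a feature table and a
survival outcome, ``predict(X)`` returns one risk score per row with the
orientation *higher score = higher hazard / shorter survival*, and fitted
attributes carry a trailing underscore.

``y`` may be a ``(time, event)`` tuple of arrays, a DataFrame with ``time``
and ``event`` columns, or a scikit-survival structured array.

Models
------
coxph     Cox proportional hazards (Efron ties), via lifelines.
coxboost  Componentwise likelihood-based boosting of the Cox model: each
          step updates only the covariate with the largest penalized
          partial-likelihood gain (ridge-penalized one-step Newton update).
glmboost  Gradient boosting with componentwise linear base learners on the
          Cox loss, via scikit-survival.
glmnet    Elastic-net penalized Cox, via scikit-survival's coxnet.
rsf       Random survival forest (log-rank splitting), via scikit-survival.
stree     Single survival tree, via scikit-survival.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sksurv.util import Surv

from .coxutils import cox_score_info_percov
from .metrics import harrell_cindex

__all__ = [
    "as_time_event", "CoxPH", "CoxBoost", "GLMBoost", "CoxNet",
    "RSFModel", "STreeModel", "MODEL_REGISTRY", "make_model",
    "fit_coxph", "fit_coxboost", "fit_glmboost", "fit_glmnet", "fit_rsf",
    "fit_stree", "predict_risk", "tune", "default_grid",
]


def as_time_event(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce any accepted outcome representation to (time, event) arrays."""
    if isinstance(y, tuple) and len(y) == 2:
        time, event = np.asarray(y[0], float), np.asarray(y[1], int)
    elif isinstance(y, pd.DataFrame):
        time, event = y["time"].to_numpy(float), y["event"].to_numpy(int)
    elif isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        event = y[names[0]].astype(int)
        time = y[names[1]].astype(float)
    else:
        raise TypeError(f"unsupported outcome type {type(y)}")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


def _check_X(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [str(c) for c in X.columns]
    if X.isna().any().any():
        raise ValueError("feature table contains NaN")
    return X


class _BaseSurvivalModel(BaseEstimator):
    """Shared fit/predict plumbing: schema checks and risk orientation."""

    name: str = ""

    def fit(self, X, y):
        X = _check_X(X)
        time, event = as_time_event(y)
        if event.sum() < 2:
            raise ValueError("need at least 2 events to fit a survival model")
        self.feature_names_ = list(X.columns)
        self._fit(X, time, event)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("model is not fitted")
        X = _check_X(X)
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        risk = np.asarray(self._predict(X[self.feature_names_]), dtype=float)
        if not np.all(np.isfinite(risk)):
            raise RuntimeError("non-finite risk scores")
        return risk

    def score(self, X, y) -> float:
        time, event = as_time_event(y)
        return harrell_cindex(self.predict(X), time, event)


class CoxPH(_BaseSurvivalModel):
    """Cox proportional hazards via partial-likelihood maximization (Efron)."""

    name = "coxph"

    def __init__(self, penalizer: float = 0.0):
        self.penalizer = penalizer

    def _fit(self, X, time, event):
        from lifelines import CoxPHFitter

        df = X.copy()
        df["_time"], df["_event"] = time, event
        fitter = CoxPHFitter(penalizer=self.penalizer)
        try:
            fitter.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:  # lifelines raises ConvergenceError
            raise RuntimeError(f"Cox PH fit failed: {exc}") from exc
        self.coef_ = fitter.params_.reindex(self.feature_names_).to_numpy()
        self.fitter_ = fitter

    def _predict(self, X):
        return X.to_numpy(float) @ self.coef_


class CoxBoost(_BaseSurvivalModel):
    """Componentwise likelihood-based boosting of the Cox model.

    At each of ``n_steps`` steps, every covariate's ridge-penalized one-step
    Newton update is evaluated at the current linear predictor; only the
    covariate with the largest penalized score statistic ``U^2 / (I + pen)``
    is updated by ``U / (I + pen)``. ``penalty=None`` uses the customary
    default of nine times the number of events.
    """

    name = "coxboost"

    def __init__(self, n_steps: int = 100, penalty: float | None = None):
        self.n_steps = n_steps
        self.penalty = penalty

    def _fit(self, X, time, event):
        if self.penalty is not None and self.penalty <= 0:
            raise ValueError("penalty must be positive")
        pen = self.penalty if self.penalty is not None else 9.0 * event.sum()
        Xv = X.to_numpy(float)
        n, p = Xv.shape
        beta = np.zeros(p)
        eta = np.zeros(n)
        path = [beta.copy()]
        for _ in range(self.n_steps):
            U, info = cox_score_info_percov(Xv, time, event, eta)
            gain = U**2 / (info + pen)
            j = int(np.argmax(gain))
            step = U[j] / (info[j] + pen)
            beta[j] += step
            eta += step * Xv[:, j]
            path.append(beta.copy())
        self.coef_ = beta
        self.coef_path_ = np.asarray(path)

    def _predict(self, X):
        return X.to_numpy(float) @ self.coef_


class GLMBoost(_BaseSurvivalModel):
    """Componentwise gradient boosting on the Cox loss (linear base learners)."""

    name = "glmboost"

    def __init__(self, mstop: int = 100, nu: float = 0.1):
        self.mstop = mstop
        self.nu = nu

    def _fit(self, X, time, event):
        if not (0 < self.nu <= 1):
            raise ValueError("learning rate nu must be in (0, 1]")
        if self.mstop == 0:
            self.coef_ = np.zeros(X.shape[1])
            self.est_ = None
            return
        from sksurv.ensemble import ComponentwiseGradientBoostingSurvivalAnalysis

        est = ComponentwiseGradientBoostingSurvivalAnalysis(
            loss="coxph", n_estimators=self.mstop, learning_rate=self.nu
        )
        est.fit(X.to_numpy(float), Surv.from_arrays(event.astype(bool), time))
        coef = np.asarray(est.coef_)
        self.intercept_ = coef[0]
        self.coef_ = coef[1:]
        self.est_ = est

    def _predict(self, X):
        return X.to_numpy(float) @ self.coef_


class CoxNet(_BaseSurvivalModel):
    """Elastic-net penalized Cox (glmnet-style).

    ``alpha`` is the l1/l2 mixing parameter in [0, 1] (1 = lasso) and
    ``lam`` the penalty strength. With ``lam=None`` a 50-knot path is fit
    and the knot at relative position ``lam_frac`` along it is used
    (0 = most penalized); tuning treats ``(alpha, lam_frac)`` as the grid.
    A pure ridge request (alpha=0) is mapped to a numerically tiny l1 ratio,
    which the coordinate-descent solver requires.
    """

    name = "glmnet"

    def __init__(self, alpha: float = 0.5, lam: float | None = None,
                 lam_frac: float = 0.5, n_lambdas: int = 50):
        self.alpha = alpha
        self.lam = lam
        self.lam_frac = lam_frac
        self.n_lambdas = n_lambdas

    def _fit(self, X, time, event):
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        l1_ratio = max(self.alpha, 1e-6)
        kwargs = dict(l1_ratio=l1_ratio, fit_baseline_model=False)
        if self.lam is not None:
            kwargs["alphas"] = [self.lam]
        else:
            kwargs["n_alphas"] = self.n_lambdas
        est = CoxnetSurvivalAnalysis(**kwargs)
        est.fit(X.to_numpy(float), Surv.from_arrays(event.astype(bool), time))
        coefs = est.coef_
        self.lambda_path_ = np.asarray(est.alphas_)
        if self.lam is not None:
            self.coef_ = coefs[:, 0]
            self.lambda_ = float(self.lam)
        else:
            # path knots are ordered most -> least penalized
            k = int(round(self.lam_frac * (coefs.shape[1] - 1)))
            self.coef_ = coefs[:, k]
            self.lambda_ = float(self.lambda_path_[k])
        self.null_model_ = bool(np.count_nonzero(self.coef_) == 0)
        self.est_ = est

    def _predict(self, X):
        return X.to_numpy(float) @ self.coef_


class RSFModel(_BaseSurvivalModel):
    """Random survival forest (log-rank splits, Nelson-Aalen leaf hazards)."""

    name = "rsf"

    def __init__(self, n_trees: int = 500, mtry: str | int = "sqrt",
                 node_size: int = 15, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.node_size = node_size
        self.seed = seed

    def _fit(self, X, time, event):
        from sksurv.ensemble import RandomSurvivalForest

        est = RandomSurvivalForest(
            n_estimators=self.n_trees,
            max_features=self.mtry,
            min_samples_leaf=self.node_size,
            random_state=self.seed,
            n_jobs=1,
        )
        est.fit(X.to_numpy(float), Surv.from_arrays(event.astype(bool), time))
        self.est_ = est

    def _predict(self, X):
        return self.est_.predict(X.to_numpy(float))

    def oob_cindex(self, X, y) -> float:
        """Out-of-bag concordance of the fitted forest."""
        time, event = as_time_event(y)
        return harrell_cindex(self.est_.predict(_check_X(X).to_numpy(float)), time, event)


class STreeModel(_BaseSurvivalModel):
    """Single survival tree (log-rank splitting)."""

    name = "stree"

    def __init__(self, depth: int = 3, minsplit: int = 20):
        self.depth = depth
        self.minsplit = minsplit

    def _fit(self, X, time, event):
        from sksurv.tree import SurvivalTree

        est = SurvivalTree(max_depth=self.depth, min_samples_split=self.minsplit)
        est.fit(X.to_numpy(float), Surv.from_arrays(event.astype(bool), time))
        if est.tree_.node_count <= 1:
            raise RuntimeError("no admissible split at the root")
        self.est_ = est

    def _predict(self, X):
        return self.est_.predict(X.to_numpy(float))


MODEL_REGISTRY: dict[str, type[_BaseSurvivalModel]] = {
    "coxph": CoxPH,
    "coxboost": CoxBoost,
    "glmboost": GLMBoost,
    "glmnet": CoxNet,
    "rsf": RSFModel,
    "stree": STreeModel,
}


def make_model(name: str, **params) -> _BaseSurvivalModel:
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_REGISTRY)}")
    return cls(**params)


# thin functional wrappers -------------------------------------------------

def fit_coxph(table, outcome, **kw):
    return CoxPH(**kw).fit(table, outcome)


def fit_coxboost(table, outcome, steps: int = 100, penalty: float | None = None):
    return CoxBoost(n_steps=steps, penalty=penalty).fit(table, outcome)


def fit_glmboost(table, outcome, mstop: int = 100, nu: float = 0.1):
    return GLMBoost(mstop=mstop, nu=nu).fit(table, outcome)


def fit_glmnet(table, outcome, alpha: float = 0.5, lam: float | None = None):
    return CoxNet(alpha=alpha, lam=lam).fit(table, outcome)


def fit_rsf(table, outcome, n_trees: int = 500, mtry="sqrt", node_size: int = 15, seed: int = 0):
    return RSFModel(n_trees=n_trees, mtry=mtry, node_size=node_size, seed=seed).fit(table, outcome)


def fit_stree(table, outcome, depth: int = 3, minsplit: int = 20):
    return STreeModel(depth=depth, minsplit=minsplit).fit(table, outcome)


def predict_risk(model: _BaseSurvivalModel, table) -> np.ndarray:
    """Risk scores for a fitted model; higher = higher hazard."""
    return model.predict(table)


# hyperparameter tuning ----------------------------------------------------

def default_grid(model_name: str, n_features: int) -> list[dict]:
    """Default tuning grids, ordered from most to least regularized so that
    C-index ties resolve toward the more regularized setting."""
    p = max(n_features, 2)
    if model_name == "coxph":
        return []
    if model_name == "coxboost":
        return [
            {"n_steps": s, "penalty": pen}
            for s in (50, 100, 200)
            for pen in (max(9 * (p - 1), 1), 100)
        ]
    if model_name == "glmboost":
        return [{"mstop": m, "nu": 0.1} for m in (50, 100, 250, 500)]
    if model_name == "glmnet":
        return [
            {"alpha": float(round(a, 1)), "lam_frac": f}
            for f in (0.2, 0.4, 0.6, 0.8)
            for a in np.arange(1.0, 0.05, -0.1)
        ]
    if model_name == "rsf":
        return [
            {"n_trees": t, "mtry": m, "node_size": ns}
            for t in (250, 500, 1000)
            for m in ("sqrt", max(p // 3, 1))
            for ns in (15, 5)
        ]
    if model_name == "stree":
        return [{"depth": d} for d in (2, 3, 4)]
    raise ValueError(f"unknown model {model_name!r}")


def _event_stratified_folds(event: np.ndarray, n_splits: int, seed: int,
                            max_attempts: int = 5):
    """3-fold split stratified by event status; refold if a fold lacks events."""
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros_like(event), event))
        if all(event[tr].sum() >= 2 and event[te].sum() >= 1 for tr, te in folds):
            return folds
    raise RuntimeError(f"could not build event-stratified folds in {max_attempts} attempts")


def tune(model_name: str, table, outcome, grid: list[dict] | None = None,
         seed: int = 0, n_splits: int = 3) -> dict:
    """Grid search by mean 3-fold cross-validated C-index.

    The grid is evaluated exhaustively; ties resolve toward the earlier
    (more regularized) grid entry. ``coxph`` has no hyperparameters and
    returns an empty dict without running CV.
    """
    if model_name == "coxph":
        return {}
    table = _check_X(table)
    time, event = as_time_event(outcome)
    if grid is None:
        grid = default_grid(model_name, table.shape[1])
    if not grid:
        raise ValueError("grid must be nonempty")
    folds = _event_stratified_folds(event, n_splits, seed)
    best_params, best_score = None, -np.inf
    log = []
    for params in grid:
        scores = []
        for tr, te in folds:
            model = make_model(model_name, **params)
            try:
                model.fit(table.iloc[tr], (time[tr], event[tr]))
                scores.append(harrell_cindex(model.predict(table.iloc[te]),
                                             time[te], event[te]))
            except (RuntimeError, ValueError):
                scores.append(np.nan)
        mean_score = float(np.nanmean(scores)) if not np.all(np.isnan(scores)) else -np.inf
        log.append({**params, "cv_cindex": mean_score})
        if mean_score > best_score:  # strict: ties keep the earlier entry
            best_params, best_score = params, mean_score
    tune.last_log = log  # simple introspection hook
    return dict(best_params or {})
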