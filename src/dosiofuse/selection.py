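"""Five feature-selection procedures for survival feature tables.

Each selector is a scikit-learn-style transformer: ``fit(X, y)`` ranks the
features of a training table against a survival outcome and stores a
fixed-size ordered subset in ``selected_features_``; ``transform(X)``
restricts a table to that subset. Thin ``fs_*`` functions wrap the classes.

Selectors
---------
cindex  Univariate Cox concordance under bootstrap resampling (after a
        Spearman redundancy prefilter): each feature's univariate Cox model
        is fit on each resample and scored by the resample C-index; features
        rank by mean C-index.
md      Minimal depth in a random survival forest: features whose first
        split tends to sit closer to the root rank higher.
vh      Variable hunting: repeated train/test splits; per iteration a forest
        ranks candidates by minimal depth, candidates are forward-added
        until the ensemble test concordance stabilizes; final ranking by
        selection frequency.
vimp    As ``vh`` but candidates ordered by permutation variable importance.
mi      Somers' Dxy association with the outcome, with redundancy-aware
        greedy de-duplication using the Gaussian mutual-information
        approximation ``MI = -0.5 * log(1 - r^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .coxutils import univariate_cox_beta
from .metrics import harrell_cindex, somers_dxy
from .models import RSFModel, as_time_event

__all__ = [
    "SelectedFeatures", "spearman_prefilter",
    "CIndexSelector", "MinimalDepthSelector", "VariableHuntingSelector",
    "MutualInfoSelector", "SELECTOR_REGISTRY", "make_selector",
    "fs_cindex", "fs_minimal_depth", "fs_variable_hunting", "fs_vimp",
    "fs_mutual_info", "gaussian_mi",
]


@dataclass
class SelectedFeatures:
    """Ordered feature subset with per-feature scores and diagnostics."""

    names: list[str]
    scores: dict[str, float]
    method: str
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("selected feature names must be unique")

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


def _comparable_pairs(time: np.ndarray, event: np.ndarray):
    """Index pairs (i, j) with t_i < t_j and event_i = 1."""
    ti, tj = time[:, None], time[None, :]
    comp = (ti < tj) & (event[:, None] == 1)
    return np.nonzero(comp)


def _batch_cindex(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Orientation-free C-index of every column at once: max(C, 1-C)."""
    i_idx, j_idx = _comparable_pairs(time, event)
    if i_idx.size == 0:
        return np.full(X.shape[1], np.nan)
    a, b = X[i_idx], X[j_idx]
    conc = (a > b).sum(axis=0)
    ties = (a == b).sum(axis=0)
    c = (conc + 0.5 * ties) / i_idx.size
    return np.maximum(c, 1 - c)


def spearman_prefilter(
    table: pd.DataFrame,
    outcome,
    rho_threshold: float = 0.9,
) -> pd.DataFrame:
    """Drop one member of every feature pair with |Spearman rho| >= threshold.

    For each offending pair (visited in deterministic column order) the
    member with the lower univariate concordance is removed. Constant
    columns are dropped with a warning (rho is undefined for them).
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if table.isna().all().any():
        raise ValueError("all-NaN feature columns are not allowed")
    time, event = as_time_event(outcome)
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant columns (rho undefined): {constant}")
        table = table.drop(columns=constant)
    cols = list(table.columns)
    rho = np.abs(stats.spearmanr(table.to_numpy(float)).statistic)
    rho = np.atleast_2d(rho)
    cidx = _batch_cindex(table.to_numpy(float), time, event)
    keep = dict.fromkeys(cols, True)
    for a in range(len(cols)):
        if not keep[cols[a]]:
            continue
        for b in range(a + 1, len(cols)):
            if not keep[cols[b]]:
                continue
            if rho[a, b] >= rho_threshold:
                drop = a if cidx[a] < cidx[b] else b
                keep[cols[drop]] = False
                if drop == a:
                    break
    return table[[c for c in cols if keep[c]]]


class _BaseSelector(BaseEstimator):
    """Shared transformer plumbing for the five selectors."""

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
            X.columns = [str(c) for c in X.columns]
        time, event = as_time_event(y)
        if event.sum() < 2:
            raise ValueError("need at least 2 events")
        result = self._select(X, time, event)
        assert all(n in X.columns for n in result.names)
        self.selected_features_ = result.names
        self.scores_ = result.scores
        self.diagnostics_ = result.diagnostics
        self.result_ = result
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def _top_k(self, ordered: list[str], k: int) -> tuple[list[str], bool]:
        flagged = k > len(ordered)
        return ordered[:k], flagged


class CIndexSelector(_BaseSelector):
    """Rank by mean univariate-Cox bootstrap C-index (after Spearman prefilter)."""

    method = "cindex"

    def __init__(self, k: int = 10, n_boot: int = 100, seed: int = 0,
                 rho_threshold: float = 0.9, prefilter: bool = True):
        self.k = k
        self.n_boot = n_boot
        self.seed = seed
        self.rho_threshold = rho_threshold
        self.prefilter = prefilter

    def _select(self, X, time, event):
        if self.prefilter and X.shape[1] >= 2:
            X = spearman_prefilter(X, (time, event), self.rho_threshold)
        cols = list(X.columns)
        Xv = X.to_numpy(float)
        n = len(time)
        rng = np.random.default_rng(self.seed)
        scores = np.zeros((self.n_boot, len(cols)))
        skipped = np.zeros(len(cols), dtype=int)
        for b in range(self.n_boot):
            idx = rng.integers(0, n, size=n)
            tb, eb = time[idx], event[idx]
            if eb.sum() < 2:
                scores[b] = np.nan
                continue
            Xb = Xv[idx]
            i_idx, j_idx = _comparable_pairs(tb, eb)
            if i_idx.size == 0:
                scores[b] = np.nan
                continue
            a, bb = Xb[i_idx].astype(np.float32), Xb[j_idx].astype(np.float32)
            gt = (a > bb).sum(axis=0)
            ge = (a >= bb).sum(axis=0)
            c_raw = (gt + ge) / (2.0 * i_idx.size)  # concordant + half ties
            for f in range(len(cols)):
                beta = univariate_cox_beta(Xb[:, f], tb, eb, max_iter=3,
                                           ties="breslow")
                if beta > 0:
                    scores[b, f] = c_raw[f]
                elif beta < 0:
                    scores[b, f] = 1 - c_raw[f]
                else:
                    scores[b, f] = 0.5
                    skipped[f] += 1
        mean_scores = np.nanmean(scores, axis=0)
        order = np.argsort(-mean_scores, kind="stable")
        ordered = [cols[i] for i in order]
        names, flagged = self._top_k(ordered, self.k)
        return SelectedFeatures(
            names=names,
            scores={cols[i]: float(mean_scores[i]) for i in order},
            method=self.method,
            seed=self.seed,
            diagnostics={"degenerate_fits": dict(zip(cols, skipped.tolist())),
                         "k_truncated": flagged},
        )


def _minimal_depths(forest, n_features: int) -> np.ndarray:
    """Mean minimal depth per feature across trees; features a tree never
    splits on get that tree's maximal-depth penalty."""
    depths = np.zeros((len(forest.estimators_), n_features))
    for t_i, est in enumerate(forest.estimators_):
        tree = est.tree_
        node_depth = np.zeros(tree.node_count, dtype=int)
        stack = [(0, 0)]
        feat_min = {}
        max_depth = 0
        while stack:
            node, d = stack.pop()
            node_depth[node] = d
            max_depth = max(max_depth, d)
            left, right = tree.children_left[node], tree.children_right[node]
            if left != -1:
                f = tree.feature[node]
                feat_min[f] = min(feat_min.get(f, np.inf), d)
                stack.append((left, d + 1))
                stack.append((right, d + 1))
        penalty = max_depth + 1
        row = np.full(n_features, float(penalty))
        for f, d in feat_min.items():
            row[f] = d
        depths[t_i] = row
    return depths.mean(axis=0)


class MinimalDepthSelector(_BaseSelector):
    """Rank by mean minimal depth in a random survival forest."""

    method = "md"

    def __init__(self, k: int = 10, n_trees: int = 250, node_size: int = 15,
                 mtry="sqrt", seed: int = 0):
        self.k = k
        self.n_trees = n_trees
        self.node_size = node_size
        self.mtry = mtry
        self.seed = seed

    def _select(self, X, time, event):
        model = RSFModel(n_trees=self.n_trees, mtry=self.mtry,
                         node_size=self.node_size, seed=self.seed)
        model.fit(X, (time, event))
        forest = model.est_
        if all(est.tree_.node_count <= 1 for est in forest.estimators_):
            raise RuntimeError("degenerate forest: no splits in any tree")
        mean_depth = _minimal_depths(forest, X.shape[1])
        cols = list(X.columns)
        order = np.argsort(mean_depth, kind="stable")
        names, flagged = self._top_k([cols[i] for i in order], self.k)
        return SelectedFeatures(
            names=names,
            scores={cols[i]: float(mean_depth[i]) for i in order},
            method=self.method,
            seed=self.seed,
            diagnostics={"k_truncated": flagged},
        )


class VariableHuntingSelector(_BaseSelector):
    """Iterated forest-based wrapper selection (variable hunting).

    Per iteration: random half/half train/test split; a forest on the train
    half orders candidates by minimal depth (``mode='md'``) or permutation
    importance on the test half (``mode='vimp'``); candidates are forward-
    added while the test C-index of a forest on the growing set changes by
    more than ``stab_tol`` (relative) — two consecutive sub-tolerance
    additions stop the hunt. Final ranking: occurrence frequency across
    iterations, ties broken by mean within-iteration rank.
    """

    method = "vh"

    def __init__(self, k: int = 10, iters: int = 50, seed: int = 0,
                 mode: str = "md", n_trees: int = 20, eval_trees: int = 10,
                 node_size: int = 15, max_candidates: int = 6,
                 stab_tol: float = 0.01, vimp_rows: int = 100,
                 vimp_pool: int = 25):
        self.k = k
        self.iters = iters
        self.seed = seed
        self.mode = mode
        self.n_trees = n_trees
        self.eval_trees = eval_trees
        self.node_size = node_size
        self.max_candidates = max_candidates
        self.stab_tol = stab_tol
        self.vimp_rows = vimp_rows
        self.vimp_pool = vimp_pool

    def _rank_candidates(self, X_tr, y_tr, X_te, y_te, seed: int) -> list[int]:
        model = RSFModel(n_trees=self.n_trees, node_size=self.node_size, seed=seed)
        model.fit(X_tr, y_tr)
        if self.mode == "md":
            depth = _minimal_depths(model.est_, X_tr.shape[1])
            order = np.argsort(depth, kind="stable")
            # threshold: features with depth below the all-feature mean
            selected = [i for i in order if depth[i] < depth.mean()]
            return selected or list(order[:1])
        # permutation importance on the held-out half, batched into one predict
        rng = np.random.default_rng(seed)
        t_te, e_te = y_te
        if len(t_te) > self.vimp_rows:  # importance rows capped for tractability
            sub = rng.choice(len(t_te), self.vimp_rows, replace=False)
            X_te, t_te, e_te = X_te.iloc[sub], t_te[sub], e_te[sub]
        Xv = X_te.to_numpy(float)
        base_c = harrell_cindex(model.est_.predict(Xv), t_te, e_te)
        split_counts: dict[int, int] = {}
        for est in model.est_.estimators_:
            for f in est.tree_.feature:
                if f >= 0:
                    split_counts[int(f)] = split_counts.get(int(f), 0) + 1
        if not split_counts:
            return [0]
        # permute only the most-used features; rarely-split ones carry ~0 VIMP
        used = sorted(sorted(split_counts, key=split_counts.get, reverse=True)
                      [: self.vimp_pool])
        stacked = []
        for f in used:
            Xp = Xv.copy()
            Xp[:, f] = rng.permutation(Xp[:, f])
            stacked.append(Xp)
        risks = model.est_.predict(np.vstack(stacked)).reshape(len(used), -1)
        imp = np.array([base_c - harrell_cindex(r, t_te, e_te) for r in risks])
        order = np.argsort(-imp, kind="stable")
        return [used[i] for i in order if imp[i] > 0] or [used[int(order[0])]]

    def _select(self, X, time, event):
        cols = list(X.columns)
        n = len(time)
        rng = np.random.default_rng(self.seed)
        tally: dict[str, int] = dict.fromkeys(cols, 0)
        rank_sum: dict[str, list[int]] = {c: [] for c in cols}
        empty_iters = 0
        for it in range(self.iters):
            it_seed = int(rng.integers(0, 2**31 - 1))
            perm = np.random.default_rng(it_seed).permutation(n)
            half = n // 2
            tr, te = perm[:half], perm[half:]
            if event[tr].sum() < 2 or event[te].sum() < 1:
                empty_iters += 1
                continue
            X_tr, X_te = X.iloc[tr], X.iloc[te]
            y_tr, y_te = (time[tr], event[tr]), (time[te], event[te])
            try:
                candidates = self._rank_candidates(X_tr, y_tr, X_te, y_te, it_seed)
            except (RuntimeError, ValueError):
                empty_iters += 1
                continue
            candidates = candidates[: self.max_candidates]
            chosen: list[int] = []
            prev_score, calm = -np.inf, 0
            for f in candidates:
                sub = [cols[i] for i in chosen + [f]]
                ev = RSFModel(n_trees=self.eval_trees, node_size=self.node_size,
                              seed=it_seed)
                try:
                    ev.fit(X_tr[sub], y_tr)
                    score = harrell_cindex(ev.predict(X_te[sub]), *y_te)
                except (RuntimeError, ValueError):
                    score = prev_score
                if np.isfinite(prev_score):
                    rel = abs(score - prev_score) / max(abs(prev_score), 1e-12)
                    calm = calm + 1 if rel < self.stab_tol else 0
                    # a member joins the hunted set only if it moved the
                    # joint importance upward; stagnant adds are not tallied
                    if score > prev_score:
                        chosen.append(f)
                    if calm >= 2:
                        break
                else:
                    chosen.append(f)
                prev_score = max(prev_score, score)
            for rank_pos, f in enumerate(chosen):
                tally[cols[f]] += 1
                rank_sum[cols[f]].append(rank_pos)
        freq = {c: tally[c] / self.iters for c in cols}
        mean_rank = {c: (np.mean(rank_sum[c]) if rank_sum[c] else np.inf) for c in cols}
        ordered = sorted(cols, key=lambda c: (-freq[c], mean_rank[c], c))
        ordered = [c for c in ordered if freq[c] > 0]
        names, flagged = self._top_k(ordered, self.k)
        return SelectedFeatures(
            names=names,
            scores=freq,
            method="vimp" if self.mode == "vimp" else "vh",
            seed=self.seed,
            diagnostics={"empty_iterations": empty_iters,
                         "mean_rank": {c: float(mean_rank[c]) for c in names},
                         "k_truncated": flagged},
        )


def gaussian_mi(r: float) -> float:
    """Gaussian mutual-information approximation ``-0.5 * ln(1 - r^2)`` (nats)."""
    r = float(np.clip(r, -0.999999, 0.999999))
    return -0.5 * np.log(1.0 - r**2)


class MutualInfoSelector(_BaseSelector):
    """Rank by |Somers' Dxy| with MI-based redundancy de-duplication."""

    method = "mi"

    def __init__(self, k: int = 10, rho_threshold: float = 0.9):
        self.k = k
        self.rho_threshold = rho_threshold

    def _select(self, X, time, event):
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        if constant:
            X = X.drop(columns=constant)
        cols = list(X.columns)
        dxy = {}
        for c in cols:
            try:
                dxy[c] = somers_dxy(X[c].to_numpy(float), time, event)
            except ValueError:
                dxy[c] = 0.0
        order = sorted(cols, key=lambda c: (-abs(dxy[c]), c))
        rho = np.atleast_2d(stats.spearmanr(X.to_numpy(float)).statistic)
        col_pos = {c: i for i, c in enumerate(cols)}
        chosen: list[str] = []
        redundancy: dict[str, float] = {}
        for c in order:
            redundant = False
            for prev in chosen:
                r = rho[col_pos[c], col_pos[prev]] if len(cols) > 1 else 0.0
                if abs(r) >= self.rho_threshold:
                    redundancy[c] = gaussian_mi(r)
                    redundant = True
                    break
            if not redundant:
                chosen.append(c)
            if len(chosen) >= self.k:
                break
        names, flagged = self._top_k(chosen, self.k)
        return SelectedFeatures(
            names=names,
            scores={c: float(dxy[c]) for c in cols},
            method=self.method,
            diagnostics={"redundant_mi": redundancy, "k_truncated": flagged,
                         "dropped_constant": constant},
        )


SELECTOR_REGISTRY = {
    "cindex": CIndexSelector,
    "md": MinimalDepthSelector,
    "vh": lambda **kw: VariableHuntingSelector(mode="md", **kw),
    "vimp": lambda **kw: VariableHuntingSelector(mode="vimp", **kw),
    "mi": MutualInfoSelector,
}


def make_selector(name: str, **params):
    try:
        factory = SELECTOR_REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown selector {name!r}; choose from {sorted(SELECTOR_REGISTRY)}")
    return factory(**params)


# thin functional wrappers -------------------------------------------------

def fs_cindex(table, outcome, k=10, n_boot=100, seed=0) -> SelectedFeatures:
    return CIndexSelector(k=k, n_boot=n_boot, seed=seed).fit(table, outcome).result_


def fs_minimal_depth(table, outcome, k=10, seed=0, **forest_params) -> SelectedFeatures:
    return MinimalDepthSelector(k=k, seed=seed, **forest_params).fit(table, outcome).result_


def fs_variable_hunting(table, outcome, iters=50, seed=0, k=10, **kw) -> SelectedFeatures:
    sel = VariableHuntingSelector(mode="md", iters=iters, seed=seed, k=k, **kw)
    return sel.fit(table, outcome).result_


def fs_vimp(table, outcome, iters=50, seed=0, k=10, **kw) -> SelectedFeatures:
    sel = VariableHuntingSelector(mode="vimp", iters=iters, seed=seed, k=k, **kw)
    return sel.fit(table, outcome).result_


def fs_mutual_info(table, outcome, k=10) -> SelectedFeatures:
    return MutualInfoSelector(k=k).fit(table, outcome).result_
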