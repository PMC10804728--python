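"""Cox partial-likelihood primitives with Efron tie handling.

Shared by the componentwise likelihood-boosting model and the fast
univariate fits used in bootstrap feature scoring. Everything operates on
plain numpy arrays: ``time`` (days), ``event`` (0/1), linear predictor
``eta`` and covariate columns.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cox_partial_loglik",
    "cox_score_info_percov",
    "univariate_cox_beta",
]


def _event_groups(time: np.ndarray, event: np.ndarray):
    """Unique event times with index arrays of tied events and risk sets.

    Assumes inputs sorted by ascending time."""
    groups = []
    event_times = np.unique(time[event == 1])
    for t in event_times:
        d_idx = np.nonzero((time == t) & (event == 1))[0]
        r_start = np.searchsorted(time, t, side="left")
        groups.append((d_idx, r_start))
    return groups


def cox_partial_loglik(time, event, eta) -> float:
    """Efron-approximated Cox partial log-likelihood."""
    order = np.argsort(time, kind="stable")
    t, e, lp = time[order], event[order], eta[order]
    w = np.exp(lp)
    ll = 0.0
    for d_idx, r_start in _event_groups(t, e):
        d = len(d_idx)
        sum_risk = w[r_start:].sum()
        sum_tied = w[d_idx].sum()
        ll += lp[d_idx].sum()
        for l_tie in range(d):
            ll -= np.log(sum_risk - l_tie / d * sum_tied)
    return float(ll)


def cox_score_info_percov(X, time, event, eta):
    """Per-covariate score U_j and (diagonal) information I_j of the Efron
    partial likelihood at linear predictor eta.

    Returns ``(U, I)`` arrays of length p. Used for componentwise boosting:
    the candidate update for covariate j is ``U_j / (I_j + penalty)``.
    """
    X = np.asarray(X, dtype=float)
    order = np.argsort(time, kind="stable")
    Xs = X[order]
    t, e, lp = time[order], event[order], eta[order]
    w = np.exp(lp)
    wx = w[:, None] * Xs
    wxx = w[:, None] * Xs**2
    # suffix sums over the risk set
    cs_w = np.cumsum(w[::-1])[::-1]
    cs_wx = np.cumsum(wx[::-1], axis=0)[::-1]
    cs_wxx = np.cumsum(wxx[::-1], axis=0)[::-1]
    p = X.shape[1]
    U = np.zeros(p)
    info = np.zeros(p)
    for d_idx, r_start in _event_groups(t, e):
        d = len(d_idx)
        s0_r = cs_w[r_start]
        s1_r = cs_wx[r_start]
        s2_r = cs_wxx[r_start]
        s0_t = w[d_idx].sum()
        s1_t = wx[d_idx].sum(axis=0)
        s2_t = wxx[d_idx].sum(axis=0)
        U += Xs[d_idx].sum(axis=0)
        for l_tie in range(d):
            frac = l_tie / d
            s0 = s0_r - frac * s0_t
            s1 = s1_r - frac * s1_t
            s2 = s2_r - frac * s2_t
            U -= s1 / s0
            info += s2 / s0 - (s1 / s0) ** 2
    return U, info


def _breslow_score_info_1d(x, time, event, beta):
    """Vectorized score/information of a one-covariate Cox model with
    Breslow tie handling (no per-group Python loop)."""
    order = np.argsort(time, kind="stable")
    t, e, xs = time[order], event[order], x[order]
    w = np.exp(np.clip(beta * xs, -500, 500))
    cs0 = np.cumsum(w[::-1])[::-1]
    cs1 = np.cumsum((w * xs)[::-1])[::-1]
    cs2 = np.cumsum((w * xs**2)[::-1])[::-1]
    ev = np.nonzero(e == 1)[0]
    r_start = np.searchsorted(t, t[ev], side="left")
    s0, s1, s2 = cs0[r_start], cs1[r_start], cs2[r_start]
    U = float((xs[ev] - s1 / s0).sum())
    info = float((s2 / s0 - (s1 / s0) ** 2).sum())
    return U, info


def univariate_cox_beta(x, time, event, max_iter: int = 20, tol: float = 1e-8,
                        ties: str = "efron") -> float:
    """Newton fit of a one-covariate Cox model; returns beta.

    ``ties='efron'`` uses the Efron partial likelihood; ``ties='breslow'``
    uses a fully vectorized Breslow scorer (preferred inside bootstrap
    loops, where resampling manufactures heavy ties)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    beta = 0.0
    X = x[:, None]
    for _ in range(max_iter):
        if ties == "breslow":
            U, I = _breslow_score_info_1d(x, time, event, beta)
        else:
            Uv, Iv = cox_score_info_percov(X, time, event, beta * x)
            U, I = float(Uv[0]), float(Iv[0])
        if I <= 0:
            break
        step = float(np.clip(U / I, -5.0, 5.0))
        beta += step
        if abs(step) < tol:
            break
    return float(beta)
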