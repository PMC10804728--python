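"""Reference synthetic benchmark: signal recovery and LOCO validation.

This module fixes the study conditions of the package's built-in benchmark
on simulated data: a five-center cohort of 500 patients with 3 informative
features among 50 (Cox-Weibull hazard, 30% censoring, mild inter-center
feature shifts). On it, the five selectors are scored by how often their
top-10 recovers the informative features, and the proportional-hazards
family of models by leave-one-center-out concordance with the full
select-tune-fit-transfer-evaluate protocol.
"""

from __future__ import annotations

import numpy as np

from .evaluation import loco_cv
from .phantom import SyntheticCohort, simulate_cohort
from .selection import SELECTOR_REGISTRY, make_selector

__all__ = [
    "BENCHMARK_BETA", "make_benchmark_cohort", "selector_recovery",
    "loco_benchmark", "leakage_audit", "compact_grids",
]

# study conditions of the reference benchmark (fixed, not tunable per run)
BENCHMARK_BETA = np.zeros(50)
BENCHMARK_BETA[:3] = [1.5, -1.2, 1.0]
N_PER_CENTER = [100, 100, 100, 100, 100]
CENSOR_RATE = 0.3
BASELINE = (1.2, 1000.0)       # Weibull shape, scale (days)
CENTER_SHIFT_SD = 0.25          # mild multi-center distribution shift


def make_benchmark_cohort(seed: int) -> SyntheticCohort:
    """The reference 5 x 100 patient cohort (3 informative of 50 features)."""
    return simulate_cohort(
        N_PER_CENTER, BENCHMARK_BETA, baseline=BASELINE,
        censor_rate=CENSOR_RATE, seed=seed, center_shift_sd=CENTER_SHIFT_SD,
    )


def selector_recovery(
    selector_names=None, n_seeds: int = 20, seed0: int = 0, k: int = 10,
    min_hits: int = 2,
) -> dict[str, dict]:
    """Fraction of seeds on which each selector's top-k contains at least
    ``min_hits`` of the 3 informative features."""
    selector_names = selector_names or list(SELECTOR_REGISTRY)
    hits = {name: [] for name in selector_names}
    for s in range(n_seeds):
        cohort = make_benchmark_cohort(seed0 + s)
        informative = set(cohort.informative)
        y = (cohort.time, cohort.event)
        for name in selector_names:
            params = {} if name == "mi" else {"seed": seed0 + s}
            sel = make_selector(name, k=k, **params)
            sel.fit(cohort.features, y)
            hits[name].append(
                len(informative & set(sel.selected_features_)) >= min_hits
            )
    return {
        name: {"rate": float(np.mean(h)), "n_seeds": n_seeds, "hits": h}
        for name, h in hits.items()
    }


def compact_grids() -> dict[str, list[dict]]:
    """Reduced tuning grids for the benchmark (documented problem sizes)."""
    return {
        "coxboost": [{"n_steps": s, "penalty": None} for s in (50, 100)],
        "glmboost": [{"mstop": m, "nu": 0.1} for m in (50, 100, 250)],
        "glmnet": [{"alpha": a, "lam_frac": f}
                   for a in (1.0, 0.5) for f in (0.3, 0.6)],
        "stree": [{"depth": d} for d in (2, 3)],
    }


def loco_benchmark(
    model_names=("coxph", "glmnet", "coxboost", "glmboost"),
    selector_name: str = "cindex",
    seed: int = 0,
    n_boot: int = 1000,
):
    """LOCO grand-mean C-index per model on the reference cohort."""
    cohort = make_benchmark_cohort(seed)
    grids = compact_grids()
    out = {}
    for model in model_names:
        res = loco_cv(
            cohort.features, (cohort.time, cohort.event), cohort.center,
            selector_name=selector_name, model_name=model,
            n_boot=n_boot, seed=seed, grid=grids.get(model),
            strategy_label="Clinical",
        )
        out[model] = res
    return out


def leakage_audit(seed: int = 0) -> float:
    """Max |coefficient change| of the C1-fold model when the held-out
    center is poisoned (outcomes shuffled, features rescaled). Must be 0:
    the protocol never lets test-center rows influence training."""
    cohort = make_benchmark_cohort(seed)
    y = (cohort.time, cohort.event)
    kwargs = dict(selector_name="mi", model_name="coxph", n_boot=10, seed=seed)
    res1 = loco_cv(cohort.features, y, cohort.center, **kwargs)

    rng = np.random.default_rng(seed)
    te = cohort.center == "C1"
    idx = np.nonzero(te)[0]
    time2, event2 = cohort.time.copy(), cohort.event.copy()
    perm = rng.permutation(idx)
    time2[idx], event2[idx] = cohort.time[perm], cohort.event[perm]
    X2 = cohort.features.copy()
    X2.loc[te] = X2.loc[te].to_numpy() * 2.0 + 5.0
    res2 = loco_cv(X2, (time2, event2), cohort.center, **kwargs)

    f1 = next(f for f in res1.folds if f.center == "C1")
    f2 = next(f for f in res2.folds if f.center == "C1")
    if f1.selected_features != f2.selected_features:
        return float("inf")
    return float(max(
        abs(f1.coef[k] - f2.coef[k]) for k in f1.selected_features
    ))
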