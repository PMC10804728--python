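"""Model evaluation: leave-one-center-out CV, bootstrap testing, KM risk
stratification and rank-based strategy comparison.

The external-validation scheme holds out one center at a time: feature
selection, hyperparameter tuning (3-fold CV) and model fitting see only the
remaining centers; the feature normalization learned on the training
centers is transferred to the held-out center; performance on the held-out
center is summarized by the bootstrap distribution of Harrell's C-index
(1000 resamples by default). Grand results aggregate the per-center means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import harrell_cindex
from .models import as_time_event, make_model, tune
from .selection import make_selector

__all__ = [
    "STRATEGIES", "BenchmarkResult", "FoldResult",
    "normalize_transfer", "bootstrap_eval", "loco_cv", "km_stratify",
    "friedman_nemenyi", "encode_clinical", "build_strategy_table",
    "CLINICAL_FIELDS",
]

STRATEGIES = ["Clinical", "CT", "Dose", "DualCTDose", "LLRR", "Wavelet", "WLS"]


@dataclass
class FoldResult:
    center: str
    cindex_mean: float
    cindex_sd: float
    n_test: int
    selected_features: list[str]
    hyperparameters: dict
    seed: int
    n_boot_skipped: int = 0
    coef: dict[str, float] | None = None  # linear models only; leakage audits


@dataclass
class BenchmarkResult:
    strategy: str
    selector: str
    model: str
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def grand_mean(self) -> float:
        return float(np.mean([f.cindex_mean for f in self.folds]))

    @property
    def grand_sd(self) -> float:
        """SD among the per-center scores (the headline +/- convention)."""
        return float(np.std([f.cindex_mean for f in self.folds], ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "strategy": self.strategy, "selector": self.selector,
                "model": self.model, "center": f.center,
                "cindex_mean": f.cindex_mean, "cindex_sd": f.cindex_sd,
                "n_test": f.n_test, "seed": f.seed,
                "selected_features": ";".join(f.selected_features),
            }
            for f in self.folds
        ])


def normalize_transfer(
    train_table: pd.DataFrame, test_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score both tables using training mean/SD only.

    Columns constant in training map to 0 everywhere (documented rule), so
    no information flows from the test set into the normalization."""
    if list(train_table.columns) != list(test_table.columns):
        raise ValueError("train and test tables must share columns")
    mean = train_table.mean(axis=0)
    sd = train_table.std(axis=0, ddof=0)
    zero = sd <= 0
    sd_safe = sd.mask(zero, 1.0)
    train_z = (train_table - mean) / sd_safe
    test_z = (test_table - mean) / sd_safe
    train_z.loc[:, zero] = 0.0
    test_z.loc[:, zero] = 0.0
    return train_z, test_z


def bootstrap_eval(
    model, test_table: pd.DataFrame, test_outcome, n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Bootstrap distribution of the test C-index.

    Test rows are resampled with replacement ``n_boot`` times; replicates
    without a comparable pair are skipped (and counted); more than 50%
    skipped is an error."""
    time, event = as_time_event(test_outcome)
    risk = model.predict(test_table)
    harrell_cindex(risk, time, event)  # raises if no comparable pair at all
    rng = np.random.default_rng(seed)
    n = len(time)
    values = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(harrell_cindex(risk[idx], time[idx], event[idx]))
        except ValueError:
            skipped += 1
    if skipped > n_boot / 2:
        raise RuntimeError(
            f"{skipped}/{n_boot} bootstrap replicates had no comparable pair"
        )
    values = np.asarray(values)
    bootstrap_eval.last_skipped = skipped
    return float(values.mean()), float(values.std(ddof=0)), values


def loco_cv(
    table: pd.DataFrame,
    outcome,
    centers,
    selector_name: str = "cindex",
    model_name: str = "coxph",
    k: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    grid: list[dict] | None = None,
    strategy_label: str = "",
    selector_params: dict | None = None,
) -> BenchmarkResult:
    """Leave-one-center-out cross-validation of one selector x model pair.

    Per held-out center: select features on the remaining centers, tune by
    3-fold CV, fit, transfer the training normalization, and evaluate on
    the held-out center with :func:`bootstrap_eval`. Folds whose selection
    yields fewer than 2 features are flagged and excluded.
    """
    centers = np.asarray(centers, dtype=str)
    unique_centers = sorted(set(centers))
    if len(unique_centers) < 2:
        raise ValueError("need at least 2 centers")
    time, event = as_time_event(outcome)
    result = BenchmarkResult(strategy=strategy_label, selector=selector_name,
                             model=model_name)
    for c_i, held_out in enumerate(unique_centers):
        te = centers == held_out
        tr = ~te
        if event[te].sum() < 1 or event[tr].sum() < 2:
            raise ValueError(f"center {held_out} lacks events")
        fold_seed = (seed * 1000 + c_i * 101) % (2**31 - 1)
        X_tr_raw, X_te_raw = table.loc[tr], table.loc[te]
        y_tr = (time[tr], event[tr])

        sel_params = dict(selector_params or {})
        if selector_name != "mi":
            sel_params.setdefault("seed", fold_seed)
        selector = make_selector(selector_name, k=k, **sel_params)
        selector.fit(X_tr_raw, y_tr)
        chosen = selector.selected_features_
        if len(chosen) < 2:
            import warnings

            warnings.warn(f"fold {held_out}: selection returned <2 features; excluded")
            continue
        X_tr, X_te = normalize_transfer(X_tr_raw[chosen], X_te_raw[chosen])

        if model_name == "coxph":
            params = {}
        else:
            params = tune(model_name, X_tr, y_tr, grid=grid, seed=fold_seed)
        model = make_model(model_name, **params)
        if "seed" in model.get_params():
            model.set_params(seed=fold_seed)
        model.fit(X_tr, y_tr)
        mean, sd, _ = bootstrap_eval(model, X_te, (time[te], event[te]),
                                     n_boot=n_boot, seed=fold_seed)
        result.folds.append(FoldResult(
            center=held_out, cindex_mean=mean, cindex_sd=sd,
            n_test=int(te.sum()), selected_features=list(chosen),
            hyperparameters=params, seed=fold_seed,
            n_boot_skipped=getattr(bootstrap_eval, "last_skipped", 0),
            coef=(dict(zip(chosen, np.asarray(model.coef_, dtype=float)))
                  if hasattr(model, "coef_") else None),
        ))
    return result


def km_stratify(risk, outcome):
    """Median-cutoff risk stratification with Kaplan-Meier curves.

    High-risk group: risk >= median; low-risk: risk < median. Returns the
    group labels, the two-sample log-rank p-value and the fitted KM curves.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    risk = np.asarray(risk, dtype=float)
    time, event = as_time_event(outcome)
    cutoff = float(np.median(risk))
    high = risk >= cutoff
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError(
            "median cutoff leaves a group with <2 subjects (massive risk ties); "
            "consider an alternative cutoff, e.g. a quantile of the unique scores"
        )
    groups = np.where(high, "high", "low")
    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    curves = {}
    for label, sel in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter(label=label)
        km.fit(time[sel], event[sel])
        curves[label] = km
    return groups, float(lr.p_value), curves


def friedman_nemenyi(score_matrix) -> tuple[float, pd.DataFrame]:
    """Friedman rank test across strategies (columns) blocking on rows,
    followed by Nemenyi pairwise comparisons when p < 0.05.

    Returns ``(friedman_p, pairwise_p)``; the pairwise matrix is all-NaN if
    the Friedman test is not significant."""
    df = pd.DataFrame(score_matrix)
    n, k = df.shape
    if k < 3 or n < 2:
        raise ValueError("need >= 3 strategies and >= 2 blocks")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, friedman_p = stats.friedmanchisquare(*[df.iloc[:, j] for j in range(k)])
    if np.isnan(friedman_p):
        # every block fully tied: the rank statistic is 0 by construction
        friedman_p = 1.0
    cols = list(df.columns)
    pairwise = pd.DataFrame(np.nan, index=cols, columns=cols)
    if friedman_p < 0.05:
        ranks = df.rank(axis=1)  # midranks for ties
        mean_ranks = ranks.mean(axis=0)
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        for a in range(k):
            for b in range(a + 1, k):
                q = abs(mean_ranks.iloc[a] - mean_ranks.iloc[b]) / se * np.sqrt(2)
                p = float(stats.studentized_range.sf(q, k, np.inf))
                pairwise.iloc[a, b] = pairwise.iloc[b, a] = min(max(p, 0.0), 1.0)
        np.fill_diagonal(pairwise.values, 1.0)
    return float(friedman_p), pairwise


# ---------------------------------------------------------------------------
# Clinical encoding and strategy tables
# ---------------------------------------------------------------------------

CLINICAL_FIELDS = ["age", "sex", "site", "t_stage", "n_stage", "tnm_stage", "treatment"]

SEX_CODES = {"M": 0, "F": 1}
T_STAGE_CODES = {"Tx": 0, "T1": 1, "T2": 2, "T3": 3, "T4": 4, "T4a": 5, "T4b": 6}
N_STAGE_CODES = {"N0": 0, "N1": 1, "N2": 2, "N2a": 3, "N2b": 4, "N2c": 5,
                 "N3": 6, "N3a": 7, "N3b": 8}
TNM_STAGE_CODES = {"I": 1, "II": 2, "IIB": 3, "III": 4, "IV": 5, "IVA": 6, "IVB": 7}
SITE_CODES = {"Unknown": 0, "Oropharynx": 1, "Nasopharynx": 2, "Larynx": 3,
              "Hypopharynx": 4}
TREATMENT_CODES = {"Radiation": 0, "CHRT": 1, "Surgery+RT": 2, "Surgery+CHRT": 3}

_CODE_MAPS = {
    "sex": SEX_CODES, "site": SITE_CODES, "t_stage": T_STAGE_CODES,
    "n_stage": N_STAGE_CODES, "tnm_stage": TNM_STAGE_CODES,
    "treatment": TREATMENT_CODES,
}


def encode_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """Encode the 7 clinical covariates to a numeric table.

    Age stays numeric; sex is binary; T/N/TNM stages are ordinal-coded in
    stage order; tumor site and treatment modality use frozen integer
    dictionaries. Unknown categories raise with the dictionary listed."""
    missing = [f for f in CLINICAL_FIELDS if f not in records.columns]
    if missing:
        raise ValueError(f"missing clinical fields: {missing}")
    out = pd.DataFrame(index=records.index)
    out["age"] = records["age"].astype(float)
    for col, codes in _CODE_MAPS.items():
        vals = records[col].astype(str)
        bad = sorted(set(vals) - set(codes))
        if bad:
            raise ValueError(
                f"unknown {col} categories {bad}; known codes: {codes}"
            )
        out[col] = vals.map(codes).astype(float)
    return out[CLINICAL_FIELDS]


def build_strategy_table(
    modality_features: dict[str, pd.DataFrame],
    clinical: pd.DataFrame,
    strategy: str,
) -> pd.DataFrame:
    """Assemble the feature table of one modelling strategy.

    ``Clinical`` uses the 7 encoded clinical covariates alone; single-
    modality strategies use that modality's 215 image features plus the
    clinical block (222 columns); ``DualCTDose`` concatenates the CT and
    dose blocks plus clinical (437 columns). Patients missing any required
    block are dropped (logged on the returned frame's attrs).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if clinical.shape[1] != len(CLINICAL_FIELDS):
        raise ValueError("clinical table must have exactly the 7 encoded fields")
    if strategy == "Clinical":
        return clinical.copy()
    key_map = {"CT": ["ct"], "Dose": ["dose"], "DualCTDose": ["ct", "dose"],
               "LLRR": ["llrr"], "Wavelet": ["wavelet"], "WLS": ["wls"]}
    blocks = []
    index = clinical.index
    for key in key_map[strategy]:
        if key not in modality_features:
            raise ValueError(f"strategy {strategy} needs modality {key!r} features")
        block = modality_features[key]
        blocks.append(block.add_prefix(f"{key}_"))
        index = index.intersection(block.index)
    dropped = sorted(set(clinical.index) - set(index))
    # clinical features are always included alongside image features
    table = pd.concat([b.loc[index] for b in blocks] + [clinical.loc[index]], axis=1)
    table.attrs["dropped_patients"] = dropped
    return table
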