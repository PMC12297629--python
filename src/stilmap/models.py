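"""Lymph-node-metastasis prediction models and their evaluation battery.

Two random-forest classifiers are compared on the same patients:

* **M1** uses clinical/pathological covariates plus TIL features
  (``age_cat``, ``t_stage``, ``til_score``, ``stilc``);
* **M2** uses the clinical/pathological covariates only
  (``age_cat``, ``t_stage``).

Covariate encodings follow ordinal integer codes throughout: age category
0 (<45) / 1 (45-65) / 2 (>65); pathological T stage 0-3 for T1-T4; sTILC 1
("TIL-cold") / 2 ("TIL-hot"); outcome ``lnm`` 1 for any of N1-N3, 0 for N0.
Tree ensembles split ordinals natively, so no one-hot expansion is used.

Evaluation: ROC AUC (tie-corrected Mann-Whitney), the DeLong test for the
difference of two correlated AUCs, the Brier score, exact interventional
Shapley attributions (all 2^4 coalitions enumerated), and decision-curve
net benefit NB(t) = TP/N - FP/N * t/(1-t).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "FEATURES_M1",
    "FEATURES_M2",
    "PatientRecord",
    "FittedModel",
    "ModelComparisonReport",
    "split_cohort",
    "train_model",
    "roc_auc",
    "delong_test",
    "brier_score",
    "exact_shapley",
    "decision_curve",
    "summarize_cohorts",
    "run_ablation_scenarios",
    "compare_models",
]

FEATURES_M1 = ("age_cat", "t_stage", "til_score", "stilc")
FEATURES_M2 = ("age_cat", "t_stage")

#: hyperparameter grid searched by stratified 5-fold cross-validated AUC;
#: kept small so repeated cohort-level refits stay cheap on one CPU
HYPERPARAM_GRID = {
    "n_estimators": (100, 300),
    "max_depth": (3, 5, None),
    "min_samples_leaf": (1, 5, 10),
}


@dataclass(frozen=True)
class PatientRecord:
    """One patient: ordinal covariates, derived TIL features, and outcome."""

    patient_id: str
    age_cat: int  # 0: <45, 1: 45-65, 2: >65
    t_stage: int  # 0: T1 ... 3: T4
    til_score: float  # in [0, 1]
    stilc: int  # 1: sTILC1 (TIL-cold), 2: sTILC2 (TIL-hot)
    lnm: int  # 1: N1-N3, 0: N0

    def __post_init__(self) -> None:
        if self.age_cat not in (0, 1, 2):
            raise ValueError(f"age_cat must be 0/1/2, got {self.age_cat}")
        if self.t_stage not in (0, 1, 2, 3):
            raise ValueError(f"t_stage must be 0..3, got {self.t_stage}")
        if not 0.0 <= self.til_score <= 1.0:
            raise ValueError(f"til_score must lie in [0,1], got {self.til_score}")
        if self.stilc not in (1, 2):
            raise ValueError(f"stilc must be 1 or 2, got {self.stilc}")
        if self.lnm not in (0, 1):
            raise ValueError(f"lnm must be 0 or 1, got {self.lnm}")


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def split_cohort(
    cohort: pd.DataFrame, test_size: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 8:2 (by default) split into training and validation cohorts.

    Stratification is on the LNM outcome; the split is disjoint, exhaustive,
    and deterministic per seed.
    """
    if not 0 < test_size < 1:
        raise ValueError("test_size must lie strictly between 0 and 1")
    if len(cohort) < 10:
        raise ValueError("cohort too small to split (need >= 10 records)")
    y = cohort["lnm"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("cannot split a single-class cohort")
    train, val = train_test_split(
        cohort, test_size=test_size, stratify=y, random_state=seed
    )
    return train.reset_index(drop=True), val.reset_index(drop=True)


@dataclass
class FittedModel:
    """A fitted forest plus the feature contract it was trained under."""

    estimator: RandomForestClassifier
    features: tuple[str, ...]
    best_params: dict
    cv_auc: float
    seed: int

    def predict_proba(self, cohort: pd.DataFrame) -> np.ndarray:
        """Event probabilities (ensemble vote fractions, no recalibration)."""
        X = _design_matrix(cohort, self.features)
        return self.estimator.predict_proba(X)[:, 1]

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]


def _design_matrix(cohort: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing feature columns {missing}")
    return cohort[list(features)].to_numpy(dtype=float)


def train_model(
    training: pd.DataFrame,
    features: Sequence[str] = FEATURES_M1,
    seed: int = 0,
    n_folds: int = 5,
    param_grid: Mapping[str, Sequence] = HYPERPARAM_GRID,
) -> FittedModel:
    """Fit a bagged randomized-tree ensemble with CV-tuned hyperparameters.

    Hyperparameters (tree count, max depth, min leaf size) are selected by
    mean stratified ``n_folds``-fold cross-validated AUC over the declared
    grid; the winning setting is refitted on the full training cohort.
    Forests are grown with warm starts so each depth/leaf combination builds
    its largest forest only once per fold. Deterministic per seed; ties in CV
    AUC resolve to the earliest grid entry.
    """
    X = _design_matrix(training, features)
    y = training["lnm"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort has a single outcome class")

    ns = sorted(param_grid["n_estimators"])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    cv_scores: dict[tuple, list[float]] = {}
    for depth in param_grid["max_depth"]:
        for leaf in param_grid["min_samples_leaf"]:
            for tr, va in folds:
                rf = RandomForestClassifier(
                    n_estimators=ns[0], max_depth=depth, min_samples_leaf=leaf,
                    random_state=seed, warm_start=True,
                )
                for ne in ns:
                    rf.set_params(n_estimators=ne)
                    rf.fit(X[tr], y[tr])
                    p = rf.predict_proba(X[va])[:, 1]
                    cv_scores.setdefault((ne, depth, leaf), []).append(
                        roc_auc(p, y[va])
                    )

    grid_order = [
        (ne, depth, leaf)
        for ne in param_grid["n_estimators"]
        for depth in param_grid["max_depth"]
        for leaf in param_grid["min_samples_leaf"]
    ]
    mean_auc = {key: float(np.mean(cv_scores[key])) for key in grid_order}
    best_key = max(grid_order, key=lambda k: mean_auc[k])  # first wins ties

    best = {"n_estimators": best_key[0], "max_depth": best_key[1],
            "min_samples_leaf": best_key[2]}
    final = RandomForestClassifier(random_state=seed, **best).fit(X, y)
    return FittedModel(
        estimator=final, features=tuple(features), best_params=best,
        cv_auc=mean_auc[best_key], seed=seed,
    )


def roc_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the tie-corrected Mann-Whitney statistic.

    Equals the fraction of (event, non-event) pairs ranked concordantly,
    counting ties as one half.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = stats.rankdata(p)  # midranks handle ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def delong_test(
    probs_a: np.ndarray, probs_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """DeLong test for the difference of two correlated AUCs.

    Uses the structural-components (placement-value) estimator of
    Var(AUC_a - AUC_b) for ROC curves computed on the same subjects:
    per-subject placements V10 (events) and V01 (non-events) are formed from
    midranks, their empirical covariance matrices S10/n1 + S01/n0 give the
    variance of the AUC difference, and z = dAUC / sqrt(var) is referred to
    the standard normal (two-sided). Degenerate variance (e.g. identical
    score vectors) returns (0, 1) by convention.
    """
    y = np.asarray(labels, dtype=int)
    pa = np.asarray(probs_a, dtype=float)
    pb = np.asarray(probs_b, dtype=float)
    if pa.shape != pb.shape or pa.shape != y.shape:
        raise ValueError("paired score vectors and labels must share a shape")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("DeLong test requires both outcome classes")

    v10 = np.empty((2, n1))
    v01 = np.empty((2, n0))
    aucs = np.empty(2)
    for m, p in enumerate((pa, pb)):
        pos, neg = p[y == 1], p[y == 0]
        all_r = _midrank(np.concatenate([pos, neg]))
        pos_r, neg_r = _midrank(pos), _midrank(neg)
        v10[m] = (all_r[:n1] - pos_r) / n0  # P(neg < pos_i) with tie halves
        v01[m] = 1.0 - (all_r[n1:] - neg_r) / n1
        aucs[m] = v10[m].mean()

    if n1 < 2 or n0 < 2:
        return 0.0, 1.0
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ (s10 / n1 + s01 / n0) @ contrast)
    dauc = float(aucs[0] - aucs[1])
    if var <= 0 or not np.isfinite(var) or math.isclose(var, 0.0, abs_tol=1e-300):
        return 0.0, 1.0
    z = dauc / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def brier_score(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def exact_shapley(
    predict: Callable[[np.ndarray], np.ndarray] | FittedModel,
    records: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    features: Sequence[str] | None = None,
) -> np.ndarray:
    """Exact interventional Shapley attributions (records x features).

    The value of a coalition S at record x is the model output averaged over
    background rows with the features in S fixed to x's values — the
    interventional expectation. All 2^m coalitions are enumerated (feasible
    for the 4-feature M1 model: 16 coalitions), so the attributions satisfy
    the efficiency, dummy and symmetry axioms exactly: per record they sum to
    f(x) minus the mean background output.
    """
    if isinstance(predict, FittedModel):
        model = predict
        if features is None:
            features = model.features
        predict_fn = model.predict_matrix
    else:
        predict_fn = predict
        if features is None:
            raise ValueError("features must be given when predict is a callable")

    if isinstance(records, pd.DataFrame):
        X = _design_matrix(records, features)
    else:
        X = np.asarray(records, dtype=float)
    if isinstance(background, pd.DataFrame):
        B = _design_matrix(background, features)
    else:
        B = np.asarray(background, dtype=float)
    if B.shape[0] == 0:
        raise ValueError("background must contain at least one row")
    m = X.shape[1]
    if m > 12:
        raise ValueError("exact enumeration is limited to <= 12 features")

    n_rec, n_bg = X.shape[0], B.shape[0]
    coalitions = list(itertools.product((0, 1), repeat=m))

    # one batched prediction: for every (coalition, record, background) row
    big = np.empty((len(coalitions), n_rec, n_bg, m))
    for ci, mask in enumerate(coalitions):
        mk = np.array(mask, dtype=bool)
        blk = np.broadcast_to(B, (n_rec, n_bg, m)).copy()
        blk[:, :, mk] = X[:, None, mk]
        big[ci] = blk
    preds = predict_fn(big.reshape(-1, m)).reshape(len(coalitions), n_rec, n_bg)
    v = preds.mean(axis=2)  # coalition value per record

    index = {mask: ci for ci, mask in enumerate(coalitions)}
    fact = [math.factorial(i) for i in range(m + 1)]
    phi = np.zeros((n_rec, m))
    for mask in coalitions:
        s = sum(mask)
        weight = fact[s] * fact[m - s - 1] / fact[m]
        for j in range(m):
            if mask[j]:
                continue
            with_j = tuple(1 if i == j else mask[i] for i in range(m))
            phi[:, j] += weight * (v[index[with_j]] - v[index[mask]])
    return phi


def decision_curve(
    probs: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decision-curve net benefit for the model, treat-all and treat-none.

    NB(t) = TP(t)/N - FP(t)/N * t/(1-t), treating a record iff its predicted
    probability is >= t. Treat-all classifies everyone positive; treat-none
    has zero net benefit by definition. Thresholds must exclude t = 1.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("decision curve requires both outcome classes")
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0, 0.01), 2)
    t = np.asarray(thresholds, dtype=float)
    if np.any(t >= 1.0) or np.any(t <= 0.0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    odds = t / (1.0 - t)
    treated = p[None, :] >= t[:, None]
    tp = (treated & (y == 1)[None, :]).sum(axis=1) / n
    fp = (treated & (y == 0)[None, :]).sum(axis=1) / n
    prevalence = y.mean()
    return pd.DataFrame(
        {
            "threshold": t,
            "nb_model": tp - fp * odds,
            "nb_all": prevalence - (1 - prevalence) * odds,
            "nb_none": np.zeros_like(t),
        }
    )


_CATEGORICAL_VARS = ("age_cat", "t_stage", "stilc", "lnm")


def summarize_cohorts(cohorts: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Baseline characteristics table with between-cohort p-values.

    For each pair of cohorts, categorical variables (age category, T stage,
    sTILC, LNM status) are compared with the chi-square test (no continuity
    correction) and the continuous TIL score with Welch's unequal-variance
    t-test. Also tabulates counts/means by LNM status within each cohort.
    """
    names = list(cohorts)
    if len(names) < 2:
        raise ValueError("need at least two cohorts to compare")
    for nm, df in cohorts.items():
        if len(df) == 0:
            raise ValueError(f"cohort {nm!r} is empty")

    rows = []
    for a, b in itertools.combinations(names, 2):
        da, db = cohorts[a], cohorts[b]
        for var in _CATEGORICAL_VARS:
            if var not in da.columns or var not in db.columns:
                continue
            levels = sorted(set(da[var]) | set(db[var]))
            table = np.array(
                [[int((d[var] == lv).sum()) for lv in levels] for d in (da, db)]
            )
            table = table[:, table.sum(axis=0) > 0]
            if table.shape[1] < 2:
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append({"cohort_a": a, "cohort_b": b, "variable": var,
                         "test": "chi2", "statistic": float(stat), "p": float(p)})
        if "til_score" in da.columns and "til_score" in db.columns:
            res = stats.ttest_ind(da["til_score"], db["til_score"], equal_var=False)
            rows.append({"cohort_a": a, "cohort_b": b, "variable": "til_score",
                         "test": "welch_t", "statistic": float(res.statistic),
                         "p": float(res.pvalue)})
    by_lnm = []
    for nm, df in cohorts.items():
        if "lnm" not in df.columns:
            continue
        for status, sub in df.groupby("lnm"):
            by_lnm.append({"cohort_a": nm, "cohort_b": f"lnm={status}",
                           "variable": "n_records", "test": "count",
                           "statistic": float(len(sub)), "p": np.nan})
            if "til_score" in sub.columns:
                by_lnm.append({"cohort_a": nm, "cohort_b": f"lnm={status}",
                               "variable": "mean_til_score", "test": "mean",
                               "statistic": float(sub["til_score"].mean()),
                               "p": np.nan})
    return pd.DataFrame(rows + by_lnm)


def run_ablation_scenarios(
    training: pd.DataFrame,
    validation: pd.DataFrame,
    test: pd.DataFrame | None,
    pca_features: Mapping[str, pd.DataFrame],
    seed: int = 0,
) -> pd.DataFrame:
    """Refit M1 with alternative TIL-feature representations and report AUCs.

    Scenarios: (a) ``all_pcs`` — every PCA component in place of the sTILC
    label; (b) ``pc1_pc2`` — only the first two components; (c) ``stilc`` —
    the primary M1 feature set. ``pca_features`` maps cohort name
    ("training"/"validation"/"test") to a frame of PC columns (``pc1`` ...)
    aligned row-wise with the cohort. Reports train/validation/test AUC per
    scenario, which exposes the overfitting of high-dimensional variants.
    """
    cohorts = {"training": training, "validation": validation}
    if test is not None:
        cohorts["test"] = test
    for nm in cohorts:
        if nm not in pca_features:
            raise ValueError(f"missing PCA features for cohort {nm!r}")
        if len(pca_features[nm]) != len(cohorts[nm]):
            raise ValueError(f"PCA features misaligned for cohort {nm!r}")

    pc_cols = [c for c in pca_features["training"].columns if c.startswith("pc")]
    if not pc_cols:
        raise ValueError("pca_features must contain pc* columns")
    merged = {
        nm: pd.concat(
            [cohorts[nm].reset_index(drop=True),
             pca_features[nm].reset_index(drop=True)], axis=1
        )
        for nm in cohorts
    }
    scenarios = {
        "all_pcs": ("age_cat", "t_stage", "til_score", *pc_cols),
        "pc1_pc2": ("age_cat", "t_stage", "til_score", "pc1", "pc2"),
        "stilc": FEATURES_M1,
    }
    rows = []
    for name, feats in scenarios.items():
        model = train_model(merged["training"], features=feats, seed=seed)
        row = {"scenario": name}
        for nm, df in merged.items():
            row[f"auc_{nm}"] = roc_auc(model.predict_proba(df), df["lnm"].to_numpy())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ModelComparisonReport:
    """Paired M1-vs-M2 evaluation across named cohorts."""

    metrics: pd.DataFrame  # cohort, auc_m1, auc_m2, delong_z, delong_p, brier_m1, brier_m2
    shapley_mean_abs: dict[str, float]
    shapley_values: pd.DataFrame  # per-record attributions on the training cohort
    net_benefit: dict[str, pd.DataFrame]

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(orient="records"),
            "shapley_mean_abs": self.shapley_mean_abs,
            "net_benefit": {k: v.to_dict(orient="list")
                            for k, v in self.net_benefit.items()},
        }


def compare_models(
    m1: FittedModel,
    m2: FittedModel,
    cohorts: Mapping[str, pd.DataFrame],
    shapley_cohort: str = "training",
    shapley_background: pd.DataFrame | None = None,
    max_shapley_records: int | None = None,
    max_background: int = 100,
    seed: int = 0,
) -> ModelComparisonReport:
    """Run the full evaluation battery for M1 vs M2 on each cohort.

    AUC, DeLong z/p, and Brier score per cohort; exact Shapley attributions of
    M1 on ``shapley_cohort`` (against a background drawn from the training
    cohort unless given, capped at ``max_background`` rows for tractability);
    decision-curve net benefit per cohort.
    """
    rows = []
    nb: dict[str, pd.DataFrame] = {}
    for name, df in cohorts.items():
        y = df["lnm"].to_numpy(dtype=int)
        p1 = m1.predict_proba(df)
        p2 = m2.predict_proba(df)
        z, pval = delong_test(p1, p2, y)
        rows.append(
            {
                "cohort": name,
                "auc_m1": roc_auc(p1, y),
                "auc_m2": roc_auc(p2, y),
                "delong_z": z,
                "delong_p": pval,
                "brier_m1": brier_score(p1, y),
                "brier_m2": brier_score(p2, y),
            }
        )
        dca = decision_curve(p1, y)
        dca["nb_m2"] = decision_curve(p2, y)["nb_model"]
        nb[name] = dca

    rng = np.random.default_rng(seed)
    shap_df = cohorts[shapley_cohort]
    if max_shapley_records is not None and len(shap_df) > max_shapley_records:
        idx = rng.choice(len(shap_df), size=max_shapley_records, replace=False)
        shap_df = shap_df.iloc[np.sort(idx)]
    bg = shapley_background if shapley_background is not None else cohorts[shapley_cohort]
    if len(bg) > max_background:
        idx = rng.choice(len(bg), size=max_background, replace=False)
        bg = bg.iloc[np.sort(idx)]
    phi = exact_shapley(m1, shap_df, bg)
    shap_values = pd.DataFrame(phi, columns=list(m1.features))
    shap_values.insert(0, "patient_id", shap_df["patient_id"].to_numpy())
    mean_abs = {f: float(np.mean(np.abs(phi[:, j])))
                for j, f in enumerate(m1.features)}

    return ModelComparisonReport(
        metrics=pd.DataFrame(rows),
        shapley_mean_abs=mean_abs,
        shapley_values=shap_values,
        net_benefit=nb,
    )
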