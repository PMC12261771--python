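"""Feature selection, patient-level splitting, the six-model bench,
metric evaluation with patient-bootstrap CIs, importance, and the
logistic confirmation step.

The bench comprises a weighted ensemble over five seeded base
learners: XGBoost (max depth 6, L2-regularized logistic objective),
LightGBM (31 leaves), a histogram gradient-boosting model (max depth
6), random forest and extremely randomized trees (100 estimators,
Gini).  The ensemble uses greedy forward selection with replacement
over validation AUC, yielding convex weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import (ExtraTreesClassifier, HistGradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import roc_auc_score

META_COLS = ("patient_id", "window_id", "sub_window", "label")
BASE_MODEL_NAMES = ("XGBoost", "LightGBM", "HistGB", "RF", "ET")
DEFAULT_TOP_K = 65


class ModelingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def mutual_information_rank(features: pd.DataFrame, labels: np.ndarray,
                            seed: int = 0) -> list[tuple[str, float]]:
    """Features ranked by estimated MI with the binary label (descending).

    Uses the k-nearest-neighbour MI estimator with a fixed seed; ties
    (including exact duplicates) break by column order, so the ranking
    is deterministic.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ModelingError("labels are constant")
    x = features.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ModelingError("feature table must be imputed before ranking")
    mi = mutual_info_classif(x, y, random_state=seed)
    order = np.lexsort((np.arange(len(mi)), -mi))
    cols = list(features.columns)
    return [(cols[i], float(mi[i])) for i in order]


def select_top_k(ranking: list[tuple[str, float]], k: int = DEFAULT_TOP_K) -> list[str]:
    """The top-k feature names in rank order (default 65)."""
    if not 1 <= k <= len(ranking):
        raise ModelingError(f"k={k} out of range for {len(ranking)} features")
    return [name for name, _ in ranking[:k]]


def sweep_top_k(features: pd.DataFrame, labels, patients, ranking,
                ks=range(30, 101, 5), seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Validation-AUC sweep over candidate k; returns (best k, table)."""
    split = patient_split(np.unique(patients), seed=seed)
    assign = np.array([split.assignment[p] for p in patients])
    rows = []
    for k in ks:
        cols = select_top_k(ranking, k)
        model = HistGradientBoostingClassifier(max_depth=6, random_state=seed)
        model.fit(features.loc[assign == "train", cols],
                  np.asarray(labels)[assign == "train"])
        prob = model.predict_proba(features.loc[assign == "validation", cols])[:, 1]
        rows.append({"k": k, "val_auc": roc_auc_score(
            np.asarray(labels)[assign == "validation"], prob)})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["val_auc"].idxmax(), "k"])
    return best, table


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitAssignment:
    assignment: dict[str, str]  # patient_id -> train | validation | test
    seed: int

    def patients(self, part: str) -> list[str]:
        return [p for p, a in self.assignment.items() if a == part]


def patient_split(patients, proportions=(0.6, 0.2, 0.2), seed: int = 0) -> SplitAssignment:
    """Disjoint, exhaustive 60/20/20 partition of unique patients."""
    patients = list(dict.fromkeys(patients))
    if len(patients) < 5:
        raise ModelingError("need at least 5 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n = len(patients)
    n_train = int(round(proportions[0] * n))
    n_val = int(round(proportions[1] * n))
    assignment = {}
    for rank, idx in enumerate(order):
        part = ("train" if rank < n_train
                else "validation" if rank < n_train + n_val else "test")
        assignment[patients[idx]] = part
    return SplitAssignment(assignment, seed)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _make_base_models(seed: int) -> dict[str, object]:
    import lightgbm as lgb
    import xgboost as xgb

    return {
        "XGBoost": xgb.XGBClassifier(
            max_depth=6, n_estimators=100, objective="binary:logistic",
            reg_lambda=1.0, eval_metric="logloss", random_state=seed,
            n_jobs=1, verbosity=0, tree_method="hist"),
        "LightGBM": lgb.LGBMClassifier(
            num_leaves=31, n_estimators=100, random_state=seed, n_jobs=1,
            verbose=-1),
        "HistGB": HistGradientBoostingClassifier(max_depth=6, random_state=seed),
        "RF": RandomForestClassifier(n_estimators=100, criterion="gini",
                                     random_state=seed, n_jobs=1),
        "ET": ExtraTreesClassifier(n_estimators=100, criterion="gini",
                                   random_state=seed, n_jobs=1),
    }


def fit_models(x_train: pd.DataFrame, y_train, seed: int = 0) -> dict[str, object]:
    """Fit the five seeded base learners with the bench hyperparameters."""
    y = np.asarray(y_train)
    if np.unique(y).size < 2:
        raise ModelingError("training data contains a single class")
    models = _make_base_models(seed)
    for m in models.values():
        m.fit(x_train, y)
    return models


@dataclass
class WeightedEnsemble:
    """Convex combination of base-model probabilities."""

    models: dict[str, object]
    weights: dict[str, float]

    def predict_proba(self, x) -> np.ndarray:
        prob = np.zeros(len(x))
        for name, w in self.weights.items():
            if w > 0:
                prob += w * self.models[name].predict_proba(x)[:, 1]
        return np.column_stack([1 - prob, prob])


def build_weighted_ensemble(models: dict[str, object], x_val: pd.DataFrame,
                            y_val, n_rounds: int = 10) -> WeightedEnsemble:
    """Greedy forward selection (with replacement) maximizing validation AUC.

    The first pick is the best single model, so the ensemble's
    validation AUC can never fall below the best base learner's.
    """
    if len(models) < 2:
        raise ModelingError("need at least 2 base models")
    y = np.asarray(y_val)
    if len(y) == 0:
        raise ModelingError("no validation rows")
    probs = {name: m.predict_proba(x_val)[:, 1] for name, m in models.items()}
    counts = {name: 0 for name in models}
    current = np.zeros(len(y))
    total = 0
    for _ in range(n_rounds):
        best_name, best_auc = None, -np.inf
        for name, p in probs.items():
            cand = (current * total + p) / (total + 1)
            auc = roc_auc_score(y, cand)
            if auc > best_auc:
                best_name, best_auc = name, auc
        counts[best_name] += 1
        total += 1
        current = (current * (total - 1) + probs[best_name]) / total
    weights = {name: c / total for name, c in counts.items()}
    return WeightedEnsemble(models, weights)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    model_name: str
    accuracy: float      # percent
    auc: float
    sensitivity: float   # percent
    specificity: float   # percent
    accuracy_ci: tuple[float, float]
    auc_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    confusion: np.ndarray  # [[tn, fp], [fn, tp]]
    n_rows: int
    n_patients: int

    def as_dict(self) -> dict:
        return {
            "model": self.model_name,
            "accuracy_pct": self.accuracy, "accuracy_lo": self.accuracy_ci[0],
            "accuracy_hi": self.accuracy_ci[1],
            "auc": self.auc, "auc_lo": self.auc_ci[0], "auc_hi": self.auc_ci[1],
            "sensitivity_pct": self.sensitivity,
            "sensitivity_lo": self.sensitivity_ci[0],
            "sensitivity_hi": self.sensitivity_ci[1],
            "specificity_pct": self.specificity,
            "specificity_lo": self.specificity_ci[0],
            "specificity_hi": self.specificity_ci[1],
            "tn": int(self.confusion[0, 0]), "fp": int(self.confusion[0, 1]),
            "fn": int(self.confusion[1, 0]), "tp": int(self.confusion[1, 1]),
            "n_rows": self.n_rows, "n_patients": self.n_patients,
        }


def _point_metrics(y: np.ndarray, prob: np.ndarray, threshold: float):
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = 100.0 * (tp + tn) / len(y)
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    auc = roc_auc_score(y, prob) if np.unique(y).size == 2 else float("nan")
    return acc, auc, sens, spec, np.array([[tn, fp], [fn, tp]])


def evaluate(model, x: pd.DataFrame, y, patients, model_name: str = "",
             threshold: float = 0.5, n_boot: int = 1000, seed: int = 0) -> ModelReport:
    """Accuracy/AUC/sensitivity/specificity with patient-bootstrap 95% CIs.

    Rows are 10-minute sub-windows; the bootstrap resamples patients
    (with all their rows) to respect within-patient correlation.
    """
    y = np.asarray(y)
    patients = np.asarray(patients)
    if np.unique(y).size < 2:
        raise ModelingError("evaluation rows contain a single class")
    prob = model.predict_proba(x)[:, 1]
    acc, auc, sens, spec, conf = _point_metrics(y, prob, threshold)
    uniq = np.unique(patients)
    groups = {p: np.flatnonzero(patients == p) for p in uniq}
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, 4), np.nan)
    for b in range(n_boot):
        sel = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([groups[p] for p in sel])
        yb, pb = y[idx], prob[idx]
        if np.unique(yb).size < 2:
            continue
        a, u, se, sp, _ = _point_metrics(yb, pb, threshold)
        boots[b] = (a, u, se, sp)
    ok = boots[~np.isnan(boots).any(axis=1)]
    if len(ok):
        lo, hi = np.percentile(ok, [2.5, 97.5], axis=0)
    else:
        lo = hi = np.full(4, np.nan)
    return ModelReport(model_name, acc, auc, sens, spec,
                       (lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2]),
                       (lo[3], hi[3]), conf, len(y), uniq.size)


# ---------------------------------------------------------------------------
# importance
# ---------------------------------------------------------------------------

def shap_values(model, x: pd.DataFrame) -> np.ndarray | None:
    """TreeSHAP contributions (rows x features) for the boosted models.

    XGBoost and LightGBM expose the exact tree-explainer natively;
    other models return None and fall back to permutation importance.
    """
    import lightgbm as lgb
    import xgboost as xgb

    if isinstance(model, xgb.XGBClassifier):
        dm = xgb.DMatrix(x)
        contrib = model.get_booster().predict(dm, pred_contribs=True)
        return contrib[:, :-1]  # last column is the base value
    if isinstance(model, lgb.LGBMClassifier):
        contrib = model.predict(x, pred_contrib=True)
        return contrib[:, :-1]
    return None


def permutation_importance_auc(model, x: pd.DataFrame, y, n_repeats: int = 5,
                               seed: int = 0) -> np.ndarray:
    """Mean AUC drop when each feature is independently permuted."""
    y = np.asarray(y)
    base = roc_auc_score(y, model.predict_proba(x)[:, 1])
    rng = np.random.default_rng(seed)
    out = np.zeros(x.shape[1])
    xv = x.to_numpy(dtype=float)
    for j in range(x.shape[1]):
        drops = []
        for _ in range(n_repeats):
            perm = xv.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            pf = pd.DataFrame(perm, columns=x.columns)
            drops.append(base - roc_auc_score(y, model.predict_proba(pf)[:, 1]))
        out[j] = np.mean(drops)
    return out


def importance_report(model, x: pd.DataFrame, y, seed: int = 0) -> pd.DataFrame:
    """Ranked per-feature contributions for the best-performing model.

    Tree models: mean |SHAP| via the native tree explainer; otherwise
    (including the ensemble) the permutation AUC-drop fallback.
    """
    contrib = shap_values(model, x)
    if contrib is not None:
        scores = np.abs(contrib).mean(axis=0)
        method = "mean_abs_shap"
    else:
        scores = permutation_importance_auc(model, x, y, seed=seed)
        method = "permutation_auc_drop"
    df = pd.DataFrame({"feature": x.columns, "importance": scores,
                       "method": method})
    return df.sort_values("importance", ascending=False, kind="stable",
                          ignore_index=True)


# ---------------------------------------------------------------------------
# logistic confirmation
# ---------------------------------------------------------------------------

def logistic_confirmation(features: pd.DataFrame, labels, covariates: pd.DataFrame | None,
                          feature_names: list[str] | None = None) -> pd.DataFrame:
    """Per-feature odds ratios with Wald 95% CIs, unadjusted and adjusted.

    The adjusted model controls for age, sex, BMI, and neck and waist
    circumference.  Complete or quasi-separation is flagged in the
    ``converged`` column rather than dropped.
    """
    y = np.asarray(labels)
    names = feature_names or list(features.columns)
    rows = []
    for name in names:
        for kind in ("unadjusted", "adjusted"):
            cols = features[[name]].copy()
            if kind == "adjusted":
                if covariates is None:
                    continue
                cols = pd.concat([cols, covariates.reset_index(drop=True)], axis=1)
            xmat = sm.add_constant(cols.to_numpy(dtype=float))
            converged = True
            try:
                import warnings

                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, xmat).fit(disp=0, maxiter=200)
                converged = bool(fit.mle_retvals.get("converged", True))
                coef = fit.params[1]
                se = fit.bse[1]
                pval = fit.pvalues[1]
            except Exception:
                converged = False
                coef, se, pval = np.nan, np.nan, np.nan
            if not np.isfinite(coef):
                # separation: ridge-penalized refit recovers a finite,
                # correctly signed estimate (flagged, CI/p withheld)
                from sklearn.linear_model import LogisticRegression

                lr = LogisticRegression(C=10.0, max_iter=2000)
                lr.fit(cols.to_numpy(dtype=float), y)
                coef = float(lr.coef_[0, 0])
                se, pval = np.nan, np.nan
                converged = False
            rows.append({
                "feature": name, "model": kind,
                "or": float(np.exp(coef)) if np.isfinite(coef) else np.nan,
                "or_lo": float(np.exp(coef - 1.96 * se)) if np.isfinite(se) else np.nan,
                "or_hi": float(np.exp(coef + 1.96 * se)) if np.isfinite(se) else np.nan,
                "coef": float(coef), "p": float(pval),
                "stars": ("**" if pval < 0.01 else "*" if pval < 0.05 else "")
                if np.isfinite(pval) else "",
                "converged": converged,
            })
    return pd.DataFrame(rows)
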