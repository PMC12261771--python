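"""End-to-end stage functions shared by the CLI, the analysis drivers,
the tests and the acceptance script.

The pipeline streams patients (simulate -> label -> window -> extract)
so a cohort never holds more than one raw record in memory, then runs
imputation, mutual-information selection, the patient-level 60/20/20
split, the six-model bench, evaluation and the logistic confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import modeling
from .catalog import catalog
from .features import extract_window, feature_frame
from .labeling import apply_exclusions, label_record
from .modeling import (DEFAULT_TOP_K, ModelReport, SplitAssignment,
                       build_weighted_ensemble, evaluate, fit_models,
                       importance_report, logistic_confirmation,
                       mutual_information_rank, patient_split, select_top_k)
from .preprocess import impute_chained
from .simulate import SimulationConfig, simulate_cohort

COVARIATE_COLS = ("age", "sex", "bmi", "neck_cm", "waist_cm")


@dataclass
class CohortFeatures:
    """Feature rows plus labeling bookkeeping for a cohort."""

    table: pd.DataFrame
    exclusion_log: list[tuple[str, str]]
    windows: pd.DataFrame
    n_simulated: int
    n_included: int


def build_feature_table(config: SimulationConfig, lactate_op: str = "ge",
                        scenario_preference: int = 1,
                        progress: bool = False) -> CohortFeatures:
    """Simulate, label, window and extract a cohort into one long table.

    Each included patient contributes one observation and one control
    window, each split into five 10-minute sub-windows (rows).
    Covariates are carried as metadata columns for the adjusted
    regression.
    """
    vectors = []
    log: list[tuple[str, str]] = []
    win_rows = []
    cov_by_patient = {}
    n_included = 0
    iterator = simulate_cohort(config)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, total=config.n_patients, desc="cohort")
    for record, truth in iterator:
        event, windows = label_record(record, lactate_op, scenario_preference)
        included, patient_log = apply_exclusions([(record, event, windows)])
        log.extend(patient_log)
        if not included:
            continue
        n_included += 1
        record, event, windows = included[0]
        cov_by_patient[record.patient_id] = record.covariates
        for w in windows:
            win_rows.append({"patient_id": w.patient_id, "role": w.role,
                             "scenario": w.scenario, "start": w.start,
                             "end": w.end, "label": w.label})
            vectors.extend(extract_window(record, w))
    table = feature_frame(vectors)
    if len(table):
        for col in COVARIATE_COLS:
            table[col] = [getattr(cov_by_patient[p], col)
                          for p in table["patient_id"]]
    return CohortFeatures(table, log, pd.DataFrame(win_rows),
                          config.n_patients, n_included)


@dataclass
class TrainResult:
    ranking: list[tuple[str, float]]
    selected: list[str]
    split: SplitAssignment
    models: dict[str, object]
    reports_test: dict[str, ModelReport]
    reports_val: dict[str, ModelReport]
    best_model_name: str
    importance: pd.DataFrame
    odds_ratios: pd.DataFrame

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.reports_test.values()])


def train_and_evaluate(cohort: CohortFeatures, seed: int = 0,
                       k: int = DEFAULT_TOP_K, threshold: float = 0.5,
                       n_boot: int = 1000) -> TrainResult:
    """Impute, select, split by patient, fit the bench and evaluate."""
    table = cohort.table
    feat_cols = list(catalog().names)
    completed = impute_chained(table[feat_cols], seed=seed)
    y = table["label"].to_numpy()
    patients = table["patient_id"].to_numpy()

    ranking = mutual_information_rank(completed, y, seed=seed)
    selected = select_top_k(ranking, k)

    split = patient_split(pd.unique(patients), seed=seed)
    assign = np.array([split.assignment[p] for p in patients])
    x = completed[selected]
    xt, yt = x[assign == "train"], y[assign == "train"]
    xv, yv = x[assign == "validation"], y[assign == "validation"]
    xs, ys = x[assign == "test"], y[assign == "test"]
    ps = patients[assign == "test"]

    models = fit_models(xt, yt, seed=seed)
    ensemble = build_weighted_ensemble(models, xv, yv)
    bench = {"WeightedEnsemble": ensemble, **models}

    reports_test = {name: evaluate(m, xs, ys, ps, name, threshold, n_boot, seed)
                    for name, m in bench.items()}
    reports_val = {name: evaluate(m, xv, yv, patients[assign == "validation"],
                                  name, threshold, max(n_boot // 4, 100), seed)
                   for name, m in bench.items()}
    best = max(reports_test, key=lambda n: reports_test[n].auc)
    imp_model = bench[best]
    importance = importance_report(imp_model, xs, ys, seed=seed)

    covs = table.loc[:, list(COVARIATE_COLS)]
    odds = logistic_confirmation(completed, y, covs, selected)

    return TrainResult(ranking, selected, split, bench, reports_test,
                       reports_val, best, importance, odds)


def run_all(config: SimulationConfig, seed: int | None = None,
            k: int = DEFAULT_TOP_K, lactate_op: str = "ge",
            scenario_preference: int = 1, n_boot: int = 1000,
            progress: bool = False) -> tuple[CohortFeatures, TrainResult]:
    """The full pipeline under one seed."""
    if seed is not None and seed != config.seed:
        from dataclasses import replace

        config = replace(config, seed=seed)
    cohort = build_feature_table(config, lactate_op, scenario_preference, progress)
    result = train_and_evaluate(cohort, seed=config.seed, k=k, n_boot=n_boot)
    return cohort, result
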