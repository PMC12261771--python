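"""Select features by mutual information and train the six-model bench.

Consumes the feature table of step 03: chained-equation imputation,
MI ranking with the default top-65 selection, a patient-level 60/20/20
split, the five seeded base learners plus the greedy weighted
ensemble, and evaluation with patient-bootstrap 95% CIs.
"""

from pathlib import Path

import pandas as pd

from preshock.pipeline import CohortFeatures, train_and_evaluate

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def main() -> None:
    table = pd.read_csv(OUT / "features.csv")
    windows = pd.read_csv(OUT / "windows.csv")
    cohort = CohortFeatures(table, [], windows, table.patient_id.nunique(),
                            table.patient_id.nunique())
    result = train_and_evaluate(cohort, seed=SEED)
    result.summary_table().to_csv(OUT / "model_reports.csv", index=False)
    pd.DataFrame(result.ranking, columns=["feature", "mi"]).to_csv(
        OUT / "mi_ranking.csv", index=False)
    pd.Series(result.selected, name="feature").to_csv(
        OUT / "selected_features.csv", index=False)
    cols = ["model", "auc", "auc_lo", "auc_hi", "accuracy_pct",
            "sensitivity_pct", "specificity_pct"]
    print(result.summary_table()[cols].to_string(index=False,
                                                 float_format="%.3f"))
    print(f"best model: {result.best_model_name}")


if __name__ == "__main__":
    main()
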