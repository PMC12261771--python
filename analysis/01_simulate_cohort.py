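"""Simulate the synthetic ICU cohort and write its ground-truth manifest.

A seeded cohort of shock patients is generated with the default
pre-shock drift; the manifest records each patient's true onset and
which self-control scenario the record layout supports.  Waveforms are
regenerated deterministically by later steps, so only the manifest is
persisted here.
"""

from pathlib import Path

import pandas as pd

from preshock.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7
N_PATIENTS = 40


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = SimulationConfig(n_patients=N_PATIENTS, seed=SEED)
    rows = []
    for record, truth in simulate_cohort(config):
        rows.append({
            "patient_id": record.patient_id,
            "shock": truth.shock,
            "onset_s": truth.onset_s,
            "scenario1_feasible": truth.scenario1_feasible,
            "scenario2_feasible": truth.scenario2_feasible,
            "n_labs": len(record.labs),
            "max_lactate": max(v for _, v in record.labs),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(OUT / "cohort_manifest.csv", index=False)
    print(f"simulated {len(manifest)} patients "
          f"({manifest.shock.sum()} shock) -> {OUT / 'cohort_manifest.csv'}")


if __name__ == "__main__":
    main()
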