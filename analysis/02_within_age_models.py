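"""Within-age models: how well does each cohort's own model classify it,
and what do the GPS features add?

Runs scripted-protocol (S1A) leave-one-subject-out evaluation of the general
five-placement model for each cohort, with and without GPS features, on the
data simulated by 01_simulate_cohorts.py.  Writes results/within_age.csv
(accuracies and per-class F1) and prints the running/walking confusion rates
that differ between cohorts.
"""

from pathlib import Path

import pandas as pd

from patd.evaluation import confusion_pair_rate, run_design
from patd.modeling import ModelConfig, build_feature_table
from patd.segmentation import SegmentationConfig
from patd.sensor_io import read_cohort

SEED = 2021
N_TREES = 100

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    if not DATA_DIR.exists():
        raise SystemExit("no simulated data found — run analysis/01_simulate_cohorts.py first")
    records = read_cohort(DATA_DIR)
    seg = SegmentationConfig()
    cache: dict = {}
    rows = []
    for sensor_mode in ("acc", "acc_gps"):
        cfg = ModelConfig(sensor_mode, "general", n_trees=N_TREES, seed=SEED)
        table = build_feature_table(records, cfg, seg, cache=cache)
        for design in ("within_old", "within_young"):
            report = run_design(records, "S1A", design, cfg, table=table)
            f1 = report.per_class_metrics()["f1"]
            rows.append({
                "design": design,
                "sensor_mode": sensor_mode,
                "overall_accuracy": round(report.accuracy, 2),
                **{f"f1_{cls}": round(float(v), 2) for cls, v in f1.items()},
            })
            rw = confusion_pair_rate(report.pooled, "running", "walking")
            print(f"{design} [{sensor_mode}]: accuracy {report.accuracy:.2f}%, "
                  f"running/walking confusion {rw:.2f}%")
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "within_age.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
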