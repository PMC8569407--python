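"""Which single device placement classifies best, and what does fusing all
five add?

Evaluates the general model and each single-placement model on the old
cohort (scripted protocol, accelerometer features, leave-one-subject-out).
Writes results/placements.csv.
"""

from pathlib import Path

import pandas as pd

from patd import POSITIONS
from patd.evaluation import run_design
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
    records = [r for r in read_cohort(DATA_DIR) if r.cohort == "old"]
    seg = SegmentationConfig()
    cache: dict = {}
    rows = []
    for scope in ["general"] + [f"individual:{p}" for p in POSITIONS]:
        cfg = ModelConfig("acc", scope, n_trees=N_TREES, seed=SEED)
        table = build_feature_table(records, cfg, seg, cache=cache)
        report = run_design(records, "S1A", "within_old", cfg, table=table)
        rows.append({"scope": scope, "overall_accuracy": round(report.accuracy, 2)})
        print(f"{scope}: {report.accuracy:.2f}%")
    frame = pd.DataFrame(rows)
    best = frame[frame.scope != "general"].sort_values("overall_accuracy").iloc[-1]
    print(f"\nbest single placement: {best.scope} at {best.overall_accuracy:.2f}%")
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "placements.csv"
    frame.to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
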