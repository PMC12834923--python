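"""Compute the five gaze metrics for every read of the simulated study.

Reads the gaze logs and masks written by 01_simulate_study.py and emits
one metrics row per read (interpretation time, lesion dwell, time to first
fixation, path length, lung coverage, capture ratio) to
results/metrics.csv.

Run from the repository root:  python analysis/02_compute_metrics.py
"""

import argparse
from pathlib import Path

import pandas as pd

from gazecad.io import load_cases, read_gaze_csv, read_mask_png
from gazecad.pipeline import compute_metric_row


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--dataset-dir", type=Path, default=Path("scratch/dataset"))
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    manifest = pd.read_csv(args.dataset_dir / "manifest.csv")
    cases = {c.case_id: c for c in load_cases(args.dataset_dir / "cases.csv")}
    rows = []
    mask, mask_file = None, None
    for entry in manifest.sort_values("case_id").itertuples():
        if entry.mask_file != mask_file:
            mask_file = entry.mask_file
            mask = read_mask_png(args.dataset_dir / mask_file)
        rec = read_gaze_csv(args.dataset_dir / entry.gaze_file)
        case = cases[str(entry.case_id)]
        row = compute_metric_row(rec, case, mask)
        row.update(reader=entry.reader, session=entry.session,
                   case_id=entry.case_id, group=case.group.value)
        rows.append(row)

    table = pd.DataFrame(rows)
    args.results_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.results_dir / "metrics.csv", index=False)
    print(f"metrics for {len(table)} reads -> results/metrics.csv")
    med = table.groupby(["reader", "session"])[
        ["interpretation_time_s", "dwell_s", "ttff_s", "path_px", "coverage_pct"]
    ].median().round(2)
    print("per reader/session medians (all groups):")
    print(med)


if __name__ == "__main__":
    main()
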