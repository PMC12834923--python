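"""Apply the capture-ratio validity criterion and pair cases across sessions.

A read is valid when strictly more than 50% of the expected gaze samples
were captured; the paired analysis set per reader is the intersection of
valid TP cases across the two sessions (listwise deletion).  Writes
results/validity.csv and results/pairing.csv.

Run from the repository root:  python analysis/03_validity_pairing.py
"""

import argparse
from pathlib import Path

import pandas as pd

from gazecad.design import Group
from gazecad.io import load_cases
from gazecad.validity import listwise_pair, make_validity_record, pairing_frame, validity_frame


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    parser.add_argument("--threshold", type=float, default=0.5)
    args = parser.parse_args()

    metrics = pd.read_csv(args.results_dir / "metrics.csv")
    cases = load_cases(args.results_dir / "cases.csv")
    records = [
        make_validity_record(r.reader, r.session, r.case_id, r.capture_ratio,
                             args.threshold)
        for r in metrics.itertuples()
    ]
    tp = {c.case_id for c in cases if c.group is Group.TP}
    pairing = listwise_pair(records, scope=tp, threshold=args.threshold)

    validity_frame(records).to_csv(args.results_dir / "validity.csv", index=False)
    ptab = pairing_frame(pairing)
    ptab.to_csv(args.results_dir / "pairing.csv", index=False)
    print(f"validity criterion: capture ratio > {args.threshold:.0%} "
          f"({sum(r.valid for r in records)}/{len(records)} reads valid)")
    print("paired TP cases per reader (listwise deletion):")
    print(ptab.to_string(index=False))


if __name__ == "__main__":
    main()
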