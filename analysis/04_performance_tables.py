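"""Tabulate diagnostic performance and box-adoption rates.

Uses every interpretation (validity filtering never applies here):
per-group accuracy by session, improved/worsened counts, adoption rates,
and overall sensitivity/specificity per reader.  Writes the
table1_*.csv family under results/.

Run from the repository root:  python analysis/04_performance_tables.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gazecad.io import load_cases
from gazecad.performance import performance_table


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--dataset-dir", type=Path, default=Path("scratch/dataset"))
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    reads = pd.read_csv(args.dataset_dir / "reads.csv")
    cases = load_cases(args.results_dir / "cases.csv")
    tables = performance_table(reads, cases)

    for name, df in tables.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(args.results_dir / f"table1_{name}.csv", index=False)
    with open(args.results_dir / "table1_metadata.json", "w") as fh:
        json.dump(tables["metadata"], fh, indent=1)

    acc = tables["accuracy"]
    tp = acc[acc.group == "TP"].pivot(index="reader", columns="session",
                                      values="accuracy_pct").round(1)
    print("TP accuracy (%) by reader (session 1 = with boxes):")
    print(tp.to_string())
    print("\nBB adoption rate (%) by group:")
    print(tables["adoption"].pivot(index="group", columns="reader",
                                   values="adoption_pct").round(1).to_string())


if __name__ == "__main__":
    main()
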