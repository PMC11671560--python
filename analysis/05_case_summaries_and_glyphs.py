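#!/usr/bin/env python
"""Aggregate per-frame features into per-case abundances and draw glyphs.

Each case's abundance is the percentage of its analyzable frames showing
each feature; cases are rendered as a grid of Chernoff faces (one face per
case) plus a per-tumor-type median table.
"""

from pathlib import Path

import pandas as pd

from cle_afq import aggregate_case, cohort_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    feats = pd.read_csv(RESULTS / "features.csv")
    manifest = pd.read_csv(RESULTS / "cohort_manifest.csv")
    types = dict(zip(manifest["case_id"].astype(str), manifest["tumor_type"]))
    summaries = [
        aggregate_case(group, tumor_type=types.get(str(case_id), ""))
        for case_id, group in feats.groupby("case_id", sort=True)
    ]
    paths = cohort_report(summaries, RESULTS)
    print(f"{len(summaries)} cases summarized")
    for s in summaries:
        top = sorted(s.pct.items(), key=lambda kv: -kv[1])[:3]
        print(f"  {s.case_id} ({s.tumor_type}, {s.n_images} frames): "
              + ", ".join(f"{k}={v:.0f}%" for k, v in top if v > 0))
    print("wrote", ", ".join(str(p) for p in paths.values()))


if __name__ == "__main__":
    main()
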