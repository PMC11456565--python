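"""Repair pulse-interval artifacts in the simulated recordings.

Reads results/simulated/subject_XX_rr.csv, writes cleaned series next to
them as subject_XX_rr_clean.csv plus a per-subject artifact summary.
"""

import argparse
from pathlib import Path

import pandas as pd

from turnload.core import RRSeries
from turnload.preprocessing import clean


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--threshold", type=float, default=0.2)
    args = ap.parse_args()

    rows = []
    for path in sorted(args.dir.glob("subject_*_rr.csv")):
        if path.stem.endswith("_clean"):
            continue
        rr = RRSeries.read_csv(path)
        cleaned, mask = clean(rr, args.threshold)
        out = path.with_name(path.stem + "_clean.csv")
        cleaned.to_csv(out)
        rows.append({
            "subject": path.stem.split("_")[1],
            "n_intervals": len(rr),
            "n_flagged": mask.n_flagged,
            "flagged_pct": 100 * mask.n_flagged / len(rr),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(args.dir / "artifact_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"mean flagged: {summary['flagged_pct'].mean():.2f}% of intervals")


if __name__ == "__main__":
    main()
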