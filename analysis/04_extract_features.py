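"""Windowed HRV features (30 per window) labeled by detected turn class.

Reads the cleaned series and detected segments, writes results/features.csv
with one row per labeled 30-s window.
"""

import argparse
from pathlib import Path

from turnload.core import RRSeries, segments_from_csv
from turnload.features import extract_features, feature_frame
from turnload.segmentation import label_windows


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out", type=Path, default=Path("results/features.csv"))
    args = ap.parse_args()

    per_subject = {}
    for path in sorted(args.dir.glob("subject_*_rr_clean.csv")):
        subject = int(path.stem.split("_")[1])
        rr = RRSeries.read_csv(path)
        segments = segments_from_csv(args.dir / f"subject_{subject:02d}_segments.csv")
        windows = extract_features(rr)
        per_subject[subject] = label_windows(windows, segments)

    table = feature_frame(per_subject)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    counts = table["class_id"].value_counts().sort_index()
    print(f"{len(table)} labeled windows from {len(per_subject)} subjects -> {args.out}")
    print("windows per class (1=climbing, 2=leveling, 3=descending):")
    print(counts.to_string())


if __name__ == "__main__":
    main()
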