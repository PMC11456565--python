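"""Simulate the flight cohort: telemetry, heartbeat series, ground truth.

Writes, per subject, under results/simulated/:
  subject_XX_telemetry.csv   time_s,heading_deg,altitude_ft,speed_kt
  subject_XX_rr.csv          time_s,rr_ms
  subject_XX_truth.csv       start_s,end_s,...,class_id,class_name
"""

import argparse
from pathlib import Path

from turnload.core import segments_to_csv
from turnload.synthetic import make_dataset


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--subjects", type=int, default=28)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    datasets = make_dataset(args.subjects, seed=args.seed)
    for ds in datasets:
        tag = f"subject_{ds.subject:02d}"
        ds.track.to_csv(args.out / f"{tag}_telemetry.csv")
        ds.rr.to_csv(args.out / f"{tag}_rr.csv")
        segments_to_csv(ds.true_segments, args.out / f"{tag}_truth.csv")

    n_beats = sum(len(ds.rr) for ds in datasets)
    dur = datasets[0].track.time[-1] / 60
    print(f"simulated {len(datasets)} subjects, {dur:.1f} min flights, "
          f"{n_beats} beats total -> {args.out}")


if __name__ == "__main__":
    main()
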