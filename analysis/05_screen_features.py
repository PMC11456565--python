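"""Screen the 30 HRV features across turn-load classes.

Normality routes each feature to ANOVA or Kruskal-Wallis; the output table
(results/screening.csv) lists per-class means and p-values, most significant
first, mirroring the usual presentation of such screens.
"""

import argparse
from pathlib import Path

import pandas as pd

from turnload.screening import screen_features, screening_table, select_features


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", type=Path, default=Path("results/screening.csv"))
    args = ap.parse_args()

    features = pd.read_csv(args.features)
    results = screen_features(features, alpha=args.alpha)
    table = screening_table(results)
    table.to_csv(args.out, index=False)
    selected = select_features(results, alpha=args.alpha)
    print(table.head(12).to_string(index=False))
    print(f"\n{len(selected)}/30 features significant at p < {args.alpha}; "
          f"most significant: {', '.join(selected[:7])}")


if __name__ == "__main__":
    main()
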