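"""Train the four turn-load classifiers and report test-set metrics.

Uses the screened features, builds length-3 window sequences per turn,
splits 70/30 (stratified), scales to [0, 1], balances the training classes
by up-sampling, then fits LSTM-Attention, plain LSTM, KNN and RF.
Writes results/model_metrics.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from turnload.evaluation import compare_models
from turnload.models import TrainConfig
from turnload.pipeline import train_and_evaluate
from turnload.screening import screen_features, select_features


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/model_metrics.csv"))
    ap.add_argument("--paper-order", action="store_true",
                    help="balance classes before splitting instead of after")
    args = ap.parse_args()

    features = pd.read_csv(args.features)
    selected = select_features(screen_features(features))
    config = TrainConfig(seed=args.seed)
    reports, histories, _ = train_and_evaluate(
        features, selected, config, paper_order=args.paper_order
    )
    table = compare_models(list(reports.values()))
    table.to_csv(args.out, index=False)
    print(table.to_string(index=False))
    for name, h in histories.items():
        print(f"{name}: {h['epochs_run']} epochs, best val loss {h['best_val_loss']:.4f}")


if __name__ == "__main__":
    main()
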