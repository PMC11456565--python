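"""End-to-end experiment drivers.

``run_experiment`` wires the whole chain together on simulated subjects:

    simulate → artifact repair → turn segmentation → windowed HRV features
    → statistical screening → sequence classification → evaluation

and returns every intermediate product, so the analysis scripts, the tests
and the acceptance script all exercise one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, models, preprocessing, screening, segmentation
from .features import FEATURE_NAMES, extract_features, feature_frame
from .models import TrainConfig
from .synthetic import SyntheticDataset, make_dataset

logger = logging.getLogger(__name__)


@dataclass
class SegmentationCheck:
    """Agreement between detected turns and the generator's ground truth."""

    n_true: int = 0
    n_detected: int = 0
    n_recovered: int = 0
    n_class_correct: int = 0

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_true if self.n_true else float("nan")

    @property
    def label_accuracy(self) -> float:
        return self.n_class_correct / self.n_true if self.n_true else float("nan")


def check_segmentation(true_segments, detected) -> SegmentationCheck:
    """Match detected turns to ground truth by time overlap."""
    chk = SegmentationCheck(n_true=len(true_segments), n_detected=len(detected))
    for ts in true_segments:
        best, best_ov = None, 0.0
        for d in detected:
            ov = min(ts.end_time, d.end_time) - max(ts.start_time, d.start_time)
            if ov > best_ov:
                best, best_ov = d, ov
        if best is not None and best_ov > 0.5 * ts.duration:
            chk.n_recovered += 1
            if best.class_id == ts.class_id:
                chk.n_class_correct += 1
    return chk


def process_subjects(
    datasets: list[SyntheticDataset],
    rel_threshold: float = 0.2,
    turn_threshold: float = 20.0,
    level_band: float = 50.0,
    min_overlap: float = 0.5,
) -> tuple[pd.DataFrame, SegmentationCheck]:
    """Clean, segment, window and label every subject; pool the features."""
    chk = SegmentationCheck()
    per_subject = {}
    for ds in datasets:
        rr_clean, _ = preprocessing.clean(ds.rr, rel_threshold)
        detected = segmentation.detect_turns(
            ds.track, threshold=turn_threshold, level_band=level_band
        )
        sub = check_segmentation(ds.true_segments, detected)
        chk.n_true += sub.n_true
        chk.n_detected += sub.n_detected
        chk.n_recovered += sub.n_recovered
        chk.n_class_correct += sub.n_class_correct
        windows = extract_features(rr_clean)
        per_subject[ds.subject] = segmentation.label_windows(
            windows, detected, min_overlap=min_overlap
        )
    return feature_frame(per_subject), chk


@dataclass
class ExperimentResult:
    features: pd.DataFrame
    segmentation: SegmentationCheck
    screening: list
    selected_features: list[str]
    reports: dict[str, evaluation.EvaluationReport]
    histories: dict[str, dict]
    ranking: pd.DataFrame
    y_test: np.ndarray = None
    test_probs: dict[str, np.ndarray] = field(default_factory=dict)


def train_and_evaluate(
    features: pd.DataFrame,
    selected: list[str],
    config: TrainConfig,
    permute_labels: bool = False,
    paper_order: bool = False,
    model_names: tuple[str, ...] = ("LSTM-Attention", "LSTM", "KNN", "RF"),
) -> tuple[dict, dict, dict]:
    """Sequence construction, split, scaling, balancing, training, reports.

    ``paper_order`` balances classes before splitting instead of after
    (up-sampled duplicates then leak across the split — kept only as a
    fidelity option).  ``permute_labels`` shuffles the labels first, giving
    the chance-level reference.
    """
    X, y, _ = models.make_sequences(features, selected, seq_len=config.seq_len)
    if permute_labels:
        rng = np.random.default_rng(config.seed + 90000)
        y = rng.permutation(y)
    if paper_order:
        X, y = models.upsample_balance(X, y, seed=config.seed + 1)
    Xtr, Xte, ytr, yte = models.split(X, y, train_frac=config.train_frac, seed=config.seed)
    Xtr, Xte, _ = models.normalize01(Xtr, Xte)
    if not paper_order:
        Xtr, ytr = models.upsample_balance(Xtr, ytr, seed=config.seed + 1)

    reports, histories, probs = {}, {}, {}
    for name in model_names:
        if name == "LSTM-Attention":
            model = models.build_lstm_attention(len(selected), config)
            histories[name] = models.train_model(model, Xtr, ytr, config)
            prob = model.predict_proba(Xte)
        elif name == "LSTM":
            model = models.build_lstm(len(selected), config)
            histories[name] = models.train_model(model, Xtr, ytr, config)
            prob = model.predict_proba(Xte)
        else:
            base = models.train_baselines(Xtr, ytr, seed=config.seed)[name]
            prob = base.predict_proba(Xte)
        probs[name] = prob
        reports[name] = evaluation.classification_metrics(yte, prob, model_name=name)
    return reports, histories, {"y_test": yte, "probs": probs}


def run_experiment(
    n_subjects: int = 28,
    seed: int = 0,
    config: TrainConfig | None = None,
    alpha: float = 0.05,
    min_selected: int = 4,
    permute_labels: bool = False,
    model_names: tuple[str, ...] = ("LSTM-Attention", "LSTM", "KNN", "RF"),
) -> ExperimentResult:
    """The full study on simulated subjects.

    Features are screened at level ``alpha``; if fewer than ``min_selected``
    survive (small simulations can be under-powered), the top
    ``min_selected`` by p-value are used so the classifiers always have a
    feature set to work with.
    """
    config = config or TrainConfig(seed=seed)
    datasets = make_dataset(n_subjects, seed=seed)
    features, seg_check = process_subjects(datasets)
    results = screening.screen_features(features, alpha=alpha)
    selected = screening.select_features(results, alpha=alpha)
    if len(selected) < min_selected:
        ranked = sorted(results, key=lambda r: r.p_value)
        selected = [r.feature_name for r in ranked[:min_selected]]
        logger.warning("screen under-powered; using top %d features", min_selected)
    reports, histories, preds = train_and_evaluate(
        features, selected, config, permute_labels=permute_labels, model_names=model_names
    )
    ranking = (
        evaluation.compare_models(list(reports.values())) if len(reports) > 1 else None
    )
    return ExperimentResult(
        features=features,
        segmentation=seg_check,
        screening=results,
        selected_features=selected,
        reports=reports,
        histories=histories,
        ranking=ranking,
        y_test=preds["y_test"],
        test_probs=preds["probs"],
    )
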