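"""End-to-end synthetic benchmark mirroring the original study design.

Trains the 13-10-6 network on segmented features of generated images
and scores it on a held-out set.  The per-class sample counts default
to the original study's composition: a training set of
70/69/72/70/75/76 images across the six classes, a lab test set of
23/15/18/21/25/30 and a field test set of 20/18/20/21/25/23.
"""

from __future__ import annotations

import numpy as np

from . import ann
from .errors import PestPipeError
from .features import extract_features
from .segmentation import SegmentationConfig, rgb_to_hsv, segment
from .synthetic_data import DEFAULT_BAND, SPECIES, make_dataset

#: Per-class sample counts of the original training/test composition.
TRAIN_COUNTS = (70, 69, 72, 70, 75, 76)
LAB_TEST_COUNTS = (23, 15, 18, 21, 25, 30)
FIELD_TEST_COUNTS = (20, 18, 20, 21, 25, 23)


def features_of_dataset(images, seg_cfg: SegmentationConfig | None = None):
    """Segment + extract features for a generated set.

    Returns (X, labels, n_failed); images whose segmentation fails are
    dropped from the matrix and counted.
    """
    if seg_cfg is None:
        seg_cfg = SegmentationConfig(band=DEFAULT_BAND)
    rows, labels = [], []
    n_failed = 0
    for li in images:
        try:
            hsv = rgb_to_hsv(li.image)
            mask = segment(li.image, seg_cfg)
            rows.append(extract_features(li.image, mask, hsv=hsv))
            labels.append(li.label)
        except PestPipeError:
            n_failed += 1
    return np.asarray(rows), labels, n_failed


def run_benchmark(
    regime: str = "easy",
    seed: int = 0,
    train_counts=TRAIN_COUNTS,
    test_counts=None,
    canvas: int = 96,
    train_cfg: ann.TrainConfig | None = None,
) -> dict:
    """Full pipeline benchmark; returns accuracy and per-class detail.

    Train and test sets come from independent seeds derived from
    ``seed``.  A test image whose segmentation fails counts as an
    error (the fielded system would misreport it too).
    """
    if test_counts is None:
        test_counts = LAB_TEST_COUNTS if regime == "easy" else FIELD_TEST_COUNTS
    ss = np.random.SeedSequence(seed)
    s_train, s_test, s_fit = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))

    train_set = make_dataset(n_per_class=train_counts, regime=regime,
                             seed=s_train, canvas=canvas)
    test_set = make_dataset(n_per_class=test_counts, regime=regime,
                            seed=s_test, canvas=canvas)

    Xtr, ytr, tr_failed = features_of_dataset(train_set)
    Xte, yte, te_failed = features_of_dataset(test_set)

    if train_cfg is None:
        train_cfg = ann.TrainConfig(learning_rate=0.2, max_epochs=300,
                                    target_mse=1e-3, seed=s_fit)
    model = ann.train(Xtr, ytr, train_cfg, class_names=list(SPECIES))

    n_total = sum(test_counts)
    per_class = {name: {"n": 0, "correct": 0} for name in SPECIES}
    n_correct = 0
    for x, truth in zip(Xte, yte):
        label, _ = ann.predict(model, x)
        per_class[truth]["n"] += 1
        if label == truth:
            per_class[truth]["correct"] += 1
            n_correct += 1
    accuracy = n_correct / n_total  # segmentation failures count against
    return {
        "regime": regime,
        "accuracy": accuracy,
        "n_train": len(Xtr),
        "n_test": n_total,
        "segmentation_failures": tr_failed + te_failed,
        "per_class": per_class,
        "final_train_mse": model.training_mse[-1] if model.training_mse else None,
        "model": model,
    }
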