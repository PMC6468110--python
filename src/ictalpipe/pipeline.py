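"""End-to-end detection pipeline glue.

Ties the stages together the way the semiautomated workflow is used in
practice: an annotated training recording (the "seizure library") fits the
epoch classifier and the HMM; the fitted detector is then applied to new
recordings and its events are scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import detector as det
from .features import FeatureSpec, build_feature_matrix
from .signal_io import AnnotationTrack, Recording, epoch_recording, labels_from_annotations
from .synthetic import EcogSimConfig, draw_seizure_events, generate_ecog

__all__ = ["FittedDetector", "train_detector", "apply_detector", "synthetic_benchmark"]


@dataclass
class FittedDetector:
    classifier: det.ClassifierModel
    hmm: det.HMMParams
    feature_spec: FeatureSpec
    epoch_length: float
    standardization: tuple[np.ndarray, np.ndarray]


def train_detector(
    recording: Recording,
    annotations: AnnotationTrack,
    epoch_length: float = 5.0,
    feature_spec: FeatureSpec | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> FittedDetector:
    """Fit classifier + HMM from one annotated recording."""
    feature_spec = feature_spec or FeatureSpec()
    index = epoch_recording(recording, epoch_length)
    labels = labels_from_annotations(annotations, index)
    fm = build_feature_matrix(recording, index, feature_spec)
    model, oof = det.train_epoch_classifier(fm, labels, n_folds=n_folds, seed=seed)
    hmm = det.estimate_hmm_params(oof, labels)
    return FittedDetector(model, hmm, feature_spec, epoch_length, (fm.mean_, fm.sd_))


def apply_detector(
    fitted: FittedDetector,
    recording: Recording,
    threshold: float = 0.5,
    min_duration_epochs: int = 2,
    merge_gap_epochs: int = 1,
) -> tuple[list[det.SeizureEvent], np.ndarray]:
    """Run a fitted detector over a recording; returns (events, posteriors).

    Held-out features are standardized with the training-set parameters
    (no re-fitting on test data).
    """
    index = epoch_recording(recording, fitted.epoch_length)
    spec = fitted.feature_spec
    raw_spec = FeatureSpec(spec.bands, spec.include_line_length, spec.extras, False)
    fm = build_feature_matrix(recording, index, raw_spec)
    mean, sd = fitted.standardization
    if mean is not None:
        fm.values = (fm.values - mean) / sd
    obs = fitted.classifier.predict_labels(fm)
    post, _ = det.forward_backward(obs, fitted.hmm)
    events = det.decode_events(
        post, index, threshold, min_duration_epochs, merge_gap_epochs
    )
    return events, post


def synthetic_benchmark(
    seed: int = 0,
    n_events: int = 20,
    amplitude_ratio: float = 10.0,
    duration: float | None = None,
) -> dict:
    """Train on one synthetic recording, detect on an independent one.

    The default benchmark places ``n_events`` seizures of 50–200 s in each
    recording at the given ictal/baseline amplitude ratio, trains the full
    classifier → HMM chain on the first recording and scores event-wise
    detection on the second. Returns the evaluation metrics plus the decoded
    events.
    """
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = n_events * 300.0
    results = {}
    recs = []
    for part in ("train", "test"):
        cfg = EcogSimConfig(
            duration=duration,
            seizure_amplitude_ratio=amplitude_ratio,
            seed=int(rng.integers(2**31)),
        )
        events = draw_seizure_events(duration, n_events, rng)
        recs.append(generate_ecog(cfg, events))
    (train_rec, train_track), (test_rec, test_track) = recs
    fitted = train_detector(train_rec, train_track, seed=seed)
    events, post = apply_detector(fitted, test_rec)
    metrics = det.evaluate_detector(events, test_track)
    results.update(metrics)
    results["events"] = events
    results["truth"] = test_track
    results["posteriors"] = post
    results["fitted"] = fitted
    return results
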