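"""Semiautomated seizure detection: classifier, HMM smoothing, event decoding.

The detection chain mirrors supervised chronic-ECoG seizure screening: a
discriminative classifier (random forest by default) labels each 5 s epoch
as baseline or seizure; the per-epoch predictions are then treated as the
observation sequence of a two-state hidden Markov model whose hidden states
are the manual annotations, and the forward–backward algorithm yields
smoothed posterior seizure probabilities. The HMM is parameterized
empirically: the transition matrix from annotation-sequence transition
counts, the emission matrix from the confusion table of *out-of-fold*
classifier predictions against annotations (out-of-fold so the emissions are
not optimistically clean), and the initial distribution as the stationary
distribution of the transition matrix. Contiguous high-posterior epochs are
finally merged into seizure events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .signal_io import BASELINE, SEIZURE, AnnotationTrack, EpochIndex
from .features import EpochFeatureMatrix

__all__ = [
    "ClassifierModel",
    "HMMParams",
    "SeizureEvent",
    "train_epoch_classifier",
    "estimate_hmm_params",
    "forward_backward",
    "decode_events",
    "evaluate_detector",
    "events_to_track",
]


@dataclass
class ClassifierModel:
    """A fitted per-epoch classifier plus its training metadata."""

    model: RandomForestClassifier
    feature_names: list[str]
    classes: np.ndarray
    fold_assignment: np.ndarray
    seed: int

    def predict_labels(self, features: EpochFeatureMatrix) -> np.ndarray:
        return self.model.predict(features.values).astype(int)

    def predict_proba(self, features: EpochFeatureMatrix) -> np.ndarray:
        return self.model.predict_proba(features.values)


@dataclass
class HMMParams:
    """Two-state (baseline, seizure) HMM parameters.

    ``transition[i, j] = P(state j at t+1 | state i at t)``;
    ``emission[s, o] = P(observed classifier label o | true state s)``;
    ``initial`` is the marginal distribution of the first state.
    """

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        for name, arr, axis in (
            ("initial", self.initial, None),
            ("transition", self.transition, 1),
            ("emission", self.emission, 1),
        ):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            sums = arr.sum() if axis is None else arr.sum(axis=axis)
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise ValueError(f"{name} rows must sum to 1 (got {sums})")


@dataclass
class SeizureEvent:
    """A decoded seizure: time span in seconds plus posterior summaries."""

    onset: float
    offset: float
    mean_posterior: float
    peak_posterior: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def train_epoch_classifier(
    features: EpochFeatureMatrix,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 200,
) -> tuple[ClassifierModel, np.ndarray]:
    """Fit the epoch classifier and return out-of-fold predictions.

    Cross-validation is stratified over the two classes with a seeded
    shuffle. The out-of-fold predicted labels for every training epoch feed
    the HMM emission estimate, so the emission matrix reflects honest
    generalization error rather than training-set fit.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if np.min(np.bincount(labels)) < n_folds:
        raise ValueError(
            "cannot stratify: the minority class has fewer epochs than folds"
        )

    X = features.values
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty(labels.size, dtype=int)
    fold_of = np.empty(labels.size, dtype=int)
    for k, (tr, te) in enumerate(skf.split(X, labels)):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        clf.fit(X[tr], labels[tr])
        oof[te] = clf.predict(X[te]).astype(int)
        fold_of[te] = k

    final = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    final.fit(X, labels)
    model = ClassifierModel(final, features.feature_names, classes, fold_of, seed)
    return model, oof


def _stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Left Perron eigenvector of a row-stochastic matrix, normalized."""
    w, v = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def estimate_hmm_params(
    predictions: np.ndarray, labels: np.ndarray, pseudocount: float = 1.0
) -> HMMParams:
    """Empirical HMM parameters from predictions and annotations.

    The transition matrix row-normalizes the annotation sequence's
    transition counts; the emission matrix row-normalizes the confusion
    counts P(predicted | true). A pseudocount (default 1) keeps rows valid
    when the annotations contain no transitions of some kind. The initial
    distribution is the stationary distribution of the transition matrix.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty annotation sequence")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be aligned")

    trans = np.full((2, 2), float(pseudocount))
    for a, b in zip(labels[:-1], labels[1:]):
        trans[a, b] += 1.0
    trans /= trans.sum(axis=1, keepdims=True)

    emis = np.full((2, 2), float(pseudocount))
    for s, o in zip(labels, predictions):
        emis[s, o] += 1.0
    emis /= emis.sum(axis=1, keepdims=True)

    return HMMParams(_stationary_distribution(trans), trans, emis, pseudocount)


def forward_backward(
    observations: np.ndarray, params: HMMParams
) -> tuple[np.ndarray, float]:
    """Exact HMM smoothing of a discrete observation sequence.

    Runs the scaled forward–backward recursions and returns
    ``(posteriors, log_likelihood)`` where ``posteriors[t, s]`` is
    P(state_t = s | all observations). Per-step scaling keeps the recursion
    stable over arbitrarily long sequences; the scaling constants give back
    the exact sequence log-likelihood.
    """
    obs = np.asarray(observations, dtype=int)
    if obs.size == 0:
        raise ValueError("empty observation sequence")
    if obs.min() < 0 or obs.max() >= params.emission.shape[1]:
        raise ValueError("observation outside the emission alphabet")

    n, s = obs.size, params.transition.shape[0]
    alpha = np.empty((n, s))
    scale = np.empty(n)

    a = params.initial * params.emission[:, obs[0]]
    scale[0] = a.sum()
    if scale[0] == 0:
        raise ValueError("observation sequence has zero probability under the model")
    alpha[0] = a / scale[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ params.transition) * params.emission[:, obs[t]]
        scale[t] = a.sum()
        if scale[t] == 0:
            raise ValueError(
                "observation sequence has zero probability under the model"
            )
        alpha[t] = a / scale[t]

    beta = np.empty((n, s))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        b = params.transition @ (params.emission[:, obs[t + 1]] * beta[t + 1])
        beta[t] = b / scale[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, float(np.sum(np.log(scale)))


def decode_events(
    posteriors: np.ndarray,
    index: EpochIndex,
    threshold: float = 0.5,
    min_duration_epochs: int = 2,
    merge_gap_epochs: int = 1,
) -> list[SeizureEvent]:
    """Turn smoothed posteriors into seizure events.

    Epochs whose seizure posterior is ≥ ``threshold`` form runs; runs
    separated by at most ``merge_gap_epochs`` sub-threshold epochs are
    merged, and merged runs shorter than ``min_duration_epochs`` are
    dropped. Event times are reported in seconds.
    """
    p = np.asarray(posteriors)
    if p.ndim == 2:
        p = p[:, SEIZURE]
    hot = p >= threshold

    runs: list[list[int]] = []
    start = None
    for i, h in enumerate(hot):
        if h and start is None:
            start = i
        elif not h and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, len(hot)])

    merged: list[list[int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= merge_gap_epochs:
            merged[-1][1] = r[1]
        else:
            merged.append(r)

    events = []
    for a, b in merged:
        if b - a < min_duration_epochs:
            continue
        seg = p[a:b]
        events.append(
            SeizureEvent(
                onset=index.time_span(a)[0],
                offset=index.time_span(b - 1)[1],
                mean_posterior=float(seg.mean()),
                peak_posterior=float(seg.max()),
            )
        )
    return events


def events_to_track(
    events: list[SeizureEvent], recording_duration: float
) -> AnnotationTrack:
    """Package decoded events as an annotation track (detector output)."""
    return AnnotationTrack(
        [(e.onset, e.offset, "seizure") for e in events], recording_duration
    )


def evaluate_detector(
    predicted: list[SeizureEvent] | AnnotationTrack,
    truth: AnnotationTrack,
    min_overlap_fraction: float = 0.5,
) -> dict:
    """Event-wise detection metrics against ground-truth annotations.

    A true seizure counts as detected if predicted events cover at least
    ``min_overlap_fraction`` of it; a predicted event with no overlapping
    true seizure is a false positive. Returns sensitivity, the false-positive
    rate per 24 h, and the event-wise confusion counts.
    """
    if isinstance(predicted, AnnotationTrack):
        pred_ivs = predicted.seizure_intervals
    else:
        pred_ivs = [(e.onset, e.offset) for e in predicted]
    true_ivs = truth.seizure_intervals

    detected = 0
    for t0, t1 in true_ivs:
        cov = sum(max(0.0, min(t1, b) - max(t0, a)) for a, b in pred_ivs)
        if cov >= min_overlap_fraction * (t1 - t0):
            detected += 1

    false_pos = 0
    for a, b in pred_ivs:
        if not any(min(t1, b) > max(t0, a) for t0, t1 in true_ivs):
            false_pos += 1

    days = truth.recording_duration / 86_400.0
    return {
        "n_true": len(true_ivs),
        "n_predicted": len(pred_ivs),
        "true_positives": detected,
        "false_negatives": len(true_ivs) - detected,
        "false_positives": false_pos,
        "sensitivity": detected / len(true_ivs) if true_ivs else float("nan"),
        "false_positives_per_24h": false_pos / days if days > 0 else float("nan"),
    }
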