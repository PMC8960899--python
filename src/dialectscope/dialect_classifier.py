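"""Two-class song dialect classification with sliding-window confidences.

Protocol: train a probability-emitting classifier on spectral summary
features of 1-s windows (50% overlap), then score each recording by the mean
per-window class confidence over a 4.5-s trim.  Training validation is
computed on the training recordings themselves and is flagged as
non-independent; honest evaluation uses held-out individuals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.linear_model import LogisticRegression

from .synthetic_data.types import SongRecording

WINDOW_S = 1.0
HOP_S = 0.5
DEFAULT_TRIM_S = 4.5

_N_BANDS = 20
_BAND_LO, _BAND_HI = 400.0, 8000.0

#: (bird_id, recording) — the unit handled by all classifier operations.
RecordingItem = tuple[str, SongRecording]


@dataclass
class WindowFeatures:
    window_start: float
    feature_vector: np.ndarray


@dataclass
class TrainedDialectModel:
    class_labels: tuple[str, str]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    estimator: LogisticRegression
    n_train: dict[str, int]
    seed: int
    training_validation: float | None = None  # non-independent; for reporting only

    def window_prob_a(self, features: np.ndarray) -> np.ndarray:
        """Probability of the first class per window (rows = windows)."""
        z = (features - self.scaler_mean) / self.scaler_std
        proba = self.estimator.predict_proba(z)
        col = list(self.estimator.classes_).index(0)
        return proba[:, col]


@dataclass
class ClassificationReport:
    per_recording: pd.DataFrame  # bird_id, true_label, predicted, confidence
    success: float
    n_train: dict[str, int]
    n_test: dict[str, int]


@dataclass
class MLSimilarityScore:
    male_id: str
    female_rearing_aviary: str
    score: float
    n_recordings_averaged: int
    mode: str = "parents"


def _band_edges(sr: int, n_fft: int) -> np.ndarray:
    freqs = np.geomspace(_BAND_LO, _BAND_HI, _N_BANDS + 2)
    return np.clip(freqs, 0, sr / 2)


def _window_feature_vector(wave: np.ndarray, sr: int) -> np.ndarray:
    """Spectral summary of one 1-s slice: log band powers (mean/std/delta),
    centroid, bandwidth, rolloff and flatness statistics."""
    nperseg = 512
    f, _, sxx = signal.stft(wave, fs=sr, nperseg=nperseg, noverlap=nperseg // 2)
    p = np.abs(sxx) ** 2 + 1e-12
    edges = _band_edges(sr, nperseg)
    bands = np.empty((_N_BANDS, p.shape[1]))
    for i in range(_N_BANDS):
        sel = (f >= edges[i]) & (f < edges[i + 2])
        bands[i] = p[sel].mean(axis=0) if sel.any() else 1e-12
    logb = np.log(bands)
    total = p.sum(axis=0)
    centroid = (f[:, None] * p).sum(axis=0) / total
    bandwidth = np.sqrt(((f[:, None] - centroid) ** 2 * p).sum(axis=0) / total)
    cum = np.cumsum(p, axis=0) / total
    rolloff = f[np.argmax(cum >= 0.85, axis=0)]
    flatness = np.exp(np.log(p).mean(axis=0)) / p.mean(axis=0)
    scalars = np.array(
        [
            centroid.mean(), centroid.std(),
            bandwidth.mean(), bandwidth.std(),
            rolloff.mean(), rolloff.std(),
            flatness.mean(), flatness.std(),
            np.abs(np.diff(centroid)).mean() if p.shape[1] > 1 else 0.0,
        ]
    )
    delta = np.abs(np.diff(logb, axis=1)).mean(axis=1) if p.shape[1] > 1 else np.zeros(_N_BANDS)
    return np.concatenate([logb.mean(axis=1), logb.std(axis=1), delta, scalars])


def extract_windows(recording: SongRecording) -> list[WindowFeatures]:
    """Cut a recording into 1-s windows at a 0.5-s hop and featurise each.

    A 4.5-s recording yields 8 windows (starts 0.0, 0.5, ..., 3.5 s).
    """
    sr = recording.sample_rate
    n = len(recording.waveform)
    win = int(WINDOW_S * sr)
    hop = int(HOP_S * sr)
    if n < win:
        raise ValueError(
            f"recording of {n / sr:.2f} s is shorter than the {WINDOW_S} s analysis window"
        )
    out = []
    for start in range(0, n - win + 1, hop):
        vec = _window_feature_vector(recording.waveform[start : start + win], sr)
        out.append(WindowFeatures(window_start=start / sr, feature_vector=vec))
    return out


def _stack_windows(recordings: list[RecordingItem]) -> np.ndarray:
    feats = []
    for _, rec in recordings:
        feats.extend(w.feature_vector for w in extract_windows(rec))
    return np.vstack(feats)


def train_classifier(
    class_a: list[RecordingItem],
    class_b: list[RecordingItem],
    seed: int,
    *,
    labels: tuple[str, str] = ("A", "B"),
) -> TrainedDialectModel:
    """Fit the windowed dialect classifier on two recording sets."""
    if len(class_a) < 2 or len(class_b) < 2:
        raise ValueError("need at least 2 recordings per class")
    xa = _stack_windows(class_a)
    xb = _stack_windows(class_b)
    x = np.vstack([xa, xb])
    y = np.concatenate([np.zeros(len(xa), dtype=int), np.ones(len(xb), dtype=int)])
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    if np.all(std < 1e-12):
        warnings.warn("degenerate training features (all identical); fit is uninformative",
                      stacklevel=2)
    std = np.where(std < 1e-12, 1.0, std)
    est = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    est.fit((x - mean) / std, y)
    model = TrainedDialectModel(
        class_labels=labels,
        scaler_mean=mean,
        scaler_std=std,
        estimator=est,
        n_train={labels[0]: len(class_a), labels[1]: len(class_b)},
        seed=seed,
    )
    # non-independent internal validation on the training recordings
    correct = 0
    for items, lab in ((class_a, labels[0]), (class_b, labels[1])):
        for _, rec in items:
            pred, _ = classify_recording(model, rec, trim=None)
            correct += pred == lab
    model.training_validation = correct / (len(class_a) + len(class_b))
    return model


def classify_recording(
    model: TrainedDialectModel,
    recording: SongRecording,
    trim: float | None = DEFAULT_TRIM_S,
) -> tuple[str, float]:
    """Label a recording and return its mean class-A confidence.

    Confidences of the two classes are complementary (sum to 1).  ``trim``
    cuts the recording to its first ``trim`` seconds; recordings shorter
    than the trim are rejected.
    """
    if trim is not None:
        need = int(trim * recording.sample_rate)
        if len(recording.waveform) < need:
            raise ValueError(
                f"recording of {recording.duration:.2f} s is shorter than the "
                f"required {trim} s trim"
            )
        recording = SongRecording(
            waveform=recording.waveform[:need],
            sample_rate=recording.sample_rate,
            bird_id=recording.bird_id,
        )
    feats = np.vstack([w.feature_vector for w in extract_windows(recording)])
    conf_a = float(model.window_prob_a(feats).mean())
    if conf_a == 0.5:
        warnings.warn("tied confidence 0.5; assigning first class", stacklevel=2)
    label = model.class_labels[0] if conf_a >= 0.5 else model.class_labels[1]
    return label, conf_a


def success_proportion(true_labels: list[str], predicted: list[str]) -> float:
    """Proportion of correctly classified recordings."""
    if not true_labels:
        raise ValueError("empty label list")
    if len(true_labels) != len(predicted):
        raise ValueError("label lists differ in length")
    return float(np.mean([t == p for t, p in zip(true_labels, predicted)]))


def _evaluate(
    model: TrainedDialectModel,
    items_by_label: dict[str, list[RecordingItem]],
    trim: float | None,
) -> ClassificationReport:
    rows = []
    for lab, items in items_by_label.items():
        for bird_id, rec in items:
            pred, conf = classify_recording(model, rec, trim=trim)
            rows.append({"bird_id": bird_id, "true_label": lab, "predicted": pred,
                         "confidence": conf})
    per_rec = pd.DataFrame(rows)
    return ClassificationReport(
        per_recording=per_rec,
        success=success_proportion(per_rec["true_label"].tolist(), per_rec["predicted"].tolist()),
        n_train=dict(model.n_train),
        n_test={lab: len(items) for lab, items in items_by_label.items()},
    )


def population_classification_success(
    train: dict[str, list[RecordingItem]],
    test: dict[str, list[RecordingItem]],
    pop_pairs: list[tuple[str, str]] | None = None,
    *,
    trim: float = DEFAULT_TRIM_S,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], dict[str, ClassificationReport]]]:
    """Pairwise classification over populations.

    Returns a square matrix (validation success below the diagonal, held-out
    test success above) plus per-pair reports.  Training and test individuals
    must be disjoint.
    """
    pops = sorted(train)
    if pop_pairs is None:
        pop_pairs = list(itertools.combinations(pops, 2))
    matrix = pd.DataFrame(np.nan, index=pops, columns=pops)
    reports: dict[tuple[str, str], dict[str, ClassificationReport]] = {}
    for p, q in pop_pairs:
        train_ids = {bid for bid, _ in train[p] + train[q]}
        test_ids = {bid for bid, _ in test.get(p, []) + test.get(q, [])}
        overlap = train_ids & test_ids
        if overlap:
            raise ValueError(f"train/test individuals overlap: {sorted(overlap)[:5]}")
        model = train_classifier(train[p], train[q], seed=seed, labels=(p, q))
        validation = _evaluate(model, {p: train[p], q: train[q]}, trim)
        held_out = _evaluate(model, {p: test[p], q: test[q]}, trim)
        lo, hi = sorted((p, q))
        matrix.loc[hi, lo] = validation.success  # below diagonal
        matrix.loc[lo, hi] = held_out.success  # above diagonal
        reports[(p, q)] = {"validation": validation, "test": held_out}
    return matrix, reports


def ml_similarity(
    female_rearing_aviary: str,
    tutor_set: list[RecordingItem],
    contrast_set: list[RecordingItem],
    candidate_males: list[RecordingItem],
    seed: int,
    *,
    mode: str = "parents",
    trim: float = DEFAULT_TRIM_S,
) -> list[MLSimilarityScore]:
    """Confidence of each candidate male's songs belonging to the focal
    female's rearing-aviary dialect class, averaged over his recordings."""
    if not tutor_set:
        raise ValueError("tutor set is empty")
    tutor_ids = {bid for bid, _ in tutor_set} | {bid for bid, _ in contrast_set}
    cand_ids = {bid for bid, _ in candidate_males}
    overlap = cand_ids & tutor_ids
    if overlap:
        raise ValueError(f"candidate males present in training set: {sorted(overlap)[:5]}")
    model = train_classifier(tutor_set, contrast_set, seed=seed, labels=("same", "different"))
    scores: dict[str, list[float]] = {}
    for bird_id, rec in candidate_males:
        _, conf = classify_recording(model, rec, trim=trim)
        scores.setdefault(bird_id, []).append(conf)
    return [
        MLSimilarityScore(
            male_id=bid,
            female_rearing_aviary=female_rearing_aviary,
            score=float(np.mean(vals)),
            n_recordings_averaged=len(vals),
            mode=mode,
        )
        for bid, vals in scores.items()
    ]
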