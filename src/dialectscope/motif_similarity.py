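"""Surrogate pairwise motif similarity on a 0-100 scale.

Per-frame feature trajectories (pitch, spectral entropy, FM, amplitude,
centroid; 10 ms step, 20 ms window) are z-scaled jointly and aligned by
dynamic time warping; the mean local distance along the optimal path is
mapped to [0, 100] via ``100 * exp(-cost / KAPPA)``.  Identical inputs score
100; the scale is comparable within this artifact only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data.types import SAMPLE_RATE, SongRecording

FRAME_STEP_S = 0.010
FRAME_WIN_S = 0.020
_PITCH_LO, _PITCH_HI = 400.0, 8000.0

#: Cost-to-score scale, frozen after one-off calibration on synthetic motifs
#: (chosen so that motif-vs-white-noise scores fall below 30 while
#: tutor-pupil pairs at low innovation stay high).
KAPPA = 1.6

#: Sakoe-Chiba band radius as a fraction of the longer trajectory.
BAND_FRACTION = 0.10


@dataclass
class SimilarityScore:
    value: float
    motif_a: str
    motif_b: str
    mode: str = "pairwise"  # or "to_supermotif"


@dataclass
class SuperMotif:
    source_ids: list[str]
    audio: np.ndarray
    sample_rate: int = SAMPLE_RATE


def feature_trajectory(wave: np.ndarray, sr: int = SAMPLE_RATE) -> np.ndarray:
    """Frame-wise (pitch Hz, entropy proxy, FM, log amplitude, centroid)."""
    if len(wave) == 0 or np.abs(wave).max() < 1e-6:
        raise ValueError("silent input: pitch undefined")
    step = int(FRAME_STEP_S * sr)
    win = int(FRAME_WIN_S * sr)
    n_frames = max(1, (len(wave) - win) // step + 1)
    freqs = np.fft.rfftfreq(win, 1 / sr)
    band = (freqs >= _PITCH_LO) & (freqs <= _PITCH_HI)
    pitch = np.empty(n_frames)
    entropy = np.empty(n_frames)
    amp = np.empty(n_frames)
    centroid = np.empty(n_frames)
    hann = np.hanning(win)
    for i in range(n_frames):
        frame = wave[i * step : i * step + win] * hann
        spec = np.abs(np.fft.rfft(frame)) ** 2 + 1e-12
        pitch[i] = freqs[band][np.argmax(spec[band])]
        entropy[i] = np.log(np.exp(np.log(spec).mean()) / spec.mean())  # Wiener entropy
        amp[i] = 0.5 * np.log((frame**2).mean() + 1e-12)
        centroid[i] = (freqs * spec).sum() / spec.sum()
    fm = np.abs(np.diff(pitch, prepend=pitch[0]))
    return np.column_stack([pitch, entropy, fm, amp, centroid])


def _dtw_mean_cost(
    a: np.ndarray,
    b: np.ndarray,
    *,
    open_end: bool = False,
    band_radius: int | None = None,
) -> float:
    """Mean local distance along the optimal DTW path.

    ``open_end=True`` aligns ``a`` as a subsequence of ``b`` (free start and
    end along ``b``).  ``band_radius`` constrains |i*m/n - j| when closed.
    """
    n, m = len(a), len(b)
    local = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    inf = np.inf
    acc = np.full((n, m), inf)
    steps = np.zeros((n, m), dtype=np.int64)
    slope = m / n
    for i in range(n):
        if open_end or band_radius is None:
            lo, hi = 0, m
        else:
            c = int(round(i * slope))
            lo, hi = max(0, c - band_radius), min(m, c + band_radius + 1)
        for j in range(lo, hi):
            d = local[i, j]
            if i == 0:
                if open_end or j == 0:
                    acc[i, j] = d
                    steps[i, j] = 1
                elif acc[i, j - 1] < inf:
                    acc[i, j] = acc[i, j - 1] + d
                    steps[i, j] = steps[i, j - 1] + 1
                continue
            best = inf
            bs = 0
            if acc[i - 1, j] < best:
                best, bs = acc[i - 1, j], steps[i - 1, j]
            if j > 0:
                if acc[i, j - 1] < best:
                    best, bs = acc[i, j - 1], steps[i, j - 1]
                if acc[i - 1, j - 1] < best:
                    best, bs = acc[i - 1, j - 1], steps[i - 1, j - 1]
            if best < inf:
                acc[i, j] = best + d
                steps[i, j] = bs + 1
    if open_end:
        j_best = int(np.argmin(acc[n - 1]))
        return float(acc[n - 1, j_best] / steps[n - 1, j_best])
    if not np.isfinite(acc[n - 1, m - 1]):
        raise RuntimeError("DTW band too narrow for the given length ratio")
    return float(acc[n - 1, m - 1] / steps[n - 1, m - 1])


def _zscale_pair(fa: np.ndarray, fb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    joint = np.vstack([fa, fb])
    mean = joint.mean(axis=0)
    std = joint.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return (fa - mean) / std, (fb - mean) / std


def pairwise_similarity(
    audio_a: np.ndarray,
    audio_b: np.ndarray,
    *,
    id_a: str = "a",
    id_b: str = "b",
    sr: int = SAMPLE_RATE,
) -> SimilarityScore:
    """Symmetric 0-100 similarity of two motif audios (100 iff identical)."""
    fa = feature_trajectory(audio_a, sr)
    fb = feature_trajectory(audio_b, sr)
    za, zb = _zscale_pair(fa, fb)
    n, m = len(za), len(zb)
    radius = max(int(BAND_FRACTION * max(n, m)), abs(n - m) + 2)
    cost = _dtw_mean_cost(za, zb, band_radius=radius)
    value = 100.0 * np.exp(-cost / KAPPA)
    return SimilarityScore(value=float(value), motif_a=id_a, motif_b=id_b, mode="pairwise")


def similarity_to_supermotif(
    audio: np.ndarray,
    supermotif: SuperMotif,
    *,
    id_a: str = "a",
    sr: int = SAMPLE_RATE,
) -> SimilarityScore:
    """Open-end similarity of a motif against a longer concatenation: the
    motif trajectory is aligned as a subsequence of the super-motif."""
    fa = feature_trajectory(audio, sr)
    fb = feature_trajectory(supermotif.audio, supermotif.sample_rate)
    za, zb = _zscale_pair(fa, fb)
    if len(za) <= len(zb):
        cost = _dtw_mean_cost(za, zb, open_end=True)
    else:
        cost = _dtw_mean_cost(zb, za, open_end=True)
    value = 100.0 * np.exp(-cost / KAPPA)
    return SimilarityScore(
        value=float(value), motif_a=id_a, motif_b="+".join(supermotif.source_ids),
        mode="to_supermotif",
    )


def build_super_motif(recordings: list[tuple[str, np.ndarray]], sr: int = SAMPLE_RATE) -> SuperMotif:
    """Concatenate motif audios, in the given order, into one stream."""
    if not recordings:
        raise ValueError("no recordings to combine")
    ids = [bid for bid, _ in recordings]
    audio = np.concatenate([np.asarray(a, dtype=np.float32) for _, a in recordings])
    return SuperMotif(source_ids=ids, audio=audio, sample_rate=sr)


def context_similarities(
    male_id: str,
    male_audio: np.ndarray,
    cohort: list[tuple[str, np.ndarray]],
    *,
    mode: str,
    sr: int = SAMPLE_RATE,
) -> SimilarityScore:
    """Similarity of a male's motif to a female-context cohort.

    ``mode='foster_father'`` compares pairwise to the single cohort member;
    ``mode in ('parents', 'peers')`` compares open-end to the cohort
    super-motif.  The focal male is always excluded from his own cohort.
    """
    cohort = [(bid, a) for bid, a in cohort if bid != male_id]
    if not cohort:
        raise ValueError(f"cohort for {male_id} is empty after self-exclusion")
    if mode == "foster_father":
        if len(cohort) != 1:
            raise ValueError("foster_father mode expects exactly one cohort member")
        score = pairwise_similarity(male_audio, cohort[0][1], id_a=male_id, id_b=cohort[0][0], sr=sr)
        return SimilarityScore(value=score.value, motif_a=male_id, motif_b=cohort[0][0],
                               mode=mode)
    if mode not in ("parents", "peers"):
        raise ValueError(f"unknown cohort mode {mode!r}")
    sm = build_super_motif(cohort, sr=sr)
    score = similarity_to_supermotif(male_audio, sm, id_a=male_id, sr=sr)
    return SimilarityScore(value=score.value, motif_a=male_id, motif_b=score.motif_b, mode=mode)
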