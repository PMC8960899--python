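"""Barcode-style tracking simulation: birds hop between 8 stations, with
station choice biased toward currently co-located preferred partners."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import BirdRecord, ExperimentDesign, PreferenceModel

#: Station coordinates (mm) on a 5 m x 2 m floor plan: six perches + two feeders.
STATIONS = np.array(
    [
        [625.0, 1600.0],  # perch 1
        [1875.0, 1600.0],  # perch 2
        [3125.0, 1600.0],  # perch 3
        [4375.0, 1600.0],  # perch 4
        [1250.0, 400.0],  # perch 5
        [3750.0, 400.0],  # perch 6
        [900.0, 1000.0],  # feeder 1
        [4100.0, 1000.0],  # feeder 2
    ]
)

STATION_IDS = [f"P{i}" for i in range(1, 7)] + ["F1", "F2"]

POSITION_JITTER_MM = 30.0


def attraction_matrix(
    birds: list[BirdRecord],
    model: PreferenceModel,
    true_pairs: list[tuple[str, str]] | None = None,
    pair_attraction: float = 0.0,
) -> np.ndarray:
    """A[i, j] = attraction of bird i toward bird j (not necessarily symmetric)."""
    n = len(birds)
    idx = {b.bird_id: i for i, b in enumerate(birds)}
    A = np.zeros((n, n))
    for i, bi in enumerate(birds):
        for j, bj in enumerate(birds):
            if i == j or bi.sex == bj.sex:
                continue
            a = 0.0
            if bi.rearing_pop == bj.rearing_pop:
                a += model.a_cult
            if bj.genetic_type == bi.rearing_type:
                a += model.a_morph
            if bi.genetic_type == "W" and bj.genetic_type == "D":
                a += model.a_WprefD
            A[i, j] = a
    if true_pairs and pair_attraction:
        for f, m in true_pairs:
            if f in idx and m in idx:
                A[idx[f], idx[m]] += pair_attraction
                A[idx[m], idx[f]] += pair_attraction
    return A


def simulate_tracking(
    birds: list[BirdRecord],
    model: PreferenceModel,
    true_pairs: list[tuple[str, str]],
    design: ExperimentDesign,
    seed: int,
    *,
    detection_prob: float = 0.9,
    pair_attraction: float = 0.0,
    stay_bonus: float = 15.0,
) -> pd.DataFrame:
    """Simulate per-tick station fixes for all birds over the experiment.

    Each sampling tick every bird re-chooses a station with probability
    proportional to ``baseline_mixing + ramp(day) * sum of attractions toward
    birds at that station`` (positions taken from the previous tick), with an
    extra ``stay_bonus`` on the bird's current station so that dwell times
    span several ticks and followers can join.  Each bird is then
    independently detected with ``detection_prob``; undetected fixes are
    absent rows.  Deterministic given ``seed``.

    Returns a DataFrame with columns
    (timestamp, day_index, bird_id, x_mm, y_mm, station_id).
    """
    if not birds:
        raise ValueError("bird list is empty")
    if design.sample_interval <= 0:
        raise ValueError("sample interval must be positive")
    rng = np.random.default_rng(seed)
    n = len(birds)
    n_stations = len(STATIONS)
    A = attraction_matrix(birds, model, true_pairs, pair_attraction)
    ids = np.array([b.bird_id for b in birds])

    pos = rng.integers(0, n_stations, size=n)
    ticks = design.ticks_per_day
    interval = design.sample_interval

    day_col, ts_col, bird_col, st_col = [], [], [], []
    for day in range(design.days):
        ramp = model.ramp(day)
        for t in range(ticks):
            onehot = np.zeros((n, n_stations))
            onehot[np.arange(n), pos] = 1.0
            scores = model.baseline_mixing + ramp * (A @ onehot)
            scores[np.arange(n), pos] += stay_bonus * model.baseline_mixing
            scores = np.maximum(scores, 1e-12)
            cdf = np.cumsum(scores, axis=1)
            u = rng.random(n) * cdf[:, -1]
            pos = (cdf < u[:, None]).sum(axis=1)
            detected = rng.random(n) < detection_prob
            k = int(detected.sum())
            if k:
                day_col.append(np.full(k, day))
                ts_col.append(np.full(k, t * interval))
                bird_col.append(ids[detected])
                st_col.append(pos[detected])

    day_arr = np.concatenate(day_col) if day_col else np.array([], dtype=int)
    st_arr = np.concatenate(st_col) if st_col else np.array([], dtype=int)
    coords = STATIONS[st_arr] if len(st_arr) else np.zeros((0, 2))
    jitter = rng.normal(0.0, POSITION_JITTER_MM, size=coords.shape)
    fixes = pd.DataFrame(
        {
            "timestamp": np.concatenate(ts_col) if ts_col else [],
            "day_index": day_arr,
            "bird_id": np.concatenate(bird_col) if bird_col else [],
            "x_mm": coords[:, 0] + jitter[:, 0],
            "y_mm": coords[:, 1] + jitter[:, 1],
            "station_id": [STATION_IDS[s] for s in st_arr],
        }
    )
    return fixes
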