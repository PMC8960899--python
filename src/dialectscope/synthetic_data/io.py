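"""File interchange: RIFF WAV songs with a metadata sidecar, tracking-fix
CSVs with ISO timestamps, interaction CSVs and YAML scenario configs."""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .scenario import ScenarioConfig
from .types import BirdRecord, PreferenceModel, SongRecording

_DAY_START = _dt.time(5, 30)  # lights on
_BASE_DATE = _dt.date(2000, 1, 1)


def write_wav(path: str | Path, recording: SongRecording) -> None:
    """Write a recording as 16-bit PCM mono WAV."""
    pcm = np.clip(recording.waveform, -1.0, 1.0)
    wavfile.write(str(path), recording.sample_rate, (pcm * 32767).astype(np.int16))


def read_wav(path: str | Path) -> SongRecording:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        wave = data.astype(np.float32) / 32768.0
    else:
        wave = data.astype(np.float32)
    return SongRecording(waveform=wave, sample_rate=int(rate))


def write_song_set(
    recordings: list[tuple[str, SongRecording]],
    birds: list[BirdRecord],
    outdir: str | Path,
) -> pd.DataFrame:
    """Write one WAV per recording (``<bird_id>_<rec#>.wav``) plus a
    metadata sidecar CSV; returns the metadata table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {b.bird_id: b for b in birds}
    counts: dict[str, int] = {}
    rows = []
    for bird_id, rec in recordings:
        counts[bird_id] = counts.get(bird_id, 0) + 1
        fname = f"{bird_id}_{counts[bird_id]}.wav"
        write_wav(outdir / fname, rec)
        b = by_id[bird_id]
        rows.append(
            {
                "filename": fname,
                "bird_id": bird_id,
                "generation": b.generation,
                "genetic_pop": b.genetic_pop,
                "rearing_pop": b.rearing_pop,
                "rearing_aviary": b.rearing_aviary,
            }
        )
    meta = pd.DataFrame(rows)
    meta.to_csv(outdir / "recordings.csv", index=False)
    return meta


def _iso(day_index: int, seconds: float) -> str:
    start = _dt.datetime.combine(_BASE_DATE + _dt.timedelta(days=int(day_index)), _DAY_START)
    return (start + _dt.timedelta(seconds=float(seconds))).isoformat()


def write_fixes_csv(fixes: pd.DataFrame, path: str | Path) -> None:
    out = fixes.copy()
    out["timestamp_iso"] = [
        _iso(d, s) for d, s in zip(out["day_index"].to_numpy(), out["timestamp"].to_numpy())
    ]
    out[["timestamp_iso", "day_index", "bird_id", "x_mm", "y_mm", "station_id"]].to_csv(
        path, index=False
    )


def read_fixes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp_iso"])
    day_start = ts.dt.normalize() + pd.Timedelta(hours=_DAY_START.hour, minutes=_DAY_START.minute)
    df["timestamp"] = (ts - day_start).dt.total_seconds()
    return df[["timestamp", "day_index", "bird_id", "x_mm", "y_mm", "station_id"]]


def write_birds_csv(birds: list[BirdRecord], path: str | Path) -> None:
    pd.DataFrame([vars(b) for b in birds]).to_csv(path, index=False)


def read_birds_csv(path: str | Path) -> list[BirdRecord]:
    df = pd.read_csv(path)
    birds = []
    for row in df.to_dict("records"):
        ff = row.get("foster_father")
        if pd.isna(ff):
            ff = None
        birds.append(
            BirdRecord(
                bird_id=str(row["bird_id"]),
                sex=str(row["sex"]),
                genetic_pop=str(row["genetic_pop"]),
                rearing_pop=str(row["rearing_pop"]),
                lineage_code=str(row["lineage_code"]),
                rearing_aviary=str(row["rearing_aviary"]),
                generation=int(row["generation"]),
                body_size=float(row["body_size"]),
                foster_father=ff,
            )
        )
    return birds


def save_scenario_config(cfg: ScenarioConfig, path: str | Path) -> None:
    data = {k: v for k, v in vars(cfg).items() if k != "preference"}
    data["pop_ids"] = list(cfg.pop_ids)
    data["preference"] = vars(cfg.preference)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    pref = PreferenceModel(**data.pop("preference", {}))
    data["pop_ids"] = tuple(data.get("pop_ids", ("D1", "W1")))
    return ScenarioConfig(preference=pref, **data)
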