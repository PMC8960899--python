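"""Song synthesis: syllable sampling from population dialects and waveform
rendering as additive FM-harmonic stacks (22,050 Hz mono).

The dialect centre displaces four latent acoustic knobs (pitch register, FM
slope, harmonic tilt, noisiness); individual and syllable-level variation is
added around the centre with the population's dispersion.
"""

from __future__ import annotations

import numpy as np

from .types import (
    SAMPLE_RATE,
    Motif,
    PopulationSpec,
    SongRecording,
    SyllablePrototype,
)

# Rendered song duration envelope (s), mirroring the recording protocol.
MIN_SONG_DURATION = 4.5
MAX_SONG_DURATION = 10.2

_F0_LOW, _F0_HIGH = 500.0, 3000.0  # keep 3rd harmonic under Nyquist
_INTER_SYLLABLE_GAP = 0.02  # s
_N_HARMONICS = 3


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def sample_syllable(pop: PopulationSpec, rng: np.random.Generator) -> SyllablePrototype:
    """Draw one syllable prototype from a population's dialect distribution."""
    c = pop.dialect_center
    d = pop.dialect_dispersion
    duration = float(rng.uniform(0.06, 0.14))
    # pitch register: octaves around 1.2 kHz
    log2_pitch = 0.6 * c[0] + d * rng.normal()
    f_center = float(np.clip(1200.0 * 2.0**log2_pitch, _F0_LOW * 1.3, _F0_HIGH / 1.3))
    # FM slope in octaves across the syllable
    slope = 0.5 * c[1] + 0.3 * d * rng.normal()
    f0_start = float(np.clip(f_center * 2.0 ** (-slope / 2), _F0_LOW, _F0_HIGH))
    f0_end = float(np.clip(f_center * 2.0 ** (slope / 2), _F0_LOW, _F0_HIGH))
    # harmonic tilt: positive tilt concentrates energy in the fundamental
    tilt = 0.8 * c[2] + 0.5 * d * rng.normal()
    k = np.arange(_N_HARMONICS, dtype=float)
    weights = np.exp(-k * (0.8 + tilt)) + 0.02
    weights /= weights.sum()
    noise_fraction = float(_sigmoid(1.2 * c[3] + 0.5 * d * rng.normal() - 2.0))
    attack = float(rng.uniform(0.005, 0.02))
    decay = float(rng.uniform(0.01, 0.04))
    return SyllablePrototype(
        duration=duration,
        f0_start=f0_start,
        f0_end=f0_end,
        harmonic_weights=tuple(weights),
        noise_fraction=noise_fraction,
        amplitude_envelope=(attack, decay),
    )


def sample_motif(
    pop: PopulationSpec,
    owner: str,
    rng: np.random.Generator,
    n_syllables: int | None = None,
) -> Motif:
    """Draw a fresh motif (3-8 syllables) for ``owner`` from ``pop``."""
    if n_syllables is None:
        n_syllables = int(rng.integers(4, 7))
    syllables = [sample_syllable(pop, rng) for _ in range(n_syllables)]
    return Motif(owner=owner, syllables=syllables, tutor=None)


def render_syllable(
    syl: SyllablePrototype,
    rng: np.random.Generator,
    sample_rate: int = SAMPLE_RATE,
) -> np.ndarray:
    """Render one syllable as an FM harmonic stack with an AD envelope."""
    n = max(8, int(round(syl.duration * sample_rate)))
    t = np.arange(n) / sample_rate
    # exponential sweep from f0_start to f0_end
    ratio = syl.f0_end / syl.f0_start
    if abs(np.log(ratio)) < 1e-9:
        phase = 2 * np.pi * syl.f0_start * t
    else:
        k = np.log(ratio) / syl.duration
        phase = 2 * np.pi * syl.f0_start * (np.exp(k * t) - 1.0) / k
    wave = np.zeros(n)
    for h, w in enumerate(syl.harmonic_weights, start=1):
        wave += w * np.sin(h * phase)
    if syl.noise_fraction > 0:
        noise = rng.normal(size=n)
        noise /= max(1e-12, np.abs(noise).max())
        wave = (1.0 - syl.noise_fraction) * wave + syl.noise_fraction * noise
    attack, decay = syl.amplitude_envelope
    env = np.ones(n)
    na = min(n, max(1, int(attack * sample_rate)))
    nd = min(n, max(1, int(decay * sample_rate)))
    env[:na] = np.linspace(0.0, 1.0, na)
    env[n - nd :] = np.linspace(1.0, 0.0, nd)
    return (wave * env).astype(np.float32)


def render_motif(
    motif: Motif,
    rng: np.random.Generator,
    sample_rate: int = SAMPLE_RATE,
    amplitude_jitter: float = 0.0,
) -> np.ndarray:
    """Render one motif rendition (syllables separated by short gaps)."""
    gap = np.zeros(int(_INTER_SYLLABLE_GAP * sample_rate), dtype=np.float32)
    chunks: list[np.ndarray] = []
    for syl in motif.syllables:
        w = render_syllable(syl, rng, sample_rate)
        if amplitude_jitter > 0:
            w = w * float(rng.uniform(1 - amplitude_jitter, 1 + amplitude_jitter))
        chunks.append(w)
        chunks.append(gap)
    return np.concatenate(chunks[:-1])


def render_motif_audio(motif: Motif, seed: int, sample_rate: int = SAMPLE_RATE) -> np.ndarray:
    """Deterministic single-rendition audio of a motif (no introduction)."""
    rng = np.random.default_rng(seed)
    wave = render_motif(motif, rng, sample_rate)
    peak = np.abs(wave).max()
    if peak > 0:
        wave = wave / peak * 0.9
    return wave.astype(np.float32)


def render_song(
    motif: Motif,
    target_duration: float,
    seed: int,
    sample_rate: int = SAMPLE_RATE,
) -> SongRecording:
    """Render a full recording: introductory syllables plus repeated motif
    renditions with small per-rendition jitter, cut to ``target_duration``.

    Deterministic given ``seed``; ``target_duration`` must lie within the
    recording protocol's envelope [4.5, 10.2] s.
    """
    if not MIN_SONG_DURATION <= target_duration <= MAX_SONG_DURATION:
        raise ValueError(
            f"target_duration {target_duration} s outside "
            f"[{MIN_SONG_DURATION}, {MAX_SONG_DURATION}] s"
        )
    rng = np.random.default_rng(seed)
    # 2-3 short introductory downsweeps, individual- but not dialect-bearing
    n_intro = int(rng.integers(2, 4))
    intro_chunks = []
    for _ in range(n_intro):
        f_hi = float(rng.uniform(2000, 3000))
        syl = SyllablePrototype(
            duration=float(rng.uniform(0.05, 0.08)),
            f0_start=f_hi,
            f0_end=f_hi * 0.55,
            harmonic_weights=(0.8, 0.2, 0.05),
            noise_fraction=0.05,
            amplitude_envelope=(0.005, 0.02),
        )
        intro_chunks.append(render_syllable(syl, rng, sample_rate))
        intro_chunks.append(np.zeros(int(0.06 * sample_rate), dtype=np.float32))
    chunks = intro_chunks
    total = sum(len(c) for c in chunks)
    n_target = int(round(target_duration * sample_rate))
    while total < n_target:
        chunks.append(render_motif(motif, rng, sample_rate, amplitude_jitter=0.1))
        pause = np.zeros(int(rng.uniform(0.05, 0.15) * sample_rate), dtype=np.float32)
        chunks.append(pause)
        total = sum(len(c) for c in chunks)
    wave = np.concatenate(chunks)[:n_target]
    peak = np.abs(wave).max()
    if peak > 0:
        wave = wave / peak * 0.9
    return SongRecording(waveform=wave.astype(np.float32), sample_rate=sample_rate, bird_id=motif.owner)
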