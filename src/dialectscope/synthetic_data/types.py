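"""Core domain records shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Frequency band (Hz) every syllable prototype must stay inside.
F_MIN = 400.0
F_MAX = 8000.0

#: Audio sample rate for all rendered song (Hz, mono).
SAMPLE_RATE = 22050


@dataclass(frozen=True)
class PopulationSpec:
    """A source population with its dialect centre and body-size distribution.

    ``dialect_center`` is a 4-vector in an abstract acoustic parameter space:
    (log2 pitch offset, FM-slope bias, harmonic tilt, noisiness bias).  Two
    populations with ``divergence_delta == 0`` share the global reference
    centre (the zero vector).
    """

    pop_id: str
    dialect_center: np.ndarray
    dialect_dispersion: float = 0.25
    divergence_delta: float = 0.0
    innovation_rate_rho: float = 0.3
    body_size_mean: float = 14.0
    body_size_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.innovation_rate_rho <= 1.0:
            raise ValueError(
                f"innovation_rate_rho must be in [0, 1], got {self.innovation_rate_rho}"
            )
        if self.divergence_delta < 0:
            raise ValueError("divergence_delta must be non-negative")
        center = np.asarray(self.dialect_center, dtype=float)
        if center.shape != (4,):
            raise ValueError("dialect_center must be a 4-vector")
        object.__setattr__(self, "dialect_center", center)
        if self.divergence_delta == 0.0 and not np.allclose(center, 0.0):
            raise ValueError("divergence_delta = 0 requires the reference centre (zeros)")

    @property
    def type_letter(self) -> str:
        """'D' (domesticated) or 'W' (wild-derived) from the population id."""
        return self.pop_id[0].upper()


@dataclass
class BirdRecord:
    """One bird; the unit all tables join on."""

    bird_id: str
    sex: str  # "M" or "F"
    genetic_pop: str
    rearing_pop: str
    lineage_code: str
    rearing_aviary: str
    generation: int
    body_size: float
    foster_father: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not 2 <= len(self.lineage_code) <= 3:
            raise ValueError(f"lineage_code must have 2-3 letters, got {self.lineage_code!r}")
        if set(self.lineage_code) - set("DW"):
            raise ValueError(f"lineage_code letters must be D/W, got {self.lineage_code!r}")

    @property
    def genetic_type(self) -> str:
        """First code letter: population type of genetic origin."""
        return self.lineage_code[0]

    @property
    def rearing_type(self) -> str:
        """Second code letter: population type of the rearing parents."""
        return self.lineage_code[1]


@dataclass(frozen=True)
class SyllablePrototype:
    """Parameters of one synthesised syllable (an FM harmonic stack)."""

    duration: float  # s
    f0_start: float  # Hz
    f0_end: float  # Hz
    harmonic_weights: tuple[float, ...]
    noise_fraction: float
    amplitude_envelope: tuple[float, float]  # (attack s, decay s)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for f in (self.f0_start, self.f0_end):
            if not F_MIN <= f <= F_MAX:
                raise ValueError(f"fundamental {f} Hz outside [{F_MIN}, {F_MAX}]")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if any(w < 0 for w in self.harmonic_weights):
            raise ValueError("harmonic_weights must be non-negative")


@dataclass
class Motif:
    """Ordered syllable sequence owned by one male; carrier of song culture."""

    owner: str
    syllables: list[SyllablePrototype]
    tutor: str | None = None

    def __post_init__(self) -> None:
        if not 3 <= len(self.syllables) <= 8:
            raise ValueError(f"motif must have 3-8 syllables, got {len(self.syllables)}")

    def __len__(self) -> int:
        return len(self.syllables)


@dataclass
class SongRecording:
    """A rendered waveform with its provenance."""

    waveform: np.ndarray  # float32, mono
    sample_rate: int = SAMPLE_RATE
    bird_id: str | None = None

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.sample_rate


@dataclass
class ExperimentDesign:
    """Aviary composition and sampling schedule of a social experiment."""

    groups: list[tuple[str, list[str]]]
    crossfoster_map: dict[str, str] = field(default_factory=dict)
    days: int = 30
    sample_interval: float = 2.0
    day_length: float = 14.5  # hours

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.days < 1:
            raise ValueError("days must be >= 1")

    @property
    def ticks_per_day(self) -> int:
        return int(self.day_length * 3600 / self.sample_interval)


@dataclass
class PreferenceModel:
    """Attraction terms shaping station choice in the tracking simulation.

    With every attraction term at 0 all dyads are exchangeable.  Attraction
    ramps linearly from 0 on day 0 to full strength after ``ramp_days``.
    """

    a_cult: float = 0.0  # shared rearing population (opposite sex)
    a_morph: float = 0.0  # partner's genetic type matches own rearing type
    a_WprefD: float = 0.0  # W-origin birds drawn to D-origin partners
    ramp_days: int = 1
    baseline_mixing: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_mixing < 0:
            raise ValueError("baseline_mixing must be non-negative")
        if self.ramp_days < 1:
            raise ValueError("ramp_days must be >= 1")

    def ramp(self, day_index: int) -> float:
        """Linear attraction scale for a given day (1.0 once fully ramped)."""
        return min(1.0, (day_index + 1) / self.ramp_days)


def make_population(
    pop_id: str,
    divergence_delta: float,
    rng: np.random.Generator,
    *,
    dialect_dispersion: float = 0.25,
    innovation_rate_rho: float = 0.3,
    body_size_mean: float | None = None,
    body_size_sd: float = 1.0,
) -> PopulationSpec:
    """Create a population whose dialect centre sits ``divergence_delta`` away
    from the global reference, in a direction drawn from ``rng``.

    Body size defaults follow the type letter: domesticated populations are
    heavier (16 g) than wild-derived ones (12 g).
    """
    if divergence_delta == 0.0:
        center = np.zeros(4)
    else:
        direction = rng.normal(size=4)
        direction /= np.linalg.norm(direction)
        center = divergence_delta * direction
    if body_size_mean is None:
        body_size_mean = 16.0 if pop_id[0].upper() == "D" else 12.0
    return PopulationSpec(
        pop_id=pop_id,
        dialect_center=center,
        dialect_dispersion=dialect_dispersion,
        divergence_delta=divergence_delta,
        innovation_rate_rho=innovation_rate_rho,
        body_size_mean=body_size_mean,
        body_size_sd=body_size_sd,
    )
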