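"""Cultural transmission across a breeding generation.

Sons copy their foster father's motif syllable by syllable, independently
replacing each syllable (probability ``rho``) with a fresh draw from the
rearing population's prototype distribution.  Daughters carry no motif but
keep a latent imprinted dialect equal to their rearing population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .song import sample_syllable
from .types import BirdRecord, ExperimentDesign, Motif, PopulationSpec


@dataclass
class Parent:
    """A breeding male: his record plus his motif (None for females)."""

    bird: BirdRecord
    motif: Motif | None


def inherit_motif(
    foster_motif: Motif,
    pupil_id: str,
    rearing_pop: PopulationSpec,
    rho: float,
    rng: np.random.Generator,
) -> Motif:
    """Copy a tutor's motif with per-syllable innovation at rate ``rho``."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"innovation rate rho must be in [0, 1], got {rho}")
    syllables = []
    for syl in foster_motif.syllables:
        if rng.random() < rho:
            syllables.append(sample_syllable(rearing_pop, rng))
        else:
            syllables.append(syl)
    return Motif(owner=pupil_id, syllables=syllables, tutor=foster_motif.owner)


def shared_syllable_fraction(pupil: Motif, tutor: Motif) -> float:
    """Fraction of pupil syllables identical (by value) to the tutor's, positionwise."""
    if len(pupil) != len(tutor):
        raise ValueError("motifs must have equal length for positionwise comparison")
    same = sum(1 for a, b in zip(pupil.syllables, tutor.syllables) if a == b)
    return same / len(pupil)


def _child_lineage_code(genetic_letter: str, foster: BirdRecord) -> str:
    # Generation-3 codes carry the foster line's full two-letter code,
    # recording the grandparental culture in the third letter.
    if foster.generation >= 2:
        return (genetic_letter + foster.lineage_code)[:3]
    return genetic_letter + foster.rearing_type


def breed_generation(
    parents: list[Parent],
    design: ExperimentDesign,
    rho: float,
    seed: int,
    *,
    populations: dict[str, PopulationSpec],
    offspring_per_father: int = 2,
    id_prefix: str = "G",
) -> list[Parent]:
    """Produce one offspring generation under a cross-fostering design.

    ``design.crossfoster_map`` maps each genetic father's bird_id to the
    rearing aviary his clutch is moved to; ``design.groups`` lists, per
    aviary, the resident bird_ids whose first motif-bearing male acts as the
    clutch's foster father.  Each father sires ``offspring_per_father`` sons
    and as many daughters.  Deterministic given ``seed``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"innovation rate rho must be in [0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    by_id = {p.bird.bird_id: p for p in parents}
    aviary_members = dict(design.groups)

    # resolve one motif-bearing foster father per aviary
    foster_of_aviary: dict[str, Parent] = {}
    for aviary, members in aviary_members.items():
        for bid in members:
            p = by_id.get(bid)
            if p is not None and p.motif is not None:
                foster_of_aviary[aviary] = p
                break

    offspring: list[Parent] = []
    counter = 0
    for father_id, aviary in design.crossfoster_map.items():
        father = by_id.get(father_id)
        if father is None:
            raise ValueError(f"unknown genetic father {father_id!r} in crossfoster_map")
        foster = foster_of_aviary.get(aviary)
        if foster is None or foster.motif is None:
            raise ValueError(
                f"rearing aviary {aviary!r} has no resident foster father with a motif"
            )
        rearing_pop_id = foster.bird.rearing_pop
        rearing_pop = populations[rearing_pop_id]
        gen = father.bird.generation + 1
        code = _child_lineage_code(father.bird.genetic_type, foster.bird)
        genetic_pop = populations[father.bird.genetic_pop]
        for k in range(2 * offspring_per_father):
            sex = "M" if k < offspring_per_father else "F"
            counter += 1
            child_id = f"{id_prefix}{gen}_{counter:04d}"
            size = float(rng.normal(genetic_pop.body_size_mean, genetic_pop.body_size_sd))
            bird = BirdRecord(
                bird_id=child_id,
                sex=sex,
                genetic_pop=father.bird.genetic_pop,
                rearing_pop=rearing_pop_id,
                lineage_code=code,
                rearing_aviary=aviary,
                generation=gen,
                body_size=size,
                foster_father=foster.bird.bird_id,
            )
            motif = None
            if sex == "M":
                motif = inherit_motif(foster.motif, child_id, rearing_pop, rho, rng)
            offspring.append(Parent(bird=bird, motif=motif))
    return offspring
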