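"""Assembly of full synthetic experiments: founder generation, cross-fostered
offspring generation, social groups, ground-truth pairs and rendered songs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breeding import Parent, inherit_motif
from .song import render_song, sample_motif
from .types import (
    BirdRecord,
    ExperimentDesign,
    Motif,
    PopulationSpec,
    PreferenceModel,
    SongRecording,
    make_population,
)


@dataclass
class ScenarioConfig:
    """Knobs of one synthetic replicate (YAML-serialisable)."""

    pop_ids: tuple[str, str] = ("D1", "W1")
    divergence_delta: float = 1.5
    dialect_dispersion: float = 0.25
    rho: float = 0.3
    n_fathers_per_aviary: int = 8
    n_aviaries_per_pop: int = 2
    n_per_type: int = 8  # birds per lineage type per sex in the social group
    n_extra_peers_per_aviary: int = 6  # peer cohort males kept out of the social group
    days: int = 30
    day_length: float = 0.5  # hours of ticks per day (desk preset)
    sample_interval: float = 2.0
    preference: PreferenceModel = field(default_factory=lambda: PreferenceModel(a_cult=3.0, ramp_days=30))
    pair_attraction: float = 3.0
    pair_fidelity: float = 0.9
    background_lambda: float = 1.2
    bonded_lambda: float = 20.0
    seed: int = 0


@dataclass
class Scenario:
    """A generated replicate with full ground truth."""

    config: ScenarioConfig
    populations: dict[str, PopulationSpec]
    gen1: list[Parent]
    gen2: list[Parent]
    design: ExperimentDesign
    true_pairs: list[tuple[str, str]]
    #: rearing aviary -> bird_ids of its 8 adult fathers (generation 1)
    fathers_of_aviary: dict[str, list[str]]
    #: generation-2 peer males kept out of the social group, so similarity
    #: cohorts never contain candidate males
    extra_peers: list[Parent] = field(default_factory=list)

    @property
    def gen2_birds(self) -> list[BirdRecord]:
        return [p.bird for p in self.gen2]

    def motif_of(self, bird_id: str) -> Motif:
        for p in self.gen1 + self.gen2 + self.extra_peers:
            if p.bird.bird_id == bird_id:
                if p.motif is None:
                    raise KeyError(f"{bird_id} carries no motif")
                return p.motif
        raise KeyError(bird_id)

    def peers_of_aviary(self, aviary: str) -> list[str]:
        """Peer-cohort males reared in ``aviary`` (not in the social group)."""
        return [p.bird.bird_id for p in self.extra_peers if p.bird.rearing_aviary == aviary]


def assortative_pairs(
    birds: list[BirdRecord],
    rng: np.random.Generator,
    attribute: str = "rearing_pop",
    fidelity: float = 1.0,
) -> list[tuple[str, str]]:
    """Monogamous matching in which a fraction ``fidelity`` of pairs shares
    the attribute level; returns (female_id, male_id) tuples.

    The number of disassortative pairs is fixed at round((1-fidelity) * n)
    and those are matched first, so the realised assortative proportion hits
    the target exactly whenever the design is balanced.
    """
    females = [b for b in birds if b.sex == "F"]
    males = [b for b in birds if b.sex == "M"]
    rng.shuffle(females)
    free = list(males)
    n_dis = int(round((1.0 - fidelity) * min(len(females), len(males))))
    pairs: list[tuple[str, str]] = []

    def _take(f: "BirdRecord", want_same: bool) -> None:
        same = [m for m in free if getattr(m, attribute) == getattr(f, attribute)]
        other = [m for m in free if getattr(m, attribute) != getattr(f, attribute)]
        pool = (same or other) if want_same else (other or same)
        m = pool[int(rng.integers(len(pool)))]
        free.remove(m)
        pairs.append((f.bird_id, m.bird_id))

    for f in females[:n_dis]:
        if free:
            _take(f, want_same=False)
    for f in females[n_dis:]:
        if free:
            _take(f, want_same=True)
    return pairs


def make_founders(
    pop: PopulationSpec,
    aviaries: list[str],
    n_fathers: int,
    rng: np.random.Generator,
) -> list[Parent]:
    """Adult generation-1 males (with motifs) for each rearing aviary."""
    out = []
    for aviary in aviaries:
        for k in range(n_fathers):
            bid = f"{aviary}_F{k + 1:02d}"
            bird = BirdRecord(
                bird_id=bid,
                sex="M",
                genetic_pop=pop.pop_id,
                rearing_pop=pop.pop_id,
                lineage_code=pop.type_letter * 2,
                rearing_aviary=aviary,
                generation=1,
                body_size=float(rng.normal(pop.body_size_mean, pop.body_size_sd)),
            )
            out.append(Parent(bird=bird, motif=sample_motif(pop, bid, rng)))
    return out


def make_replicate(cfg: ScenarioConfig, seed: int | None = None) -> Scenario:
    """Generate one cross-fostered replicate with known ground truth.

    Two populations, ``n_aviaries_per_pop`` rearing aviaries each with
    ``n_fathers_per_aviary`` adult tutors; generation 2 contains equal
    numbers of the four lineage types (DD, DW, WD, WW) per sex, reared
    across those aviaries, sons tutored by a rotating resident father with
    innovation ``rho``.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    pops: dict[str, PopulationSpec] = {}
    for pid in cfg.pop_ids:
        pops[pid] = make_population(
            pid,
            cfg.divergence_delta,
            rng,
            dialect_dispersion=cfg.dialect_dispersion,
            innovation_rate_rho=cfg.rho,
        )
    aviaries_of_pop = {
        pid: [f"{pid}-A{k + 1}" for k in range(cfg.n_aviaries_per_pop)] for pid in cfg.pop_ids
    }
    gen1: list[Parent] = []
    fathers_of_aviary: dict[str, list[str]] = {}
    for pid in cfg.pop_ids:
        founders = make_founders(pops[pid], aviaries_of_pop[pid], cfg.n_fathers_per_aviary, rng)
        gen1.extend(founders)
        for aviary in aviaries_of_pop[pid]:
            fathers_of_aviary[aviary] = [
                p.bird.bird_id for p in founders if p.bird.rearing_aviary == aviary
            ]
    father_by_id = {p.bird.bird_id: p for p in gen1}

    # generation 2: for each (genetic pop, rearing pop) type, n_per_type per sex
    gen2: list[Parent] = []
    counter = 0
    for genetic_pid in cfg.pop_ids:
        for rearing_pid in cfg.pop_ids:
            code = pops[genetic_pid].type_letter + pops[rearing_pid].type_letter
            rear_aviaries = aviaries_of_pop[rearing_pid]
            for sex in ("M", "F"):
                for k in range(cfg.n_per_type):
                    counter += 1
                    aviary = rear_aviaries[k % len(rear_aviaries)]
                    fathers = fathers_of_aviary[aviary]
                    foster_id = fathers[counter % len(fathers)]
                    bid = f"G2_{code}{sex}{counter:03d}"
                    bird = BirdRecord(
                        bird_id=bid,
                        sex=sex,
                        genetic_pop=genetic_pid,
                        rearing_pop=rearing_pid,
                        lineage_code=code,
                        rearing_aviary=aviary,
                        generation=2,
                        body_size=float(
                            rng.normal(
                                pops[genetic_pid].body_size_mean,
                                pops[genetic_pid].body_size_sd,
                            )
                        ),
                        foster_father=foster_id,
                    )
                    motif = None
                    if sex == "M":
                        motif = inherit_motif(
                            father_by_id[foster_id].motif, bid, pops[rearing_pid], cfg.rho, rng
                        )
                    gen2.append(Parent(bird=bird, motif=motif))

    extra_peers: list[Parent] = []
    for rearing_pid in cfg.pop_ids:
        for aviary in aviaries_of_pop[rearing_pid]:
            fathers = fathers_of_aviary[aviary]
            for k in range(cfg.n_extra_peers_per_aviary):
                counter += 1
                foster_id = fathers[k % len(fathers)]
                bid = f"P2_{aviary}_{k + 1:02d}"
                bird = BirdRecord(
                    bird_id=bid,
                    sex="M",
                    genetic_pop=rearing_pid,
                    rearing_pop=rearing_pid,
                    lineage_code=pops[rearing_pid].type_letter * 2,
                    rearing_aviary=aviary,
                    generation=2,
                    body_size=float(
                        rng.normal(pops[rearing_pid].body_size_mean, pops[rearing_pid].body_size_sd)
                    ),
                    foster_father=foster_id,
                )
                extra_peers.append(
                    Parent(
                        bird=bird,
                        motif=inherit_motif(
                            father_by_id[foster_id].motif, bid, pops[rearing_pid], cfg.rho, rng
                        ),
                    )
                )

    design = ExperimentDesign(
        groups=[("social-1", [p.bird.bird_id for p in gen2])],
        days=cfg.days,
        sample_interval=cfg.sample_interval,
        day_length=cfg.day_length,
    )
    true_pairs = assortative_pairs(
        [p.bird for p in gen2], rng, attribute="rearing_pop", fidelity=cfg.pair_fidelity
    )
    return Scenario(
        config=cfg,
        populations=pops,
        gen1=gen1,
        gen2=gen2,
        design=design,
        true_pairs=true_pairs,
        fathers_of_aviary=fathers_of_aviary,
        extra_peers=extra_peers,
    )


def render_recordings(
    males: list[Parent],
    n_recordings: int,
    seed: int,
    mean_duration: float = 6.8,
    sd_duration: float = 1.6,
) -> list[tuple[str, SongRecording]]:
    """Render ``n_recordings`` songs per motif-bearing male with durations
    drawn from the recording-protocol envelope (clipped to [4.5, 10.2] s)."""
    rng = np.random.default_rng(seed)
    out = []
    for p in males:
        if p.motif is None:
            continue
        for r in range(n_recordings):
            dur = float(np.clip(rng.normal(mean_duration, sd_duration), 4.5, 10.2))
            rec_seed = int(rng.integers(0, 2**31 - 1))
            out.append((p.bird.bird_id, render_song(p.motif, dur, rec_seed)))
    return out


def make_classification_dataset(
    n_pops: int,
    delta: float,
    rho: float,
    n_train_males: int,
    n_test_males: int,
    recs_per_male: int,
    seed: int,
    *,
    dispersion: float = 0.25,
    pop_ids: list[str] | None = None,
) -> tuple[dict[str, list[tuple[str, SongRecording]]], dict[str, list[tuple[str, SongRecording]]]]:
    """Training (generation 1) and held-out test (generation 2 sons, reared
    within population) song sets for ``n_pops`` populations.

    Returns (train, test): pop_id -> list of (bird_id, SongRecording).
    """
    rng = np.random.default_rng(seed)
    if pop_ids is None:
        pop_ids = ([f"W{i}" for i in range(1, n_pops + 1)] + [f"D{i}" for i in range(1, n_pops + 1)])[
            :n_pops
        ]
    train: dict[str, list[tuple[str, SongRecording]]] = {}
    test: dict[str, list[tuple[str, SongRecording]]] = {}
    for pid in pop_ids:
        pop = make_population(pid, delta, rng, dialect_dispersion=dispersion)
        fathers = [
            Parent(
                bird=BirdRecord(
                    bird_id=f"{pid}_T{k:03d}",
                    sex="M",
                    genetic_pop=pid,
                    rearing_pop=pid,
                    lineage_code=pop.type_letter * 2,
                    rearing_aviary=f"{pid}-A1",
                    generation=1,
                    body_size=float(rng.normal(pop.body_size_mean, pop.body_size_sd)),
                ),
                motif=sample_motif(pop, f"{pid}_T{k:03d}", rng),
            )
            for k in range(n_train_males)
        ]
        sons = []
        for k in range(n_test_males):
            tutor = fathers[k % n_train_males]
            bid = f"{pid}_S{k:03d}"
            sons.append(
                Parent(
                    bird=BirdRecord(
                        bird_id=bid,
                        sex="M",
                        genetic_pop=pid,
                        rearing_pop=pid,
                        lineage_code=pop.type_letter * 2,
                        rearing_aviary=f"{pid}-A1",
                        generation=2,
                        body_size=float(rng.normal(pop.body_size_mean, pop.body_size_sd)),
                        foster_father=tutor.bird.bird_id,
                    ),
                    motif=inherit_motif(tutor.motif, bid, pop, rho, rng),
                )
            )
        train[pid] = render_recordings(fathers, recs_per_male, int(rng.integers(2**31 - 1)))
        test[pid] = render_recordings(sons, recs_per_male, int(rng.integers(2**31 - 1)))
    return train, test
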