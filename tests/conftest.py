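"""Shared fixtures: small synthetic worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dialectscope.synthetic_data import (
    PreferenceModel,
    ScenarioConfig,
    make_population,
    make_replicate,
    render_motif_audio,
    sample_motif,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pop_pair():
    """Two well-separated populations (D1, W1)."""
    r = np.random.default_rng(7)
    return (
        make_population("D1", 1.5, r),
        make_population("W1", 1.5, r),
    )


@pytest.fixture(scope="session")
def motif_d(pop_pair):
    return sample_motif(pop_pair[0], "ownerD", np.random.default_rng(11))


@pytest.fixture(scope="session")
def motif_w(pop_pair):
    return sample_motif(pop_pair[1], "ownerW", np.random.default_rng(12))


@pytest.fixture(scope="session")
def audio_d(motif_d):
    return render_motif_audio(motif_d, 21)


@pytest.fixture(scope="session")
def audio_w(motif_w):
    return render_motif_audio(motif_w, 22)


@pytest.fixture(scope="session")
def small_scenario():
    """Desk-scale cross-fostered replicate with strong cultural preference."""
    cfg = ScenarioConfig(
        n_per_type=4,
        n_fathers_per_aviary=4,
        n_extra_peers_per_aviary=3,
        days=8,
        day_length=0.2,
        preference=PreferenceModel(a_cult=4.0, ramp_days=8),
        pair_fidelity=0.9,
        seed=99,
    )
    return make_replicate(cfg)
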