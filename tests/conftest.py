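"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from phagescan import synthetic_data as sd
from phagescan.io_formats import ProteinRecord


@pytest.fixture(scope="session")
def screen_fixture():
    """One seeded Acr-screen fixture: 50 decoys + 3 planted homologs."""
    cfg = sd.GeneratorConfig(
        seed=1, n_decoys=50,
        planted=[sd.PlantSpec("acr_ref_1"), sd.PlantSpec("acr_ref_2"),
                 sd.PlantSpec("acr_ref_3")])
    return sd.gen_screen_fixture(cfg)


@pytest.fixture(scope="session")
def defense_fixture():
    """Seeded annotated genomes (120 MAGs) with planted islands + marker."""
    cfg = sd.GeneratorConfig(seed=2, genomes=120, marker_prevalence=0.05)
    return sd.gen_defense_genomes(cfg)


@pytest.fixture()
def random_records():
    rng = np.random.default_rng(42)
    return [ProteinRecord(f"p{i}", sd._random_residues(
        int(rng.integers(40, 120)), rng)) for i in range(10)]
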