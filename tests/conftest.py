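from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oligocov import (ProbePlant, PrimerPlant, SyntheticConfig, TaxonSpec,
                      builtin_primer_sets, builtin_probe_table,
                      generate_synthetic_db)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def probes() -> dict:
    return {o.name: o for o in builtin_probe_table()}


@pytest.fixture(scope="session")
def primer_sets() -> dict:
    return {p.name: p for p in builtin_primer_sets()}


@pytest.fixture(scope="session")
def small_synthetic(probes, primer_sets):
    """A small mixed-community database with planted probes and primers."""
    cfg = SyntheticConfig(
        taxa=(TaxonSpec("Dechloromonas", 10),
              TaxonSpec("Thauera", 8),
              TaxonSpec("Ca_Accumulibacter", 6)),
        length_range=(900, 1000),
        probe_plants=(
            ProbePlant(probes["PAO651"], {"Ca_Accumulibacter": 0.8,
                                          "Dechloromonas": 0.1}),
            ProbePlant(probes["DEMFE455"], {"Dechloromonas": 0.6,
                                            "Ca_Accumulibacter": 0.2}),
        ),
        primer_plants=(
            PrimerPlant(primer_sets["515F-926R"],
                        {"Dechloromonas": 0.9, "Thauera": 0.9,
                         "Ca_Accumulibacter": 0.9},
                        forward_position=(0, 30)),
        ),
        probe_zone_start=400,
        subject_n_fraction=0.005,
    )
    return generate_synthetic_db(cfg, seed=20240123)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
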