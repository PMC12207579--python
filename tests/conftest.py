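"""Shared fixtures: small simulated diallels reused across test modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from diallelgp import kinship, simdiallel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def diallel_sim():
    """Moderate diallel with all four variance components, three replicates."""
    cfg = simdiallel.SimConfig(
        n_parents=12, offspring_per_family=10, infertile_fraction=0.35,
        n_markers=300, genotyped_fraction=0.3,
        traits=[simdiallel.TraitConfig(
            name="dm", mean=20.26, sigma2_a=2.42, sigma2_f=0.38,
            sigma2_l=4.61, sigma2_e=0.70, reps_per_year=(3,),
            cytoplasm_effects={"T/b": -2.24, "D": -1.45, "W/g": 0.0})])
    return simdiallel.simulate_population(cfg, seed=77)


@pytest.fixture(scope="session")
def diallel_A(diallel_sim):
    return kinship.build_A_tetraploid(diallel_sim.pedigree)


@pytest.fixture(scope="session")
def diallel_cyto(diallel_sim):
    return diallel_sim.pedigree.set_index("clone_id")["cytoplasm_type"]


@pytest.fixture(scope="session")
def additive_only_sim():
    """Additive-genetics-only population used by calibration checks."""
    cfg = simdiallel.SimConfig(
        n_parents=14, offspring_per_family=10, infertile_fraction=0.45,
        n_markers=250,
        traits=[simdiallel.TraitConfig(
            name="t", mean=10.0, sigma2_a=3.0, sigma2_f=0.0,
            sigma2_l=0.0, sigma2_e=1.5, reps_per_year=(2,))])
    return simdiallel.simulate_population(cfg, seed=55)
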