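import numpy as np
import pandas as pd
import pytest

from rhizovir.simulate import SimulationConfig, simulate_bundle
from rhizovir.types import (
    Compartment,
    GrowthStage,
    Rotation,
    Sample,
    SampleDesign,
)


def make_design(
    compartments=("bulk", "rhizosphere", "root"),
    rotations=("continuous", "virgin"),
    stages=("seedling", "stem_extension", "pre_harvest"),
    n_replicates=2,
) -> SampleDesign:
    samples = []
    for comp in compartments:
        for rot in rotations:
            for stage in stages:
                for rep in range(1, n_replicates + 1):
                    samples.append(
                        Sample(
                            sample_id=f"{comp[:4]}_{rot[:4]}_{stage[:4]}_r{rep}",
                            compartment=Compartment(comp),
                            rotation=Rotation(rot),
                            growth_stage=GrowthStage(stage),
                            replicate=rep,
                        )
                    )
    return SampleDesign(samples)


@pytest.fixture(scope="session")
def design36() -> SampleDesign:
    return make_design()


@pytest.fixture(scope="session")
def small_bundle():
    """Moderate-noise synthetic bundle shared across tests."""
    cfg = SimulationConfig(
        n_votus=40, n_ssrna_votus=8, priming_set_size=5, leak_rate=0.02, seed=11
    )
    design, catalog, annotations, bundle, truth = simulate_bundle(cfg)
    return {
        "config": cfg,
        "design": design,
        "catalog": catalog,
        "annotations": annotations,
        "bundle": bundle,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Zero-noise bundle: dispersion 0, no leak, breadth saturating."""
    cfg = SimulationConfig(
        n_votus=40,
        n_ssrna_votus=0,
        priming_set_size=5,
        nb_dispersion=0.0,
        leak_rate=0.0,
        breadth_delta=0.0,
        seed=7,
    )
    design, catalog, annotations, bundle, truth = simulate_bundle(cfg)
    return {
        "config": cfg,
        "design": design,
        "catalog": catalog,
        "annotations": annotations,
        "bundle": bundle,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
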