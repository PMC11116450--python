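import numpy as np
import pandas as pd
import pytest

from oa_stratify.cohort import CohortConfig, DescriptorSpec, PlantedEffect, generate_cohort
from oa_stratify.rnm import Edge, NetworkSpec, Node


@pytest.fixture(scope="session")
def study_cohort():
    """Default-structure synthetic study cohort (51 subjects, 25 SF subset)."""
    from oa_stratify.pipeline import study_cohort_config

    return generate_cohort(study_cohort_config(seed=7))


@pytest.fixture
def single_descriptor_config():
    """One 4-level descriptor driven by one analyte via a strong step shift."""
    def make(seed, effect=4.0, kind="step"):
        return CohortConfig(
            n_subjects=51, n_sf_subset=51,
            descriptor_specs=(DescriptorSpec("SE", levels=4),),
            analyte_names=("LEPTIN",),
            planted_effects=(PlantedEffect("LEPTIN", "SE", effect, kind=kind),),
            seed=seed,
        )
    return make


@pytest.fixture
def chain_network():
    """A -> B -> C activation chain; A is the clamped input, C the output TF."""
    return NetworkSpec(
        nodes={
            "A": Node("A", "input"),
            "B": Node("B", "internal"),
            "C": Node("C", "output_tf"),
        },
        edges=[Edge("A", "B", 1), Edge("B", "C", 1)],
    )


@pytest.fixture
def separable_toy():
    """Two Gaussian blobs separated by 6 SD along the first feature."""
    rng = np.random.default_rng(0)
    n = 20
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 2))
    X[:, 0] += 6.0 * y
    return X, y
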