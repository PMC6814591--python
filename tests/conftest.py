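import numpy as np
import pytest

from agesig.datatypes import AgeGroup, SampleMeta, StudyDesign
from agesig.simulate import SimConfig, simulate_study


def make_samples(species="mouse", tissue="liver", n_per_age=3):
    """Samples for one (species, tissue) across the three age groups."""
    out = []
    for age in AgeGroup:
        for rep in range(1, n_per_age + 1):
            out.append(
                SampleMeta(
                    sample_id=f"{species}_{tissue}_{age.value}_{rep}",
                    species=species,
                    tissue=tissue,
                    age_group=age,
                    replicate=rep,
                )
            )
    return out


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic study shared across read-only tests."""
    cfg = SimConfig(
        n_genes=300,
        design=StudyDesign.balanced(
            ["human", "mouse", "zebrafish", "killifish"],
            ["brain", "liver", "skin"],
            n_replicates=4,
        ),
        n_conserved_up=8,
        n_conserved_down=8,
        n_tissue_markers=4,
        seed=42,
    )
    return cfg, simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
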