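import io

import numpy as np
import pytest

from mitosub import (
    AnnotatedGenome,
    Region,
    SimulationConfig,
    TrueModel,
    propagate_sequences,
    read_branch_table,
    simulate,
)


@pytest.fixture(scope="session")
def tiny_genome() -> AnnotatedGenome:
    """A 48-base circular genome: one coding gene, one rRNA, one light-strand
    coding gene, plus 6 unannotated sites and one excluded hot-spot."""
    #          1        10        20        30        40
    sequence = "ATGGTTCGAGAGTTTACCGGCATCTAAGGCGCATTACGCTAGGATCAA"
    regions = [
        Region("G1", "protein_coding", 1, 27),
        Region("R1", "rRNA", 28, 36),
        Region("G2", "protein_coding", 37, 42, strand="light"),
    ]
    return AnnotatedGenome(sequence, regions, excluded_sites={30})


@pytest.fixture()
def three_node_tree():
    """root -> a (C7T) -> b (T7A), a second tip c below the root."""
    text = (
        "parent_id\tchild_id\tis_tip\tsubstitutions\n"
        "root\ta\t0\tC7T\n"
        "a\tb\t1\tT7A\n"
        "root\tc\t1\t\n"
    )
    return read_branch_table(io.StringIO(text))


@pytest.fixture(scope="session")
def sim_dataset():
    """A small seeded end-to-end simulation shared by read-only tests."""
    config = SimulationConfig(
        seed=20240915,
        n_tips=60,
        branch_time_mean=1.0,
        true_model=TrueModel(
            intercept=-4.0,
            effects={
                "codon_position": {"2": -0.7, "3": 0.9},
                "right_neighbor": {"G": 0.6},
            },
        ),
    )
    return simulate(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(77)
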