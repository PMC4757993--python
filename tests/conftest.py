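import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motifhmm.blocks import load_seed_blocks
from motifhmm.model import MotifHMM, assemble_motif_hmm, build_pssms
from motifhmm.mutation import build_mutation_matrix

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def seed_blocks():
    return load_seed_blocks()


@pytest.fixture(scope="session")
def mut():
    return build_mutation_matrix(calibrate=True)


@pytest.fixture(scope="session")
def gdsl_hmm(seed_blocks, mut):
    return assemble_motif_hmm(seed_blocks, mut)


@pytest.fixture(scope="session")
def gdsl_pssms(seed_blocks, mut):
    return build_pssms(seed_blocks, mut)


@pytest.fixture(scope="session")
def tiny_hmm():
    """One block of width 2 over a 3-letter alphabet."""
    return MotifHMM(
        block_ids=["A"],
        block_emissions=[np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]])],
        alphabet="ABC",
        insert_emission=1.0 / 3.0,
    )


@pytest.fixture(scope="session")
def tiny2_hmm():
    """Two blocks of width 2 each (4 match states) over a 3-letter alphabet."""
    return MotifHMM(
        block_ids=["A", "B"],
        block_emissions=[
            np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]]),
            np.array([[0.3, 0.6, 0.1], [0.5, 0.25, 0.25]]),
        ],
        alphabet="ABC",
        insert_emission=1.0 / 3.0,
    )
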