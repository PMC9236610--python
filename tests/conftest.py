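import numpy as np
import pytest

from psifold.energy import EnergyModel
from psifold.pipeline import PipelineConfig
from psifold.structure import SecondaryStructure
from psifold.synthetic import (ReactivitySimulationParams,
                               gen_junction_sequence, simulate_reactivities)


@pytest.fixture(scope="session")
def default_model():
    return EnergyModel()


@pytest.fixture(scope="session")
def toy_model():
    """Hand-computable parameters: every stack -2.0, hairpin penalty a flat
    5.0, internal 1.0 flat, AU/GU ends +0.5."""
    return EnergyModel(stack=np.full((6, 6), -2.0), hairpin_base=5.0,
                       internal_base=1.0, loop_log_coeff=0.0,
                       ml_offset=3.0, ml_branch=0.4, ml_unpaired=0.1,
                       au_end_penalty=0.5)


@pytest.fixture(scope="session")
def js60():
    """Small planted-hairpin junction fixture."""
    return gen_junction_sequence(length=60, junction_offset=24,
                                 hairpin_arm=8, seed=3)


@pytest.fixture(scope="session")
def js234():
    """Study-sized planted-hairpin junction fixture (234 nt)."""
    return gen_junction_sequence(length=234, junction_offset=93,
                                 hairpin_arm=10, seed=7)


@pytest.fixture(scope="session")
def profile60(js60):
    return simulate_reactivities(js60.true_structure,
                                 ReactivitySimulationParams(seed=11))


@pytest.fixture(scope="session")
def config60(js60):
    """Small synthetic pipeline config (fast per-variant runs)."""
    return PipelineConfig.for_synthetic(js60, seed=5, n_samples=60)


@pytest.fixture(scope="session")
def config234(js234):
    return PipelineConfig.for_synthetic(js234, seed=3, n_samples=100)


def build_multi_hairpin(n_blocks: int = 12):
    """Reference with many helices: per block CGCGCG-AACA-CGCGCG-AAA.

    Gives >= 20 helix-end A/C observations and a large stacked class, so
    three-context calibration does not fall back to the merged-paired
    class.
    """
    arm = "CGCGCG"
    loop, spacer = "AACA", "AAA"
    seq_parts, pairs = [], []
    offset = 0
    for _ in range(n_blocks):
        block = arm + loop + arm + spacer
        for k in range(6):
            pairs.append((offset + 1 + k, offset + len(arm) + len(loop)
                          + len(arm) - k))
        seq_parts.append(block)
        offset += len(block)
    sequence = "".join(seq_parts)
    return SecondaryStructure.from_pairs(sequence, pairs)


@pytest.fixture(scope="session")
def multi_hairpin_reference():
    return build_multi_hairpin()
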