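import dataclasses

import numpy as np
import pytest

from seq2track import ArchitectureConfig, TrainingConfig, build_model
from seq2track.synth import make_dataset, make_task_family


@pytest.fixture(scope="session")
def tiny_arch():
    """Smallest valid architecture used by most unit tests."""
    return ArchitectureConfig(
        sequence_length=256, bin_size=8, num_pooling_stages=3,
        num_conv_blocks=3, num_attention_blocks=2, model_width=12,
        num_heads=3, head_dim=4, output_bins=24, num_tracks=3,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_arch):
    return build_model(tiny_arch, seed=0)


@pytest.fixture
def random_input(tiny_arch):
    rng = np.random.default_rng(7)
    return np.eye(4)[rng.integers(0, 4, tiny_arch.sequence_length)]


@pytest.fixture(scope="session")
def tiny_dataset(tiny_arch):
    """A 6-example, 3-track planted-grammar dataset matching tiny_arch."""
    fam = make_task_family(3, 1.0, tiny_arch.num_tracks, 1,
                           window=tiny_arch.sequence_length,
                           bin_size=tiny_arch.bin_size, seed=11,
                           motif_length=6, mean_plants_per_motif=2.0)
    return make_dataset(fam.members[0], 6, seed=12,
                        output_bins=tiny_arch.output_bins)


def reduced(arch, **kw):
    return dataclasses.replace(arch, **kw)
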