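import os

# cap BLAS threads before numpy spins up its pools: the workloads here are
# many small matmuls where thread fan-out costs more than it saves
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np
import pytest

try:
    from threadpoolctl import threadpool_limits

    threadpool_limits(1)
except ImportError:  # pragma: no cover
    pass

from ddiscl import DescriptorSet, SynthConfig, build_similarity_profiles, generate


@pytest.fixture(scope="session")
def tiny_descriptors() -> DescriptorSet:
    """Four drugs, two feature types, hand-written bits."""
    return DescriptorSet(
        drug_ids=["a", "b", "c", "d"],
        blocks={
            "substructure": np.array(
                [[1, 1, 0, 0], [1, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]]
            ),
            "target": np.array(
                [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0]]
            ),
        },
    )


@pytest.fixture(scope="session")
def small_synth():
    """A small planted-structure dataset shared by split/training tests."""
    cfg = SynthConfig(
        n_drugs=24, n_feature_types=2, descriptors_per_type=64,
        bit_density=0.15, n_classes=4, n_archetypes=4,
        pair_coverage=0.8, imbalance_exponent=1.0,
        label_noise=0.0, bit_noise=0.01, seed=7,
    )
    descriptors, dataset, truth = generate(cfg)
    return cfg, descriptors, dataset, truth


@pytest.fixture(scope="session")
def small_profiles(small_synth):
    _, descriptors, _, _ = small_synth
    return build_similarity_profiles(descriptors)
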