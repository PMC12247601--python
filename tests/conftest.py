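import numpy as np
import pytest

from brainalign import (
    CommonPair,
    ResponseMatrix,
    SyntheticConfig,
    generate_multisubject,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(rng, n=10, v=6, subject_id="s1", prefix="stim"):
    ids = np.array([f"{prefix}{i:04d}" for i in range(n)])
    return ResponseMatrix(subject_id, ids, rng.standard_normal((n, v)))


def make_pair(rng, n=20, v=5):
    """A generic row-matched pair with independent Gaussian entries."""
    ids = np.array([f"stim{i:04d}" for i in range(n)])
    src = ResponseMatrix("src", ids, rng.standard_normal((n, v)))
    tgt = ResponseMatrix("tgt", ids, rng.standard_normal((n, v)))
    return CommonPair(src, tgt)


@pytest.fixture(scope="session")
def noiseless_orthogonal():
    """Small noiseless cohort where an exact scaled rotation links subjects."""
    cfg = SyntheticConfig(
        n_stimuli=240, n_common=80, k=6, v=20, noise_sd=0.0,
        mode="orthogonal", seed=7,
    )
    return generate_multisubject(cfg)


@pytest.fixture(scope="session")
def noiseless_permuted():
    """Noiseless cohort whose subjects differ only by a voxel permutation."""
    cfg = SyntheticConfig(
        n_stimuli=600, n_common=200, k=8, v=30, noise_sd=0.0,
        mode="permuted_voxels", seed=11,
    )
    return generate_multisubject(cfg)
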