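"""Shared fixtures: small phantoms kept cheap enough for the full suite."""

import numpy as np
import pytest

from nordicvaso import ComplexSeries, DenoiseConfig, PhantomSpec, simulate_run


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast phantom: 4 trials per run, 8^3-compatible patches."""
    return PhantomSpec(
        grid_dims=(24, 24, 12),
        n_runs=2,
        volumes_per_contrast_per_run=48,
        rest_block_len=6,
        task_block_len=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_spec):
    return simulate_run(small_spec, run_index=0)


@pytest.fixture(scope="session")
def standard_run():
    """One run of the standard phantom (12 trials, >2000 ROI voxels)."""
    spec = PhantomSpec(seed=7)
    return spec, simulate_run(spec, run_index=0)


@pytest.fixture
def noise_series():
    """Pure complex Gaussian noise with 4 trailing noise volumes."""
    rng = np.random.default_rng(5)
    vals = rng.standard_normal((16, 16, 8, 64)) + 1j * rng.standard_normal(
        (16, 16, 8, 64))
    return ComplexSeries(3.0 * vals, contrast="nulled", n_noise_volumes=4)
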