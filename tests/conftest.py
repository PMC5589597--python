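import numpy as np
import pytest

from rtpseudo.io_core import ImageVolume, BinaryMask
from rtpseudo.phantom import PhantomSpec, ScanGeometry, generate_head_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Compact noisy head phantom used across the suite."""
    return PhantomSpec(seed=1, spacing=2.5, head_semi_axes=(60.0, 70.0, 75.0))


@pytest.fixture(scope="session")
def small_head(small_spec):
    return generate_head_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_head():
    """Noise-free variant for tests that need exact tissue values."""
    spec = PhantomSpec(seed=1, spacing=2.5, head_semi_axes=(60.0, 70.0, 75.0),
                       noise_sigma_hu=0.0, noise_sigma_mr=0.0)
    return generate_head_phantom(spec)


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                modality="CT"):
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin,
                       modality=modality)


def make_mask(data, like=None):
    if like is not None:
        return BinaryMask.from_volume(like, np.asarray(data, dtype=bool))
    return BinaryMask(np.asarray(data), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


def fast_config(seed=3, **overrides):
    """Compact experiment config: small head, matched scan grids."""
    from rtpseudo.pipeline import ExperimentConfig

    defaults = dict(
        phantom=PhantomSpec(spacing=2.5, head_semi_axes=(60.0, 70.0, 75.0)),
        dct_geometry=ScanGeometry(0.0, 2.5, 2.5),
        pct_geometry=ScanGeometry(0.0, 2.5, 2.5),
        pmr_geometry=ScanGeometry(0.0, 2.5, 2.5),
        interscan_delta_mm=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


@pytest.fixture(scope="session")
def zero_perturbation_result():
    """Experiment with identical DCT/PCT geometry and no body change."""
    from rtpseudo.pipeline import run_experiment

    return run_experiment(fast_config(seed=3))


@pytest.fixture(scope="session")
def perturbed_result():
    """Experiment with a 1 mm body change and no tilt mismatch.

    The ground-truth grid is 2 mm so the 1 mm surface change is resolvable
    (a sub-voxel dilation below half a voxel flips no voxel at all).
    """
    from rtpseudo.pipeline import run_experiment

    return run_experiment(fast_config(
        seed=4, interscan_delta_mm=1.0,
        phantom=PhantomSpec(spacing=2.0, head_semi_axes=(60.0, 70.0, 75.0))))
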