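import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# the all-inlier MCD fallback on degenerate (noise-free) residuals is routine
warnings.filterwarnings("ignore", message="singular robust covariance")
warnings.filterwarnings("ignore", message="The covariance matrix associated")


@pytest.fixture(scope="session")
def noise_free_mini_series():
    """Five noise-free images of the reference geometry with ground truth."""
    import pinklaue as pl

    exp = pl.reference_experiment(n_images=5)
    cfg = pl.reference_config(
        n_images=5,
        mosaicity_deg=0.0,
        divergence_deg=0.0,
        centroid_jitter_px=0.0,
        min_intensity=8000.0,
    )
    observed, truth = pl.generate_series(exp, cfg)
    return exp, cfg, observed, truth


@pytest.fixture(scope="session")
def small_detector():
    from pinklaue.geometry import DetectorModel

    return DetectorModel(
        distance=100.0,
        origin_mm=np.array([3.2, 3.2]),
        pixel_size=0.1,
        n_fast=64,
        n_slow=64,
    )
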