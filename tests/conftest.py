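import numpy as np
import pytest

from feedtrack import ScenarioConfig, run_synthetic


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@pytest.fixture(scope="session")
def small_noise_free_run():
    """One-minute uncorrupted scenario, tracked end to end (shared: read-only)."""
    cfg = ScenarioConfig.noise_free(duration_s=60.0, seed=42)
    gt, rendered_by_frame, result = run_synthetic(cfg)
    return cfg, gt, rendered_by_frame, result


@pytest.fixture(scope="session")
def small_noisy_run():
    """One-minute default-noise scenario, tracked end to end (shared: read-only)."""
    cfg = ScenarioConfig(duration_s=60.0, seed=7)
    gt, rendered_by_frame, result = run_synthetic(cfg)
    return cfg, gt, rendered_by_frame, result
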