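import numpy as np
import pytest

from vftrend.synthetic_data import SynthConfig, generate_cohort
from vftrend.vf_core import NormativeGrid, build_grid_10_2, prepare_cohort


@pytest.fixture(scope="session")
def grid():
    return build_grid_10_2()


@pytest.fixture(scope="session")
def norm():
    return NormativeGrid.constant()


def noise_free_linear_config(**overrides) -> SynthConfig:
    """Generator settings whose truth is exactly linear at every location:
    no noise, no rounding, no schedule jitter, shallow damage so the 0 dB
    floor and 35 dB ceiling are never reached."""
    base = dict(
        n_patients=6, n_eyes=8, baseline_md_mean=-5.0, baseline_md_sd=0.0,
        md_slope_mean=-0.33, md_slope_sd=0.1, pointwise_slope_sd=0.05,
        defect_field_sd=0.0, noise_sd_at_ceiling=0.0, noise_sd_at_floor=0.0,
        interval_jitter_sd=0.0, unreliable_test_rate=0.0,
        round_to_integer=False, seed=7,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cohort, truth, normative = generate_cohort(noise_free_linear_config())
    prepared, excluded = prepare_cohort(cohort)
    assert not excluded
    return prepared, truth, normative


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """A small realistic cohort for integration-style tests."""
    cfg = SynthConfig(n_patients=6, n_eyes=8, seed=11)
    cohort, truth, normative = generate_cohort(cfg)
    prepared, _ = prepare_cohort(cohort)
    return prepared, truth, normative
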