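"""Shared fixtures: small synthetic stacks and analysis configs."""

import warnings

import numpy as np
import pytest

import myceliotrack as mt

# the deprecation chatter from scikit-image morphology APIs is not ours
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def analysis_config() -> mt.RunConfig:
    """Analysis config for simulated stacks: the tip search radius follows the
    rule of thumb of ~3x the expected per-frame tip advance (16.33 µm/h at a
    20-min interval is ~5.4 µm per frame)."""
    return mt.RunConfig(tip_radius_um=15.0)


@pytest.fixture(scope="session")
def small_growth_params() -> mt.GrowthParams:
    """A quick single-spore run: short delay, small field, ~10 growth frames."""
    return mt.GrowthParams(
        seed=7,
        n_frames=14,
        germination_delay_h=1.0,
        frame_interval_s=1200.0,
        field_px=256,
        specific_rate_h=0.0,  # unbranched: keeps the run tiny and predictable
        elongation_rate_mean_um_h=12.0,
        elongation_rate_sd_um_h=0.0,
        drift_step_px=0,
    )


@pytest.fixture(scope="session")
def small_run(small_growth_params, analysis_config):
    truth = mt.grow(small_growth_params)
    stack, masks = mt.render(truth)
    result = mt.analyze_stack(stack, analysis_config)
    return truth, stack, masks, result
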