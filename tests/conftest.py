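"""Shared fixtures: a desk-scale phantom cohort and one trained pipeline.

The heavy fixtures are session-scoped so the end-to-end cohort and the
papillary segmenter are built once and reused by every test that needs them.
"""

import numpy as np
import pytest

from dociseg.phantom import PhantomConfig, generate_cohort
from dociseg.pipeline import run_analysis
from dociseg.regional import GateConfig
from dociseg.segmodel import SegModelConfig
from dociseg.trainer import AugmentConfig, TrainConfig

#: desk-scale working resolution — keeps CPU training in tens of seconds
DESK = dict(height=64, width=64, n_channels=8)


def desk_model_config(h: int, w: int, c: int) -> SegModelConfig:
    """Reduced-filter SE-UNet sized for 64×64 phantom images."""
    return SegModelConfig(
        input=(h, w, c),
        encoder_filters=(8, 16, 32),
        se_min_channels=16,
        bottleneck_filters=48,
        se_reduction=4,
    )


def desk_gate_config() -> GateConfig:
    # window:image ratio matched to the study's 45-64 px windows on full
    # slides; 24/12 plays that role at 64 px
    return GateConfig(window_px=24, stride_px=12)


@pytest.fixture(scope="session")
def phantom_config() -> PhantomConfig:
    return PhantomConfig(seed=1, **DESK)


@pytest.fixture(scope="session")
def cohort(phantom_config):
    return generate_cohort(phantom_config)


@pytest.fixture(scope="session")
def desk_analysis(cohort):
    """Full gate + papillary segmenter run on the desk-scale cohort."""
    return run_analysis(
        cohort,
        targets=("papillary",),
        gate_config=desk_gate_config(),
        model_config_factory=desk_model_config,
        train=TrainConfig(max_epochs=30, patience=8, batch_size=4, seed=0),
        augment=AugmentConfig(output_size=64, seed=0),
        seed=0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
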