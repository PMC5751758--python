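"""Shared fixtures: scaled-down synthetic studies and pipeline configs.

The heavy end-to-end fixtures are session-scoped so the recovery,
contract and comparison tests share one LOSO evaluation.
"""

import numpy as np
import pytest

from emostage.evaluation import evaluate_three_stage
from emostage.features.extract import extract_dataset
from emostage.pipeline import PipelineConfig
from emostage.stage1 import Stage1Config
from emostage.stage2 import Stage2Config
from emostage.stage3 import Stage3Config
from emostage.synth import SynthConfig, generate_dataset

# coarse sweep grid keeps the per-fold training sweeps desk-scale
TEST_GRID = (5, 20, 80, 300, 742)


def make_pipeline_config(scheme: str = "HA_LA") -> PipelineConfig:
    return PipelineConfig(
        scheme=scheme,
        stage1=Stage1Config(fe1_grid=TEST_GRID, fe_s1_grid=TEST_GRID,
                            k_grid=(5,), min_group_size=2),
        stage2=Stage2Config(fe2_grid=TEST_GRID),
        stage3=Stage3Config(fe3_grid=TEST_GRID))


@pytest.fixture(scope="session")
def pipeline_config():
    return make_pipeline_config()


@pytest.fixture(scope="session")
def strong_study():
    """8 subjects x 8 trials x 20 s at the default (detectable) effects."""
    cfg = SynthConfig(n_subjects=8, trials_per_subject=8, duration=20.0,
                      seed=101)
    recordings, truth = generate_dataset(cfg)
    ds = extract_dataset(recordings, max_duration=cfg.duration)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def strong_report(strong_study, pipeline_config):
    """One shared LOSO evaluation of the three-stage method."""
    _cfg, ds, truth = strong_study
    return evaluate_three_stage(ds, pipeline_config, seed=101, truth=truth)


@pytest.fixture(scope="session")
def separated_study():
    """Well-separated planted groups for the recovery benchmark:
    large between-group shift, small within-group subject scatter."""
    cfg = SynthConfig(n_subjects=10, trials_per_subject=8, duration=20.0,
                      seed=101, group_effect=2.0, subject_sd=0.2)
    recordings, truth = generate_dataset(cfg)
    ds = extract_dataset(recordings, max_duration=cfg.duration)
    return cfg, ds, truth
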