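"""Shared fixtures: small phantom cohorts and a trained compact model.

Everything is generated programmatically and seeded; no data files.
"""

import dataclasses

import numpy as np
import pytest

from uwunet.architectures import ArchitectureSpec, build_model
from uwunet.experiment import TrainConfig, run_experiment
from uwunet.phantom import PhantomConfig, generate_cohort_samples


@pytest.fixture(scope="session")
def small_cohort():
    """48 phantom images from 6 patients at 64x64 — enough patients for
    grouped splitting, small enough for fast training."""
    cfg = dataclasses.replace(PhantomConfig().for_size(64), n_patients=6, seed=7)
    return generate_cohort_samples(cfg, total_images=48)


@pytest.fixture(scope="session")
def tiny_spec():
    """A narrow two-stage network for fast training smoke tests."""
    return ArchitectureSpec("tiny", base_width=8, depth=2)


@pytest.fixture(scope="session")
def trained_tiny(small_cohort, tiny_spec):
    """A compact network trained to convergence on the small phantom cohort.

    Shared by evaluation and Grad-CAM tests so the suite trains it once.
    """
    cfg = TrainConfig(batch_size=16, max_epochs=10, patience=10, seed=0)
    model, result, history = run_experiment(tiny_spec, small_cohort, cfg)
    return model, result, history, small_cohort
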