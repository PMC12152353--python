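"""Shared fixtures: layouts, noise-free and noisy synthetic trials."""

from __future__ import annotations

import numpy as np
import pytest

import pickplace as pp


@pytest.fixture(scope="session")
def layout() -> pp.WorkspaceLayout:
    return pp.WorkspaceLayout.default()


@pytest.fixture(scope="session")
def clean_params() -> pp.CohortParams:
    """Noise-free generation: no tracking noise, no dropouts, no artifacts."""
    return pp.CohortParams(noise_sd_px=0.0, p_likelihood_dropout=0.0)


@pytest.fixture(scope="session")
def clean_trial(layout, clean_params):
    """One noise-free search-size-4 trial with ground truth."""
    spec = pp.TrialSpec("P01", 1, 1, "pile", "red", 4, 2200.0)
    track, truth = pp.generate_trial_trajectory(spec, layout, clean_params,
                                                rng=42)
    return spec, track, truth


@pytest.fixture(scope="session")
def seg_config(layout) -> pp.SegmentationConfig:
    return pp.SegmentationConfig(layout=layout)


@pytest.fixture(scope="session")
def small_cohort_results():
    """4 participants x 27 trials with default noise, fully processed."""
    params = pp.CohortParams(n_participants=4, trials_per_participant=27,
                             seed=11)
    cohort = pp.generate_cohort(params)
    return cohort, pp.process_cohort(cohort)
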