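"""Shared fixtures: synthetic cohorts at two problem sizes.

``small_cohort`` is a reduced cohort (n=12, 15 s trials) for fast unit
tests; ``study_cohort`` matches the study-scale analysis conditions
(n=46, 28 neutral / 18 towards, ~40 s trials) and is embedded once per
session for the tests that need movement-space vectors.
"""

import numpy as np
import pytest

import strangertest as st

LIGHT_GRID = [{"n_filters": 8, "learning_rate": 1e-3}]


@pytest.fixture(scope="session")
def small_cohort():
    cfg = st.synthgen.CohortConfig(
        n_trials=12, seed=3,
        arena=st.synthgen.ArenaSpec(duration=15, duration_jitter=1),
    )
    return st.synthgen.generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    return st.synthgen.generate_cohort(st.synthgen.CohortConfig(n_trials=46, seed=42))


@pytest.fixture(scope="session")
def study_embedding(study_cohort):
    """Preprocess + embed the study-scale cohort once for the session."""
    dataset, _ = st.trajio.preprocess(study_cohort.trials)
    model, log = st.embedding.train_autoencoder(
        dataset, grid=LIGHT_GRID, seed=7, epochs=80, patience=15)
    emb = st.embedding.encode(model, dataset)
    return study_cohort, dataset, model, emb
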