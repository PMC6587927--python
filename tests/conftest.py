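import numpy as np
import pytest

from p3decode import (
    ConditionSpec,
    ExperimentSpec,
    NoiseSpec,
    epoch_events,
    make_template,
    preprocess_recording,
    simulate_database,
    simulate_experiment,
    standard_montage,
)
from p3decode.decoder import ModelConfig, build_model, train_on_epochs
from p3decode.scenarios import SCENARIO_NOISE


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def template(montage):
    return make_template(montage=montage)


@pytest.fixture(scope="session")
def clean_db(montage, template):
    """Small noiseless, jitterless single-condition database for exact checks."""
    spec = ExperimentSpec(
        "CLEAN", 1, 600,
        (ConditionSpec("only", class_ratio=(1, 1, 2)),),
        seed=11,
        noise=NoiseSpec(pink_sd=0.0, osc_amp=0.0, white_sd=0.0),
    )
    return simulate_experiment(spec, template=template, montage=montage)


@pytest.fixture(scope="session")
def noisy_db(montage, template):
    """Default-noise database used by preprocessing and decoding unit tests."""
    spec = ExperimentSpec(
        "NOISY", 1, 60, (ConditionSpec("only", class_ratio=(1, 1, 4)),), seed=21
    )
    return simulate_experiment(spec, template=template, montage=montage)


@pytest.fixture(scope="session")
def untrained_decoder():
    return build_model(ModelConfig(), seed=3)


@pytest.fixture(scope="session")
def scenario_decoder(montage, template):
    """The expensive shared fixture: a decoder trained across 3 synthetic
    experiments at scenario noise, used by the acceptance-style tests.

    Returns (trained_decoder, train_kwargs) where train_kwargs documents the
    simulation settings test sets must match (noise level, template).
    """
    train_conds = (ConditionSpec("mix", class_ratio=(2, 1, 9), distractor_scale=0.6),)
    specs = [
        ExperimentSpec(f"TR{i}", 1, 900, train_conds, seed=100 + i, noise=SCENARIO_NOISE)
        for i in (1, 2, 3)
    ]
    dbs = simulate_database(specs, template=template, montage=montage)
    pool = []
    for db in dbs:
        for _, rec in db.recordings.items():
            pool.append(epoch_events(preprocess_recording(rec), db.events))
    trained = train_on_epochs(build_model(ModelConfig(), seed=7), pool, n_iterations=30, seed=7)
    return trained


def make_test_db(template, montage, conditions, n_trials, seed, n_subjects=1, isi_s=1.25):
    """Simulate a held-out test experiment at scenario noise and preprocess it."""
    spec = ExperimentSpec(
        "TEST", n_subjects, n_trials, tuple(conditions), seed=seed,
        noise=SCENARIO_NOISE, isi_s=isi_s,
    )
    db = simulate_experiment(spec, template=template, montage=montage)
    recs = {s: preprocess_recording(r) for s, r in db.recordings.items()}
    return db, recs
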