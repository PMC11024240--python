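"""Shared fixtures: simulated survival data and trained tiny image models."""

import numpy as np
import pytest

from iuasurv.evaluation import ipcw_time_auc
from iuasurv.imaging_model import (
    BackboneSpec,
    SurvivalHeadSpec,
    TrainConfig,
    build_model,
    predict_cohort,
    train,
)
from iuasurv.synthetic_cohort import GeneratorConfig, generate_cohort, make_splits

# the strong-signal study condition used by the end-to-end image experiments:
# a large severity effect (hazard ratio e^6 across the severity range) so the
# 12-month discrimination ceiling of the generating law is well above 0.8
STRONG_SIGNAL_BETA = -6.0
TRAIN_SEEDS = (1, 2, 3)


def simulate_ph_cohort(n, beta, rate=0.08, censor_low=5, censor_high=60, seed=0):
    """Plain tabular proportional-hazards simulation with uniform censoring."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = rng.normal(size=(n, p))
    T = rng.exponential(1.0 / (rate * np.exp(X @ np.asarray(beta))))
    C = rng.uniform(censor_low, censor_high, n)
    times = np.maximum(np.minimum(T, C), 1e-9)
    events = (T <= C).astype(int)
    return X, times, events


@pytest.fixture(scope="session")
def ph_data_500():
    """n=500, true beta (0.8, -0.5), ~20-30% censoring."""
    X, t, e = simulate_ph_cohort(500, [0.8, -0.5], seed=0)
    return X, t, e


def train_strong_signal(seed, epochs=35):
    """Generate the strong-signal image cohort and train the tiny CNN."""
    cfg = GeneratorConfig(
        n_patients=200, seed=seed, beta_severity=STRONG_SIGNAL_BETA, image_size=64
    )
    cohort, truth, images = generate_cohort(cfg)
    proc = {
        pid: [im.astype(float) / 255.0 * 2.0 - 1.0 for im in ims]
        for pid, ims in images.items()
    }
    splits = make_splits(cohort, seed=seed)
    model = build_model(
        BackboneSpec(name="tiny_test", input_size=64), SurvivalHeadSpec(), seed=seed
    )
    tc = TrainConfig(
        learning_rate=0.01, epochs=epochs, seed=seed, weight_decay=1e-4, lr_decay=0.96
    )
    history = train(model, cohort.subset(splits["train"]), proc, tc)
    test = cohort.subset(splits["test"])
    scores = predict_cohort(model, test, proc)
    auc12 = ipcw_time_auc(scores, test.times, test.events, 12.0).auc
    return {
        "config": cfg,
        "cohort": cohort,
        "truth": truth,
        "images": proc,
        "splits": splits,
        "model": model,
        "history": history,
        "test_scores": scores,
        "auc12": auc12,
    }


@pytest.fixture(scope="session")
def strong_signal_runs():
    """Three independently seeded end-to-end trainings (shared across tests)."""
    return {seed: train_strong_signal(seed) for seed in TRAIN_SEEDS}


@pytest.fixture(scope="session")
def trained_run(strong_signal_runs):
    """One representative trained run for interpretability checks."""
    return strong_signal_runs[TRAIN_SEEDS[0]]
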