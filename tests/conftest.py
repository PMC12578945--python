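"""Shared fixtures.

The expensive artifacts — a three-subject synthetic dataset, conditioned
copies, and trained classifiers — are session-scoped so every test file
reuses one computation.  Problem sizes are desk scale (tens of trials per
class) to keep the full suite fast on one CPU while leaving enough test
data for the statistical properties to be meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

import gaitmotion as gm
from gaitmotion.preprocess import preprocess_collection
from gaitmotion.trial_io import TrialCollection, align_trial

N_PER_CLASS = 30
MASTER_SEED = 11
CNN_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def default_profile():
    return gm.sample_profile("S01", np.random.SeedSequence([MASTER_SEED, 7, 0]))


@pytest.fixture(scope="session")
def gen_config():
    return gm.GeneratorConfig(n_per_class=N_PER_CLASS, master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def dataset3(gen_config):
    """Three subjects, 20 trials/class each: 300 raw native-rate bundles."""
    return gm.gen_dataset(3, gen_config)


@pytest.fixture(scope="session")
def dataset3_raw(dataset3):
    """Aligned (5000x35) but unconditioned trials."""
    return TrialCollection([align_trial(b) for b in dataset3.bundles])


@pytest.fixture(scope="session")
def dataset3_proc(dataset3_raw):
    """Fully conditioned trials, the input to every classifier."""
    return preprocess_collection(dataset3_raw)


def _subject_subset(coll, subjects):
    idx = [i for i, t in enumerate(coll.trials) if t.subject_id in subjects]
    return coll.select(idx)


@pytest.fixture(scope="session")
def two_subject_proc(dataset3_proc):
    return _subject_subset(dataset3_proc, {"S01", "S02"})


@pytest.fixture(scope="session")
def two_subject_raw(dataset3_raw):
    return _subject_subset(dataset3_raw, {"S01", "S02"})


@pytest.fixture(scope="session")
def held_out_proc(dataset3_proc):
    return _subject_subset(dataset3_proc, {"S03"})


@pytest.fixture(scope="session")
def cnn_runs(two_subject_proc):
    """CNN trained with the default recipe for three seeds.

    Returns a list of dicts with the fitted model, its train/test split
    seed, the test collection and the test accuracy.
    """
    runs = []
    config = gm.TrainConfig()
    for seed in CNN_SEEDS:
        train, test = gm.split_dataset(two_subject_proc,
                                       config.split_fraction, seed)
        model = gm.build_cnn(seed=seed)
        gm.train_model(model, train, config, seed)
        runs.append({
            "seed": seed,
            "model": model,
            "test": test,
            "accuracy": gm.evaluate(model, test).accuracy,
        })
    return runs


@pytest.fixture(scope="session")
def lstm_accuracies(two_subject_proc):
    config = gm.TrainConfig()
    accs = []
    for seed in (0, 1):
        train, test = gm.split_dataset(two_subject_proc,
                                       config.split_fraction, seed)
        model = gm.build_lstm(seed=seed)
        gm.train_model(model, train, config, seed)
        accs.append(gm.evaluate(model, test).accuracy)
    return accs


@pytest.fixture(scope="session")
def svm_accuracies(two_subject_proc):
    config = gm.TrainConfig()
    accs = []
    for seed in (0, 1):
        train, test = gm.split_dataset(two_subject_proc,
                                       config.split_fraction, seed)
        model = gm.build_svm(seed=seed)
        gm.train_model(model, train, config, seed)
        accs.append(gm.evaluate(model, test).accuracy)
    return accs


@pytest.fixture(scope="session")
def transfer_result(dataset3_proc):
    """Three-variant LOSO protocol over the three subjects."""
    return gm.transfer_protocol(
        dataset3_proc, lambda s: gm.build_cnn(seed=s),
        gm.TrainConfig(), gm.TransferConfig(), seed=0)


@pytest.fixture(scope="session")
def smoothing_results(cnn_runs, two_subject_raw):
    """Raw vs Kalman-smoothed window-centre accuracy on a continuous
    stream, one stream per trained CNN seed (1-s stride)."""
    from gaitmotion.deployment import (classify_stream, concat_stream,
                                       kalman_smooth, stream_accuracy)
    results = []
    for run in cnn_runs:
        _, test_raw = gm.split_dataset(two_subject_raw, 0.8, run["seed"])
        stream = concat_stream(test_raw.select(range(30)),
                               order_seed=run["seed"])
        trace = classify_stream(run["model"], stream, stride_rows=1000)
        results.append({
            "raw": stream_accuracy(trace, stream),
            "smoothed": stream_accuracy(kalman_smooth(trace), stream),
        })
    return results


@pytest.fixture(scope="session")
def tiny_collection(default_profile):
    """15 aligned trials (3 per class) from one subject, unconditioned."""
    config = gm.GeneratorConfig(n_per_class=3, master_seed=5)
    ds = gm.gen_dataset(1, config)
    return TrialCollection([align_trial(b) for b in ds.bundles])
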