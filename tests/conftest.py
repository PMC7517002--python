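import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import emosig

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_table():
    """Fused feature table of one compact 4-class synthetic dataset,
    shared across tests that only read it."""
    spec = emosig.demo_4class(n_per_class=10, duration_s=24.0)
    recs = emosig.generate_dataset(spec, seed=101)
    segs = [s for r in recs for s in emosig.segment_recording(r, 6.0)]
    return emosig.build_feature_table(segs)


@pytest.fixture(scope="session")
def trained_models(demo_table):
    """SVM + DT + ELM trained on a fixed stratified split of demo_table."""
    cfg = emosig.ExperimentConfig(train_fraction=0.8, repetitions=1, seed=7)
    train, test = emosig.holdout_split(demo_table, cfg, 0)
    scaler = emosig.Scaler().fit(train)
    train_s, test_s = scaler.transform(train), scaler.transform(test)
    Xtr, ytr, _ = emosig.split_xy(train_s)
    Xte, yte, _ = emosig.split_xy(test_s)
    svm = emosig.train_svm(Xtr, ytr)
    dt = emosig.train_dt(Xtr, ytr)
    elm = emosig.train_elm(Xtr, ytr, M=min(10 * Xtr.shape[1], len(ytr)), seed=7)
    return {"svm": svm, "dt": dt, "elm": elm, "Xte": Xte, "yte": yte,
            "Xtr": Xtr, "ytr": ytr}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
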