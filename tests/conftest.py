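import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from myosignal import pipeline, synth
from myosignal.preprocess import QuantMatrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_matrix(values, design, scale="intensity", **kw):
    """Build a QuantMatrix from a plain dict/array specification."""
    return QuantMatrix(values=values, design=design, scale=scale, **kw)


@pytest.fixture(scope="session")
def timecourse_design():
    return synth.timecourse_design()


@pytest.fixture(scope="session")
def small_phospho():
    """A small complete phospho simulation shared by read-only tests."""
    models = synth.make_kinase_models(
        3, motif_informativeness=0.7, conditions=["0h", "30m", "24h", "d5"], seed=7
    )
    qm, windows, truth = synth.simulate_phospho(
        models,
        n_sites_per_kinase=10,
        n_background=50,
        design=synth.timecourse_design(),
        noise_sd=0.3,
        mnar_quantile=0.0,
        mcar_rate=0.0,
        seed=8,
    )
    return qm, windows, truth


@pytest.fixture(scope="session")
def timecourse_run():
    """Default time-course scenario (motif 0.7, noise 0.5), shared across tests."""
    return pipeline.run_timecourse(seed=11)


@pytest.fixture(scope="session")
def inhibition_run():
    return pipeline.run_inhibition(seed=11)


@pytest.fixture(scope="session")
def proteome_run():
    return pipeline.run_proteome_clustering(seed=11)


@pytest.fixture
def toy_design():
    """4 conditions x 4 replicates, 2 batches (the 16-sample phospho layout)."""
    return synth.make_design(["t0", "t1", "t2", "t3"], 4, n_batches=2)


def random_quant(design, n_features=20, seed=0, missing=0.0, scale="intensity"):
    rng = np.random.default_rng(seed)
    vals = rng.normal(20, 2, size=(n_features, len(design)))
    if missing:
        vals[rng.random(vals.shape) < missing] = np.nan
    values = pd.DataFrame(
        vals,
        index=[f"f{i:03d}" for i in range(n_features)],
        columns=list(design.index),
    )
    return QuantMatrix(values=values, design=design, scale=scale)
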