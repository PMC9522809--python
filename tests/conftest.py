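import numpy as np
import pytest

import scentmap as sm
from scentmap.pipeline import run_pipeline, PipelineConfig
from scentmap.synthetic import write_fixture


@pytest.fixture(scope="session")
def tiny_dataset():
    """40 molecules over 4 well-separated archetypes."""
    return sm.sample_dataset(sm.GeneratorConfig(n_molecules=40, n_archetypes=4, seed=11))


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """A small but complete trained pipeline on synthetic data.

    60 molecules / 6 archetypes, a 212-30-10-30-212 autoencoder at
    reduced epochs and a 6x5 hexagonal SOM — enough structure for the
    extraction and query tests without slow training.
    """
    out = tmp_path_factory.mktemp("pipe")
    gen = sm.GeneratorConfig(n_molecules=60, n_archetypes=6, seed=7)
    dataset = sm.sample_dataset(gen)
    fixture_dir = out / "fixture"
    write_fixture(dataset, fixture_dir)
    cfg = PipelineConfig(
        spectra_path=str(fixture_dir / "spectra.msp"),
        descriptors_path=str(fixture_dir / "descriptors.csv"),
        output_dir=str(out / "run"),
        ae=sm.AEConfig(layer_sizes=(212, 30, 10, 30, 212), epochs=60, seed=5),
        som=sm.SOMConfig(width=6, height=5, iterations=800, seed=6),
    )
    result = run_pipeline(cfg, resume=False)
    return {"config": cfg, "dataset": dataset, "result": result, "dir": out}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
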