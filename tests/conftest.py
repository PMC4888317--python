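import time

import pytest

from petqi.core import load_default_terminology
from petqi.phantom import PhantomSpec, generate_pet_series


@pytest.fixture(scope="session")
def terminology():
    return load_default_terminology()


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_sigma=0.0)


@pytest.fixture(scope="session")
def pet_series(noiseless_spec):
    return generate_pet_series(noiseless_spec)


@pytest.fixture(scope="session")
def study_batch(tmp_path_factory):
    """One full pipeline run on the default phantom study, shared and timed."""
    from petqi.pipeline import PipelineConfig, run_study_batch

    out = tmp_path_factory.mktemp("batch")
    start = time.monotonic()
    manifest = run_study_batch(PipelineConfig(out_dir=out, seed=7))
    elapsed = time.monotonic() - start
    return manifest, out, elapsed
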