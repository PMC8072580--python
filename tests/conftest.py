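import warnings

import pytest

from chromqsar.dataset import load_bundled_dataset
from chromqsar.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def bundled():
    """The packaged 19-congener dataset, freshly parsed."""
    return load_bundled_dataset()


@pytest.fixture()
def table():
    """A mutable copy of the bundled dataset (batch fits write derived columns)."""
    return load_bundled_dataset()


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run on the bundled data, shared across tests."""
    with warnings.catch_warnings():
        # two compounds legitimately trigger the negative-intercept fallback
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_pipeline(RunConfig(reproduce=True))
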