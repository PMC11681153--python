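import pytest

from appss.fixtures import fixtures
from appss.linguistic import default_scale
from appss.pipeline import PipelineInputs


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture(scope="session")
def K4(scale):
    return scale["K4"]


@pytest.fixture(scope="session")
def K5(scale):
    return scale["K5"]


@pytest.fixture(scope="session")
def study_inputs():
    """The bundled COVID-19 worked example, ready for run_pipeline."""
    return PipelineInputs(
        plpm=fixtures("covid-india-plpm"),
        data=fixtures("covid-india-data"),
        scale=fixtures("covid-india-scale"),
        bins=fixtures("covid-india-bins"),
        hierarchy=fixtures("covid-india-hierarchy"),
    )
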