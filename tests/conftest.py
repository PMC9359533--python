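import pytest

from peplib import (ClassifierParams, ErrorModel, LibraryModel,
                    PipelineConfig, alpha_msh_template)


@pytest.fixture(scope="session")
def template():
    return alpha_msh_template()


@pytest.fixture(scope="session")
def config(template):
    return PipelineConfig(template=template)


@pytest.fixture(scope="session")
def params():
    return ClassifierParams()


@pytest.fixture(scope="session")
def clean_error_model():
    """Error-free sequencing."""
    return ErrorModel(substitution_rate=0.0, homopolymer_indel_rate=0.0)


@pytest.fixture(scope="session")
def uniform_model():
    """Small unbiased library with uniform abundances, no aberrations."""
    return LibraryModel(n_true_variants=50, colony_count=50)
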