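import numpy as np
import pytest

from bsamap.ica import decompose
from bsamap.labeling import label_components
from bsamap.phantom import (
    PhantomSpec,
    SourceSpec,
    generate_subject,
    truth_templates,
)
from bsamap.preprocess import PreprocConfig, preprocess


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_subject(default_spec):
    """One default phantom subject (noisy series + ground truth), seed 42."""
    return generate_subject(default_spec, 42)


@pytest.fixture(scope="session")
def preprocessed(phantom_subject):
    series, _ = phantom_subject
    return preprocess(series, PreprocConfig())


@pytest.fixture(scope="session")
def decomposition(preprocessed):
    return decompose(preprocessed, n_components=8, seed=1)


@pytest.fixture(scope="session")
def templates(phantom_subject):
    _, truth = phantom_subject
    return truth_templates(truth)


@pytest.fixture(scope="session")
def component_labels(decomposition, templates, phantom_subject):
    series, _ = phantom_subject
    return label_components(decomposition, templates, tr_seconds=series.tr_seconds)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def artifact_spec() -> PhantomSpec:
    """3 neuronal + 2 artifact sources (white-noise time courses)."""
    neuronal = [SourceSpec(c, 4.5) for c in [(5, 5, 4), (14, 5, 4), (5, 14, 4)]]
    artifact = [
        SourceSpec(c, 4.5, band=None, neuronal=False)
        for c in [(14, 14, 4), (9, 9, 8)]
    ]
    return PhantomSpec(sources=tuple(neuronal + artifact))
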