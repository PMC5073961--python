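import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

from dtmtox import (DTMSimSpec, DynamicTopicModel, StudySimSpec,
                    generate_dtm_corpus, generate_expression_study)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small simulated corpus shared by model tests (2 topics, 3 slices)."""
    spec = DTMSimSpec(n_topics=2, n_words=40, n_slices=3, docs_per_slice=20,
                      tokens_per_doc=40, seed=5)
    corpus, truth = generate_dtm_corpus(spec)
    return corpus, truth


@pytest.fixture(scope="session")
def tiny_fit(tiny_corpus):
    corpus, _ = tiny_corpus
    model = DynamicTopicModel(n_topics=2, alpha=0.05, em_max_iter=25,
                              random_state=0).fit(corpus)
    return corpus, model


@pytest.fixture(scope="session")
def small_study():
    """Small planted-module study: 8 compounds, 2 groups, 3 replicates."""
    from dtmtox.simulate import MoaGroup
    spec = StudySimSpec(
        n_compounds=8,
        moa_groups=[MoaGroup("a", 4, module_size=25, effect_size=2.0,
                             profile="sustained"),
                    MoaGroup("b", 4, module_size=25, effect_size=2.0,
                             profile="late")],
        n_genes=400, seed=3,
    )
    return generate_expression_study(spec), spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
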