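import warnings

import pytest

from icufusion import fhir_model, protocol_translation, synthgen


@pytest.fixture(scope="session")
def code_registry():
    return fhir_model.default_code_registry()


@pytest.fixture(scope="session")
def feature_registry():
    return protocol_translation.default_feature_registry()


@pytest.fixture(scope="session")
def worked_case():
    return synthgen.generate_worked_case()


@pytest.fixture(scope="session")
def small_corpus(code_registry, feature_registry):
    """A small multi-dialect corpus plus per-category compiled rules."""
    cohort = synthgen.generate_cohort(synthgen.CohortSpec(n=10, seed=42))
    messages, manifest = synthgen.generate_streams(
        cohort, synthgen.StreamSpec(bytes_per_mbps=2_000.0, seed=42)
    )
    rules = {}
    for msg in messages:
        key = (msg.category, msg.dialect)
        if key not in rules:
            rules[key] = protocol_translation.compile_parser(
                msg.category, msg.dialect, feature_registry, code_registry
            )
    return messages, rules, manifest


@pytest.fixture()
def no_sklearn_noise():
    """Silence sklearn deprecation/convergence chatter in training tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        yield
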