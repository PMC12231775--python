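import pytest

from adcea import load_base_case


@pytest.fixture(scope="session")
def base_params():
    """The bundled base-case parameter set (session-scoped, read-only).

    Tests that mutate parameters must copy first
    (``base_params.model_copy(deep=True)``).
    """
    return load_base_case()


@pytest.fixture()
def params(base_params):
    """A deep copy safe to mutate."""
    return base_params.model_copy(deep=True)
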