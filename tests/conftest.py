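import pytest

from caredesign import build_fixture_bundle


@pytest.fixture(scope="session")
def bundle():
    return build_fixture_bundle()


@pytest.fixture()
def option_a(bundle):
    return bundle.options["A"]


@pytest.fixture()
def option_b(bundle):
    return bundle.options["B"]
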