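import pytest

from lantimine.templates import TemplateLibrary


@pytest.fixture(scope="session")
def lib() -> TemplateLibrary:
    return TemplateLibrary.default()
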