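import pytest


@pytest.fixture
def write_file(tmp_path):
    """Write text content to a temp file and return its path."""

    def _write(name: str, content: str):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write
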