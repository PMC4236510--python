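import pytest

from mipscan.anchor_align import load_default_references
from mipscan.classify import RuleTable


@pytest.fixture(scope="session")
def refs():
    return load_default_references()


@pytest.fixture(scope="session")
def rules():
    return RuleTable.load()


@pytest.fixture()
def fasta_writer(tmp_path):
    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
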