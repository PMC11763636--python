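import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def write_table(tmp_path):
    """Write header + rows as a TSV file and return its path."""

    def _write(name: str, header: list[str], rows: list[list]) -> Path:
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(name: str, entries: list[tuple[str, str]]) -> Path:
        path = tmp_path / name
        path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))
        return path

    return _write
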