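import pytest

from fqpipe.preprocess import run_serial
from fqpipe.synth import GenSpec, generate_pairs


@pytest.fixture(scope="session")
def small_pairs(tmp_path_factory):
    """200 synthetic mate pairs, 60 bp, slash-style identifiers."""
    tmp = tmp_path_factory.mktemp("pairs")
    spec = GenSpec(n_pairs=200, read_length=60, seed=11)
    p1, p2 = generate_pairs(spec, tmp / "sim")
    return spec, p1, p2


@pytest.fixture(scope="session")
def encoded_small(small_pairs, tmp_path_factory):
    """Encoded-unit file for the 200-pair fixture."""
    _, p1, p2 = small_pairs
    sink = tmp_path_factory.mktemp("encoded")
    result = run_serial(p1, p2, sink)
    return result.output_path
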