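import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from coaxfold import build_orderings, find_helix_candidates
from coaxfold.cli import cloverleaf_spec
from coaxfold.geometry import enumerate_coax_pairs
from coaxfold.synthetic import generate_planted_sequence


@pytest.fixture(scope="session")
def cloverleaf():
    """A decoy-free planted cloverleaf: (seq, truth)."""
    seq, truth = generate_planted_sequence(cloverleaf_spec(1))
    return seq, truth


@pytest.fixture(scope="session")
def hairpin_instance():
    """Single GC hairpin with its index and coax list."""
    seq = "GGCGCGAAAACGCGCC"
    cands = find_helix_candidates(seq)
    index = build_orderings(cands)
    coax = enumerate_coax_pairs(index, seq)
    return seq, index, coax
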