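import pytest

from mirprof import make_reference_set


def brute_force_hits(read: str, reference: str, max_mismatches: int):
    """Position-by-position Hamming scan: the independent matching oracle."""
    m = len(read)
    hits = []
    for s in range(len(reference) - m + 1):
        mm = sum(1 for a, b in zip(read, reference[s : s + m]) if a != b)
        if mm <= max_mismatches:
            hits.append((s, s + m, mm))
    return hits


@pytest.fixture(scope="session")
def refs():
    """Small seeded reference set shared across tests."""
    return make_reference_set(11, n_decoys=4, n_extra_precursors=4, genome_length=1500)
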