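"""Shared fixtures and independent oracles used across the test suite."""
from collections import Counter

import numpy as np
import pytest

from kmerdiff import SequenceRecord

_COMP = str.maketrans("ACGT", "TGCA")


def brute_canonical(kmer: str):
    """String-comparison canonical form; independent of the packed-code path."""
    if set(kmer) - set("ACGT"):
        return None
    rc = kmer.translate(_COMP)[::-1]
    return min(kmer, rc)


def brute_count(seqs, k):
    """Enumerate every window of every sequence and canonicalize by string."""
    counts = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            canon = brute_canonical(s[i : i + k])
            if canon is not None:
                counts[canon] += 1
    return counts


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_genome():
    """Two short chromosomes with all-ACGT content."""
    r = np.random.default_rng(11)
    return [
        SequenceRecord("c1", "".join(r.choice(list("ACGT"), size=400))),
        SequenceRecord("c2", "".join(r.choice(list("ACGT"), size=250))),
    ]
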