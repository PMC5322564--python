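"""Shared fixtures: a fixed reference amplicon and error-free pair construction."""

import numpy as np
import pytest

from indelscan import AmpliconReference, ReadPair, random_amplicon, reverse_complement

#: Period-4 reference: any ungapped shift by a non-multiple of 4 mismatches at
#: every position, so constructed indels produce exact, unambiguous breakpoints.
PERIODIC = "ACGT" * 50  # 200 bp


@pytest.fixture(scope="session")
def ref() -> AmpliconReference:
    """A fixed 200-bp random amplicon cut at position 100."""
    return random_amplicon(200, 100, rng=np.random.default_rng(20160901))


@pytest.fixture(scope="session")
def periodic_ref() -> AmpliconReference:
    return AmpliconReference("periodic", PERIODIC, cut_site=100, guide_interval=(83, 103))


def error_free_pair(molecule: str, read_length: int = 150, qual: int = 35,
                    read_id: str = "pair") -> ReadPair:
    """The exact read pair a perfect sequencer would emit for a molecule."""
    rl = min(read_length, len(molecule))
    return ReadPair(
        read_id=read_id,
        forward_seq=molecule[:rl],
        reverse_seq=reverse_complement(molecule[-rl:]),
        forward_qual=(qual,) * rl,
        reverse_qual=(qual,) * rl,
    )
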