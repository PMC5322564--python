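"""The two-sided consecutive-mismatch breakpoint caller against literal oracles."""

import numpy as np
import pytest

from indelscan import (
    CallStatus,
    ObservedSequence,
    call_indel,
    forward_breakpoint,
    length_difference,
    reverse_breakpoint,
)

from .conftest import PERIODIC
from .oracles import brute_forward_breakpoint, brute_reverse_breakpoint


class TestScans:
    def test_identity_has_no_breakpoint(self):
        assert forward_breakpoint("ACGTACGT", "ACGTACGT") is None
        assert reverse_breakpoint("ACGTACGT", "ACGTACGT") is None

    def test_two_consecutive_mismatches(self):
        assert forward_breakpoint("AAAACCAA", "AAAAAAAA") == 4
        assert reverse_breakpoint("AAAACCAA", "AAAAAAAA") == 6

    def test_isolated_mismatch_tolerated(self):
        assert forward_breakpoint("AACAAAAA", "AAAAAAAA") is None
        assert reverse_breakpoint("AACAAAAA", "AAAAAAAA") is None

    def test_n_counts_as_mismatch(self):
        assert forward_breakpoint("AANNAAAA", "AAAAAAAA") == 2
        assert forward_breakpoint("AANAAAAA", "AANAAAAA") is None  # isolated N-vs-N

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            forward_breakpoint("", "ACGT")

    def test_reverse_is_mirrored_forward(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            ref = "".join(rng.choice(list("ACGT"), size=n))
            obs = list(ref)
            for _ in range(int(rng.integers(0, 6))):
                p = int(rng.integers(n))
                obs[p] = "ACGT"[int(rng.integers(4))]
            obs = "".join(obs)
            k = forward_breakpoint(obs[::-1], ref[::-1])
            expected = None if k is None else len(ref) - k
            assert reverse_breakpoint(obs, ref) == expected


def _random_edited(rng, min_len=20, max_len=60):
    """A random reference and an observed sequence carrying random
    substitutions and (sometimes) an indel."""
    n = int(rng.integers(min_len, max_len + 1))
    ref = "".join(rng.choice(list("ACGT"), size=n))
    obs = list(ref)
    for _ in range(int(rng.integers(0, 5))):  # substitutions
        obs[int(rng.integers(n))] = "ACGTN"[int(rng.integers(5))]
    kind = rng.integers(3)
    if kind == 1:  # deletion
        start = int(rng.integers(0, n - 1))
        length = int(rng.integers(1, min(10, n - start) + 1))
        obs = obs[:start] + obs[start + length:]
    elif kind == 2:  # insertion
        at = int(rng.integers(0, n + 1))
        ins = [str(b) for b in rng.choice(list("ACGT"), size=int(rng.integers(1, 9)))]
        obs = obs[:at] + ins + obs[at:]
    return ref, "".join(obs)


def test_scans_match_brute_force_oracle():
    """Randomised equivalence with the literal every-offset oracle."""
    rng = np.random.default_rng(123)
    for _ in range(500):
        ref, obs = _random_edited(rng)
        if not obs:
            continue
        assert forward_breakpoint(obs, ref) == brute_forward_breakpoint(obs, ref)
        assert reverse_breakpoint(obs, ref) == brute_reverse_breakpoint(obs, ref)


def _observed(seq, anchor_ok=True):
    return ObservedSequence("read", seq, overlap_length=0, anchor_ok=anchor_ok)


class TestCallIndel:
    def test_wildtype(self, periodic_ref):
        call = call_indel(_observed(periodic_ref.sequence), periodic_ref)
        assert call.status is CallStatus.WILDTYPE_LIKE
        assert call.deletion_length == 0 and call.inserted_sequence == ""
        assert length_difference(call) == 0

    def test_clean_deletion(self, periodic_ref):
        # period-4 reference: a 6 bp deletion mismatches at every shifted
        # position, so both scans stop exactly at the true interval
        seq = PERIODIC[:60] + PERIODIC[66:]
        call = call_indel(_observed(seq), periodic_ref)
        assert call.status is CallStatus.EDITED
        assert call.deletion_interval == (60, 66)
        assert call.inserted_sequence == ""
        assert call.length_difference == -6

    def test_insertion_matches_oracle(self, periodic_ref):
        # both insertion ends mismatch their aligned reference bases, so the
        # scans pin the junction exactly (exact breakpoints depend on this
        # flanking identity; an aliasing insertion would shift or cross)
        ins = "GGGA"
        seq = PERIODIC[:63] + ins + PERIODIC[63:]
        call = call_indel(_observed(seq), periodic_ref)
        assert call.status is CallStatus.EDITED
        assert call.length_difference == 4
        assert call.inserted_sequence == ins
        assert call.deletion_interval == (63, 63)
        assert call.forward_breakpoint == brute_forward_breakpoint(seq, PERIODIC)
        assert call.reverse_breakpoint == brute_reverse_breakpoint(seq, PERIODIC)
        # the called regions replay to the observed sequence
        f, r = call.deletion_interval
        assert PERIODIC[:f] + call.inserted_sequence + PERIODIC[r:] == seq

    def test_aliasing_insertion_is_flagged_crossed(self, periodic_ref):
        # "GATC" inserted at 63 partially matches the period-4 context: the
        # scans slide past each other and the call is flagged, not silently
        # miscalled
        seq = PERIODIC[:63] + "GATC" + PERIODIC[63:]
        call = call_indel(_observed(seq), periodic_ref)
        assert call.status is CallStatus.ARTIFACT_CROSSED
        assert call.length_difference == 4  # actual length change retained

    def test_isolated_substitutions_stay_wildtype_like(self, ref):
        """Non-adjacent substitutions never produce a false edited call."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            seq = list(ref.sequence)
            positions = rng.choice(np.arange(0, len(seq), 2), size=5, replace=False)
            for p in positions:
                seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
            call = call_indel(_observed("".join(seq)), ref)
            assert call.status is CallStatus.WILDTYPE_LIKE

    def test_deletion_in_homopolymer_run_crosses(self):
        """Scans overshooting through a homopolymer cross and are flagged."""
        rng = np.random.default_rng(2)
        left = "".join(rng.choice(list("CGT"), size=60))
        right = "".join(rng.choice(list("CGT"), size=60))
        refseq = left + "A" * 10 + right
        from indelscan import AmpliconReference

        ref = AmpliconReference("homo", refseq, cut_site=65, guide_interval=(48, 68))
        obs = left + "A" * 4 + right  # 6 bp deleted inside the A-run
        call = call_indel(_observed(obs), ref)
        assert call.status is CallStatus.ARTIFACT_CROSSED
        # left scan slides to the run's right edge (64), right scan to its
        # left edge; the breakpoints cross in observed coordinates
        assert (call.forward_breakpoint, call.reverse_breakpoint) == (64, 66)
        r_obs = call.obs_length - (call.ref_length - call.reverse_breakpoint)
        assert call.forward_breakpoint > r_obs

    def test_unanchored_not_called(self, ref):
        call = call_indel(_observed(ref.sequence, anchor_ok=False), ref)
        assert call.status is CallStatus.UNANCHORED
        assert call.forward_breakpoint is None


def test_length_identity_on_random_indels(ref):
    """len(obs) - len(ref) = insertion - deletion for every non-crossed call."""
    rng = np.random.default_rng(77)
    checked = 0
    for _ in range(300):
        ref_seq = ref.sequence
        start = int(rng.integers(45, 150))
        dlen = int(rng.integers(0, 12))
        ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 8))))
        obs = ref_seq[:start] + ins + ref_seq[start + dlen:]
        call = call_indel(_observed(obs), ref)
        if call.status in (CallStatus.WILDTYPE_LIKE, CallStatus.EDITED):
            assert call.length_difference == len(obs) - len(ref_seq)
            checked += 1
    assert checked > 200
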