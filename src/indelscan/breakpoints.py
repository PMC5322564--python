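"""Two-sided breakpoint calling by inward consecutive-mismatch scanning.

Each observed sequence is compared to the wild-type amplicon ungapped, from
both ends moving inward.  A breakpoint is the position where the two sequences
first differ by at least two consecutive mismatches; isolated single
mismatches (sequencing errors) never trigger one.  The wild-type sequence
between the forward and reverse breakpoints is the deletion region; the
observed sequence between them is the insertion region.

Because the scans are independent, chance matches between the reference and
the shifted observed sequence can make them overshoot past one another;
such crossed calls pair a spurious long insertion with a long deletion and
are flagged ``artifact_crossed`` rather than discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from ._seqops import mismatch_mask, seq_to_array
from .reference import AmpliconReference
from .stitch import ObservedSequence

logger = logging.getLogger(__name__)


class CallStatus(str, Enum):
    WILDTYPE_LIKE = "wildtype_like"
    EDITED = "edited"
    ARTIFACT_CROSSED = "artifact_crossed"
    UNANCHORED = "unanchored"


def forward_breakpoint(obs: str, ref: str) -> int | None:
    """Smallest ``i`` with mismatches at both ``i`` and ``i + 1`` (left-aligned).

    Returns ``None`` when no two consecutive mismatches occur within
    ``min(len(obs), len(ref)) - 1``; scanning stops at the shorter length.
    """
    if not obs or not ref:
        raise ValueError("empty sequence")
    n = min(len(obs), len(ref))
    mm = mismatch_mask(seq_to_array(obs)[:n], seq_to_array(ref)[:n])
    double = mm[:-1] & mm[1:]
    if not double.any():
        return None
    return int(np.argmax(double))


def reverse_breakpoint(obs: str, ref: str) -> int | None:
    """Mirror scan from the right; returns the breakpoint in reference coordinates.

    The value is half-open-exclusive: the reference position just after the
    last disrupted base, i.e. the deletion interval's end.  It equals
    ``len(ref) - forward_breakpoint(reversed(obs), reversed(ref))``.
    """
    k = forward_breakpoint(obs[::-1], ref[::-1])
    return None if k is None else len(ref) - k


@dataclass
class IndelCall:
    """Editing outcome of one observed sequence, in reference coordinates.

    ``deletion_interval`` is ``(forward_breakpoint, reverse_breakpoint)`` and
    may be stored inverted (start > end) for crossed calls; its effective
    length is then zero.  ``obs_interval`` is the corresponding half-open
    interval on the observed sequence whose content is ``inserted_sequence``.
    """

    read_id: str
    forward_breakpoint: int | None
    reverse_breakpoint: int | None
    deletion_interval: tuple[int, int]
    inserted_sequence: str
    status: CallStatus
    obs_length: int = 0
    ref_length: int = 0

    @property
    def deletion_length(self) -> int:
        start, end = self.deletion_interval
        return max(0, end - start)

    @property
    def insertion_length(self) -> int:
        return len(self.inserted_sequence)

    @property
    def length_difference(self) -> int:
        """Signed length change of the observed sequence versus wild type.

        Insertion length minus deletion length, which equals
        ``len(obs) - len(ref)`` for every non-crossed call.  For
        ``artifact_crossed`` calls the region lengths are unreliable, so the
        actual ``len(obs) - len(ref)`` is reported instead — the efficiency
        statistic counts sequences by their real length change.
        """
        if self.status is CallStatus.ARTIFACT_CROSSED:
            return self.obs_length - self.ref_length
        return self.insertion_length - self.deletion_length


_EMPTY = (0, 0)


def call_indel(obs: ObservedSequence, ref: AmpliconReference) -> IndelCall:
    """Call the deletion and insertion regions of one anchored observed sequence.

    Outcomes:

    * both scans find no breakpoint -> ``wildtype_like`` with empty regions;
    * exactly one scan fires -> ``wildtype_like`` with a logged warning (a
      lone disrupted end cannot define regions);
    * both fire and the breakpoints do not cross -> ``edited`` with
      deletion ``ref[f:r]`` and insertion ``obs[f:r_obs]``;
    * the breakpoints cross in reference or observed coordinates ->
      ``artifact_crossed`` with both regions reported but flagged.

    Sequences that failed the anchor filter are returned as ``unanchored``
    without calling.
    """
    seq = obs.sequence
    base = dict(read_id=obs.read_id, obs_length=len(seq), ref_length=len(ref))
    if not obs.anchor_ok:
        return IndelCall(
            forward_breakpoint=None, reverse_breakpoint=None,
            deletion_interval=_EMPTY, inserted_sequence="",
            status=CallStatus.UNANCHORED, **base,
        )
    f = forward_breakpoint(seq, ref.sequence)
    k = forward_breakpoint(seq[::-1], ref.sequence[::-1])
    r_ref = None if k is None else len(ref) - k
    r_obs = None if k is None else len(seq) - k

    if f is None or r_ref is None:
        if (f is None) != (r_ref is None):
            logger.warning(
                "%s: one-sided breakpoint (f=%s, r=%s); classified wildtype_like",
                obs.read_id, f, r_ref,
            )
        return IndelCall(
            forward_breakpoint=None, reverse_breakpoint=None,
            deletion_interval=_EMPTY, inserted_sequence="",
            status=CallStatus.WILDTYPE_LIKE, **base,
        )

    inserted = seq[f:r_obs]  # empty when r_obs <= f
    crossed = f > r_ref or f > r_obs
    if crossed:
        status = CallStatus.ARTIFACT_CROSSED
    elif r_ref > f or inserted:
        status = CallStatus.EDITED
    else:  # pragma: no cover - both scans fired yet both regions empty
        status = CallStatus.WILDTYPE_LIKE
    return IndelCall(
        forward_breakpoint=f, reverse_breakpoint=r_ref,
        deletion_interval=(f, r_ref), inserted_sequence=inserted,
        status=status, **base,
    )


def length_difference(call: IndelCall) -> int:
    """Functional access to :attr:`IndelCall.length_difference`."""
    return call.length_difference
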