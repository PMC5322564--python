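"""Merge paired-end mates into observed sequences and enforce wild-type anchors.

A read pair covers the amplicon from both ends; the mates are merged at their
3'-end overlap (at least 15 bp by default) into one "observed sequence" per
molecule.  Each end of the stitched sequence is a mate's 5' end and must retain
a terminal stretch of wild-type sequence (40 bp by default) for the sequence to
enter breakpoint calling — this anchor filter discards chimeric or mispriming
products and molecules whose edits reach the primer regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seqops import count_mismatches, mismatch_mask, seq_to_array
from .reference import VALID_BASES, AmpliconReference

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Machine-readable rejection reasons emitted by the stitcher and anchor filter.
REASON_NO_OVERLAP = "no_overlap"
REASON_AMBIGUOUS = "ambiguous_overlap"
REASON_TOO_SHORT = "too_short"
REASON_ANCHOR_FAIL = "anchor_fail"


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over ``{A, C, G, T, N}``; N maps to N.

    Raises
    ------
    ValueError
        If a non-nucleotide character occurs, naming its position.
    """
    for i, c in enumerate(seq):
        if c not in VALID_BASES:
            raise ValueError(f"non-nucleotide character {c!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """One forward and one reverse mate with per-base Phred qualities."""

    read_id: str
    forward_seq: str
    reverse_seq: str
    forward_qual: tuple[int, ...] | list[int]
    reverse_qual: tuple[int, ...] | list[int]

    def __post_init__(self) -> None:
        if len(self.forward_seq) != len(self.forward_qual):
            raise ValueError(f"{self.read_id}: forward sequence/quality length mismatch")
        if len(self.reverse_seq) != len(self.reverse_qual):
            raise ValueError(f"{self.read_id}: reverse sequence/quality length mismatch")


@dataclass
class ObservedSequence:
    """A stitched merged read pair, ready for breakpoint calling."""

    read_id: str
    sequence: str
    overlap_length: int
    anchor_ok: bool | None = None


@dataclass(frozen=True)
class StitchRejection:
    """A pair (or stitched sequence) dropped before calling, with its reason."""

    read_id: str
    reason: str


def stitch_pair(
    pair: ReadPair,
    min_overlap: int = 15,
    max_overlap_mismatch_frac: float = 0.1,
) -> ObservedSequence | StitchRejection:
    """Merge a read pair at the best 3'-end overlap of at least ``min_overlap`` bp.

    The reverse mate is reverse-complemented and slid along the forward mate's
    3' end.  Among overlaps whose mismatch fraction is at most
    ``max_overlap_mismatch_frac``, the one with the fewest mismatches wins
    (ties broken towards the longest overlap).  At discordant overlap positions
    the base with the higher Phred score is kept; quality ties keep the forward
    base.  Stitched length is ``len(F) + len(R) - overlap``.
    """
    if not pair.forward_seq or not pair.reverse_seq:
        raise ValueError(f"{pair.read_id}: empty mate")
    fwd = seq_to_array(pair.forward_seq)
    rev_seq = reverse_complement(pair.reverse_seq)
    rev = seq_to_array(rev_seq)
    rev_qual = np.asarray(pair.reverse_qual[::-1], dtype=np.int32)
    fwd_qual = np.asarray(pair.forward_qual, dtype=np.int32)

    best_mm = -1
    best_len = 0
    n_best = 0
    for olen in range(min(len(fwd), len(rev)), min_overlap - 1, -1):
        mm = count_mismatches(fwd[-olen:], rev[:olen])
        if mm > max_overlap_mismatch_frac * olen:
            continue
        if best_mm < 0 or mm < best_mm:
            best_mm, best_len, n_best = mm, olen, 1
        elif mm == best_mm and olen == best_len:  # pragma: no cover - lengths are distinct
            n_best += 1
    if best_mm < 0:
        return StitchRejection(pair.read_id, REASON_NO_OVERLAP)
    if n_best > 1:  # pragma: no cover - defensive; distinct lengths break all ties
        return StitchRejection(pair.read_id, REASON_AMBIGUOUS)

    olen = best_len
    f_tail = fwd[-olen:].copy()
    r_head = rev[:olen]
    discord = mismatch_mask(f_tail, r_head)
    take_rev = discord & (rev_qual[:olen] > fwd_qual[-olen:])
    f_tail[take_rev] = r_head[take_rev]
    merged = (
        pair.forward_seq[: len(fwd) - olen]
        + f_tail.tobytes().decode("ascii")
        + rev_seq[olen:]
    )
    return ObservedSequence(pair.read_id, merged, overlap_length=olen)


def check_wildtype_anchor(
    obs: ObservedSequence,
    ref: AmpliconReference,
    anchor_len: int = 40,
    max_anchor_mismatches: int = 0,
) -> bool:
    """True iff both ends of the stitched sequence retain wild-type anchors.

    The first ``anchor_len`` bases are compared to the reference's first
    ``anchor_len`` bases and the last to the reference's last, each tolerating
    at most ``max_anchor_mismatches`` mismatches.  Sequences shorter than
    ``2 * anchor_len`` fail outright.
    """
    s = obs.sequence
    if len(s) < 2 * anchor_len:
        return False
    head_mm = count_mismatches(
        seq_to_array(s[:anchor_len]), seq_to_array(ref.sequence[:anchor_len])
    )
    tail_mm = count_mismatches(
        seq_to_array(s[-anchor_len:]), seq_to_array(ref.sequence[-anchor_len:])
    )
    return head_mm <= max_anchor_mismatches and tail_mm <= max_anchor_mismatches


@dataclass
class StitchResult:
    """Batch output: anchor-validated observed sequences plus a rejection log."""

    observed: list[ObservedSequence] = field(default_factory=list)
    rejections: list[StitchRejection] = field(default_factory=list)
    n_input: int = 0

    @property
    def anchored(self) -> list[ObservedSequence]:
        return [o for o in self.observed if o.anchor_ok]


def stitch_pairs(
    pairs: list[ReadPair],
    ref: AmpliconReference,
    min_overlap: int = 15,
    max_overlap_mismatch_frac: float = 0.1,
    anchor_len: int = 40,
    max_anchor_mismatches: int = 0,
) -> StitchResult:
    """Stitch a batch of pairs and apply the wild-type anchor filter.

    Anchor-failing sequences are recorded in the rejection log (reason
    ``too_short`` or ``anchor_fail``) and returned with ``anchor_ok=False``
    alongside the log so callers can still account for them.
    """
    result = StitchResult(n_input=len(pairs))
    for pair in pairs:
        out = stitch_pair(pair, min_overlap, max_overlap_mismatch_frac)
        if isinstance(out, StitchRejection):
            result.rejections.append(out)
            continue
        if len(out.sequence) < 2 * anchor_len:
            out.anchor_ok = False
            result.rejections.append(StitchRejection(pair.read_id, REASON_TOO_SHORT))
        else:
            out.anchor_ok = check_wildtype_anchor(out, ref, anchor_len, max_anchor_mismatches)
            if not out.anchor_ok:
                result.rejections.append(StitchRejection(pair.read_id, REASON_ANCHOR_FAIL))
        result.observed.append(out)
    return result


def write_observed_fasta(observed: list[ObservedSequence], path: str | Path) -> None:
    """Write stitched sequences as FASTA (id = read id, overlap in description)."""
    with open(path, "w") as fh:
        for obs in observed:
            fh.write(f">{obs.read_id} overlap={obs.overlap_length} anchor_ok={obs.anchor_ok}\n")
            fh.write(obs.sequence + "\n")


def write_rejection_log(rejections: list[StitchRejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for rej in rejections:
            fh.write(f"{rej.read_id}\t{rej.reason}\n")
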