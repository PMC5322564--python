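"""Ground-truthed amplicon read simulator.

Emulates MiSeq-style amplicon deep sequencing of a Cas9-targeted locus: a
wild-type amplicon, a configurable fraction of edited molecules carrying a
cut-site-spanning deletion (optionally with an insertion at the junction),
and 150-bp paired-end reads covering the amplicon from both ends with
uniform substitution errors and Phred qualities, including an optional
linear quality decline on the reverse read's 3' end.

Every simulated molecule carries a :class:`TrueOutcome`, so the stitcher,
breakpoint caller and spectrum statistics can be validated against known
ground truth.  Identical configurations (including seed) produce
byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import AmpliconReference, random_amplicon
from .stitch import ReadPair

#: Terminal wild-type stretch (bp per end) that edits must never invade, so
#: unedited and cleanly edited molecules always pass the anchor filter.
ANCHOR_LEN = 40

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class LengthDistribution:
    """Distribution of indel lengths: ``fixed``, ``geometric`` or ``uniform``.

    * ``fixed(L)`` — every draw is ``L``;
    * ``geometric(p)`` — support 1, 2, ... with mean ``1/p``;
    * ``uniform(low, high)`` — integers drawn uniformly on ``[low, high]``.
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "geometric", "uniform"):
            raise ValueError(f"unknown length distribution {self.kind!r}")
        if self.kind == "geometric" and not 0 < self.params[0] <= 1:
            raise ValueError("geometric parameter must be in (0, 1]")
        if self.kind == "uniform" and not 1 <= self.params[0] <= self.params[1]:
            raise ValueError("uniform bounds must satisfy 1 <= low <= high")
        if self.kind == "fixed" and self.params[0] < 1:
            raise ValueError("fixed length must be >= 1")

    @classmethod
    def fixed(cls, length: int) -> "LengthDistribution":
        return cls("fixed", (int(length),))

    @classmethod
    def geometric(cls, p: float) -> "LengthDistribution":
        return cls("geometric", (float(p),))

    @classmethod
    def uniform(cls, low: int, high: int) -> "LengthDistribution":
        return cls("uniform", (int(low), int(high)))

    @classmethod
    def parse(cls, text: str) -> "LengthDistribution":
        """Parse ``"fixed:6"``, ``"geometric:0.35"`` or ``"uniform:1,10"``."""
        kind, _, arg = text.partition(":")
        params = tuple(float(x) for x in arg.split(",")) if arg else ()
        if kind == "fixed":
            return cls.fixed(int(params[0]))
        if kind == "geometric":
            return cls.geometric(params[0])
        if kind == "uniform":
            return cls.uniform(int(params[0]), int(params[1]))
        raise ValueError(f"cannot parse length distribution {text!r}")

    def draw(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return int(self.params[0])
        if self.kind == "geometric":
            return int(rng.geometric(self.params[0]))
        low, high = self.params
        return int(rng.integers(int(low), int(high) + 1))

    def __str__(self) -> str:
        args = ",".join(f"{p:g}" for p in self.params)
        return f"{self.kind}:{args}"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults emulate the sequenced TP53 experiment: a 200-bp amplicon cut in
    the middle, 2x150-bp reads (100-bp mutual overlap), 10,000 molecules per
    sample, 60% edited molecules with NHEJ-like geometric deletion lengths,
    occasional short junction insertions, and a 1e-3 per-base substitution
    error rate.
    """

    amplicon_length: int = 200
    cut_site: int = 100
    edited_fraction: float = 0.6
    deletion_length_distribution: LengthDistribution = field(
        default_factory=lambda: LengthDistribution.geometric(0.35)
    )
    insertion_probability: float = 0.2
    insertion_length_distribution: LengthDistribution = field(
        default_factory=lambda: LengthDistribution.geometric(0.6)
    )
    substitution_error_rate: float = 0.001
    read_length: int = 150
    n_molecules: int = 10_000
    rng_seed: int = 0
    # Quality model (exercises the stitcher's quality-based resolution and the
    # documented reverse-read 3'-end artifact).
    base_quality: int = 35
    reverse_ramp_length: int = 40
    reverse_ramp_min_quality: int = 20
    #: When set, substitution errors are redrawn until no two fall on adjacent
    #: molecule positions (across both mates), so isolated errors can never
    #: mimic the two-consecutive-mismatch breakpoint signature.
    forbid_adjacent_errors: bool = False

    def __post_init__(self) -> None:
        for name in ("edited_fraction", "insertion_probability", "substitution_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if 2 * self.read_length - self.amplicon_length < 15:
            raise ValueError(
                "read pairs cannot overlap by >= 15 bp: need "
                "2 * read_length - amplicon_length >= 15"
            )
        if not ANCHOR_LEN <= self.cut_site <= self.amplicon_length - ANCHOR_LEN:
            raise ValueError(
                f"cut_site must lie in [{ANCHOR_LEN}, amplicon_length - {ANCHOR_LEN}]"
            )
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if self.read_length < 15:
            raise ValueError("read_length must be >= 15")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Copy with fields replaced (convenience around dataclasses.replace)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrueOutcome:
    """Ground truth for one simulated molecule.

    The deletion interval is half-open in reference coordinates; an empty
    interval (start == end) means no deletion.  ``is_edited`` is false iff
    both the deletion and the insertion are empty.
    """

    molecule_id: str
    deletion_start: int
    deletion_end: int
    inserted_sequence: str
    is_edited: bool

    def __post_init__(self) -> None:
        if self.deletion_start > self.deletion_end:
            raise ValueError("deletion_start must be <= deletion_end")
        edited = self.deletion_end > self.deletion_start or bool(self.inserted_sequence)
        if edited != self.is_edited:
            raise ValueError("is_edited inconsistent with deletion/insertion content")

    @property
    def deletion_length(self) -> int:
        return self.deletion_end - self.deletion_start

    @property
    def length_difference(self) -> int:
        return len(self.inserted_sequence) - self.deletion_length


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _place_deletion(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw a deletion interval containing (or abutting) the cut site,
    uniformly over admissible placements, never invading a terminal anchor."""
    for _ in range(_PLACEMENT_RETRIES):
        length = config.deletion_length_distribution.draw(rng)
        start = int(rng.integers(config.cut_site - length, config.cut_site + 1))
        if start >= ANCHOR_LEN and start + length <= config.amplicon_length - ANCHOR_LEN:
            return start, start + length
    raise RuntimeError(
        f"could not place a deletion clear of the {ANCHOR_LEN} bp anchors "
        f"after {_PLACEMENT_RETRIES} attempts; deletion lengths too large "
        "for this amplicon"
    )


def simulate_molecules(
    config: SimulationConfig,
    reference: AmpliconReference,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, TrueOutcome]]:
    """Draw ``n_molecules`` molecules with ground truth.

    With probability ``edited_fraction`` a molecule carries a deletion
    spanning (or abutting) the cut site and, independently with
    ``insertion_probability``, a random insertion at the deletion junction.
    Unedited molecules equal the wild-type amplicon.
    """
    if len(reference) != config.amplicon_length:
        raise ValueError("reference length does not match config.amplicon_length")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    wt = reference.sequence
    out: list[tuple[str, TrueOutcome]] = []
    for i in range(config.n_molecules):
        mol_id = f"mol{i:06d}"
        if rng.random() < config.edited_fraction:
            start, end = _place_deletion(config, rng)
            ins = ""
            if rng.random() < config.insertion_probability:
                ins = _random_seq(rng, config.insertion_length_distribution.draw(rng))
            seq = wt[:start] + ins + wt[end:]
            truth = TrueOutcome(mol_id, start, end, ins, is_edited=True)
        else:
            seq = wt
            truth = TrueOutcome(mol_id, config.cut_site, config.cut_site, "", is_edited=False)
        out.append((seq, truth))
    return out


def _reverse_quality_profile(config: SimulationConfig) -> np.ndarray:
    """Phred profile of the reverse read: flat, with a linear decline to
    ``reverse_ramp_min_quality`` over the last ``reverse_ramp_length`` cycles."""
    qual = np.full(config.read_length, config.base_quality, dtype=np.int32)
    ramp = min(config.reverse_ramp_length, config.read_length)
    if ramp > 0 and config.reverse_ramp_min_quality < config.base_quality:
        qual[-ramp:] = np.linspace(
            config.base_quality, config.reverse_ramp_min_quality, ramp
        ).round().astype(np.int32)
    return qual


def _apply_errors(
    fwd: np.ndarray,
    rev: np.ndarray,
    mol_len: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Substitute bases in place at the configured per-base error rate.

    With ``forbid_adjacent_errors`` the error positions (mapped to molecule
    coordinates across both mates) are redrawn until pairwise non-adjacent.
    """
    rate = config.substitution_error_rate
    if rate == 0:
        return
    for _ in range(_PLACEMENT_RETRIES):
        f_pos = np.nonzero(rng.random(len(fwd)) < rate)[0]
        r_pos = np.nonzero(rng.random(len(rev)) < rate)[0]
        if not config.forbid_adjacent_errors:
            break
        # reverse-read index j reads molecule position mol_len - 1 - j
        mol_pos = np.concatenate([f_pos, mol_len - 1 - r_pos])
        mol_pos.sort()
        if len(mol_pos) == len(np.unique(mol_pos)) and (np.diff(mol_pos) > 1).all():
            break
    else:
        raise RuntimeError("could not draw non-adjacent error positions")
    for arr, pos in ((fwd, f_pos), (rev, r_pos)):
        for p in pos:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = choices[rng.integers(len(choices))]


def molecules_to_read_pairs(
    molecules: list[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    ids: list[str] | None = None,
) -> list[ReadPair]:
    """Sequence each molecule from both ends into a 2x``read_length`` pair.

    The forward read is the molecule's first ``read_length`` bases; the
    reverse read is the reverse complement of its last ``read_length`` bases
    (shorter molecules give fully overlapping pairs).  Substitution errors
    are applied independently per base; qualities follow the config's quality
    model.
    """
    from .stitch import reverse_complement  # local to avoid cycle at import time

    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if ids is None:
        ids = [f"mol{i:06d}" for i in range(len(molecules))]
    rev_qual_full = _reverse_quality_profile(config)
    pairs: list[ReadPair] = []
    for mol_id, mol in zip(ids, molecules):
        if len(mol) < 15:
            raise ValueError(f"{mol_id}: molecule shorter than 15 bp cannot be sequenced")
        rl = min(config.read_length, len(mol))
        fwd = np.frombuffer(mol[:rl].encode(), dtype=np.uint8).copy()
        rev = np.frombuffer(
            reverse_complement(mol[-rl:]).encode(), dtype=np.uint8
        ).copy()
        _apply_errors(fwd, rev, len(mol), config, rng)
        pairs.append(ReadPair(
            read_id=mol_id,
            forward_seq=fwd.tobytes().decode("ascii"),
            reverse_seq=rev.tobytes().decode("ascii"),
            forward_qual=tuple(int(q) for q in np.full(rl, config.base_quality)),
            reverse_qual=tuple(int(q) for q in rev_qual_full[:rl]),
        ))
    return pairs


def write_fastq(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    """Write mates as two Phred+33 FASTQ files with identical read ids."""
    def records(which_seq: str, which_qual: str):
        for p in pairs:
            rec = SeqRecord(Seq(getattr(p, which_seq)), id=p.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(getattr(p, which_qual))
            yield rec

    SeqIO.write(records("forward_seq", "forward_qual"), str(r1_path), "fastq")
    SeqIO.write(records("reverse_seq", "reverse_qual"), str(r2_path), "fastq")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Load mates back from two FASTQ files; ids must agree pairwise."""
    pairs = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq"), strict=True
    ):
        if rec1.id != rec2.id:
            raise ValueError(f"mate id mismatch: {rec1.id} vs {rec2.id}")
        pairs.append(ReadPair(
            read_id=rec1.id,
            forward_seq=str(rec1.seq),
            reverse_seq=str(rec2.seq),
            forward_qual=tuple(rec1.letter_annotations["phred_quality"]),
            reverse_qual=tuple(rec2.letter_annotations["phred_quality"]),
        ))
    return pairs


def write_truth_table(truths: list[TrueOutcome], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tdeletion_start\tdeletion_end\tinserted_sequence\tis_edited\n")
        for t in truths:
            fh.write(
                f"{t.molecule_id}\t{t.deletion_start}\t{t.deletion_end}\t"
                f"{t.inserted_sequence}\t{int(t.is_edited)}\n"
            )


@dataclass
class SimulatedSample:
    """One simulated sample: reference, molecules, ground truth and read pairs."""

    config: SimulationConfig
    reference: AmpliconReference
    molecules: list[str]
    truths: list[TrueOutcome]
    pairs: list[ReadPair]


def simulate_sample(
    config: SimulationConfig, reference: AmpliconReference | None = None
) -> SimulatedSample:
    """Run the whole generator under one seeded RNG stream.

    When no reference is given, a random amplicon is drawn first from the
    same stream, so a config fully determines the sample (byte-identical
    FASTQ across runs).
    """
    rng = np.random.default_rng(config.rng_seed)
    if reference is None:
        reference = random_amplicon(config.amplicon_length, config.cut_site, rng=rng)
    mols = simulate_molecules(config, reference, rng)
    molecules = [seq for seq, _ in mols]
    truths = [t for _, t in mols]
    pairs = molecules_to_read_pairs(
        molecules, config, rng, ids=[t.molecule_id for t in truths]
    )
    return SimulatedSample(config, reference, molecules, truths, pairs)
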