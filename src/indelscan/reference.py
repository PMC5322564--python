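"""Wild-type amplicon reference: the coordinate frame for all breakpoint calls.

An :class:`AmpliconReference` bundles the wild-type amplicon sequence with the
guide (protospacer) interval and the expected Cas9 cut site.  All coordinates
in the package are 0-based, intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class AmpliconReference:
    """Wild-type amplicon with cut-site and guide annotation.

    Parameters
    ----------
    name
        Amplicon identifier (FASTA record id).
    sequence
        Wild-type amplicon sequence over ``{A, C, G, T, N}``.
    cut_site
        0-based reference offset of the expected blunt cut; the nick falls
        between ``cut_site - 1`` and ``cut_site``.
    guide_interval
        Half-open interval of the sgRNA protospacer on the amplicon.
    """

    name: str
    sequence: str
    cut_site: int
    guide_interval: tuple[int, int]

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"non-nucleotide characters in reference: {sorted(bad)}")
        gs, ge = self.guide_interval
        if not (0 <= gs < ge <= len(self.sequence)):
            raise ValueError(f"guide interval {self.guide_interval} outside amplicon")
        if not (gs - 10 <= self.cut_site <= ge + 10):
            raise ValueError(
                f"cut site {self.cut_site} not within 10 bp of guide {self.guide_interval}"
            )
        if not (0 <= self.cut_site <= len(self.sequence)):
            raise ValueError("cut site outside amplicon")

    def __len__(self) -> int:
        return len(self.sequence)


def random_amplicon(
    length: int,
    cut_site: int,
    *,
    guide_length: int = 20,
    name: str = "amplicon",
    rng: np.random.Generator | int | None = None,
) -> AmpliconReference:
    """Draw a uniform-random wild-type amplicon around a given cut site.

    The guide is placed so the cut falls 3 bp inside its 3' end, the canonical
    blunt-cut position for SpCas9.
    """
    rng = np.random.default_rng(rng)
    if not (guide_length <= cut_site <= length - 3):
        raise ValueError("cut site too close to an amplicon end for the guide")
    seq = "".join(rng.choice(list("ACGT"), size=length))
    guide_start = cut_site - (guide_length - 3)
    return AmpliconReference(
        name=name,
        sequence=seq,
        cut_site=cut_site,
        guide_interval=(guide_start, guide_start + guide_length),
    )


def write_reference(ref: AmpliconReference, fasta_path: str | Path, annot_path: str | Path) -> None:
    """Write the amplicon as FASTA plus a BED-like annotation file.

    The annotation has two rows (0-based, half-open): the guide interval
    (name ``guide``) and the cut site as a 1-bp feature (name ``cut_site``).
    """
    SeqIO.write([SeqRecord(Seq(ref.sequence), id=ref.name, description="")], str(fasta_path), "fasta")
    with open(annot_path, "w") as fh:
        gs, ge = ref.guide_interval
        fh.write(f"{ref.name}\t{gs}\t{ge}\tguide\n")
        fh.write(f"{ref.name}\t{ref.cut_site}\t{ref.cut_site + 1}\tcut_site\n")


def read_reference(fasta_path: str | Path, annot_path: str | Path) -> AmpliconReference:
    """Load an :class:`AmpliconReference` from FASTA + BED-like annotation."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one reference record, found {len(records)}")
    rec = records[0]
    guide = cut = None
    with open(annot_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, feat = line.rstrip("\n").split("\t")[:4]
            if feat == "guide":
                guide = (int(start), int(end))
            elif feat == "cut_site":
                cut = int(start)
    if guide is None or cut is None:
        raise ValueError("annotation must contain 'guide' and 'cut_site' features")
    return AmpliconReference(
        name=rec.id, sequence=str(rec.seq).upper(), cut_site=cut, guide_interval=guide
    )
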