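"""End-to-end analysis: read pairs -> observed sequences -> calls -> profile."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .breakpoints import CallStatus, IndelCall, call_indel
from .reference import AmpliconReference
from .simulate import SimulatedSample, SimulationConfig, simulate_sample
from .spectrum import EditingProfile, build_profile, write_profile
from .stitch import ReadPair, StitchResult, stitch_pairs, write_observed_fasta, write_rejection_log


@dataclass
class SampleAnalysis:
    """All intermediate and final products of one sample's analysis."""

    sample_id: str
    stitch_result: StitchResult
    calls: list[IndelCall]
    profile: EditingProfile

    def status_counts(self) -> dict[str, int]:
        counts = dict.fromkeys([s.value for s in CallStatus], 0)
        for c in self.calls:
            counts[c.status.value] += 1
        return counts


def analyze_pairs(
    pairs: list[ReadPair],
    ref: AmpliconReference,
    sample_id: str = "sample",
    min_overlap: int = 15,
    max_overlap_mismatch_frac: float = 0.1,
    anchor_len: int = 40,
    max_anchor_mismatches: int = 0,
    n_top: int = 20,
    long_insertion_threshold: int = 25,
) -> SampleAnalysis:
    """Stitch, anchor-filter, breakpoint-call and aggregate one sample."""
    stitched = stitch_pairs(
        pairs, ref, min_overlap, max_overlap_mismatch_frac, anchor_len, max_anchor_mismatches
    )
    calls = [call_indel(obs, ref) for obs in stitched.observed]
    profile = build_profile(sample_id, calls, ref, n_top, long_insertion_threshold)
    return SampleAnalysis(sample_id, stitched, calls, profile)


def analyze_simulated(config: SimulationConfig, **kwargs) -> tuple[SimulatedSample, SampleAnalysis]:
    """Simulate a sample under ``config`` and run the full analysis on it."""
    sample = simulate_sample(config)
    analysis = analyze_pairs(sample.pairs, sample.reference, **kwargs)
    return sample, analysis


def calls_to_frame(calls: list[IndelCall]) -> pd.DataFrame:
    """Per-read call table (TSV-ready)."""
    return pd.DataFrame([
        {
            "read_id": c.read_id,
            "forward_breakpoint": c.forward_breakpoint,
            "reverse_breakpoint": c.reverse_breakpoint,
            "deletion_start": c.deletion_interval[0],
            "deletion_end": c.deletion_interval[1],
            "insertion": c.inserted_sequence,
            "status": c.status.value,
            "length_difference": c.length_difference,
        }
        for c in calls
    ])


def write_analysis(analysis: SampleAnalysis, outdir: str | Path) -> None:
    """Write stitched FASTA, rejection log, call TSV and the profile files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_observed_fasta(analysis.stitch_result.observed, outdir / "observed.fasta")
    write_rejection_log(analysis.stitch_result.rejections, outdir / "rejections.tsv")
    calls_to_frame(analysis.calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    write_profile(analysis.profile, outdir)
    report = {
        "sample_id": analysis.sample_id,
        "n_pairs": analysis.stitch_result.n_input,
        "n_stitched": len(analysis.stitch_result.observed),
        "n_rejected": len(analysis.stitch_result.rejections),
        "status_counts": analysis.status_counts(),
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
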