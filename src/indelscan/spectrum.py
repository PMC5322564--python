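"""Sample-level editing-outcome statistics.

Aggregates per-read indel calls into the quantities an editing experiment is
summarised by: indel efficiency (fraction of sequences whose length differs
from wild type), the per-position edited fraction along the amplicon,
deletion/insertion length histograms, a per-position deletion pileup, and a
ranked table of the most frequent editing patterns with per-sample counts.

Conventions
-----------
* ``unanchored`` calls never enter any statistic.
* ``artifact_crossed`` calls are excluded from per-position fractions,
  pileups and length histograms (their regions are unreliable) but are
  retained in the pattern table, with long insertions rendered as a
  bracketed length.
* A length-neutral call (equal deletion and insertion length) counts in both
  histograms and in the per-position fractions, but not in indel efficiency:
  its length does not differ from wild type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .breakpoints import CallStatus, IndelCall
from .reference import AmpliconReference

#: Statuses that enter per-position fractions, pileups and histograms.
_CLEAN = (CallStatus.WILDTYPE_LIKE, CallStatus.EDITED)


def _anchored(calls: Iterable[IndelCall]) -> list[IndelCall]:
    return [c for c in calls if c.status is not CallStatus.UNANCHORED]


def _clean(calls: Iterable[IndelCall]) -> list[IndelCall]:
    return [c for c in calls if c.status in _CLEAN]


def indel_efficiency(calls: Iterable[IndelCall]) -> float:
    """Percentage of anchor-passing sequences that differ in length from wild type.

    Length-neutral edited calls (insertion and deletion of the same length)
    are not counted: they do not differ in length.
    """
    kept = _anchored(calls)
    if not kept:
        raise ValueError("no anchor-passing calls")
    n_diff = sum(1 for c in kept if c.length_difference != 0)
    return 100.0 * n_diff / len(kept)


def per_position_edit_fraction(
    calls: Iterable[IndelCall],
    ref: AmpliconReference,
    insertion_marks: str = "both",
) -> np.ndarray:
    """Fraction of sequences in which each reference position was edited.

    A position counts as edited when a deletion spans it or when an insertion
    is adjacent to it.  Adjacency marks the two reference bases flanking the
    insertion junction ``f`` (positions ``f - 1`` and ``f``); set
    ``insertion_marks`` to ``"left"`` or ``"right"`` for a one-sided rule.
    Crossed-artifact calls are excluded.
    """
    kept = _clean(calls)
    if not kept:
        raise ValueError("no usable calls")
    counts = np.zeros(len(ref), dtype=np.int64)
    for c in kept:
        start, end = c.deletion_interval
        if end > start:
            counts[start:end] += 1
        if c.inserted_sequence:
            f = c.forward_breakpoint
            marks = {"both": (f - 1, f), "left": (f - 1,), "right": (f,)}[insertion_marks]
            for p in marks:
                if 0 <= p < len(ref):
                    counts[p] += 1
    return counts / len(kept)


def deletion_pileup(calls: Iterable[IndelCall], ref: AmpliconReference) -> np.ndarray:
    """Per-position count of calls whose deletion spans the position."""
    counts = np.zeros(len(ref), dtype=np.int64)
    for c in _clean(calls):
        start, end = c.deletion_interval
        if end > start:
            counts[start:end] += 1
    return counts


def _length_hist(lengths: list[int], n: int) -> dict[int, float]:
    hist: dict[int, float] = {}
    for length in lengths:
        hist[length] = hist.get(length, 0) + 1
    hist = {k: v / n for k, v in sorted(hist.items())}
    hist[0] = 1.0 - sum(frac for length, frac in hist.items() if length > 0)
    return dict(sorted(hist.items()))


def deletion_length_hist(calls: Iterable[IndelCall]) -> dict[int, float]:
    """Fraction of sequences having a deletion of each length (0 = none).

    A call carrying both a deletion and an insertion contributes to both this
    histogram and :func:`insertion_length_hist`.
    """
    kept = _clean(calls)
    if not kept:
        raise ValueError("no usable calls")
    return _length_hist([c.deletion_length for c in kept if c.deletion_length > 0], len(kept))


def insertion_length_hist(calls: Iterable[IndelCall]) -> dict[int, float]:
    """Fraction of sequences having an insertion of each length (0 = none)."""
    kept = _clean(calls)
    if not kept:
        raise ValueError("no usable calls")
    return _length_hist([c.insertion_length for c in kept if c.insertion_length > 0], len(kept))


def _render_alignment(
    ref: AmpliconReference,
    deletion: tuple[int, int] | None,
    insertion_rendered: str,
    window: int = 20,
) -> str:
    """One alignment line: reference up to f, the insertion at the junction,
    dashes across the deletion, then reference from the reverse breakpoint."""
    if deletion is None:
        gs, ge = ref.guide_interval
        ws, we = max(0, gs - window), min(len(ref), ge + window)
        return ref.sequence[ws:we]
    f, r = deletion
    ws = max(0, min(f, r) - window)
    we = min(len(ref), max(f, r) + window)
    ins = f"({insertion_rendered})" if insertion_rendered else ""
    dashes = "-" * max(0, r - f)
    return ref.sequence[ws:f] + ins + dashes + ref.sequence[max(f, r):we]


def top_patterns(
    calls_by_sample: Mapping[str, Iterable[IndelCall]],
    ref: AmpliconReference,
    n_top: int = 20,
    long_insertion_threshold: int = 25,
) -> pd.DataFrame:
    """Rank editing patterns by total count across samples.

    A pattern is a (deletion interval, inserted sequence) combination;
    wild-type-like calls form the all-empty pattern.  Insertions longer than
    ``long_insertion_threshold`` are rendered as ``[L]`` (their length in
    brackets) instead of the literal sequence — these are typically
    crossed-breakpoint artifacts.  Ties are broken by smaller deletion start,
    then lexicographic insertion.  Returns a DataFrame with one row per
    pattern: deletion coordinates, rendered insertion, per-sample counts,
    total, and a rendered alignment line.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    samples = list(calls_by_sample)
    counts: dict[tuple, dict[str, int]] = {}
    for sample, calls in calls_by_sample.items():
        for c in _anchored(calls):
            if c.status is CallStatus.WILDTYPE_LIKE:
                key = (None, None, "")
            else:
                key = (*c.deletion_interval, c.inserted_sequence)
            counts.setdefault(key, dict.fromkeys(samples, 0))[sample] += 1

    def sort_key(item):
        (del_start, _del_end, ins), per_sample = item
        total = sum(per_sample.values())
        start = del_start if del_start is not None else -1
        return (-total, start, ins)

    rows = []
    for (del_start, del_end, ins), per_sample in sorted(counts.items(), key=sort_key)[:n_top]:
        long_ins = len(ins) > long_insertion_threshold
        rendered_ins = f"[{len(ins)}]" if long_ins else ins
        deletion = None if del_start is None else (del_start, del_end)
        rows.append({
            "deletion_start": del_start,
            "deletion_end": del_end,
            "insertion": rendered_ins,
            **{f"count_{s}": per_sample[s] for s in samples},
            "total": sum(per_sample.values()),
            "alignment": _render_alignment(ref, deletion, rendered_ins),
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        # keep coordinates integral; the wild-type pattern has none
        table["deletion_start"] = table["deletion_start"].astype("Int64")
        table["deletion_end"] = table["deletion_end"].astype("Int64")
    return table


@dataclass
class EditingProfile:
    """Per-sample aggregation of indel calls."""

    sample_id: str
    n_sequences: int
    indel_efficiency: float
    per_position_edit_fraction: np.ndarray
    deletion_length_hist: dict[int, float]
    insertion_length_hist: dict[int, float]
    pattern_table: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def summary(self) -> dict:
        """JSON-serialisable run summary."""
        return {
            "sample_id": self.sample_id,
            "n_sequences": self.n_sequences,
            "indel_efficiency_percent": self.indel_efficiency,
            "max_per_position_edit_fraction": float(self.per_position_edit_fraction.max()),
            "modal_deletion_length": max(
                self.deletion_length_hist, key=lambda k: (k > 0) * self.deletion_length_hist[k],
                default=0,
            ),
        }


def build_profile(
    sample_id: str,
    calls: list[IndelCall],
    ref: AmpliconReference,
    n_top: int = 20,
    long_insertion_threshold: int = 25,
    insertion_marks: str = "both",
) -> EditingProfile:
    """Aggregate one sample's calls into an :class:`EditingProfile`."""
    kept = _anchored(calls)
    if not kept:
        raise ValueError(f"{sample_id}: no anchor-passing calls")
    return EditingProfile(
        sample_id=sample_id,
        n_sequences=len(kept),
        indel_efficiency=indel_efficiency(kept),
        per_position_edit_fraction=per_position_edit_fraction(kept, ref, insertion_marks),
        deletion_length_hist=deletion_length_hist(kept),
        insertion_length_hist=insertion_length_hist(kept),
        pattern_table=top_patterns({sample_id: kept}, ref, n_top, long_insertion_threshold),
    )


def write_profile(profile: EditingProfile, outdir: str | Path) -> None:
    """Write per-position fractions, histograms, pattern table and summary."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "position": np.arange(len(profile.per_position_edit_fraction)),
        "edit_fraction": profile.per_position_edit_fraction,
    }).to_csv(outdir / "per_position_edit_fraction.tsv", sep="\t", index=False)
    for name, hist in (
        ("deletion_length_hist", profile.deletion_length_hist),
        ("insertion_length_hist", profile.insertion_length_hist),
    ):
        pd.DataFrame({"length": list(hist), "fraction": list(hist.values())}).to_csv(
            outdir / f"{name}.tsv", sep="\t", index=False
        )
    profile.pattern_table.to_csv(outdir / "pattern_table.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(profile.summary(), fh, indent=2)
        fh.write("\n")


def plot_profile(profile: EditingProfile, path: str | Path) -> None:
    """Three-panel figure: per-position edited fraction and both length histograms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3))
    axes[0].plot(profile.per_position_edit_fraction)
    axes[0].set(xlabel="reference position", ylabel="edited fraction",
                title=profile.sample_id)
    for ax, hist, label in (
        (axes[1], profile.deletion_length_hist, "deletion length (bp)"),
        (axes[2], profile.insertion_length_hist, "insertion length (bp)"),
    ):
        lengths = [k for k in hist if k > 0]
        ax.bar(lengths, [hist[k] for k in lengths])
        ax.set(xlabel=label, ylabel="fraction of sequences")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
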