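# Methods

## The editing-outcome model

An amplicon sequencing experiment observes, for each sequenced molecule, one
repaired allele of a Cas9-cut locus. The package models each observed
sequence as wild type with at most one contiguous deletion and at most one
insertion at the deletion junction — the natural data model for
non-homologous end joining at a single cut, and the one implied by a
two-breakpoint representation. Every coordinate is 0-based; intervals are
half-open.

## Stitching and anchor filtering

Mates are merged at the overlap of their 3′ ends. Among candidate overlap
lengths `L ≥ min_overlap` (default 15 bp), the stitcher keeps the one with
the fewest mismatches, breaking ties towards the longest overlap, and
rejects the pair (`no_overlap`) if no candidate has mismatch fraction
≤ `max_overlap_mismatch_frac` (default 0.1). Exact-match stitching would
preferentially discard error-bearing molecules, biasing the spectrum, so
mismatches are tolerated and each discordant overlap base is resolved to
the mate with the higher Phred score (ties keep the forward base, which is
usually the higher-quality cycle). `N` counts as a mismatch everywhere,
including against another `N`.

The anchor filter requires the stitched sequence's first and last
`anchor_len` bases (default 40) to match the reference's respective ends
with at most `max_anchor_mismatches` mismatches (default 0, i.e. exact).
It is applied post-stitching; for full-length mates this is equivalent to a
per-mate 5′ check. The exact default is deliberately strict — a single
terminal sequencing error discards the sequence — and the budget is exposed
because analyses of error-bearing data (including our own robustness runs)
legitimately admit a few isolated anchor mismatches.

## Breakpoint calling

The caller is ungapped by construction: the observed sequence is compared
positionally to the reference from the left (left-aligned) and from the
right (right-aligned), and each scan stops at the first occurrence of two
consecutive mismatches. Requiring two consecutive mismatches makes the scan
robust to isolated substitution errors: a lone mismatch can never open a
breakpoint. Scanning stops at the shorter of the two lengths; a scan that
finds no double mismatch returns no breakpoint.

Statuses:

* both scans silent → `wildtype_like`;
* exactly one scan fires → `wildtype_like` with a logged warning (a single
  disrupted end defines no region);
* both fire, breakpoints ordered → `edited`, with deletion `ref[f:r]` and
  insertion `obs[f:r_obs]`;
* breakpoints cross in either coordinate system → `artifact_crossed`.

Crossing deserves emphasis because it is common, not exotic. After a true
deletion, the shifted flank matches the reference at ~1/4 of positions by
chance, so each scan independently overshoots the true breakpoint with
probability 1 − (3/4)² ≈ 0.44 per side; whenever the overshoots meet, the
call crosses. Crossed calls are retained and flagged rather than discarded:
their actual length change (`len(obs) − len(ref)`) is still exact and feeds
the efficiency statistic, but their region coordinates are unreliable and
are excluded from per-position fractions, pileups and length histograms.
They remain in the pattern table (the long-insertion variants rendered with
a bracketed length), since collapsing them would hide a known artifact of
this algorithm family. Deletion placements are not normalised across
homology shifts — two calls deleting the same bases from a repeat may carry
shifted coordinates — so recovery guarantees are stated up to
shift-equivalence (equal length change, replay of the called regions onto
the reference reproducing the molecule up to isolated mismatches).

## Spectrum statistics

All statistics exclude `unanchored` sequences. Indel efficiency is the
percentage of anchor-passing sequences whose length differs from wild type;
a length-neutral edit (deletion and insertion of equal length) is edited
but invisible to this statistic, exactly as a length-based readout implies.
The per-position edited fraction counts, at each reference position, the
non-crossed calls whose deletion spans it or whose insertion is adjacent to
it; "adjacent" marks the two bases flanking the insertion junction
(configurable to one-sided). The denominator is all anchor-passing,
non-crossed sequences — wild-type-like sequences dilute the fraction, which
matches reading "fraction of sequences" literally. Length histograms are
fractions of the same denominator; a call with both a deletion and an
insertion contributes to both histograms, and the mass at length 0 is the
complement of the edited mass. Pattern ranking is by total count across
samples, ties broken by smaller deletion start then lexicographic insertion;
insertions longer than 25 bp (display choice) are shown as `[L]`.

## The simulator as study conditions

The generator emulates the sequenced experiment: a 200 bp amplicon (any
longer region is informative only through its amplified window; 200 bp
gives the canonical 100 bp mate overlap at 2×150 bp), cut site at position
100 with a 20 bp guide ending 3 bp past the cut (the blunt SpCas9 geometry),
10,000 molecules per sample, and 60% edited molecules. Deletion lengths
default to geometric(0.35) (mean ≈ 2.9 bp, short deletions dominating, as
NHEJ spectra show); each deletion is placed uniformly among positions
containing or abutting the cut site, redrawn (capped) if it would invade a
40 bp terminal anchor. Insertions occur in 20% of edited molecules, at the
deletion junction only, with geometric(0.6) lengths. Sequencing errors are
uniform substitutions at 10⁻³ per base; qualities are flat Phred 35 with a
linear decline to 20 over the reverse read's last 40 cycles, which exercises
the stitcher's quality resolution and the documented reverse-read artifact.
A `forbid_adjacent_errors` switch redraws error positions until pairwise
non-adjacent across both mates — used to verify that isolated errors can
never fake an edit.

What the simulator does **not** model: PCR chimeras and amplification bias,
adapter read-through, indel sequencing errors (the caller is ungapped and
its error tolerance is the two-mismatch rule, so read-level indels are out
of model), context-dependent error rates, and microhomology-mediated
outcome biases. Passing tests therefore demonstrate correctness of the
algorithmics on the stated molecule model, not robustness to every failure
mode of real libraries.

## Numerical and engineering choices

Mismatch counting and the scans operate on byte arrays (numpy), keeping a
10,000-pair sample under ~10 s on one CPU; FASTQ/FASTA I/O goes through
Biopython. All randomness flows from a single `numpy` generator seeded by
the config, so a configuration determines its FASTQ bytes exactly. Test and
verification runs use 10,000 molecules (matching the per-sample depth
default) for rate recovery and robustness checks, and smaller samples
(150–800) where only structural invariants are asserted. Degenerate inputs
fail loudly: empty sequences, molecules under 15 bp, all-zero band
intensities, non-positive diameters and invalid configurations all raise
with specific messages rather than propagating nonsense.

## Known limitations

* Crossed-scan calls lose their region coordinates; only their length
  change is trusted. A gapped realignment of flagged calls would recover
  them but is deliberately out of scope (the method is defined ungapped).
* The per-position edited fraction's peak can shift a few bases from the
  cut site when local sequence context sends many calls into the crossed
  class asymmetrically; the effect is visible across simulator seeds.
* One-sided breakpoints are classified wild-type-like with a warning; in
  pathological references (e.g. exactly periodic sequence) a real length
  change can therefore go uncounted. Random and natural amplicons make this
  vanishingly rare.
* The SURVEYOR formula assumes complete heteroduplex cleavage and
  independent allele pairing; it is a densitometry estimate, not a
  sequencing-grade measurement.
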