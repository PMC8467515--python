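# Methods

## The doRNA family model

The package models a family of rRNA-derived fragments anchored on the
5′ end of mature 5.8S rRNA. The family is defined entirely by sequence
identity to an anchored reference window:

- the 12-nt **core** equals mature 5.8S positions 2–13;
- the 13-nt **+1 variant** adds the first mature base (position 1); it
  is reported as `C-doRNA` when that base is a cytosine (human, mouse)
  and as `plus1_variant` otherwise (fly carries a 5′ adenine), with the
  5′ base recorded on the call either way;
- members of 14–18 nt are successive single-base 5′ extensions into
  ITS1 (`extended_variant`, offsets −2…−6);
- the 3′ end is invariant: every member terminates on the G at 5.8S
  position 13 (G13), immediately 5′ of the 2′-O-methylated U14. Any
  sequence whose match continues 3′ of position 13 is `non_doRNA`.

Membership is decided by comparing a read to the unique reference
window of its length ending at position 13 — not by genomic alignment.
rDNA operons are present in hundreds of near-identical copies, so a
locus-based definition would be ill-posed, whereas the anchored-window
definition is exact, deterministic and testable. Anchor derivation
validates G13 and U14 and fails with distinct error codes when a record
lacks a 5.8S feature, has insufficient ITS1 context (the 18-nt ceiling
needs 5 upstream bases), or violates the base constraints.

With `allow_mismatches=1`, one internal substitution is tolerated
(accommodating rDNA copy heterogeneity) but the 3′-terminal G may never
be substituted; the default is strict identity. Loosening the tolerance
can only add family members, never remove them (tested property).

## Trimming and collapsing

Reads are insert + 3′ adapter. The trimmer finds the leftmost exact
occurrence of the adapter's first `min_overlap` (default 8) bases and
then checks the full aligned adapter span at ≤ `max_mismatch_rate`
(default 0.1) mismatches; failing candidates are skipped and the search
continues rightward. Inserts outside 8–30 nt, with > 1 ambiguous base,
or with no adapter are rejected with machine-readable reasons. Adapter
sequences are user-overridable; the default is the Illumina TruSeq
small-RNA 3′ adapter. All sequences are canonicalized to DNA letters
(U→T) on ingest.

Identical trimmed inserts collapse to one `UniqueRead` (count desc,
lexicographic tie-break — reproducible output ordering). RPM uses the
trimmed in-window total as denominator by default (recorded in output
metadata); the sum of RPM equals 10⁶ exactly when the denominator is
the library total.

Dominance fractions are computed on raw counts within a length class.
The combined share of the top 12-mer plus top 13-mer is reported under
both plausible denominators (the 12+13 nt class union and the whole
8–30 nt window), since the choice materially changes the number.

## Mapping ultra-short queries

A 12-nt query is far below the reliable seeded-alignment range of
heuristic tools, and at these lengths only complete enumeration of
perfect (or 1-mismatch) hits is meaningful. At 0 mismatches an 8-mer
seed index over both strands answers queries; at ≥ 1 mismatches a
direct Hamming scan over each record is used instead, because a fixed
8-mer pigeonhole cannot cover queries shorter than 16 nt, and the
reference sets in scope (rRNA units, a few kb) make the scan trivially
cheap. Alignments are ungapped, so every hit covers the whole query;
identity is `100·(L−mm)/L`. Hits carry overlapping feature names and a
position report relative to the 5.8S 5′ end (position 1 = first 5.8S
base; upstream ITS1 positions negative, no zero). Equivalence with a
brute-force both-strand scan is asserted over randomized
(reference, query) pairs in the test suite.

## Ratio estimation and comparison

The C-doRNA/doRNA ratio is `c/d` from the ladder table. Uncertainty is
a percentile bootstrap: `(c, d)` are resampled jointly from a
multinomial with the observed proportions (n = c + d, default 2000
resamples, seeded), and the CI is the empirical 2.5–97.5% band of the
resampled ratios. The bootstrap is distribution-free and its coverage
is directly checkable by simulation: over 200 seeded count-level
replicates at 10⁵ family reads the 95% CI covers the planted ratio
93–97% of the time (tested).

`compare_ratios` tests log(ratio_a) − log(ratio_b) = 0 by the same
bootstrap (two-sided p from the resampled sign fractions, floored at
1/n_bootstrap); rare zero denominators in resamples are floored at 0.5
before the log. A plain two-sample t-test on per-replicate ratios is
provided separately as plumbing for replicate-level (culture-to-
culture) comparisons; neither procedure is claimed to be anything more
than what it is.

## Partner filtering and quantitation closed forms

Pull-down candidates are kept for a bait iff peptide count is strictly
greater than 3 (configurable) **and** the protein shows zero peptides
in the negative-RNA control — "absent" is read literally as zero, not
sub-threshold. The Venn partition is exact set algebra; disjointness
and the union identity are asserted on randomized inputs.

qPCR standard curves are ordinary least squares of Cq on log10(copies)
(scipy), requiring ≥ 3 points spanning ≥ 2 log10; efficiency is
`10^(−1/slope) − 1` (slope −3.3219 ⇔ 100%). Copy numbers invert the
fitted line exactly. A ΔCq mode (`relative_quantity`) supports
reference-gene (e.g. U6) normalization; absolute copies are the default
for ratio work. Compartment fractions, reporter normalization
(`100·(F/R)/(F₀/R₀)`) and wound closure
(`unrecovered = 100·area_t/area_t0`) are the stated closed forms, with
domain checks (positive denominators; areas clamped at the initial
area with a warning).

## Synthetic data: what it emulates, what it does not

`simulate_library` plants, per library: family reads split
multinomially over the ladder (core weight 1, +1 variant weight equal
to the species ratio — presets human 5.0, mouse 1.0, fly 0.25 — and a
decaying extension ladder, default weights 0.05/0.03/0.02/0.012/0.006
for offsets −2…−6); background miRNA-like 19–24-mers with Zipf-decaying
abundances; and uniform random degradation fragments of the reference.
Defaults: 50% family reads, 20% degradation, 30% miRNA background,
10⁵ reads, substitution error rate 0.001. These composition defaults
sit inside the observed range for animal samples (the 12+13 nt classes
carrying 22–74% of the window; a single 12-mer ≥ 70% of its class) and
are fixed once; the truth table records pre-error counts and sums to
`n_reads` exactly, so every downstream stage can be checked for exact
recovery at error rate 0.

Deliberate simplifications: substitution errors only (no indels —
inserts are ≤ 30 nt and classification is exact-match), uniform quality
strings, no instrument-specific error profile, no 5′-adapter artifacts,
single-sample libraries. Background sequences are re-drawn if they
contain the adapter seed or classify into the family, keeping planted
categories unambiguous; consequently passing recovery tests demonstrate
correctness of the bookkeeping and statistics, not robustness to every
real-library artifact.

The bundled reference is a 600-nt synthetic 45S-like precursor
(5′ETS–18S–ITS1–5.8S–ITS2–28S). The 5.8S 5′-terminal 20 bases are fixed
to the published human/mouse start `CGACTCTTAGCGGTGGATCA` (making core,
variant and the G13/U14 checks exact); all other bases are seeded-random
filler, re-drawn until the record contains no adapter seed and no
second occurrence of the core. The fly record is a synthetic stand-in
satisfying the observed constraints (5′ A on the 13-mer, core differing
from human at 2 positions, G13/U14); no test asserts the literal fly
sequence. Real records are drop-in replacements.

`simulate_family_counts` exposes the count-level multinomial sampler
that `simulate_library` uses to plant family reads; replication studies
(CI coverage over hundreds of seeds) run at this level, which is the
identical statistical process without the string generation.

## Problem sizes and determinism

The test suite and acceptance script run end-to-end pipelines at
2×10⁵ reads per species preset (≈10⁵ family reads), 200-replicate
coverage and unbiasedness studies at the count level, and 1 000-pair
mapper/oracle comparisons; these sizes give sub-percent sampling error
on the ratio while keeping a full run in seconds on one CPU. Every
stochastic component takes an explicit seed (numpy `default_rng`);
identical configuration + seed gives byte-identical FASTQ, TSV and JSON
outputs, and the pipeline manifest records sha256 checksums of all
inputs and outputs to make reruns verifiable.

## Known limitations

- Classification is reference-exact; a genuinely polymorphic 5.8S
  start (beyond one substitution) would require a per-sample anchor.
- The bootstrap CI is percentile-based; at very small family counts
  (d ≲ 50) its coverage degrades as for any percentile bootstrap.
- The mapper is ungapped by design; it does not aim at genome-scale
  references and holds oriented copies of each record in memory.
- Compartment fractions treat dot counts and copy numbers identically;
  units are the caller's responsibility (recorded in metadata only).
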