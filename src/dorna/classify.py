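"""doRNA family classification and the C-doRNA/doRNA ratio statistic.

The doRNA family is anchored on the 5' end of 5.8S rRNA: the 12-nt core
(doRNA) spans mature 5.8S positions 2-13, its 13-nt variant adds the
first mature base (a 5' cytosine in human and mouse, hence C-doRNA),
and longer members are single-nucleotide 5' extensions of the same
sequence, walking back into ITS1 once they exceed 13 nt.  The 3' end is
invariant: every family member terminates on the G at 5.8S position 13,
immediately upstream of the 2'-O-methylated U14.  A sequence extended on
its 3' side is never a family member.

Membership is decided by sequence identity against the anchored
reference window ending at position 13 - not by genomic alignment -
because the family's defining evidence is exact matching and the rDNA
loci are multi-copy.

The relative abundance of the 13-nt and 12-nt forms is summarized as the
C-doRNA/doRNA count ratio, with a percentile-bootstrap confidence
interval over multinomial resampling of the two counts (species-stable;
roughly 5 in human, 1 in mouse, 0.25 in fly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mapper import ReferenceFeatureSet, canonicalize
from .sequence_io import InputError, UniqueRead

CATEGORY_DORNA = "doRNA"
CATEGORY_C_DORNA = "C-doRNA"
CATEGORY_PLUS1 = "plus1_variant"
CATEGORY_EXTENDED = "extended_variant"
CATEGORY_NON = "non_doRNA"

CORE_LENGTH = 12
DEFAULT_MAX_TOTAL_LENGTH = 18


class AnchorError(ValueError):
    """Anchor derivation failure with a machine-readable code."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class DoRNAAnchor:
    """The reference window the doRNA family aligns to.

    core_sequence: 5.8S positions 2..13 (the 12-nt doRNA).
    c_variant_sequence: positions 1..13 (the 13-nt +1 variant).
    upstream_context: ITS1 bases immediately 5' of the mature 5.8S
    start, long enough to spell out every allowed 5' extension.
    three_prime_ref_pos: record coordinate (0-based) of the invariant
    3'-terminal base, i.e. 5.8S position 13.
    methylation_note: True when 5.8S position 14 is U - the ribose-
    methylation site bordering the family's 3' end.
    """

    accession: str
    core_sequence: str
    c_variant_sequence: str
    three_prime_ref_pos: int
    upstream_context: str
    max_total_length: int = DEFAULT_MAX_TOTAL_LENGTH
    methylation_note: bool = True

    def __post_init__(self) -> None:
        if len(self.core_sequence) != CORE_LENGTH:
            raise AnchorError("anchor_validation", "core must be 12 nt")
        if not self.c_variant_sequence.endswith(self.core_sequence) or len(self.c_variant_sequence) != 13:
            raise AnchorError("anchor_validation", "13-nt variant must be 1 extra 5' base + core")
        if len(self.upstream_context) < self.max_total_length - 13:
            raise AnchorError("insufficient_upstream",
                              f"need >= {self.max_total_length - 13} nt of upstream (ITS1) context")

    @property
    def window_sequence(self) -> str:
        """Longest allowed family sequence: ends at 5.8S position 13."""
        full = self.upstream_context + self.c_variant_sequence
        return full[-self.max_total_length:]

    def expected_sequence(self, length: int) -> str:
        """The unique family sequence of a given total length (12..max)."""
        if not CORE_LENGTH <= length <= self.max_total_length:
            raise InputError(f"no family sequence of length {length}")
        return self.window_sequence[-length:]


def derive_anchor(refs: ReferenceFeatureSet, accession: str,
                  max_total_length: int = DEFAULT_MAX_TOTAL_LENGTH) -> DoRNAAnchor:
    """Extract and validate the doRNA anchor from a 5.8S-bearing record.

    Raises AnchorError with codes "missing_58S_feature",
    "insufficient_upstream" or "anchor_validation" (position 13 must be
    G; position 14 must be U/T).
    """
    if accession not in refs.records:
        raise InputError(f"unknown accession {accession!r}")
    feat = refs.feature(accession, "5.8S")
    if feat is None:
        raise AnchorError("missing_58S_feature", f"record {accession} lacks a 5.8S feature")
    seq = refs.records[accession]
    needed_upstream = max_total_length - 13
    if feat.start < needed_upstream:
        raise AnchorError("insufficient_upstream",
                          f"record {accession} has only {feat.start} nt upstream of 5.8S; "
                          f"{needed_upstream} required")
    if feat.end - feat.start < 14:
        raise AnchorError("anchor_validation", "5.8S feature shorter than 14 nt")
    prefix = seq[feat.start : feat.start + 14]
    if prefix[12] != "G":
        raise AnchorError("anchor_validation",
                          f"5.8S position 13 is {prefix[12]}, expected the invariant G")
    if prefix[13] != "T":
        raise AnchorError("anchor_validation",
                          f"5.8S position 14 is {prefix[13]}, expected U (2'-O-methylation site)")
    return DoRNAAnchor(
        accession=accession,
        core_sequence=prefix[1:13],
        c_variant_sequence=prefix[:13],
        three_prime_ref_pos=feat.start + 12,
        upstream_context=seq[feat.start - needed_upstream : feat.start],
        max_total_length=max_total_length,
        methylation_note=True,
    )


@dataclass(frozen=True)
class DoRNACall:
    """Classification of one sequence against the anchor.

    five_prime_offset is 0 for the core, -1 for the 13-nt variant and
    -k for a k-nt further 5' extension; family members always end at
    5.8S position 13.  five_prime_base records the added base of
    offset -1 calls (C in human/mouse; A in fly).
    """

    sequence: str
    category: str
    five_prime_offset: int
    mismatches: int = 0
    five_prime_base: str | None = None


def classify_read(sequence: str, anchor: DoRNAAnchor, allow_mismatches: int = 0) -> DoRNACall:
    """Assign a sequence to the doRNA ladder or to non_doRNA.

    Strict mode (default) requires identity with the reference window
    ending at 5.8S position 13.  With allow_mismatches=1, one internal
    substitution is tolerated (accommodating rDNA copy heterogeneity)
    but the 3'-terminal base must still be the invariant G.
    """
    seq = canonicalize(sequence)
    if not 8 <= len(seq) <= 30:
        raise InputError(f"sequence length {len(seq)} outside [8, 30]")
    length = len(seq)
    if CORE_LENGTH <= length <= anchor.max_total_length:
        expected = anchor.expected_sequence(length)
        if allow_mismatches == 0:
            mism = 0 if seq == expected else None
        else:
            hamming = sum(a != b for a, b in zip(seq, expected))
            # 3' terminal base (the invariant G) may not be substituted
            mism = hamming if hamming <= allow_mismatches and seq[-1] == expected[-1] else None
        if mism is not None:
            offset = -(length - CORE_LENGTH)
            if offset == 0:
                return DoRNACall(seq, CATEGORY_DORNA, 0, mism)
            if offset == -1:
                category = CATEGORY_C_DORNA if seq[0] == "C" else CATEGORY_PLUS1
                return DoRNACall(seq, category, -1, mism, five_prime_base=seq[0])
            return DoRNACall(seq, CATEGORY_EXTENDED, offset, mism)
    return DoRNACall(seq, CATEGORY_NON, 0, 0)


def tabulate_ladder(uniques: Sequence[UniqueRead], anchor: DoRNAAnchor,
                    allow_mismatches: int = 0) -> pd.DataFrame:
    """Tabulate the 5'-extension ladder of a collapsed library.

    One row per family offset 0..-(max_total_length-12) plus one
    aggregate non_doRNA row; counts conserve the library total.
    """
    offsets = range(0, -(anchor.max_total_length - CORE_LENGTH) - 1, -1)
    rows = {off: {"category": None, "offset": off, "length": CORE_LENGTH - off,
                  "sequence": anchor.expected_sequence(CORE_LENGTH - off),
                  "count": 0, "rpm": 0.0}
            for off in offsets}
    non = {"category": CATEGORY_NON, "offset": pd.NA, "length": pd.NA,
           "sequence": pd.NA, "count": 0, "rpm": 0.0}
    for u in uniques:
        call = classify_read(u.sequence, anchor, allow_mismatches=allow_mismatches)
        if call.category == CATEGORY_NON:
            non["count"] += u.count
            non["rpm"] += u.rpm or 0.0
        else:
            row = rows[call.five_prime_offset]
            row["count"] += u.count
            row["rpm"] += u.rpm or 0.0
            row["category"] = call.category
    for off, row in rows.items():
        if row["category"] is None:
            # name the row by what a read at this offset would be called
            row["category"] = classify_read(row["sequence"], anchor).category
    table = pd.DataFrame(list(rows.values()) + [non])
    return table.reset_index(drop=True)


@dataclass(frozen=True)
class RatioEstimate:
    """C-doRNA/doRNA count ratio with a percentile-bootstrap CI."""

    c_count: int
    d_count: int
    ratio: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int
    ci_level: float = 0.95


def estimate_ratio(c_count: int, d_count: int, n_bootstrap: int = 2000,
                   seed: int = 0, ci_level: float = 0.95) -> RatioEstimate:
    """Point estimate c/d with a seeded percentile-bootstrap CI.

    The two counts are resampled jointly from a multinomial with their
    observed proportions; the CI is the empirical (alpha/2, 1-alpha/2)
    quantile band of the resampled ratios.
    """
    if c_count < 0 or d_count < 0:
        raise InputError("counts must be non-negative")
    if d_count == 0:
        raise ZeroDivisionError("doRNA count is zero; ratio undefined")
    ratio = c_count / d_count
    rng = np.random.default_rng(seed)
    n = c_count + d_count
    draws = rng.multinomial(n, [c_count / n, d_count / n], size=n_bootstrap).astype(float)
    denom = np.maximum(draws[:, 1], 0.5)  # guard rare all-c resamples
    ratios = draws[:, 0] / denom
    alpha = 1.0 - ci_level
    ci_low, ci_high = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    return RatioEstimate(c_count, d_count, ratio, float(ci_low), float(ci_high),
                         n_bootstrap, seed, ci_level)


@dataclass(frozen=True)
class RatioComparison:
    """Bootstrap comparison of two ratio estimates on the log scale."""

    log_ratio_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_bootstrap: int
    seed: int


def _bootstrap_log_ratios(est: RatioEstimate, rng: np.random.Generator, n_bootstrap: int) -> np.ndarray:
    n = est.c_count + est.d_count
    draws = rng.multinomial(n, [est.c_count / n, est.d_count / n], size=n_bootstrap).astype(float)
    return np.log(np.maximum(draws[:, 0], 0.5)) - np.log(np.maximum(draws[:, 1], 0.5))


def compare_ratios(sample_a: RatioEstimate, sample_b: RatioEstimate,
                   n_bootstrap: int = 2000, seed: int = 0) -> RatioComparison:
    """Two-sided bootstrap test of log(ratio_a) - log(ratio_b) == 0."""
    if sample_a.d_count == 0 or sample_b.d_count == 0:
        raise ZeroDivisionError("zero doRNA denominator")
    rng = np.random.default_rng(seed)
    delta = (_bootstrap_log_ratios(sample_a, rng, n_bootstrap)
             - _bootstrap_log_ratios(sample_b, rng, n_bootstrap))
    point = float(np.log(sample_a.ratio) - np.log(sample_b.ratio))
    ci_low, ci_high = np.quantile(delta, [0.025, 0.975])
    p_le = float(np.mean(delta <= 0.0))
    p_ge = float(np.mean(delta >= 0.0))
    p_value = min(1.0, 2.0 * min(p_le, p_ge))
    p_value = max(p_value, 1.0 / n_bootstrap)
    return RatioComparison(point, float(ci_low), float(ci_high), p_value, n_bootstrap, seed)


def ratio_ttest(ratios_a: Sequence[float], ratios_b: Sequence[float]) -> tuple[float, float]:
    """Plain two-sample t-test on per-replicate ratios (plumbing for
    replicate-level comparisons across cultures)."""
    from scipy import stats

    res = stats.ttest_ind(np.asarray(ratios_a, float), np.asarray(ratios_b, float))
    return float(res.statistic), float(res.pvalue)


def ratio_from_ladder(ladder: pd.DataFrame) -> tuple[int, int]:
    """(c_count, d_count) from a tabulate_ladder table."""
    d = int(ladder.loc[ladder["offset"] == 0, "count"].sum())
    c = int(ladder.loc[ladder["offset"] == -1, "count"].sum())
    return c, d


def write_ladder_tsv(ladder: pd.DataFrame, path: str | Path) -> None:
    ladder.to_csv(path, sep="\t", index=False, na_rep="NA")
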