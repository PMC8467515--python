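"""Length-distribution profiling of the 8-30 nt window.

Computes the per-length read/RPM spectrum of a collapsed library, the
fraction of reads in a chosen length window (e.g. the 12+13 nt classes),
and the dominant sequences per length class.  Dominance fractions are
computed on raw counts; when a single library is profiled this equals
the RPM-based fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_io import InputError, UniqueRead

MIN_LEN = 8
MAX_LEN = 30


@dataclass(frozen=True)
class LengthBin:
    reads: int
    rpm: float
    n_unique: int


@dataclass(frozen=True)
class LengthProfile:
    per_length: dict[int, LengthBin]
    total_reads: int


@dataclass(frozen=True)
class DominanceRecord:
    """The share a single sequence holds within its length class."""

    length: int
    top_sequence: str
    top_count: int
    fraction: float


def length_histogram(uniques: Sequence[UniqueRead], min_len: int = MIN_LEN, max_len: int = MAX_LEN) -> LengthProfile:
    """Exact per-length totals of a collapsed, in-window library."""
    bins: dict[int, list[float]] = {}
    total = 0
    for u in uniques:
        length = len(u.sequence)
        if not min_len <= length <= max_len:
            raise InputError(f"sequence of length {length} outside [{min_len}, {max_len}]; trim first")
        reads, rpm, n_unique = bins.setdefault(length, [0, 0.0, 0])
        bins[length] = [reads + u.count, rpm + (u.rpm or 0.0), n_unique + 1]
        total += u.count
    per_length = {length: LengthBin(int(r), rpm, int(n))
                  for length, (r, rpm, n) in sorted(bins.items())}
    return LengthProfile(per_length=per_length, total_reads=total)


def window_fraction(profile: LengthProfile, lengths: Iterable[int]) -> float:
    """Fraction of all profiled reads whose length is in `lengths`."""
    lengths = set(lengths)
    if profile.total_reads == 0:
        raise InputError("empty profile")
    bad = {l for l in lengths if not MIN_LEN <= l <= MAX_LEN}
    if bad:
        raise InputError(f"lengths {sorted(bad)} outside [{MIN_LEN}, {MAX_LEN}]")
    hit = sum(bin_.reads for length, bin_ in profile.per_length.items() if length in lengths)
    return hit / profile.total_reads


def dominant_sequences(uniques: Sequence[UniqueRead], length: int, k: int = 1) -> list[DominanceRecord]:
    """Top-k sequences of one length class with their within-class share.

    Ties break lexicographically.  No reads at that length -> empty list.
    """
    if not MIN_LEN <= length <= MAX_LEN:
        raise InputError(f"length {length} outside [{MIN_LEN}, {MAX_LEN}]")
    if k < 1:
        raise InputError("k must be >= 1")
    in_class = sorted((u for u in uniques if len(u.sequence) == length),
                      key=lambda u: (-u.count, u.sequence))
    class_total = sum(u.count for u in in_class)
    return [DominanceRecord(length, u.sequence, u.count, u.count / class_total)
            for u in in_class[:k]]


def two_sequence_share(uniques: Sequence[UniqueRead], lengths: tuple[int, int] = (12, 13)) -> dict[str, float]:
    """Combined share of the top sequence of each requested length class.

    The denominator for such a combined statistic is ambiguous, so both
    are returned: the union of the requested length classes
    ("share_of_classes") and the whole 8-30 nt window ("share_of_window").
    """
    profile = length_histogram(uniques)
    top_counts = 0
    for length in lengths:
        recs = dominant_sequences(uniques, length, k=1)
        if recs:
            top_counts += recs[0].top_count
    class_total = sum(profile.per_length[l].reads for l in lengths if l in profile.per_length)
    return {
        "share_of_classes": top_counts / class_total if class_total else 0.0,
        "share_of_window": top_counts / profile.total_reads if profile.total_reads else 0.0,
    }


def write_profile_tsv(profile: LengthProfile, path: str | Path) -> None:
    lines = ["length\treads\trpm\tn_unique"]
    for length, bin_ in profile.per_length.items():
        lines.append(f"{length}\t{bin_.reads}\t{bin_.rpm:.4f}\t{bin_.n_unique}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dominance_tsv(records: Sequence[DominanceRecord], path: str | Path) -> None:
    lines = ["length\ttop_sequence\ttop_count\tfraction"]
    for r in records:
        lines.append(f"{r.length}\t{r.top_sequence}\t{r.top_count}\t{r.fraction:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
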