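"""Reading, trimming, collapsing and normalizing ultra-short sRNA reads.

The library insert of interest is 8-30 nt, flanked on its 3' side by the
ligation adapter; a read is therefore insert + (possibly partial) adapter.
Trimming locates the adapter by a seed-and-extend rule: the leftmost exact
occurrence of the adapter's first `min_overlap` bases wins, and the
alignment of the remaining adapter bases against the read must stay within
`max_mismatch_rate` mismatches over the aligned span.  Reads whose insert
falls outside the window, carries more than one ambiguous base, or shows
no adapter are rejected with a machine-readable reason.

Identical trimmed inserts are collapsed into a single `UniqueRead` with a
count, and counts are scaled to reads per million (RPM).  Sequences are
canonicalized to DNA letters (U -> T) on ingest.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

from .mapper import canonicalize, reverse_complement
from .references import DEFAULT_ADAPTER3


class InputError(ValueError):
    """Malformed input data."""


class ConfigurationError(ValueError):
    """Invalid processing configuration."""


_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class Read:
    """A single sequencing read (canonical DNA alphabet)."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", canonicalize(self.sequence))
        if not self.sequence:
            raise InputError(f"read {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise InputError(f"read {self.id!r} contains invalid characters {bad}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise InputError(f"read {self.id!r}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed read: one distinct sequence with its raw count and RPM."""

    sequence: str
    count: int
    rpm: float | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise InputError("UniqueRead count must be >= 1")


@dataclass(frozen=True)
class TrimConfig:
    """3'-adapter trimming parameters.

    min_overlap is the exact adapter prefix that must be present in the
    read; max_mismatch_rate bounds mismatches over the full aligned
    adapter span once the seed is found.
    """

    adapter3: str = DEFAULT_ADAPTER3
    min_overlap: int = 8
    max_mismatch_rate: float = 0.1
    min_insert: int = 8
    max_insert: int = 30
    max_n: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "adapter3", canonicalize(self.adapter3))
        if self.min_overlap < 5:
            raise ConfigurationError("min_overlap must be >= 5")
        if len(self.adapter3) < self.min_overlap:
            raise ConfigurationError("adapter shorter than min_overlap")
        if not 0 <= self.max_mismatch_rate <= 1:
            raise ConfigurationError("max_mismatch_rate must be in [0, 1]")
        if not 0 <= self.min_insert <= self.max_insert:
            raise ConfigurationError("require 0 <= min_insert <= max_insert")


class TrimResult(NamedTuple):
    insert: Read | None
    reason: str | None

    @property
    def accepted(self) -> bool:
        return self.insert is not None


def trim_adapter(read: Read, cfg: TrimConfig | None = None) -> TrimResult:
    """Trim the 3' adapter off a read, returning the insert or a rejection.

    Rejection reasons: "no_adapter", "length_out_of_window", "too_many_N".
    """
    cfg = cfg or TrimConfig()
    seq = read.sequence
    seed = cfg.adapter3[: cfg.min_overlap]
    pos = 0
    cut = -1
    while True:
        pos = seq.find(seed, pos)
        if pos == -1:
            break
        aligned = seq[pos : pos + len(cfg.adapter3)]
        mism = sum(a != b for a, b in zip(aligned, cfg.adapter3))
        if mism <= cfg.max_mismatch_rate * len(aligned):
            cut = pos
            break
        pos += 1
    if cut == -1:
        return TrimResult(None, "no_adapter")
    insert_seq = seq[:cut]
    if not insert_seq or not cfg.min_insert <= len(insert_seq) <= cfg.max_insert:
        return TrimResult(None, "length_out_of_window")
    if insert_seq.count("N") > cfg.max_n:
        return TrimResult(None, "too_many_N")
    quality = read.quality[:cut] if read.quality is not None else None
    return TrimResult(Read(read.id, insert_seq, quality), None)


def collapse_reads(reads: Iterable[Read | str]) -> list[UniqueRead]:
    """Collapse identical sequences into UniqueReads.

    Output order is deterministic: count descending, then lexicographic.
    """
    counts: Counter[str] = Counter()
    for read in reads:
        seq = read.sequence if isinstance(read, Read) else canonicalize(str(read))
        counts[seq] += 1
    return [UniqueRead(seq, n)
            for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def rpm_normalize(uniques: Sequence[UniqueRead], total: int | None = None) -> list[UniqueRead]:
    """Set rpm = count / total * 1e6 on every record.

    `total` defaults to the sum of counts (the trimmed in-window library
    size); it may be larger but never smaller, and never zero.
    """
    observed = sum(u.count for u in uniques)
    if total is None:
        total = observed
    if total == 0:
        raise InputError("cannot RPM-normalize with total == 0")
    if total < observed:
        raise InputError(f"total {total} < sum of counts {observed}")
    return [replace(u, rpm=u.count / total * 1_000_000) for u in uniques]


class ContaminantHit(NamedTuple):
    name: str
    offset: int
    strand: str


def screen_contaminants(query: str, contaminants: Iterable[tuple[str, str]]) -> list[ContaminantHit]:
    """Find exact occurrences of `query` in any contaminant, both strands.

    An empty result means the query sequence is clean (no adapter /
    linker / vector / primer origin).  Queries shorter than 8 nt are too
    unspecific to screen and are refused.
    """
    q = canonicalize(query)
    if len(q) < 8:
        raise InputError("contaminant screening requires a query of >= 8 nt")
    hits: list[ContaminantHit] = []
    for name, seq in contaminants:
        for strand, oriented in (("+", q), ("-", reverse_complement(q))):
            start = 0
            cseq = canonicalize(seq)
            while True:
                idx = cseq.find(oriented, start)
                if idx == -1:
                    break
                hits.append(ContaminantHit(name, idx, strand))
                start = idx + 1
    return hits


# ---------------------------------------------------------------------------
# File I/O


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    return gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate Phred+33 FASTQ records (gzip transparent)."""
    from Bio import SeqIO

    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield Read(rec.id, str(rec.seq), qual)


def read_fasta(path: str | Path) -> Iterator[Read]:
    from Bio import SeqIO

    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield Read(rec.id, str(rec.seq))


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = read.quality or "I" * len(read)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def write_collapsed_fasta(uniques: Sequence[UniqueRead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with headers >seq<rank>_x<count>."""
    with _open_text(path, "wt") as handle:
        for rank, u in enumerate(uniques, start=1):
            handle.write(f">seq{rank}_x{u.count}\n{u.sequence}\n")


def write_collapsed_tsv(uniques: Sequence[UniqueRead], path: str | Path,
                        metadata: dict[str, object] | None = None) -> None:
    lines = ["# alphabet: DNA"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    lines.append("sequence\tcount\trpm")
    for u in uniques:
        rpm = f"{u.rpm:.6f}" if u.rpm is not None else "NA"
        lines.append(f"{u.sequence}\t{u.count}\t{rpm}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_collapsed_tsv(path: str | Path) -> list[UniqueRead]:
    uniques: list[UniqueRead] = []
    header_seen = False
    for line in _open_text(path):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        seq, count, rpm = line.split("\t")
        uniques.append(UniqueRead(seq, int(count), None if rpm == "NA" else float(rpm)))
    return uniques
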