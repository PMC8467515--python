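"""Exact and near-exact mapping of ultra-short (8-30 nt) queries.

Queries this short fall below the reliable operating range of seeded
heuristic aligners, so hits are enumerated exhaustively: an 8-mer seed
index answers mismatch-free queries, and a direct Hamming scan over each
(small, rRNA-scale) record handles tolerated substitutions.  Both strands
are always searched; alignments are ungapped, so every reported hit covers
the full query.

Coordinates are 0-based half-open internally; human-readable reports
(`annotate_hit_position`, TSV headers) use 1-based inclusive positions.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

MIN_QUERY_LEN = 8
MAX_QUERY_LEN = 30
_SEED_K = 8


def canonicalize(sequence: str) -> str:
    """Uppercase and rewrite the sequence in DNA letters (U -> T)."""
    return sequence.upper().replace("U", "T")


def reverse_complement(sequence: str) -> str:
    return canonicalize(sequence).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A named interval on a reference record (0-based, half-open)."""

    accession: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid feature interval {self.start}..{self.end}")


@dataclass
class ReferenceFeatureSet:
    """Reference sequences plus their annotated rRNA features.

    `records` maps accession to the (DNA-canonical) sequence.  Features
    name sub-intervals such as 18S, ITS1, 5.8S, ITS2 and 28S on a 45S-like
    precursor record.  At most one 5.8S feature is allowed per record.
    """

    records: dict[str, str]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = {acc: canonicalize(seq) for acc, seq in self.records.items()}
        for acc, seq in self.records.items():
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"record {acc} contains non-nucleotide characters {bad}")
        for feat in self.features:
            if feat.accession not in self.records:
                raise ValueError(f"feature on unknown record {feat.accession}")
            if feat.end > len(self.records[feat.accession]):
                raise ValueError(f"feature {feat.name} exceeds record {feat.accession}")
        for acc in self.records:
            n58 = sum(1 for f in self.features if f.accession == acc and f.name == "5.8S")
            if n58 > 1:
                raise ValueError(f"record {acc} carries {n58} 5.8S features; at most 1 allowed")

    def feature(self, accession: str, name: str) -> Feature | None:
        for feat in self.features:
            if feat.accession == accession and feat.name == name:
                return feat
        return None

    def features_of(self, accession: str) -> list[Feature]:
        return [f for f in self.features if f.accession == accession]

    @classmethod
    def from_fasta(cls, fasta_path: str | Path, features_tsv: str | Path | None = None) -> "ReferenceFeatureSet":
        """Load records from FASTA and features from a TSV.

        The feature TSV has columns accession, name, start, end (0-based
        half-open); lines starting with '#' are ignored.
        """
        from Bio import SeqIO

        fasta_path = Path(fasta_path)
        opener = gzip.open if fasta_path.suffix == ".gz" else open
        with opener(fasta_path, "rt") as handle:
            records = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
        features: list[Feature] = []
        if features_tsv is not None:
            for line in Path(features_tsv).read_text().splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                acc, name, start, end = line.split("\t")[:4]
                features.append(Feature(acc, name, int(start), int(end)))
        return cls(records=records, features=features)


@dataclass(frozen=True)
class MatchHit:
    """One ungapped occurrence of a query on a reference record."""

    query: str
    accession: str
    start: int
    end: int
    strand: str
    identity_pct: float
    query_coverage_pct: float
    feature_overlap: tuple[str, ...] = ()


class ReferenceIndex:
    """8-mer seed index over both strands of a reference set."""

    def __init__(self, refs: ReferenceFeatureSet, min_len: int = MIN_QUERY_LEN, max_len: int = MAX_QUERY_LEN):
        if not refs.records:
            raise ValueError("reference set is empty")
        if min_len < _SEED_K:
            raise ValueError(f"min_len must be >= {_SEED_K}")
        self.refs = refs
        self.min_len = min_len
        self.max_len = max_len
        # seed -> list of (accession, strand, offset in strand-oriented sequence)
        self._seeds: dict[str, list[tuple[str, str, int]]] = {}
        self._oriented: dict[tuple[str, str], str] = {}
        self._encoded: dict[tuple[str, str], np.ndarray] = {}
        for acc, seq in refs.records.items():
            for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
                self._oriented[(acc, strand)] = oriented
                self._encoded[(acc, strand)] = np.frombuffer(oriented.encode(), dtype=np.uint8)
                for i in range(len(oriented) - _SEED_K + 1):
                    self._seeds.setdefault(oriented[i : i + _SEED_K], []).append((acc, strand, i))

    def seed_candidates(self, seed: str) -> list[tuple[str, str, int]]:
        return self._seeds.get(seed, [])


def build_reference_index(refs: ReferenceFeatureSet, min_len: int = MIN_QUERY_LEN, max_len: int = MAX_QUERY_LEN) -> ReferenceIndex:
    return ReferenceIndex(refs, min_len=min_len, max_len=max_len)


def _forward_coords(acc: str, strand: str, offset: int, qlen: int, record_len: int) -> tuple[int, int]:
    if strand == "+":
        return offset, offset + qlen
    start = record_len - offset - qlen
    return start, start + qlen


def _overlapping_features(refs: ReferenceFeatureSet, acc: str, start: int, end: int) -> tuple[str, ...]:
    out = [f.name for f in sorted(refs.features_of(acc), key=lambda f: (f.start, f.name))
           if f.start < end and start < f.end]
    return tuple(out)


def map_query(query: str, index: ReferenceIndex, max_mismatches: int = 0) -> list[MatchHit]:
    """Enumerate every occurrence of `query` with at most `max_mismatches`
    substitutions, on both strands of every record.

    Returns hits sorted by (accession, start, strand).  A hit on strand
    '-' means the reverse complement of the query matches the forward
    record at [start, end); mapping the reverse complement of a query
    therefore swaps strand labels and nothing else.
    """
    q = canonicalize(query)
    if not index.min_len <= len(q) <= index.max_len:
        raise ValueError(f"query length {len(q)} outside [{index.min_len}, {index.max_len}]")
    hits: list[MatchHit] = []
    refs = index.refs
    if max_mismatches == 0:
        seen: set[tuple[str, int, str]] = set()
        for acc, strand, offset in index.seed_candidates(q[:_SEED_K]):
            oriented = index._oriented[(acc, strand)]
            if oriented[offset : offset + len(q)] != q:
                continue
            start, end = _forward_coords(acc, strand, offset, len(q), len(refs.records[acc]))
            key = (acc, start, strand)
            if key in seen:
                continue
            seen.add(key)
            hits.append(MatchHit(q, acc, start, end, strand, 100.0, 100.0,
                                 _overlapping_features(refs, acc, start, end)))
    else:
        qarr = np.frombuffer(q.encode(), dtype=np.uint8)
        for acc in refs.records:
            for strand in ("+", "-"):
                enc = index._encoded[(acc, strand)]
                if len(enc) < len(qarr):
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(enc, len(qarr))
                mismatches = (windows != qarr).sum(axis=1)
                for offset in np.nonzero(mismatches <= max_mismatches)[0]:
                    mm = int(mismatches[offset])
                    start, end = _forward_coords(acc, strand, int(offset), len(q), len(refs.records[acc]))
                    identity = 100.0 * (len(q) - mm) / len(q)
                    hits.append(MatchHit(q, acc, start, end, strand, identity, 100.0,
                                         _overlapping_features(refs, acc, start, end)))
    hits.sort(key=lambda h: (h.accession, h.start, h.strand))
    return hits


def annotate_hit_position(hit: MatchHit, refs: ReferenceFeatureSet) -> str:
    """Report a hit's span relative to the 5' end of the 5.8S feature.

    Position 1 is the first 5.8S base; positions upstream (in ITS1) are
    negative, with no position 0.  A record without a 5.8S feature is
    reported in raw 1-based coordinates.
    """
    feat = refs.feature(hit.accession, "5.8S")
    if feat is None:
        return f"{hit.accession}:{hit.start + 1}..{hit.end}"

    def rel(pos0: int) -> int:
        delta = pos0 - feat.start
        return delta + 1 if delta >= 0 else delta

    rel_start, rel_end = rel(hit.start), rel(hit.end - 1)
    if rel_start >= 1:
        return f"5.8S:{rel_start}..{rel_end}"
    return f"{rel_start}..{rel_end}"


def write_hits_tsv(hits: Sequence[MatchHit], path: str | Path, refs: ReferenceFeatureSet | None = None) -> None:
    """Write hits as TSV (1-based inclusive coordinates in the report)."""
    lines = ["# coordinates: 1-based inclusive",
             "query\taccession\tstart\tend\tstrand\tidentity_pct\tquery_coverage_pct\tfeatures\tposition"]
    for h in hits:
        pos = annotate_hit_position(h, refs) if refs is not None else ""
        lines.append(f"{h.query}\t{h.accession}\t{h.start + 1}\t{h.end}\t{h.strand}"
                     f"\t{h.identity_pct:.2f}\t{h.query_coverage_pct:.2f}\t{','.join(h.feature_overlap)}\t{pos}")
    Path(path).write_text("\n".join(lines) + "\n")
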