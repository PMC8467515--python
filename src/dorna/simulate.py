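"""Seeded generators of synthetic inputs with planted ground truth.

`simulate_library` emulates the statistical structure of an 8-30 nt
sRNA-seq library built around the doRNA family: a dominant 12-nt core
and 13-nt 5'-extended variant at a species-specific ratio (presets
human 5.0, mouse 1.0, fly 0.25), a decaying 5'-extension ladder anchored
at the invariant 3' end, background miRNA-like 19-24-mers and random
degradation fragments, a ligated 3' adapter and substitution sequencing
errors.  Every read's insert is planted from an exact truth table, so
downstream stages can be checked for exact recovery at error rate 0.

All generators are deterministic: the same configuration and seed give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify
from .classify import DoRNAAnchor, derive_anchor
from .mapper import ReferenceFeatureSet
from .quant import PERFECT_SLOPE
from .references import DEFAULT_ADAPTER3, synthetic_precursor
from .sequence_io import Read

PRESET_RATIOS = {"human": 5.0, "mouse": 1.0, "fly": 0.25}

#: Default 5'-extension ladder weights (relative to a core weight of 1),
#: decaying with extension length as in observed stair-shaped alignments.
DEFAULT_LADDER_WEIGHTS = {-2: 0.05, -3: 0.03, -4: 0.02, -5: 0.012, -6: 0.006}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LibrarySimConfig:
    """Composition of a simulated 8-30 nt library.

    family_fraction is the share of reads drawn from the doRNA ladder
    (12+13 nt classes dominate it); degradation_fraction is the share of
    random reference fragments; the remainder is spread over n_mirnas
    miRNA-like sequences with Zipf-decaying abundances.
    """

    species_preset: str = "human"
    true_ratio: float | None = None  # None -> species preset
    family_fraction: float = 0.5
    ladder_weights: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_LADDER_WEIGHTS))
    n_reads: int = 100_000
    error_rate: float = 0.001
    adapter3: str = DEFAULT_ADAPTER3
    n_mirnas: int = 20
    degradation_fraction: float = 0.2
    seed: int = 1

    def __post_init__(self) -> None:
        if self.species_preset not in PRESET_RATIOS and self.species_preset != "custom":
            raise ValueError(f"unknown species preset {self.species_preset!r}")
        if self.true_ratio is None:
            object.__setattr__(self, "true_ratio", PRESET_RATIOS.get(self.species_preset))
        if self.true_ratio is None or self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive (required for 'custom')")
        if any(w < 0 for w in self.ladder_weights.values()):
            raise ValueError("ladder weights must be >= 0")
        if not 0 <= self.family_fraction <= 1 or not 0 <= self.degradation_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.family_fraction + self.degradation_fraction > 1:
            raise ValueError("family_fraction + degradation_fraction exceeds 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthTable:
    """Planted per-sequence counts and the planted family ratio."""

    sequences: pd.DataFrame  # columns: sequence, category, offset, length, count
    planted_ratio: float
    n_reads: int

    @property
    def per_length(self) -> dict[int, int]:
        g = self.sequences.groupby("length")["count"].sum()
        return {int(k): int(v) for k, v in g.items()}

    def count_of(self, sequence: str) -> int:
        m = self.sequences.loc[self.sequences["sequence"] == sequence, "count"]
        return int(m.sum())


def _family_probabilities(cfg: LibrarySimConfig) -> tuple[list[int], np.ndarray]:
    """Family category offsets and their within-family probabilities."""
    offsets = [0, -1] + sorted(cfg.ladder_weights, reverse=True)
    weights = np.array([1.0, cfg.true_ratio] + [cfg.ladder_weights[o] for o in offsets[2:]])
    return offsets, weights / weights.sum()


def simulate_family_counts(cfg: LibrarySimConfig, n_family: int,
                           rng: np.random.Generator) -> dict[int, int]:
    """Multinomial draw of family-read counts per ladder offset.

    This is the sampler `simulate_library` uses to plant family counts;
    exposed so replication studies (e.g. CI coverage over many seeds)
    can run at the count level.
    """
    offsets, probs = _family_probabilities(cfg)
    counts = rng.multinomial(n_family, probs)
    return dict(zip(offsets, (int(c) for c in counts)))


def _random_kmer(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _background_mirnas(cfg: LibrarySimConfig, rng: np.random.Generator) -> list[str]:
    """Fixed miRNA-like 19-24-mers, free of the adapter seed; their
    19-24 nt lengths keep them disjoint from the <=18 nt family ladder."""
    seed8 = cfg.adapter3[:8]
    out: list[str] = []
    while len(out) < cfg.n_mirnas:
        seq = _random_kmer(rng, int(rng.integers(19, 25)))
        if seed8 in seq or seq in out:
            continue
        out.append(seq)
    return out


def _degradation_fragment(rng: np.random.Generator, refseq: str, anchor: DoRNAAnchor,
                          seed8: str) -> str:
    while True:
        length = int(rng.integers(8, 31))
        start = int(rng.integers(0, len(refseq) - length + 1))
        frag = refseq[start : start + length]
        if seed8 in frag or "N" in frag:
            continue
        if classify.classify_read(frag, anchor).category != classify.CATEGORY_NON:
            continue
        return frag


def simulate_library(cfg: LibrarySimConfig,
                     reference: ReferenceFeatureSet | None = None,
                     fastq_path: str | Path | None = None) -> tuple[list[Read], TruthTable]:
    """Generate a full synthetic library and its planted truth table.

    Reads are insert + 3' adapter with per-base substitution errors at
    cfg.error_rate.  The truth table records pre-error insert counts and
    sums exactly to n_reads.  Optionally writes FASTQ to `fastq_path`.
    """
    rng = np.random.default_rng(cfg.seed)
    if reference is None:
        species = cfg.species_preset if cfg.species_preset in PRESET_RATIOS else "human"
        reference = synthetic_precursor(species)
    accession = next(iter(reference.records))
    anchor = derive_anchor(reference, accession)
    refseq = reference.records[accession]
    seed8 = cfg.adapter3[:8]

    offsets, family_probs = _family_probabilities(cfg)
    mirnas = _background_mirnas(cfg, rng)
    mirna_fraction = 1.0 - cfg.family_fraction - cfg.degradation_fraction
    zipf = 1.0 / np.arange(1, len(mirnas) + 1) if mirnas else np.array([])
    probs = np.concatenate([
        cfg.family_fraction * family_probs,
        mirna_fraction * zipf / zipf.sum() if len(zipf) else [],
        [cfg.degradation_fraction],
    ])
    counts = rng.multinomial(cfg.n_reads, probs / probs.sum())
    family_counts = counts[: len(offsets)]
    mirna_counts = counts[len(offsets) : len(offsets) + len(mirnas)]
    n_degradation = int(counts[-1])

    rows: list[dict] = []
    inserts: list[str] = []
    for off, n in zip(offsets, family_counts):
        seq = anchor.expected_sequence(classify.CORE_LENGTH - off)
        category = classify.classify_read(seq, anchor).category
        rows.append({"sequence": seq, "category": category, "offset": off,
                     "length": len(seq), "count": int(n)})
        inserts.extend([seq] * int(n))
    for seq, n in zip(mirnas, mirna_counts):
        rows.append({"sequence": seq, "category": "miRNA", "offset": pd.NA,
                     "length": len(seq), "count": int(n)})
        inserts.extend([seq] * int(n))
    frag_counter: dict[str, int] = {}
    for _ in range(n_degradation):
        frag = _degradation_fragment(rng, refseq, anchor, seed8)
        frag_counter[frag] = frag_counter.get(frag, 0) + 1
        inserts.append(frag)
    for seq, n in sorted(frag_counter.items()):
        rows.append({"sequence": seq, "category": "degradation", "offset": pd.NA,
                     "length": len(seq), "count": n})

    truth_df = (pd.DataFrame(rows, columns=["sequence", "category", "offset", "length", "count"])
                if rows else pd.DataFrame(columns=["sequence", "category", "offset", "length", "count"]))
    truth = TruthTable(truth_df, planted_ratio=float(cfg.true_ratio), n_reads=cfg.n_reads)

    order = rng.permutation(len(inserts))
    raw = [inserts[i] + cfg.adapter3 for i in order]
    reads = _apply_errors(raw, cfg.error_rate, rng)
    read_objs = [Read(f"sim{i:07d}", seq, "I" * len(seq)) for i, seq in enumerate(reads)]
    if fastq_path is not None:
        from .sequence_io import write_fastq

        write_fastq(read_objs, fastq_path)
    return read_objs, truth


def _apply_errors(reads: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    if error_rate == 0 or not reads:
        return reads
    lengths = np.fromiter((len(r) for r in reads), dtype=np.int64)
    n_errors = rng.binomial(lengths, error_rate)
    out = list(reads)
    for idx in np.nonzero(n_errors)[0]:
        seq = bytearray(out[idx].encode())
        positions = rng.choice(len(seq), size=int(n_errors[idx]), replace=False)
        for pos in positions:
            alternatives = [b for b in b"ACGT" if b != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(3))]
        out[idx] = seq.decode()
    return out


def simulate_peptides(n_a_only: int, n_b_only: int, n_shared: int,
                      n_negative_contaminated: int = 0, n_subthreshold: int = 0,
                      seed: int = 0, min_peptides_exclusive: int = 3) -> pd.DataFrame:
    """Peptide-count table with a planted Venn partition plus decoys.

    Planted partners carry > min_peptides_exclusive peptides and no
    negative-control signal, so the partner filter + Venn partition
    recover (n_a_only, n_b_only, n_shared) exactly.  Decoys are either
    present in the negative control or below the peptide threshold.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    idx = 0

    def strong() -> int:
        return int(rng.integers(min_peptides_exclusive + 1, 31))

    def weak() -> int:
        return int(rng.integers(1, min_peptides_exclusive + 1))

    def add(bait: str, count: int) -> None:
        rows.append({"protein_id": pid, "bait": bait, "peptide_count": count,
                     "coverage_pct": round(float(rng.uniform(5, 90)), 1)})

    for _ in range(n_a_only):
        pid = f"P{(idx := idx + 1):04d}"
        add("doRNA", strong())
    for _ in range(n_b_only):
        pid = f"P{(idx := idx + 1):04d}"
        add("C-doRNA", strong())
    for _ in range(n_shared):
        pid = f"P{(idx := idx + 1):04d}"
        add("doRNA", strong())
        add("C-doRNA", strong())
    for _ in range(n_negative_contaminated):
        pid = f"P{(idx := idx + 1):04d}"
        add(rng.choice(["doRNA", "C-doRNA"]), strong())
        add("negative", int(rng.integers(1, 6)))
    for _ in range(n_subthreshold):
        pid = f"P{(idx := idx + 1):04d}"
        add(rng.choice(["doRNA", "C-doRNA"]), weak())
    return pd.DataFrame(rows, columns=["protein_id", "bait", "peptide_count", "coverage_pct"])


def simulate_qpcr(true_copies: Mapping[str, float], efficiency: float = 1.0,
                  noise_sd: float = 0.0, seed: int = 0,
                  dilution_copies: Sequence[float] = (1e7, 1e6, 1e5, 1e4, 1e3, 1e2),
                  intercept: float = 36.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-target serial-dilution standards plus unknown-sample Cq values.

    Cq = intercept + slope * log10(copies) + N(0, noise_sd), with
    slope = -1/log10(1 + efficiency).
    """
    if not 0.5 < efficiency <= 1.2:
        raise ValueError("efficiency must lie in (0.5, 1.2]")
    if any(c <= 0 for c in true_copies.values()):
        raise ValueError("true copy numbers must be positive")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(1.0 + efficiency)
    std_rows, unk_rows = [], []
    for target in true_copies:
        for copies in dilution_copies:
            cq = intercept + slope * np.log10(copies) + rng.normal(0.0, noise_sd)
            std_rows.append({"target": target, "copies": float(copies), "cq": float(cq)})
        cq = intercept + slope * np.log10(true_copies[target]) + rng.normal(0.0, noise_sd)
        unk_rows.append({"target": target, "cq": float(cq)})
    return pd.DataFrame(std_rows), pd.DataFrame(unk_rows)
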