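"""Protein-partner candidate filtering and Venn partition.

Pull-down candidates identified by LC/MS-MS are kept for a bait RNA only
when they show strictly more than `min_peptides_exclusive` peptide
matches for that bait and zero peptides in the negative-RNA control.
Kept sets for the two baits are then partitioned into exclusive and
shared partners; an IP enrichment is reported as a plain fold change
over the IgG control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

BAIT_DORNA = "doRNA"
BAIT_C_DORNA = "C-doRNA"
BAIT_NEGATIVE = "negative"
_KNOWN_BAITS = {BAIT_DORNA, BAIT_C_DORNA, BAIT_NEGATIVE}


@dataclass(frozen=True)
class PeptideRecord:
    protein_id: str
    bait: str
    peptide_count: int
    coverage_pct: float | None = None

    def __post_init__(self) -> None:
        if self.bait not in _KNOWN_BAITS:
            raise ValueError(f"unknown bait label {self.bait!r}; expected one of {sorted(_KNOWN_BAITS)}")
        if self.peptide_count < 0:
            raise ValueError("peptide_count must be >= 0")


@dataclass(frozen=True)
class VennPartition:
    a_only: frozenset[str]
    b_only: frozenset[str]
    shared: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {"a_only": len(self.a_only), "b_only": len(self.b_only),
                "shared": len(self.shared), "union": len(self.a_only | self.b_only | self.shared)}

    def to_dict(self) -> dict[str, object]:
        return {"a_only": sorted(self.a_only), "b_only": sorted(self.b_only),
                "shared": sorted(self.shared), "counts": self.counts}


def _as_records(records) -> list[PeptideRecord]:
    if isinstance(records, pd.DataFrame):
        return [PeptideRecord(str(r.protein_id), str(r.bait), int(r.peptide_count),
                              float(r.coverage_pct) if "coverage_pct" in records.columns
                              and pd.notna(getattr(r, "coverage_pct", None)) else None)
                for r in records.itertuples(index=False)]
    return [r if isinstance(r, PeptideRecord) else PeptideRecord(*r) for r in records]


def filter_partners(records, min_peptides_exclusive: int = 3) -> dict[str, set[str]]:
    """Kept candidates per bait.

    A protein absent from a bait's table counts as 0 peptides.  Kept for
    bait b iff peptide_count(b) > min_peptides_exclusive and
    peptide_count(negative) == 0 (strictly absent, not sub-threshold).
    """
    recs = _as_records(records)
    counts: dict[tuple[str, str], int] = {}
    for r in recs:
        key = (r.protein_id, r.bait)
        counts[key] = counts.get(key, 0) + r.peptide_count
    proteins = {r.protein_id for r in recs}
    kept: dict[str, set[str]] = {BAIT_DORNA: set(), BAIT_C_DORNA: set()}
    for bait in (BAIT_DORNA, BAIT_C_DORNA):
        for protein in proteins:
            if (counts.get((protein, bait), 0) > min_peptides_exclusive
                    and counts.get((protein, BAIT_NEGATIVE), 0) == 0):
                kept[bait].add(protein)
    return kept


def venn_partition(set_a: Iterable[str], set_b: Iterable[str]) -> VennPartition:
    a, b = set(set_a), set(set_b)
    return VennPartition(frozenset(a - b), frozenset(b - a), frozenset(a & b))


def ip_fold_enrichment(target_quantity_ab: float, target_quantity_igg: float) -> float:
    """Fold change of an antibody IP over the IgG control IP."""
    if target_quantity_igg <= 0:
        raise ValueError("IgG control quantity must be > 0")
    if target_quantity_ab <= 0:
        raise ValueError("antibody IP quantity must be > 0")
    return target_quantity_ab / target_quantity_igg


def read_peptides_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_id", "bait", "peptide_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns {sorted(missing)}")
    return df
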