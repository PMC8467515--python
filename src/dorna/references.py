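"""Bundled synthetic references and contaminant sequences.

The package anchors the doRNA family on the 5' end of 5.8S rRNA inside a
45S-like precursor.  Because tests and simulations must run without
downloads, a compact synthetic precursor record is generated here for
each supported species.  It is explicitly a synthetic stand-in: the 5.8S
5'-terminal bases are fixed to the species' published start (so the
12-nt core, its 13-nt 5'-extended variant, the 3'-terminal G at 5.8S
position 13 and the U at position 14 are all exact), while spacers and
the remainder of each subunit are seeded-random filler.  Real precursor
records loaded from FASTA + feature TSV are drop-in replacements.
"""

from __future__ import annotations

import numpy as np

from .mapper import Feature, ReferenceFeatureSet

#: Illumina TruSeq small-RNA 3' adapter; the default trimming target.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

#: Common library-construction sequences used by the contamination screen:
#: small-RNA 3'/5' adapters, RT and PCR primers, and a generic vector primer.
CONTAMINANTS: dict[str, str] = {
    "TruSeq_smallRNA_3p_adapter": "TGGAATTCTCGGGTGCCAAGG",
    "TruSeq_smallRNA_5p_adapter": "GTTCAGAGTTCTACAGTCCGACGATC",
    "TruSeq_smallRNA_RT_primer": "GCCTTGGCACCCGAGAATTCCA",
    "TruSeq_universal_adapter": "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC",
    "Illumina_PCR_primer_1": "AATGATACGGCGACCACCGAGATCTACACGTTCAGAGTTCTACAGTCCGA",
    "Illumina_PCR_primer_2": "CAAGCAGAAGACGGCATACGA",
    "M13_forward_primer": "GTAAAACGACGGCCAGT",
    "M13_reverse_primer": "CAGGAAACAGCTATGAC",
}

# 5'-terminal bases of mature 5.8S rRNA per species.  Position 1 is the
# first mature base (the extra 5' base of the 13-nt variant); positions
# 2..13 are the 12-nt core, ending on the invariant G13, followed by U14.
# Human and mouse share an identical start; the fly entry is a synthetic
# stand-in that satisfies the observed constraints (5' A, core differing
# from the human core at 2 positions, G13, U14).
_58S_PREFIX = {
    "human": "CGACTCTTAGCGGTGGATCA",
    "mouse": "CGACTCTTAGCGGTGGATCA",
    "fly": "AAACTCTAAGCGGTGGATCA",
}

# Segment lengths of the synthetic precursor (total 600 nt).
_LAYOUT = (("5ETS", 80), ("18S", 150), ("ITS1", 100), ("5.8S", 120), ("ITS2", 80), ("28S", 70))

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def synthetic_precursor(species: str = "human", seed: int = 0) -> ReferenceFeatureSet:
    """Build the synthetic 45S-like precursor record for `species`.

    Deterministic for a given (species, seed).  The filler sequence is
    re-drawn until the record contains neither the default adapter seed
    nor a second occurrence of the core / 13-nt variant, so that planted
    reads map and classify unambiguously.
    """
    species = species.lower()
    if species not in _58S_PREFIX:
        raise ValueError(f"unknown species preset {species!r}; choose from {sorted(_58S_PREFIX)}")
    prefix = _58S_PREFIX[species]
    core = prefix[1:13]
    c_variant = prefix[:13]
    adapter_seed = DEFAULT_ADAPTER3[:8]

    for attempt in range(100):
        species_tag = sum(ord(c) * 31**i for i, c in enumerate(species)) % (2**31)
        rng = np.random.default_rng((seed, attempt, species_tag))
        parts: list[str] = []
        features: list[Feature] = []
        acc = f"SYNTH_45S_{species.upper()}"
        pos = 0
        for name, length in _LAYOUT:
            if name == "5.8S":
                seg = prefix + _random_seq(rng, length - len(prefix))
            else:
                seg = _random_seq(rng, length)
            parts.append(seg)
            features.append(Feature(acc, name, pos, pos + length))
            pos += length
        seq = "".join(parts)
        from .mapper import reverse_complement

        clean = (seq.count(core) == 1 and seq.count(c_variant) == 1
                 and adapter_seed not in seq and adapter_seed not in reverse_complement(seq))
        if clean:
            return ReferenceFeatureSet(records={acc: seq}, features=features)
    raise RuntimeError("could not build a clean synthetic reference")  # pragma: no cover


def contaminant_records() -> list[tuple[str, str]]:
    """The bundled contaminant set as (name, sequence) pairs."""
    return list(CONTAMINANTS.items())
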