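"""Closed-form quantitation helpers used around the sequencing pipeline.

qPCR standard curves (Cq regressed on log10 input copies, with the
amplification efficiency 10^(-1/slope) - 1), absolute copy numbers from
Cq, nucleus/cytoplasm compartment fractions, dual-luciferase reporter
normalization, and scratch-assay wound closure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Slope of a perfectly efficient (doubling-per-cycle) standard curve.
PERFECT_SLOPE = -1.0 / np.log10(2.0)  # -3.3219...


@dataclass(frozen=True)
class StandardCurve:
    slope: float       # Cq per log10 copies; < 0 for a valid curve
    intercept: float   # Cq at 1 copy
    r_squared: float
    efficiency: float  # fraction; 1.0 == 100% (doubling per cycle)


def fit_standard_curve(dilutions) -> StandardCurve:
    """OLS fit of Cq on log10(copies) over a serial dilution.

    Requires >= 3 points spanning >= 2 log10 of input; copies must be
    positive.  Accepts a DataFrame/records with fields (copies, cq) or
    an iterable of (copies, cq) pairs.
    """
    if isinstance(dilutions, pd.DataFrame):
        pairs = list(zip(dilutions["copies"], dilutions["cq"]))
    else:
        pairs = [(d["copies"], d["cq"]) if isinstance(d, Mapping) else tuple(d) for d in dilutions]
    if len(pairs) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    copies = np.array([p[0] for p in pairs], dtype=float)
    cq = np.array([p[1] for p in pairs], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    x = np.log10(copies)
    if x.max() - x.min() < 2.0:
        raise ValueError("dilution series must span >= 2 log10 of input")
    fit = stats.linregress(x, cq)
    if fit.slope >= 0:
        raise ValueError(f"non-negative slope {fit.slope:.3f}; Cq must decrease with input")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue ** 2), float(efficiency))


def copies_from_cq(cq: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10^((cq - intercept)/slope)."""
    if curve.slope >= 0:
        raise ValueError("invalid curve: slope must be < 0")
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


def relative_quantity(cq_target: float, cq_reference: float, efficiency: float = 1.0) -> float:
    """Reference-gene-normalized quantity via the ΔCq model:
    (1+E)^(Cq_ref - Cq_target)."""
    if not 0 < efficiency <= 1.5:
        raise ValueError("efficiency must be in (0, 1.5]")
    return float((1.0 + efficiency) ** (cq_reference - cq_target))


COMPARTMENTS = ("nucleus", "cytoplasm")


@dataclass(frozen=True)
class CompartmentQuant:
    rna_id: str
    compartment: str
    quantity: float
    fraction: float


def compartment_fractions(quantities) -> list[CompartmentQuant]:
    """Per-RNA nucleus/cytoplasm fractions (dot counts or copy numbers).

    Accepts a DataFrame with columns (rna_id, compartment, quantity) or
    a mapping rna_id -> {compartment: quantity}.  Fractions per RNA sum
    to 1; an all-zero RNA is an error.
    """
    if isinstance(quantities, pd.DataFrame):
        grouped: dict[str, dict[str, float]] = {}
        for r in quantities.itertuples(index=False):
            grouped.setdefault(str(r.rna_id), {})[str(r.compartment)] = float(r.quantity)
    else:
        grouped = {str(k): {str(c): float(q) for c, q in v.items()} for k, v in quantities.items()}
    out: list[CompartmentQuant] = []
    for rna_id, comps in grouped.items():
        unknown = set(comps) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartments {sorted(unknown)} for {rna_id}")
        if any(q < 0 for q in comps.values()):
            raise ValueError(f"negative quantity for {rna_id}")
        total = sum(comps.values())
        if total == 0:
            raise ValueError(f"all-zero quantities for {rna_id}")
        for comp in COMPARTMENTS:
            if comp in comps:
                out.append(CompartmentQuant(rna_id, comp, comps[comp], comps[comp] / total))
    return out


def reporter_normalize(fluc: float, rluc: float, control_fluc: float, control_rluc: float) -> float:
    """Fluc/Rluc of a sample as a percentage of the control's Fluc/Rluc."""
    for name, value in (("fluc", fluc), ("rluc", rluc),
                        ("control_fluc", control_fluc), ("control_rluc", control_rluc)):
        if value <= 0:
            raise ValueError(f"{name} must be > 0")
    return 100.0 * (fluc / rluc) / (control_fluc / control_rluc)


def wound_closure(area_t0: float, area_t: float) -> tuple[float, float]:
    """(percent closure, percent unrecovered) of a scratched area.

    unrecovered = 100 * area_t / area_t0; closure is its complement.
    An area_t exceeding area_t0 is clamped with a warning.
    """
    if area_t0 <= 0:
        raise ValueError("initial area must be > 0")
    if area_t < 0:
        raise ValueError("area must be >= 0")
    if area_t > area_t0:
        warnings.warn("area at t exceeds initial area; clamping to 100% unrecovered")
        area_t = area_t0
    unrecovered = 100.0 * area_t / area_t0
    return 100.0 - unrecovered, unrecovered
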