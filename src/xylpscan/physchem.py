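"""ProtParam-style physicochemical characterization of protein sequences.

Length, average molecular weight, theoretical pI (Bjellqvist pKa set),
GRAVY and Kyte-Doolittle hydropathy profile, Guruprasad instability index
and the aliphatic index, plus the categorical labels used for family-wide
summaries (alkaline pI > 7.0, unstable > 40, hydrophobic GRAVY > 0).

Molecular weight, GRAVY and the instability table come from Biopython's
ProtParam implementation (ExPASy conventions).  The pI is found by bisection
on [0, 14] over Biopython's Bjellqvist charge model: the net charge is
strictly decreasing in pH, so the zero crossing is unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .core_io import ProteinRecord

__all__ = [
    "PhyschemProfile",
    "HydropathyProfile",
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "gravy",
    "hydropathy_profile",
    "instability_index",
    "aliphatic_index",
    "physchem_profile",
]

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = set(CANONICAL)

#: Average mass of one water molecule (Da), released per peptide bond.
WATER_DA = 18.0153


def _check_canonical(sequence: str, what: str) -> None:
    if not sequence:
        raise ValueError(f"{what}: empty sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in _CANONICAL_SET:
            raise ValueError(
                f"{what}: non-canonical residue {aa!r} at position {i}"
            )


@dataclass(frozen=True)
class HydropathyProfile:
    """Sliding Kyte-Doolittle window means; one value per window center."""

    window: int
    values: tuple[float, ...]


@dataclass(frozen=True)
class PhyschemProfile:
    protein_id: str
    length: int
    mw: float           # kDa
    pi: float
    gravy: float
    instability: float
    aliphatic: float
    is_alkaline: bool   # pi > 7.0
    is_unstable: bool   # instability > 40
    is_hydrophobic: bool  # gravy > 0


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    _check_canonical(sequence, "molecular_weight")
    return ProteinAnalysis(sequence).molecular_weight() / 1000.0


def net_charge(sequence: str, ph: float) -> float:
    """Net charge at a given pH under the Bjellqvist pKa set."""
    _check_canonical(sequence, "net_charge")
    return IsoelectricPoint(sequence).charge_at_pH(ph)


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """Theoretical pI: bisection on [0, 14] until |net charge| < tol.

    The charge function is strictly decreasing in pH, so plain bisection on
    the full pH scale converges to the unique zero crossing.
    """
    _check_canonical(sequence, "isoelectric_point")
    ip = IsoelectricPoint(sequence)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        q = ip.charge_at_pH(mid)
        if abs(q) < tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    _check_canonical(sequence, "gravy")
    return float(np.mean([KYTE_DOOLITTLE[aa] for aa in sequence]))


def hydropathy_profile(sequence: str, window: int = 9) -> HydropathyProfile:
    """Unweighted sliding-window Kyte-Doolittle means (ProtScale defaults)."""
    _check_canonical(sequence, "hydropathy_profile")
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > len(sequence):
        raise ValueError(
            f"window {window} longer than sequence ({len(sequence)} residues)"
        )
    vals = np.array([KYTE_DOOLITTLE[aa] for aa in sequence])
    kernel = np.ones(window) / window
    means = np.convolve(vals, kernel, mode="valid")
    return HydropathyProfile(window, tuple(float(v) for v in means))


def instability_index(sequence: str) -> float:
    """Guruprasad instability index: (10/L) x sum of DIWV dipeptide weights."""
    _check_canonical(sequence, "instability_index")
    if len(sequence) < 2:
        raise ValueError("instability_index needs at least 2 residues")
    return float(ProteinAnalysis(sequence).instability_index())


def aliphatic_index(sequence: str) -> float:
    """AI = X_Ala + 2.9 * X_Val + 3.9 * (X_Ile + X_Leu), X in mole percent."""
    _check_canonical(sequence, "aliphatic_index")
    n = len(sequence)
    frac = {aa: 100.0 * sequence.count(aa) / n for aa in "AVIL"}
    return frac["A"] + 2.9 * frac["V"] + 3.9 * (frac["I"] + frac["L"])


def physchem_profile(protein: ProteinRecord) -> PhyschemProfile:
    """The full characterization row for one protein."""
    seq = protein.sequence
    pi = isoelectric_point(seq)
    insta = instability_index(seq)
    grav = gravy(seq)
    return PhyschemProfile(
        protein_id=protein.id,
        length=len(seq),
        mw=molecular_weight(seq),
        pi=pi,
        gravy=grav,
        instability=insta,
        aliphatic=aliphatic_index(seq),
        is_alkaline=pi > 7.0,
        is_unstable=insta > 40.0,
        is_hydrophobic=grav > 0.0,
    )
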