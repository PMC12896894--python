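"""Xylogen-like protein (XYLP) membership rule.

A chimeric AGP qualifies as an XYLP when three conditions hold together:

1. at least one PAST-rich region: a maximal union of windows of length
   >= ``l_min`` whose Pro/Ala/Ser/Thr fraction is >= ``theta`` (default 35%);
2. at least one AG glycomodule dipeptide (AP, PA, SP, PS, TP, PT) starting
   inside some PAST-rich region;
3. a non-specific lipid-transfer protein (nsLTP) scaffold of eight
   cysteines in the order C1-X-C2-X-P-X-C3C4-X-C5XC6-X-C7-X-C8: C3 and C4
   adjacent, exactly one residue between C5 and C6, at least one proline
   strictly between C2 and C3, and the remaining spacers within
   configurable bounds.

The single residue between C5 and C6 is typically hydrophobic (most often
leucine); it is annotated but never used as a filter, because natural
family members with other residues there exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import ProteinRecord

__all__ = [
    "PAST_RESIDUES",
    "GLYCOMODULE_DIPEPTIDES",
    "HYDROPHOBIC_RESIDUES",
    "PastRegion",
    "GlycomoduleHit",
    "LtpMotifMatch",
    "MotifBounds",
    "ClassifyConfig",
    "XylpCall",
    "past_fraction",
    "find_past_regions",
    "find_glycomodules",
    "match_nsltp_motif",
    "classify_xylp",
    "name_candidates",
]

PAST_RESIDUES = frozenset("PAST")
GLYCOMODULE_DIPEPTIDES = ("AP", "PA", "SP", "PS", "TP", "PT")
HYDROPHOBIC_RESIDUES = frozenset("LIVAFM")


@dataclass(frozen=True)
class PastRegion:
    """A PAST-rich stretch; positions are 1-based inclusive."""

    start: int
    end: int
    past_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class GlycomoduleHit:
    position: int       # 1-based start of the dipeptide
    dipeptide: str


@dataclass(frozen=True)
class LtpMotifMatch:
    cys_positions: tuple[int, ...]   # 8 strictly increasing 1-based positions
    spacer_lengths: tuple[int, ...]  # 7 residue counts between consecutive Cs
    inter56_residue: str
    inter56_hydrophobic: bool
    proline_position: int            # a Pro strictly between C2 and C3


@dataclass(frozen=True)
class MotifBounds:
    """Allowed residue counts for the variable X spacers of the scaffold.

    The fixed elements (C3C4 adjacent, single residue in C5XC6, Pro between
    C2 and C3) are hard constraints and not configurable.
    """

    c1_c2: tuple[int, int] = (5, 15)
    c2_c3: tuple[int, int] = (8, 20)
    c4_c5: tuple[int, int] = (5, 30)
    c6_c7: tuple[int, int] = (10, 30)
    c7_c8: tuple[int, int] = (3, 20)

    def __post_init__(self) -> None:
        for name in ("c1_c2", "c2_c3", "c4_c5", "c6_c7", "c7_c8"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"motif bound {name}: min {lo} > max {hi}")


@dataclass(frozen=True)
class ClassifyConfig:
    theta: float = 0.35
    l_min: int = 20
    bounds: MotifBounds = field(default_factory=MotifBounds)


@dataclass(frozen=True)
class XylpCall:
    protein_id: str
    past_regions: tuple[PastRegion, ...]
    glyco_hits: tuple[GlycomoduleHit, ...]
    motif: Optional[LtpMotifMatch]
    verdict: str                      # "XYLP" | "not_XYLP"
    reasons: tuple[str, ...]


def past_fraction(sequence: str, start: int, end: int) -> float:
    """PAST fraction of the 1-based inclusive window [start, end].

    'X' and other non-PAST letters count in the denominator only.
    """
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(
            f"window [{start},{end}] invalid for sequence of length {len(sequence)}"
        )
    window = sequence[start - 1:end]
    return sum(1 for aa in window if aa in PAST_RESIDUES) / len(window)


def find_past_regions(sequence: str, theta: float = 0.35,
                      l_min: int = 20) -> list[PastRegion]:
    """Maximal PAST-rich regions: union of all qualifying windows.

    A window qualifies when it is at least ``l_min`` residues long and its
    PAST fraction is >= ``theta`` (inclusive).  Positions covered by any
    qualifying window are merged into maximal runs, reported left to right
    with each run's own PAST fraction.
    """
    if not (0.0 < theta <= 1.0):
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    if l_min < 2:
        raise ValueError(f"l_min must be >= 2, got {l_min}")
    n = len(sequence)
    if n < l_min:
        return []
    # prefix[i] = number of PAST residues among the first i letters
    prefix = [0] * (n + 1)
    for i, aa in enumerate(sequence):
        prefix[i + 1] = prefix[i] + (aa in PAST_RESIDUES)
    # The union of all qualifying windows starting at s is [s, max_e(s)]
    # for the largest qualifying end, so coverage reduces to an interval
    # merge over per-start maximal windows (O(n^2) window checks).
    intervals: list[tuple[int, int]] = []
    for s in range(n):
        best_e = -1
        for e in range(s + l_min - 1, n):
            length = e - s + 1
            if (prefix[e + 1] - prefix[s]) >= theta * length - 1e-12:
                best_e = e
        if best_e >= 0:
            intervals.append((s, best_e))
    regions: list[PastRegion] = []
    for s, e in sorted(intervals):
        if regions and s <= regions[-1].end:  # regions[-1].end is 1-based
            last = regions.pop()
            s0, e0 = last.start - 1, max(last.end - 1, e)
        else:
            s0, e0 = s, e
        frac = (prefix[e0 + 1] - prefix[s0]) / (e0 - s0 + 1)
        regions.append(PastRegion(start=s0 + 1, end=e0 + 1, past_fraction=frac))
    return regions


def find_glycomodules(sequence: str,
                      region: PastRegion | None = None) -> list[GlycomoduleHit]:
    """All AG glycomodule dipeptides whose start lies in the given region.

    Overlapping occurrences are all reported, positions ascending.  With no
    region the full sequence is scanned.
    """
    lo = region.start if region else 1
    hi = min(region.end if region else len(sequence), len(sequence) - 1)
    if region and not (1 <= region.start <= region.end <= len(sequence)):
        raise ValueError("region outside sequence bounds")
    hits: list[GlycomoduleHit] = []
    for pos in range(lo, hi + 1):
        dip = sequence[pos - 1:pos + 1]
        if dip in GLYCOMODULE_DIPEPTIDES:
            hits.append(GlycomoduleHit(position=pos, dipeptide=dip))
    return hits


def _gap(a: int, b: int) -> int:
    """Residues strictly between positions a < b."""
    return b - a - 1


def match_nsltp_motif(sequence: str,
                      bounds: MotifBounds | None = None) -> Optional[LtpMotifMatch]:
    """Leftmost eight-cysteine nsLTP scaffold assignment, or None.

    The leftmost assignment is the lexicographically smallest tuple
    (C1, C2, ..., C8) satisfying all constraints; a depth-first search over
    cysteine positions in ascending order returns exactly that.
    """
    if bounds is None:
        bounds = MotifBounds()
    cys = [i + 1 for i, aa in enumerate(sequence) if aa == "C"]
    if len(cys) < 8:
        return None
    rng = {0: bounds.c1_c2, 1: bounds.c2_c3, 2: (0, 0), 3: bounds.c4_c5,
           4: (1, 1), 5: bounds.c6_c7, 6: bounds.c7_c8}

    def ok_link(idx: int, prev: int, nxt: int) -> bool:
        lo, hi = rng[idx]
        g = _gap(prev, nxt)
        if not (lo <= g <= hi):
            return False
        if idx == 1:  # Pro strictly between C2 and C3
            return "P" in sequence[prev:nxt - 1]
        return True

    def extend(assign: list[int], start_at: int) -> Optional[tuple[int, ...]]:
        if len(assign) == 8:
            return tuple(assign)
        link = len(assign) - 1
        for p in cys:
            if p <= assign[-1]:
                continue
            if _gap(assign[-1], p) > rng[link][1]:
                break  # cys sorted ascending; gap only grows
            if ok_link(link, assign[-1], p):
                out = extend(assign + [p], 0)
                if out is not None:
                    return out
        return None

    for c1 in cys:
        out = extend([c1], 0)
        if out is not None:
            c = out
            spacers = tuple(_gap(c[i], c[i + 1]) for i in range(7))
            inter56 = sequence[c[4]]  # single residue between C5 and C6
            pro = next(
                p for p in range(c[1] + 1, c[2])
                if sequence[p - 1] == "P"
            )
            return LtpMotifMatch(
                cys_positions=c,
                spacer_lengths=spacers,
                inter56_residue=inter56,
                inter56_hydrophobic=inter56 in HYDROPHOBIC_RESIDUES,
                proline_position=pro,
            )
    return None


def classify_xylp(protein: ProteinRecord,
                  config: ClassifyConfig | None = None) -> XylpCall:
    """Apply the three-part XYLP rule to one protein."""
    cfg = config or ClassifyConfig()
    regions = tuple(find_past_regions(protein.sequence, cfg.theta, cfg.l_min))
    hits: list[GlycomoduleHit] = []
    for region in regions:
        hits.extend(find_glycomodules(protein.sequence, region))
    hits_t = tuple(sorted(set(hits), key=lambda h: h.position))
    motif = match_nsltp_motif(protein.sequence, cfg.bounds)

    reasons: list[str] = []
    reasons.append("past_region" if regions else "no_past_region")
    reasons.append("glycomodule_in_region" if hits_t else "no_glycomodule_in_region")
    reasons.append("nsltp_motif" if motif else "no_nsltp_motif")
    verdict = "XYLP" if (regions and hits_t and motif) else "not_XYLP"
    return XylpCall(
        protein_id=protein.id, past_regions=regions, glyco_hits=hits_t,
        motif=motif, verdict=verdict, reasons=tuple(reasons),
    )


def name_candidates(calls: Sequence[XylpCall], prefix: str = "XYLP") -> dict[str, str]:
    """Name accepted proteins ``prefix``1..n in input order."""
    accepted = [c.protein_id for c in calls if c.verdict == "XYLP"]
    if not accepted:
        warnings.warn("no accepted XYLP candidates to name")
        return {}
    return {pid: f"{prefix}{i}" for i, pid in enumerate(accepted, start=1)}
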