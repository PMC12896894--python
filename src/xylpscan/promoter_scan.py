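"""Promoter extraction and IUPAC cis-element scanning with category rollups.

The scanner takes a named dictionary of IUPAC motifs (PlantCARE-style:
name, pattern, category, subcategory).  A small curated default dictionary
covering the commonly reported plant elements (ABRE variants, the MeJA
TGACG/CGTCA pair, gibberellin/auxin/SA/ethylene elements, meristem and
seed-storage elements, MYB/MYC/DRE/LTR/MBS/WUN stress elements and a few
light-responsive boxes) ships with the package; users supply their own TSV
for anything else.

Scanning is position-by-position on the plus strand by default, matching
how PlantCARE-style dictionaries list reverse-complement element pairs
(e.g. TGACG-motif and CGTCA-motif) as separate entries; both-strand mode
is available.  Overlapping matches are all counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core_io import GeneLocus, read_table

__all__ = [
    "IUPAC_DNA",
    "Motif",
    "PromoterHit",
    "PromoterSequence",
    "ElementCountTable",
    "load_motif_dictionary",
    "default_motif_dictionary",
    "reverse_complement",
    "extract_upstream",
    "scan_motifs",
    "count_by_category",
]

IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = ("growth_development", "phytohormone", "stress", "light", "other")


@dataclass(frozen=True)
class Motif:
    name: str
    pattern: str
    category: str
    subcategory: str = ""

    def __post_init__(self) -> None:
        for ch in self.pattern:
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"motif {self.name!r}: invalid IUPAC letter {ch!r}"
                )
        if self.category not in CATEGORIES:
            raise ValueError(
                f"motif {self.name!r}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class PromoterHit:
    gene_id: str
    motif_name: str
    strand: str   # "+" | "-"
    offset: int   # 1-based leftmost position of the matched segment


@dataclass(frozen=True)
class PromoterSequence:
    gene_id: str
    sequence: str
    truncated: bool = False


@dataclass
class ElementCountTable:
    counts: pd.DataFrame                  # genes x motifs
    category_totals: dict[str, int] = field(default_factory=dict)
    category_percent: dict[str, float] = field(default_factory=dict)
    empty: bool = False

    @property
    def grand_total(self) -> int:
        return int(sum(self.category_totals.values()))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_motif_dictionary(path: str | Path) -> list[Motif]:
    """Load a motif dictionary TSV: name, pattern, category, subcategory."""
    df = read_table(path, {"name": str, "pattern": str, "category": str})
    sub = df["subcategory"] if "subcategory" in df.columns else [""] * len(df)
    motifs = [
        Motif(n, p.upper(), c, "" if pd.isna(s) else str(s))
        for n, p, c, s in zip(df["name"], df["pattern"], df["category"], sub)
    ]
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names in dictionary")
    return motifs


def default_motif_dictionary() -> list[Motif]:
    """The curated default plant cis-element dictionary shipped with the package."""
    with resources.as_file(
        resources.files("xylpscan") / "data" / "plant_cis_elements.tsv"
    ) as p:
        return load_motif_dictionary(p)


def extract_upstream(genome: Mapping[str, str], locus: GeneLocus,
                     length: int = 2000) -> PromoterSequence:
    """The promoter window upstream of the translational start.

    Plus strand: the ``length`` bases ending immediately before the gene
    start.  Minus strand: the reverse complement of the bases immediately
    after the gene end.  Windows truncated at a chromosome boundary are
    flagged; a gene flush with the boundary yields an empty sequence with
    a warning.
    """
    if locus.chromosome not in genome:
        raise ValueError(f"chromosome {locus.chromosome!r} not in genome")
    chrom = genome[locus.chromosome].upper()
    if locus.strand == "+":
        hi = locus.start - 1            # last promoter base, 1-based
        lo = max(1, hi - length + 1)
        seq = chrom[lo - 1:hi]
        truncated = (hi - lo + 1) < length
    else:
        lo = locus.end + 1
        hi = min(len(chrom), locus.end + length)
        seq = reverse_complement(chrom[lo - 1:hi])
        truncated = (hi - lo + 1) < length
    if not seq:
        warnings.warn(f"gene {locus.gene_id}: no upstream sequence available")
        return PromoterSequence(locus.gene_id, "", truncated=True)
    return PromoterSequence(locus.gene_id, seq, truncated=truncated)


def _matches_at(seq: str, pattern: str, pos0: int) -> bool:
    for k, pch in enumerate(pattern):
        sch = seq[pos0 + k]
        if sch == "N":
            if pch != "N":
                return False
        elif sch not in IUPAC_DNA[pch]:
            return False
    return True


def scan_motifs(promoter: str | PromoterSequence,
                dictionary: Sequence[Motif],
                strands: str = "+",
                gene_id: str | None = None) -> list[PromoterHit]:
    """Every occurrence of every dictionary motif in the promoter.

    ``strands`` is ``"+"`` (default) or ``"both"``.  An ``N`` in the
    promoter matches only a pattern ``N``.  Minus-strand hits are found by
    matching against the reverse complement and reported at the leftmost
    original coordinate of the matched segment.
    """
    if isinstance(promoter, PromoterSequence):
        gene_id = gene_id or promoter.gene_id
        seq = promoter.sequence.upper()
    else:
        seq = promoter.upper()
        gene_id = gene_id or ""
    if strands not in {"+", "both"}:
        raise ValueError(f"strands must be '+' or 'both', got {strands!r}")
    L = len(seq)
    rc = reverse_complement(seq)
    hits: list[PromoterHit] = []
    for motif in dictionary:
        m = len(motif.pattern)
        if m == 0 or m > L:
            continue
        literal = all(len(IUPAC_DNA[c]) == 1 for c in motif.pattern)
        for target, strand in ((seq, "+"), (rc, "-")):
            if strand == "-" and strands != "both":
                continue
            if literal:
                # exact substring search; a promoter 'N' can never equal a
                # concrete base, so semantics match the general matcher
                pos0 = target.find(motif.pattern)
                positions = []
                while pos0 != -1:
                    positions.append(pos0)
                    pos0 = target.find(motif.pattern, pos0 + 1)
            else:
                positions = [p for p in range(L - m + 1)
                             if _matches_at(target, motif.pattern, p)]
            for pos0 in positions:
                offset = pos0 + 1 if strand == "+" else L - pos0 - m + 1
                hits.append(PromoterHit(gene_id, motif.name, strand, offset))
    hits.sort(key=lambda h: (h.motif_name, h.strand, h.offset))
    return hits


def count_by_category(hits: Sequence[PromoterHit],
                      dictionary: Sequence[Motif]) -> ElementCountTable:
    """Gene x motif count matrix plus per-category totals and percentages."""
    by_name = {m.name: m for m in dictionary}
    for h in hits:
        if h.motif_name not in by_name:
            raise ValueError(f"hit references unknown motif {h.motif_name!r}")
    genes = sorted({h.gene_id for h in hits})
    names = [m.name for m in dictionary]
    counts = pd.DataFrame(0, index=genes, columns=names, dtype=int)
    for h in hits:
        counts.loc[h.gene_id, h.motif_name] += 1
    totals = {c: 0 for c in CATEGORIES}
    for name in names:
        totals[by_name[name].category] += int(counts[name].sum())
    grand = sum(totals.values())
    if grand == 0:
        percent = {c: 0.0 for c in CATEGORIES}
        return ElementCountTable(counts, totals, percent, empty=True)
    percent = {c: 100.0 * v / grand for c, v in totals.items()}
    return ElementCountTable(counts, totals, percent, empty=False)
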