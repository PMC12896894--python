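"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes an operation's expected output by direct
enumeration or closed form, deliberately sharing no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils.IsoelectricPoint import (
    negative_pKs, pKcterminal, pKnterminal, positive_pKs,
)

PAST = set("PAST")
_STOPS = set(standard_dna_table.stop_codons)


def brute_force_past_regions(seq: str, theta: float = 0.35,
                             l_min: int = 20) -> list[tuple[int, int]]:
    """Union of all windows >= l_min with PAST fraction >= theta.

    Marks every position covered by any qualifying window, then reads off
    maximal runs as 1-based inclusive (start, end) intervals.
    """
    n = len(seq)
    is_past = np.array([c in PAST for c in seq], dtype=float)
    covered = np.zeros(n, dtype=bool)
    for s in range(n):
        running = 0.0
        for e in range(s, n):
            running += is_past[e]
            length = e - s + 1
            if length >= l_min and running / length >= theta - 1e-12:
                covered[s:e + 1] = True
    regions = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j + 1 < n and covered[j + 1]:
                j += 1
            regions.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return regions


def exhaustive_nsltp_assignment(seq: str, bounds=None) -> tuple[int, ...] | None:
    """Smallest valid 8-cysteine assignment by full combination enumeration."""
    if bounds is None:
        spans = {0: (5, 15), 1: (8, 20), 2: (0, 0), 3: (5, 30), 4: (1, 1),
                 5: (10, 30), 6: (3, 20)}
    else:
        spans = {0: bounds.c1_c2, 1: bounds.c2_c3, 2: (0, 0), 3: bounds.c4_c5,
                 4: (1, 1), 5: bounds.c6_c7, 6: bounds.c7_c8}
    cys = [i + 1 for i, aa in enumerate(seq) if aa == "C"]
    best = None
    for combo in itertools.combinations(cys, 8):
        ok = True
        for k in range(7):
            gap = combo[k + 1] - combo[k] - 1
            lo, hi = spans[k]
            if not (lo <= gap <= hi):
                ok = False
                break
            if k == 1 and "P" not in seq[combo[1]:combo[2] - 1]:
                ok = False
                break
        if ok and (best is None or combo < best):
            best = combo
    return best


_IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]",
    "M": "[AC]", "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGTN]",
}


def regex_iupac_hits(seq: str, pattern: str) -> list[int]:
    """1-based plus-strand match offsets via regex lookahead (overlaps kept)."""
    rx = re.compile("(?=" + "".join(_IUPAC_RE[c] for c in pattern) + ")")
    return [m.start() + 1 for m in rx.finditer(seq)]


def grid_search_pi(seq: str, step: float = 0.001) -> float:
    """0.001-step grid argmin of |net charge| over pH 0..14.

    The Bjellqvist charge model is rebuilt here directly from the
    published pKa tables (vectorized over the whole grid).
    """
    grid = np.arange(0.0, 14.0 + step / 2, step)
    charge = np.zeros_like(grid)
    counts: dict[str, int] = {}
    for aa in seq:
        counts[aa] = counts.get(aa, 0) + 1
    nterm_pk = pKnterminal.get(seq[0], positive_pKs["Nterm"])
    cterm_pk = pKcterminal.get(seq[-1], negative_pKs["Cterm"])
    charge += 1.0 / (1.0 + 10.0 ** (grid - nterm_pk))
    for aa, pk in positive_pKs.items():
        if aa == "Nterm":
            continue
        charge += counts.get(aa, 0) / (1.0 + 10.0 ** (grid - pk))
    charge -= 1.0 / (1.0 + 10.0 ** (cterm_pk - grid))
    for aa, pk in negative_pKs.items():
        if aa == "Cterm":
            continue
        charge -= counts.get(aa, 0) / (1.0 + 10.0 ** (pk - grid))
    return float(grid[np.argmin(np.abs(charge))])


def _aa_of(codon: str) -> str:
    return "*" if codon in _STOPS else standard_dna_table.forward_table[codon]


def ng86_codon_oracle(c1: str, c2: str):
    """(s_sites_avg, sd, nd) for one codon pair by explicit enumeration."""
    def sites(codon):
        aa = _aa_of(codon)
        s = 0.0
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if aa != "*" and _aa_of(alt) == aa:
                    s += 1 / 3
        return s

    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths, blocked = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, valid = c1, 0.0, 0.0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa_of(cur) == "*" or _aa_of(nxt) == "*":
                valid = False
                nd += 1
            elif _aa_of(cur) == _aa_of(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (paths if valid else blocked).append((sd, nd))
    use = paths or blocked
    sd = sum(p[0] for p in use) / len(use) if use else 0.0
    nd = sum(p[1] for p in use) / len(use) if use else 0.0
    return (sites(c1) + sites(c2)) / 2.0, sd, nd


def tree_path_lengths(tree, taxa):
    """Pairwise leaf-to-leaf path lengths of a dendropy tree as an array."""
    pdm = tree.phylogenetic_distance_matrix()
    tn = tree.taxon_namespace
    n = len(taxa)
    out = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                out[i, j] = pdm.patristic_distance(tn.get_taxon(a),
                                                   tn.get_taxon(b))
    return out
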