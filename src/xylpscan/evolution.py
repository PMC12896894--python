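"""Phylogeny, Ka/Ks and duplication-mode analysis.

* Poisson-corrected amino-acid distances with pairwise deletion.
* Neighbor-joining (Saitou-Nei) with deterministic taxon-name tie-breaks,
  negative branch lengths clamped to zero, and column-bootstrap support.
* Nei-Gojobori (1986) Ka/Ks with pathway averaging and Jukes-Cantor
  correction; pairs with pS >= 0.75 (or pN >= 0.75, the same singularity)
  or Ks = 0 are reported as N/A rather than given an unreliable ratio.
* Tandem / segmental / dispersed duplication labels from gene ranks and
  longest collinear chains (MCScanX-style match size and gap limits).

Trees are dendropy objects throughout, so Newick round-trips and
bipartition bookkeeping use a standard library rather than ad hoc code.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .core_io import GeneLocus, Msa

__all__ = [
    "DistanceMatrix",
    "KaKsResult",
    "DuplicationCall",
    "poisson_distance",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
    "back_translate_alignment",
    "ng86_kaks",
    "classify_duplications",
]

_STOPS = set(standard_dna_table.stop_codons)
_NT = "ACGT"


def _translate_codon(codon: str) -> str:
    return "*" if codon in _STOPS else standard_dna_table.forward_table[codon]


# --------------------------------------------------------------------------
# distances and trees
# --------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with saturated pairs flagged."""

    taxa: tuple[str, ...]
    d: np.ndarray
    saturated: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def poisson_distance(msa: Msa, cap: float = 10.0) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) under pairwise deletion.

    p is the mismatch fraction over alignment columns where both rows are
    ungapped.  A pair with p = 1 cannot be corrected and is assigned
    ``cap`` and flagged saturated.
    """
    if len(msa.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    n = len(msa.taxa)
    d = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i, j in itertools.combinations(range(n), 2):
        ri, rj = msa.rows[i], msa.rows[j]
        shared = mism = 0
        for a, b in zip(ri, rj):
            if a != "-" and b != "-":
                shared += 1
                if a != b:
                    mism += 1
        if shared == 0:
            raise ValueError(
                f"no shared ungapped sites for pair ({msa.taxa[i]}, {msa.taxa[j]})"
            )
        p = mism / shared
        if p >= 1.0:
            dist = cap
            saturated.add((msa.taxa[i], msa.taxa[j]))
        else:
            dist = -math.log(1.0 - p)
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(msa.taxa), d, frozenset(saturated))


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster labels (a cluster is labelled by its smallest leaf
    name), so the topology is a deterministic function of the input.
    Negative branch lengths are clamped to zero and counted on the
    returned tree as ``tree.n_clamped_branches``.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa for a tree")
    taxon_ns = dendropy.TaxonNamespace(sorted(dm.taxa))
    nodes: dict[str, dendropy.Node] = {}
    for name in dm.taxa:
        node = dendropy.Node()
        node.taxon = taxon_ns.get_taxon(name)
        nodes[name] = node
    # active clusters keyed by smallest member leaf name
    dist: dict[frozenset[str], float] = {}
    active: list[str] = sorted(dm.taxa)
    for a, b in itertools.combinations(dm.taxa, 2):
        dist[frozenset((a, b))] = dm.get(a, b)
    clamped = 0

    def d_of(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 2:
        m = len(active)
        r = {a: sum(d_of(a, b) for b in active if b != a) for a in active}
        best: Optional[tuple[float, str, str]] = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * d_of(a, b) - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        dab = d_of(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            la, clamped = 0.0, clamped + 1
        if lb < 0:
            lb, clamped = 0.0, clamped + 1
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        new_label = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_label, c))] = 0.5 * (d_of(a, c) + d_of(b, c) - dab)
        active = sorted(c for c in active if c not in (a, b)) + [new_label]
        active = sorted(set(active))
        nodes[new_label] = parent
    a, b = active
    root = dendropy.Node()
    # place the final edge on the unrooted tree: attach b under a's node's
    # parent structure via a basal trifurcation when possible
    na, nb = nodes[a], nodes[b]
    dab = max(d_of(a, b), 0.0)
    if not na.child_nodes() and nb.child_nodes():
        na, nb = nb, na
    if na.child_nodes():
        # use the last joined cluster as the seed: its two children plus b
        for child in list(na.child_nodes()):
            na.remove_child(child)
            root.add_child(child)
        root.add_child(nb)
        nb.edge.length = dab
    else:
        root.add_child(na)
        root.add_child(nb)
        na.edge.length = dab / 2
        nb.edge.length = dab / 2
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    tree.n_clamped_branches = clamped
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the smaller-side leaf-name sets.

    Each internal edge splits the leaves in two; the split is recorded as a
    frozenset of the side not containing the alphabetically first leaf, so
    representation is rooting-independent.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else frozenset(leaves - below)
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def bootstrap_support(msa: Msa, B: int = 1000,
                      seed: int | None = None) -> dendropy.Tree:
    """NJ tree with column-bootstrap support percentages on internal edges.

    ``B`` replicates resample alignment columns with replacement (equal
    width); support for each internal bipartition of the full-data tree is
    the percentage of replicate trees containing it.  Internal node labels
    carry the rounded integer support; exact floats are on
    ``node.support``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(msa.taxa) < 4:
        raise ValueError("need at least 4 taxa for bootstrap support")
    main = nj_tree(poisson_distance(msa))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_bipartitions(main)}
    rng = np.random.default_rng(seed)
    L = msa.n_sites
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep_rows = tuple("".join(row[c] for c in cols) for row in msa.rows)
        rep = Msa(msa.taxa, rep_rows)
        rep_splits = tree_bipartitions(nj_tree(poisson_distance(rep)))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    leaves = {lf.taxon.label for lf in main.leaf_node_iter()}
    anchor = min(leaves)
    for node in main.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else frozenset(leaves - below)
        if side in counts:
            sup = 100.0 * counts[side] / B
            node.support = sup
            node.label = str(int(round(sup)))
    main.bootstrap_b = B
    main.bootstrap_seed = seed
    return main


# --------------------------------------------------------------------------
# Ka/Ks (Nei-Gojobori 1986 with Jukes-Cantor correction)
# --------------------------------------------------------------------------

def back_translate_alignment(protein_msa: Msa,
                             cds: Mapping[str, str]) -> Msa:
    """Expand a protein alignment to codons using each taxon's CDS.

    Each CDS must translate (standard code) to its ungapped protein row; a
    single terminal stop codon is stripped before checking.  Protein gaps
    become ``---``.
    """
    rows: list[str] = []
    for taxon, prow in zip(protein_msa.taxa, protein_msa.rows):
        if taxon not in cds:
            raise ValueError(f"no CDS provided for taxon {taxon!r}")
        seq = cds[taxon].upper().replace("U", "T")
        ungapped = prow.replace("-", "")
        if len(seq) == 3 * (len(ungapped) + 1) and seq[-3:] in _STOPS:
            seq = seq[:-3]
        if len(seq) != 3 * len(ungapped):
            raise ValueError(
                f"taxon {taxon!r}: CDS length {len(seq)} does not match "
                f"{len(ungapped)} residues"
            )
        translated = str(Seq(seq).translate())
        for i, (aa_cds, aa_msa) in enumerate(zip(translated, ungapped), start=1):
            if aa_cds != aa_msa:
                raise ValueError(
                    f"taxon {taxon!r}: translation mismatch at residue {i} "
                    f"({aa_cds} vs {aa_msa})"
                )
        codons = [seq[3 * i:3 * i + 3] for i in range(len(ungapped))]
        out = []
        k = 0
        for aa in prow:
            if aa == "-":
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        rows.append("".join(out))
    return Msa(protein_msa.taxa, tuple(rows))


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: Optional[float]
    ka: Optional[float]
    ratio: Optional[float]
    na_reason: Optional[str] = None
    n_codons: int = 0


def _syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one codon.

    Changes creating a stop codon count as nonsynonymous, so the two
    counts always sum to 3.
    """
    aa = _translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        s = 0
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if _translate_codon(alt) == aa and aa != "*":
                s += 1
        syn += s / 3.0
    return syn, 3.0 - syn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous steps over substitution pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    is blocked, all pathways are used with stop steps scored
    nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    blocked_results = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            a1, a2 = _translate_codon(cur), _translate_codon(nxt)
            if a2 == "*" or a1 == "*":
                valid = False
            if a1 == a2 and a1 != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        (results if valid else blocked_results).append((sd, nd))
    use = results or blocked_results
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def _jc_correct(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


_AMBIG = set("-NRYSWKMBDHVX")


def ng86_kaks(cds1: str, cds2: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for an aligned codon pair.

    Site counts are averaged over both sequences; difference counts are
    pathway-averaged per codon.  pS and pN are Jukes-Cantor corrected to
    Ks and Ka.  The ratio is N/A when pS >= 0.75, pN >= 0.75 (correction
    singularity / saturation) or Ks = 0.
    """
    c1, c2 = cds1.upper(), cds2.upper()
    if len(c1) != len(c2):
        raise ValueError("aligned codon sequences differ in length")
    if len(c1) % 3 != 0:
        raise ValueError(f"length {len(c1)} is not a multiple of 3")
    S1 = N1 = S2 = N2 = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(c1), 3):
        a, b = c1[i:i + 3], c2[i:i + 3]
        if _AMBIG.intersection(a) or _AMBIG.intersection(b):
            continue
        if a in _STOPS or b in _STOPS:
            continue
        n_codons += 1
        s1, nn1 = _syn_nonsyn_sites(a)
        s2, nn2 = _syn_nonsyn_sites(b)
        S1 += s1
        N1 += nn1
        S2 += s2
        N2 += nn2
        dsd, dnd = _pathway_differences(a, b)
        sd += dsd
        nd += dnd
    S = (S1 + S2) / 2.0
    N = (N1 + N2) / 2.0
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    ratio: Optional[float] = None
    na_reason: Optional[str] = None
    if ps >= 0.75:
        na_reason = "pS >= 0.75"
    elif pn >= 0.75:
        na_reason = "pN >= 0.75"
    elif ks == 0.0:
        na_reason = "Ks = 0"
    else:
        ratio = ka / ks
    return KaKsResult(S=S, N=N, sd=sd, nd=nd, ps=ps, pn=pn, ks=ks, ka=ka,
                      ratio=ratio, na_reason=na_reason, n_codons=n_codons)


# --------------------------------------------------------------------------
# duplication-mode classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationCall:
    pair: tuple[str, str]
    mode: str                      # "tandem" | "segmental" | "dispersed"
    chain_id: Optional[int] = None
    chain_length: Optional[int] = None


def _longest_chains(anchors: list[tuple[int, int, int]], match_size: int,
                    max_gaps: int) -> dict[int, tuple[int, int]]:
    """Greedy extraction of longest strictly-monotone anchor chains.

    ``anchors`` holds (x_rank, y_rank, pair_index).  Both orientations are
    tried; consecutive anchors must advance on both axes with at most
    ``max_gaps`` skipped ranks between them.  Returns pair_index ->
    (chain_id, chain_length) for pairs in chains of >= match_size anchors.
    """
    assigned: dict[int, tuple[int, int]] = {}
    remaining = list(anchors)
    chain_id = 0
    while True:
        best_chain: list[tuple[int, int, int]] = []
        for sign in (1, -1):
            pts = sorted(remaining, key=lambda t: (t[0], sign * t[1]))
            n = len(pts)
            f = [1] * n
            prev = [-1] * n
            for i in range(n):
                xi, yi = pts[i][0], sign * pts[i][1]
                for j in range(i):
                    xj, yj = pts[j][0], sign * pts[j][1]
                    if (xj < xi and yj < yi
                            and xi - xj - 1 <= max_gaps
                            and yi - yj - 1 <= max_gaps
                            and f[j] + 1 > f[i]):
                        f[i] = f[j] + 1
                        prev[i] = j
            if n:
                end = max(range(n), key=lambda i: (f[i], -pts[i][0], -pts[i][1]))
                chain = []
                k = end
                while k != -1:
                    chain.append(pts[k])
                    k = prev[k]
                chain.reverse()
                if len(chain) > len(best_chain):
                    best_chain = chain
        if len(best_chain) < match_size:
            break
        chain_id += 1
        for anc in best_chain:
            assigned[anc[2]] = (chain_id, len(best_chain))
            remaining.remove(anc)
    return assigned


def classify_duplications(loci: Sequence[GeneLocus],
                          pairs: Sequence[tuple[str, str]],
                          match_size: int = 5,
                          max_gaps: int = 25,
                          tandem_window: int = 2) -> list[DuplicationCall]:
    """Label homologous gene pairs as tandem, segmental or dispersed.

    Tandem: same chromosome and rank distance <= ``tandem_window``.
    Segmental: member of a collinear chain of >= ``match_size`` anchors
    (strictly increasing ranks on both chromosomes, either orientation,
    with <= ``max_gaps`` genes skipped between consecutive anchors).
    Everything else is dispersed.
    """
    by_id = {l.gene_id: l for l in loci}
    for a, b in pairs:
        for g in (a, b):
            if g not in by_id:
                raise ValueError(f"unknown gene {g!r} in homolog pair")
    calls: dict[int, DuplicationCall] = {}
    # group non-tandem pairs by (unordered) chromosome pair
    groups: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for idx, (a, b) in enumerate(pairs):
        la, lb = by_id[a], by_id[b]
        if (la.chromosome == lb.chromosome
                and abs(la.rank - lb.rank) <= tandem_window):
            calls[idx] = DuplicationCall(pair=(a, b), mode="tandem")
            continue
        if (la.chromosome, la.rank) > (lb.chromosome, lb.rank):
            la, lb = lb, la
        key = (la.chromosome, lb.chromosome)
        groups.setdefault(key, []).append((la.rank, lb.rank, idx))
    next_chain = 0
    for key in sorted(groups):
        assigned = _longest_chains(groups[key], match_size, max_gaps)
        local_ids = sorted({cid for cid, _ in assigned.values()})
        remap = {cid: next_chain + i + 1 for i, cid in enumerate(local_ids)}
        next_chain += len(local_ids)
        for rank_a, rank_b, idx in groups[key]:
            if idx in assigned:
                cid, clen = assigned[idx]
                calls[idx] = DuplicationCall(
                    pair=pairs[idx], mode="segmental",
                    chain_id=remap[cid], chain_length=clen,
                )
            else:
                calls[idx] = DuplicationCall(pair=pairs[idx], mode="dispersed")
    return [calls[i] for i in range(len(pairs))]
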