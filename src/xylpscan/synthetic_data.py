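"""Seeded generators emulating the pipeline's inputs, with ground truth.

Each generator plants structure a downstream stage must recover — XYLP
proteins among decoys, codon pairs with known substitution composition,
alignments evolved on a known tree, chromosomes with tandem/collinear
duplicate layouts, promoters with known motif counts, Ct tables with known
fold changes — and returns the planted truth alongside the data.  All
randomness flows through one ``numpy.random.default_rng(seed)``, so
regeneration from the same seed is byte-identical.

Background residue and nucleotide draws are uniform over restricted
alphabets with rejection filters (documented per generator) so that
accidental rule matches are impossible or vanishingly rare and always
checked.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .core_io import GeneLocus, Msa, ProteinRecord
from .promoter_scan import IUPAC_DNA, Motif, scan_motifs
from .xylp_classify import GLYCOMODULE_DIPEPTIDES

__all__ = [
    "ProteomeTruth",
    "CodonPairTruth",
    "LayoutResult",
    "PromoterTruth",
    "CtTruth",
    "gen_xylp_proteome",
    "gen_codon_pair",
    "gen_msa_on_tree",
    "gen_genome_layout",
    "gen_promoter_set",
    "gen_ct_table",
]

# PAST-free, cysteine-free background alphabet: backgrounds can never form
# a PAST-rich window nor an eight-cysteine scaffold.
_BG_ALPHABET = "DEFGHIKLMNQRVWY"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = set(standard_dna_table.stop_codons)


def _rand_str(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


# --------------------------------------------------------------------------
# proteome with planted XYLPs and decoys
# --------------------------------------------------------------------------

@dataclass
class ProteomeTruth:
    xylp_ids: list[str]
    decoy_past_ids: list[str]     # PAST region + glycomodules, no scaffold
    decoy_motif_ids: list[str]    # scaffold, no PAST region
    background_ids: list[str]
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    cys_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)


def _past_block(rng: np.random.Generator) -> str:
    """A 30-60 residue all-PAST block tiled from glycomodule dipeptides."""
    n_dip = int(rng.integers(15, 31))
    return "".join(rng.choice(GLYCOMODULE_DIPEPTIDES, size=n_dip))


def _nsltp_scaffold(rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
    """An eight-cysteine scaffold with mid-range spacers (1-based positions)."""
    g = [int(rng.integers(7, 13)),    # C1-C2 within [5,15]
         int(rng.integers(10, 17)),   # C2-C3 within [8,20]
         0,                           # C3C4 adjacent
         int(rng.integers(10, 21)),   # C4-C5 within [5,30]
         1,                           # C5XC6
         int(rng.integers(14, 26)),   # C6-C7 within [10,30]
         int(rng.integers(5, 16))]    # C7-C8 within [3,20]
    fill = lambda n: _rand_str(rng, _BG_ALPHABET, n)
    s2 = list(fill(g[1]))
    s2[int(rng.integers(0, g[1]))] = "P"   # Pro strictly between C2 and C3
    inter56 = str(rng.choice(list("LIVAFM"), p=[0.5, 0.1, 0.1, 0.1, 0.1, 0.1]))
    parts = ["C", fill(g[0]), "C", "".join(s2), "CC", fill(g[3]), "C",
             inter56, "C", fill(g[5]), "C", fill(g[6]), "C"]
    seq = "".join(parts)
    cys = tuple(i + 1 for i, aa in enumerate(seq) if aa == "C")
    return seq, cys


def gen_xylp_proteome(seed: int, n_background: int = 50, n_xylp: int = 8,
                      n_decoy_past: int = 5, n_decoy_motif: int = 5,
                      ) -> tuple[list[ProteinRecord], ProteomeTruth]:
    """A proteome of PAST-poor backgrounds, planted XYLPs and one-rule decoys.

    Planted XYLPs carry a fully PAST (fraction 1.0) region of 30-60
    residues tiled from glycomodule dipeptides plus a cysteine scaffold
    that satisfies the default spacer bounds.  Each decoy violates exactly
    one rule; backgrounds contain neither PAST residues nor cysteines.
    """
    rng = np.random.default_rng(seed)
    truth = ProteomeTruth([], [], [], [])
    records: list[ProteinRecord] = []

    for i in range(n_xylp):
        pid = f"xylp_{i + 1}"
        flank = _rand_str(rng, _BG_ALPHABET, int(rng.integers(20, 41)))
        block = _past_block(rng)
        mid = _rand_str(rng, _BG_ALPHABET, int(rng.integers(5, 16)))
        scaffold, cys_local = _nsltp_scaffold(rng)
        tail = _rand_str(rng, _BG_ALPHABET, int(rng.integers(10, 31)))
        seq = flank + block + mid + scaffold + tail
        start = len(flank) + 1
        truth.xylp_ids.append(pid)
        truth.regions[pid] = (start, start + len(block) - 1)
        off = len(flank) + len(block) + len(mid)
        truth.cys_positions[pid] = tuple(off + p for p in cys_local)
        records.append(ProteinRecord(pid, seq, "planted XYLP"))

    for i in range(n_decoy_past):
        pid = f"decoypast_{i + 1}"
        seq = (_rand_str(rng, _BG_ALPHABET, int(rng.integers(20, 41)))
               + _past_block(rng)
               + _rand_str(rng, _BG_ALPHABET, int(rng.integers(20, 41))))
        truth.decoy_past_ids.append(pid)
        records.append(ProteinRecord(pid, seq, "decoy: no nsLTP scaffold"))

    for i in range(n_decoy_motif):
        pid = f"decoymotif_{i + 1}"
        scaffold, _ = _nsltp_scaffold(rng)
        seq = (_rand_str(rng, _BG_ALPHABET, int(rng.integers(20, 41)))
               + scaffold
               + _rand_str(rng, _BG_ALPHABET, int(rng.integers(10, 31))))
        truth.decoy_motif_ids.append(pid)
        records.append(ProteinRecord(pid, seq, "decoy: no PAST region"))

    for i in range(n_background):
        pid = f"bg_{i + 1}"
        seq = _rand_str(rng, _BG_ALPHABET, int(rng.integers(120, 221)))
        truth.background_ids.append(pid)
        records.append(ProteinRecord(pid, seq, "background"))

    order = rng.permutation(len(records))
    return [records[i] for i in order], truth


# --------------------------------------------------------------------------
# codon pair with planted substitution composition
# --------------------------------------------------------------------------

@dataclass
class CodonPairTruth:
    syn_subs: int
    nonsyn_subs: int
    syn_codons: list[int]      # 0-based codon indices
    nonsyn_codons: list[int]


def _codon_alternatives(codon: str) -> tuple[list[str], list[str]]:
    """Single-nucleotide, non-stop alternatives split syn/nonsyn."""
    aa = standard_dna_table.forward_table.get(codon)
    syn, non = [], []
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in _STOPS:
                continue
            (syn if standard_dna_table.forward_table[alt] == aa else non).append(alt)
    return syn, non


_VERSATILE_CODONS = sorted(
    c for c in standard_dna_table.forward_table
    if _codon_alternatives(c)[0] and _codon_alternatives(c)[1]
)


def gen_codon_pair(seed: int, n_codons: int = 200, syn_subs: int = 5,
                   nonsyn_subs: int = 5) -> tuple[str, str, CodonPairTruth]:
    """An ancestral CDS and a derived copy with exact substitution counts.

    The ancestor is drawn from codons that allow both a synonymous and a
    nonsynonymous single-nucleotide change; each requested substitution
    hits a distinct codon, so the planted (syn, nonsyn) counts are exactly
    the NG86 difference counts.
    """
    if syn_subs + nonsyn_subs > n_codons:
        raise ValueError(
            f"cannot place {syn_subs}+{nonsyn_subs} substitutions in "
            f"{n_codons} codons (one per codon)"
        )
    rng = np.random.default_rng(seed)
    codons = list(rng.choice(_VERSATILE_CODONS, size=n_codons))
    anc = "".join(codons)
    chosen = rng.choice(n_codons, size=syn_subs + nonsyn_subs, replace=False)
    syn_idx = sorted(int(i) for i in chosen[:syn_subs])
    non_idx = sorted(int(i) for i in chosen[syn_subs:])
    derived = codons.copy()
    for i in syn_idx:
        alts = _codon_alternatives(codons[i])[0]
        derived[i] = str(rng.choice(alts))
    for i in non_idx:
        alts = _codon_alternatives(codons[i])[1]
        derived[i] = str(rng.choice(alts))
    truth = CodonPairTruth(syn_subs, nonsyn_subs, syn_idx, non_idx)
    return anc, "".join(derived), truth


# --------------------------------------------------------------------------
# alignment evolved on a tree
# --------------------------------------------------------------------------

def gen_msa_on_tree(seed: int, tree: dendropy.Tree, length: int = 500) -> Msa:
    """Evolve an alignment along a tree by Poisson substitution.

    Branch lengths are expected substitutions per site.  Each site on each
    branch receives a Poisson(b) number of events; every event replaces
    the residue uniformly with one of the other 19, so zero-length
    branches copy their parent exactly.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(_AA20))
    root_seq = rng.integers(0, 20, size=length)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    leaf_rows: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            current = root_seq
        else:
            parent = seqs[id(node.parent_node)]
            b = node.edge.length or 0.0
            current = parent.copy()
            n_events = rng.poisson(b, size=length)
            for site in np.nonzero(n_events)[0]:
                state = current[site]
                for _ in range(n_events[site]):
                    step = int(rng.integers(0, 19))
                    state = step if step < state else step + 1
                current[site] = state
            seqs[id(node)] = current
        if node.is_leaf():
            leaf_rows[node.taxon.label] = "".join(aa[current])
    taxa = tuple(sorted(leaf_rows))
    return Msa(taxa, tuple(leaf_rows[t] for t in taxa))


# --------------------------------------------------------------------------
# genome layout with planted duplication structure
# --------------------------------------------------------------------------

@dataclass
class LayoutResult:
    loci: list[GeneLocus]
    pairs: list[tuple[str, str]]
    modes: dict[tuple[str, str], str]        # planted mode per pair
    chains: list[list[tuple[str, str]]]      # planted collinear blocks

    def gff_text(self) -> str:
        lines = ["##gff-version 3"]
        for l in sorted(self.loci, key=lambda x: (x.chromosome, x.start)):
            lines.append("\t".join([
                l.chromosome, "synth", "gene", str(l.start), str(l.end),
                ".", l.strand, ".", f"ID={l.gene_id}",
            ]))
            for k, (a, b) in enumerate(l.exon_intervals, start=1):
                lines.append("\t".join([
                    l.chromosome, "synth", "exon", str(a), str(b), ".",
                    l.strand, ".", f"ID={l.gene_id}.exon{k};Parent={l.gene_id}",
                ]))
        return "\n".join(lines) + "\n"

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["gene_a", "gene_b"])


def _make_exons(start: int, end: int, n_ex: int) -> tuple[tuple[int, int], ...]:
    span = end - start + 1
    block = max(span // (2 * n_ex - 1), 1)
    exons = []
    for i in range(n_ex):
        a = start + 2 * i * block
        b = end if i == n_ex - 1 else a + block - 1
        exons.append((a, min(b, end)))
    return tuple(exons)


def gen_genome_layout(seed: int, n_chrom: int = 5, genes_per_chrom: int = 40,
                      n_tandem: int = 3, n_collinear_blocks: int = 2,
                      block_size: int = 6, n_dispersed: int = 3,
                      ) -> LayoutResult:
    """Chromosomes with planted tandem, collinear-block and dispersed pairs.

    Collinear blocks are order-preserving runs of ``block_size`` anchors
    between two chromosomes; tandem pairs are rank-adjacent on one
    chromosome; dispersed pairs are isolated cross-chromosome anchors on
    chromosome pairs no block uses.  Gene starts increase with rank, so
    ranks recovered from the GFF equal the planted ranks.
    """
    rng = np.random.default_rng(seed)
    loci: list[GeneLocus] = []
    gid = lambda c, r: f"c{c}g{r:03d}"
    for c in range(1, n_chrom + 1):
        for r in range(1, genes_per_chrom + 1):
            start = 500 + (r - 1) * 3000 + int(rng.integers(0, 500))
            length = int(rng.integers(600, 1501))
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 5))
            loci.append(GeneLocus(
                gene_id=gid(c, r), chromosome=f"chr{c}", start=start, end=end,
                strand=strand, rank=r, exon_intervals=_make_exons(start, end, n_ex),
            ))
    used: dict[int, set[int]] = {c: set() for c in range(1, n_chrom + 1)}

    def claim_run(c: int, size: int) -> int:
        for _ in range(200):
            r0 = int(rng.integers(1, genes_per_chrom - size + 2))
            if all(r not in used[c] for r in range(r0, r0 + size)):
                used[c].update(range(r0, r0 + size))
                return r0
        raise RuntimeError("could not place planted structure; too crowded")

    pairs: list[tuple[str, str]] = []
    modes: dict[tuple[str, str], str] = {}
    chains: list[list[tuple[str, str]]] = []
    chrom_pairs = list(itertools.combinations(range(1, n_chrom + 1), 2))
    rng.shuffle(chrom_pairs)
    if n_collinear_blocks + n_dispersed > len(chrom_pairs):
        raise ValueError("not enough chromosome pairs for the requested plants")
    block_chrom_pairs = chrom_pairs[:n_collinear_blocks]
    disp_chrom_pairs = chrom_pairs[n_collinear_blocks:
                                   n_collinear_blocks + n_dispersed]
    for (ca, cb) in block_chrom_pairs:
        a0 = claim_run(ca, block_size)
        b0 = claim_run(cb, block_size)
        chain = []
        for k in range(block_size):
            p = (gid(ca, a0 + k), gid(cb, b0 + k))
            pairs.append(p)
            modes[p] = "segmental"
            chain.append(p)
        chains.append(chain)
    for _ in range(n_tandem):
        c = int(rng.integers(1, n_chrom + 1))
        r0 = claim_run(c, 2)
        p = (gid(c, r0), gid(c, r0 + 1))
        pairs.append(p)
        modes[p] = "tandem"
    for (ca, cb) in disp_chrom_pairs:
        ra = claim_run(ca, 1)
        rb = claim_run(cb, 1)
        p = (gid(ca, ra), gid(cb, rb))
        pairs.append(p)
        modes[p] = "dispersed"
    return LayoutResult(loci=loci, pairs=pairs, modes=modes, chains=chains)


# --------------------------------------------------------------------------
# promoters with planted motif counts
# --------------------------------------------------------------------------

@dataclass
class PromoterTruth:
    plant_counts: dict[str, int]
    offsets: dict[str, list[tuple[str, int]]]   # gene -> [(motif, offset)]


def _concretize(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        ch if len(IUPAC_DNA[ch]) == 1 else str(rng.choice(sorted(IUPAC_DNA[ch])))
        for ch in pattern
    )


def gen_promoter_set(seed: int, n_genes: int = 10,
                     plant_counts: dict[str, int] | None = None,
                     dictionary: list[Motif] | None = None,
                     length: int = 2000,
                     ) -> tuple[dict[str, str], PromoterTruth]:
    """Random promoters with exact planted motif counts per gene.

    Each gene's promoter is uniform A/C/G/T background with the requested
    number of non-overlapping motif instances pasted in; the whole
    promoter is rejection-sampled until a plus-strand scan of every
    planted motif finds exactly the planted count (no accidental extras).
    """
    from .promoter_scan import default_motif_dictionary
    plant_counts = dict(plant_counts or {})
    dictionary = dictionary or default_motif_dictionary()
    by_name = {m.name: m for m in dictionary}
    for name in plant_counts:
        if name not in by_name:
            raise ValueError(f"unknown motif {name!r} in plant_counts")
    planted_motifs = [by_name[n] for n in sorted(plant_counts)]
    total_len = sum(plant_counts[m.name] * len(m.pattern) for m in planted_motifs)
    if total_len > length // 2:
        raise ValueError("planted motifs do not plausibly fit in the promoter")
    rng = np.random.default_rng(seed)
    nt = "ACGT"
    truth = PromoterTruth(plant_counts, {})
    sequences: dict[str, str] = {}
    for g in range(1, n_genes + 1):
        gene = f"gene_{g}"
        seq = list(rng.choice(list(nt), size=length))
        placed: list[tuple[int, int]] = []   # 0-based [start, end)
        offsets: list[tuple[str, int]] = []
        for motif in planted_motifs:
            m = len(motif.pattern)
            for _ in range(plant_counts[motif.name]):
                for _try in range(1000):
                    pos = int(rng.integers(0, length - m + 1))
                    if all(pos + m <= a or pos >= b for a, b in placed):
                        break
                else:
                    raise RuntimeError(
                        f"could not pack planted motifs into {gene}"
                    )
                placed.append((pos, pos + m))
                seq[pos:pos + m] = list(_concretize(rng, motif.pattern))
                offsets.append((motif.name, pos + 1))
        wanted = {(name, off - 1) for name, off in offsets}
        # scrub accidental matches: mutate one background base inside each
        # stray occurrence until a plus-strand scan finds exactly the plants
        for _round in range(300):
            promoter = "".join(seq)
            stray = [
                (motif, h.offset - 1)
                for motif in planted_motifs
                for h in scan_motifs(promoter, [motif], strands="+")
                if (motif.name, h.offset - 1) not in wanted
            ]
            if not stray:
                break
            for motif, pos in stray:
                m = len(motif.pattern)
                mutable = [
                    p for p in range(pos, pos + m)
                    if all(p < a or p >= b for a, b in placed)
                ]
                if not mutable:
                    raise RuntimeError(
                        f"{gene}: accidental {motif.name} inside planted "
                        "instances cannot be removed"
                    )
                p = mutable[int(rng.integers(0, len(mutable)))]
                seq[p] = nt[(nt.index(seq[p]) + int(rng.integers(1, 4))) % 4]
        else:
            raise RuntimeError(
                f"could not generate promoter for {gene} without accidental "
                "motif matches"
            )
        sequences[gene] = "".join(seq)
        truth.offsets[gene] = sorted(offsets, key=lambda t: t[1])
    return sequences, truth


# --------------------------------------------------------------------------
# qRT-PCR Ct table with planted fold changes
# --------------------------------------------------------------------------

@dataclass
class CtTruth:
    fold_changes: dict[tuple[str, str], float]
    reference_gene: str
    control_sample: str
    noise_sd: float


def gen_ct_table(seed: int, genes: list[str], samples: list[str],
                 fold_changes: dict[tuple[str, str], float] | None = None,
                 noise_sd: float = 0.1, replicates: int = 3,
                 reference_gene: str = "Actin",
                 control_sample: str | None = None,
                 ) -> tuple[pd.DataFrame, CtTruth]:
    """A long-format Ct table realizing known fold changes.

    Reference Ct is a constant plus Gaussian noise; a target's Ct in a
    sample is its control baseline minus log2(fold change) plus noise, so
    2^-ddCt recovers the planted fold up to the noise.
    """
    rng = np.random.default_rng(seed)
    control = control_sample or samples[0]
    folds = dict(fold_changes or {})
    for key, f in folds.items():
        if f <= 0:
            raise ValueError(f"fold change for {key} must be > 0, got {f}")
    base_ref = 20.0
    baselines = {g: float(rng.uniform(3.0, 6.0)) for g in genes}
    rows = []
    for s in samples:
        for rep in range(1, replicates + 1):
            ref_ct = base_ref + float(rng.normal(0.0, noise_sd))
            rows.append(dict(gene=reference_gene, sample=s, replicate=rep,
                             ct=ref_ct))
            for g in genes:
                fold = folds.get((g, s), 1.0)
                ct = (base_ref + baselines[g] - math.log2(fold)
                      + float(rng.normal(0.0, noise_sd)))
                rows.append(dict(gene=g, sample=s, replicate=rep, ct=ct))
    df = pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])
    truth = CtTruth(folds, reference_gene, control, noise_sd)
    return df, truth
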