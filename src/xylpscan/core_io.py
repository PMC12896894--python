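"""Readers/writers for the standard formats the pipeline touches.

FASTA goes through Bio.SeqIO, GFF3 through gffutils (in-memory database),
Newick through dendropy, and tabular data through pandas.  All genomic
coordinates carried by :class:`GeneLocus` are GFF3-style 1-based inclusive;
any 0-based half-open arithmetic (promoter extraction, BED export) converts
at the point of use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = [
    "ProteinRecord",
    "GeneLocus",
    "Msa",
    "AnnotationSidecar",
    "read_fasta",
    "write_fasta",
    "read_gene_loci",
    "gene_structure_summary",
    "read_msa",
    "write_newick",
    "read_newick",
    "read_table",
    "write_table",
    "read_sidecar",
]

_GAP_CHARS = set("-.")


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein: identifier, residue string, free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = _GAP_CHARS.intersection(self.sequence)
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains gap character(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class GeneLocus:
    """A gene model: span, strand, per-chromosome rank and exon intervals.

    ``start``/``end`` and every exon interval are 1-based inclusive (GFF3
    convention).  ``rank`` is the 1-based order of the gene along its
    chromosome sorted by genomic start, regardless of strand.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int
    exon_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        prev_end = None
        for (a, b) in self.exon_intervals:
            if a > b:
                raise ValueError(f"gene {self.gene_id}: exon interval {a}>{b}")
            if a < self.start or b > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{a},{b}] outside gene span "
                    f"[{self.start},{self.end}]"
                )
            if prev_end is not None and a <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exon intervals overlap or unsorted"
                )
            prev_end = b


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: parallel taxa and equal-length rows."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows have unequal lengths {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class AnnotationSidecar:
    """External-predictor annotations merged into reports, never computed.

    Per-protein optional fields: signal peptide, GPI anchor (+ likelihood),
    subcellular localization.
    """

    records: dict[str, dict] = field(default_factory=dict)

    def validate_against(self, known_ids: Iterable[str]) -> None:
        unknown = set(self.records) - set(known_ids)
        if unknown:
            raise ValueError(f"sidecar references unknown protein ids: {sorted(unknown)}")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and terminal ``*`` stop symbols stripped.
    Raises on an empty file and on duplicate identifiers.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, seq, desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Read a (nucleotide or protein) FASTA into an id -> sequence mapping."""
    return {r.id: r.sequence for r in read_fasta(path)}


def _exon_span(exons: list) -> int:
    return sum(f.end - f.start + 1 for f in exons)


def read_gene_loci(gff_path: str | Path) -> list[GeneLocus]:
    """Parse gene models from GFF3 into :class:`GeneLocus` records.

    Exons are attached through their parent; when a gene carries several
    mRNA isoforms the longest (by summed exon length) represents the gene
    and the presence of alternatives is flagged with a warning.  Rank is
    assigned per chromosome by sorting genes on start.
    """
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    raw: list[dict] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {gene.id}: unknown strand symbol {gene.strand!r}"
            )
        mrnas = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        if mrnas:
            with_exons = [
                (m, list(db.children(m, featuretype="exon"))) for m in mrnas
            ]
            with_exons.sort(key=lambda t: (-_exon_span(t[1]), t[0].id))
            if len(with_exons) > 1:
                warnings.warn(
                    f"gene {gene.id}: {len(with_exons)} isoforms; using the longest"
                )
            exon_feats = with_exons[0][1]
        else:
            exon_feats = list(db.children(gene, featuretype="exon", level=1))
        exons = tuple(sorted((f.start, f.end) for f in exon_feats))
        for (a, b) in exons:
            if a < gene.start or b > gene.end:
                raise ValueError(
                    f"gene {gene.id}: exon [{a},{b}] outside gene span"
                )
        raw.append(dict(
            gene_id=gene.id, chromosome=gene.seqid, start=gene.start,
            end=gene.end, strand=gene.strand, exons=exons,
        ))
    loci: list[GeneLocus] = []
    by_chrom: dict[str, list[dict]] = {}
    for r in raw:
        by_chrom.setdefault(r["chromosome"], []).append(r)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda r: (r["start"], r["gene_id"]))
        for rank, r in enumerate(genes, start=1):
            loci.append(GeneLocus(
                gene_id=r["gene_id"], chromosome=chrom, start=r["start"],
                end=r["end"], strand=r["strand"], rank=rank,
                exon_intervals=r["exons"],
            ))
    return loci


def gene_structure_summary(locus: GeneLocus) -> tuple[int, int]:
    """Return ``(exon_count, intron_count)``; introns = exons - 1."""
    n = len(locus.exon_intervals)
    if n == 0:
        raise ValueError(f"gene {locus.gene_id} has no exon intervals")
    return n, n - 1


def read_msa(path: str | Path, fmt: str | None = None) -> Msa:
    """Read an aligned FASTA or CLUSTAL file into an :class:`Msa`."""
    path = Path(path)
    if fmt is None:
        first = path.read_text().lstrip()[:20].upper()
        fmt = "clustal" if first.startswith("CLUSTAL") else "fasta"
    aln = list(SeqIO.parse(str(path), fmt))
    if not aln:
        raise ValueError(f"no alignment rows found in {path}")
    return Msa(tuple(r.id for r in aln), tuple(str(r.seq).upper() for r in aln))


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths and internal support labels."""
    tree.write(
        path=str(path), schema="newick", suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def read_table(path: str | Path, schema: Mapping[str, type] | None = None) -> pd.DataFrame:
    """Read a TSV with a header row; enforce and type required columns."""
    df = pd.read_csv(path, sep="\t")
    if schema:
        for col, dtype in schema.items():
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r} in {path}")
            df[col] = df[col].astype(dtype)
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write a TSV with a deterministic column order."""
    out = df[list(columns)] if columns is not None else df
    out.to_csv(path, sep="\t", index=False)


_SIDECAR_SCHEMA = {"protein_id": str}


def read_sidecar(path: str | Path,
                 known_ids: Iterable[str] | None = None) -> AnnotationSidecar:
    df = read_table(path, _SIDECAR_SCHEMA)
    records: dict[str, dict] = {}
    for _, row in df.iterrows():
        entry = {}
        for key in ("signal_peptide", "gpi_anchor"):
            if key in df.columns:
                entry[key] = bool(row[key])
        if "gpi_likelihood" in df.columns:
            lik = float(row["gpi_likelihood"])
            if not 0.0 <= lik <= 1.0:
                raise ValueError(
                    f"gpi_likelihood {lik} for {row['protein_id']} outside [0,1]"
                )
            entry["gpi_likelihood"] = lik
        if "subcellular" in df.columns:
            entry["subcellular"] = str(row["subcellular"])
        records[row["protein_id"]] = entry
    sc = AnnotationSidecar(records)
    if known_ids is not None:
        sc.validate_against(known_ids)
    return sc
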