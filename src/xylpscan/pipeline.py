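"""Orchestration of the gene-family workflow into report tables.

``run_pipeline`` wires the stages — classification, physicochemical
profiling, phylogeny, Ka/Ks, duplication classification, promoter
scanning, expression — over files named in a :class:`PipelineConfig`,
writing one subdirectory per stage, a combined summary TSV, and the
serialized configuration + log at the output root.  Stages are skippable;
any stage error aborts the run.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    read_fasta, read_fasta_dict, read_gene_loci, read_msa, read_sidecar,
    read_table, write_newick, write_table, gene_structure_summary,
)
from .evolution import (
    back_translate_alignment, bootstrap_support, classify_duplications,
    ng86_kaks,
)
from .expression import cluster_rows, relative_expression_ddct
from .physchem import physchem_profile
from .promoter_scan import (
    count_by_category, default_motif_dictionary, extract_upstream,
    load_motif_dictionary, scan_motifs,
)
from .xylp_classify import ClassifyConfig, MotifBounds, classify_xylp, name_candidates

ALL_STAGES = ("classify", "physchem", "phylo", "kaks", "dupes",
              "promoters", "expression")

log = logging.getLogger("xylpscan")


@dataclass
class PipelineConfig:
    out_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    # classification
    proteome: Optional[str] = None
    theta: float = 0.35
    l_min: int = 20
    motif_bounds: MotifBounds = field(default_factory=MotifBounds)
    name_prefix: str = "XYLP"
    sidecar: Optional[str] = None
    # phylogeny / kaks
    msa: Optional[str] = None
    cds: Optional[str] = None
    pairs: Optional[str] = None
    bootstrap_b: int = 1000
    # duplications
    gff: Optional[str] = None
    match_size: int = 5
    max_gaps: int = 25
    tandem_window: int = 2
    # promoters
    genome: Optional[str] = None
    motifs: Optional[str] = None
    promoter_length: int = 2000
    promoter_strands: str = "+"
    # expression
    tpm: Optional[str] = None
    heatmap_transform: Optional[str] = "log2"
    ct: Optional[str] = None
    reference_gene: Optional[str] = None
    control_sample: Optional[str] = None

    def validate(self) -> None:
        requirements = {
            "classify": ["proteome"],
            "physchem": ["proteome"],
            "phylo": ["msa"],
            "kaks": ["pairs", "cds", "msa"],
            "dupes": ["gff", "pairs"],
            "promoters": ["genome", "gff"],
            "expression": [],
        }
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            for attr in requirements[stage]:
                if getattr(self, attr) is None:
                    raise ValueError(
                        f"stage {stage!r} requires config field {attr!r}"
                    )
        if "expression" in self.stages and not (self.tpm or self.ct):
            raise ValueError("stage 'expression' requires tpm and/or ct input")
        if self.ct and not (self.reference_gene and self.control_sample):
            raise ValueError(
                "ct quantification requires reference_gene and control_sample"
            )


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    return obj


def classification_table(calls, names) -> pd.DataFrame:
    rows = []
    for c in calls:
        best = max(c.past_regions, key=lambda r: r.past_fraction * r.length,
                   default=None)
        rows.append(dict(
            protein_id=c.protein_id,
            verdict=c.verdict,
            name=names.get(c.protein_id, ""),
            n_past_regions=len(c.past_regions),
            best_region=f"{best.start}-{best.end}" if best else "",
            n_glycomodules=len(c.glyco_hits),
            cys_positions=",".join(map(str, c.motif.cys_positions)) if c.motif else "",
            reasons=";".join(c.reasons),
        ))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the configured stages; returns the per-stage report tables."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict[str, pd.DataFrame] = {}
    try:
        log.info("xylpscan %s; seed=%d; stages=%s", __version__, config.seed,
                 ",".join(config.stages))
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(_to_plain(config), fh, sort_keys=True)

        if "classify" in config.stages:
            stage_dir = out / "classify"
            stage_dir.mkdir(exist_ok=True)
            proteome = read_fasta(config.proteome)
            ccfg = ClassifyConfig(config.theta, config.l_min, config.motif_bounds)
            calls = [classify_xylp(p, ccfg) for p in proteome]
            names = (name_candidates(calls, config.name_prefix)
                     if any(c.verdict == "XYLP" for c in calls) else {})
            table = classification_table(calls, names)
            write_table(table, stage_dir / "classification.tsv")
            with open(stage_dir / "past_regions.bed", "w") as fh:
                for c in calls:
                    for r in c.past_regions:
                        fh.write(f"{c.protein_id}\t{r.start - 1}\t{r.end}\t"
                                 f"past_region\t{r.past_fraction:.3f}\n")
            results["classify"] = table
            log.info("classify: %d/%d accepted",
                     sum(c.verdict == "XYLP" for c in calls), len(calls))

        if "physchem" in config.stages:
            stage_dir = out / "physchem"
            stage_dir.mkdir(exist_ok=True)
            proteome = read_fasta(config.proteome)
            profiles = [physchem_profile(p) for p in proteome]
            table = pd.DataFrame([dataclasses.asdict(p) for p in profiles])
            table["mw"] = table["mw"].round(2)
            table["pi"] = table["pi"].round(2)
            if config.sidecar:
                sc = read_sidecar(config.sidecar, [p.id for p in proteome])
                for col in ("signal_peptide", "gpi_anchor", "gpi_likelihood",
                            "subcellular"):
                    table[col] = [
                        sc.records.get(pid, {}).get(col, "")
                        for pid in table["protein_id"]
                    ]
            write_table(table, stage_dir / "physchem.tsv")
            results["physchem"] = table
            log.info("physchem: %d profiles", len(table))

        if "phylo" in config.stages:
            stage_dir = out / "phylo"
            stage_dir.mkdir(exist_ok=True)
            msa = read_msa(config.msa)
            tree = bootstrap_support(msa, B=config.bootstrap_b, seed=config.seed)
            write_newick(tree, stage_dir / "tree.nwk")
            sup = [
                float(node.label) for node in tree.preorder_node_iter()
                if node.label is not None and not node.is_leaf()
            ]
            results["phylo"] = pd.DataFrame({"support": sup})
            log.info("phylo: %d taxa, B=%d", len(msa.taxa), config.bootstrap_b)

        if "kaks" in config.stages:
            stage_dir = out / "kaks"
            stage_dir.mkdir(exist_ok=True)
            msa = read_msa(config.msa)
            cds = read_fasta_dict(config.cds)
            codon_msa = back_translate_alignment(msa, cds)
            pairs_df = read_table(config.pairs, {"gene_a": str, "gene_b": str})
            rows = []
            for a, b in zip(pairs_df["gene_a"], pairs_df["gene_b"]):
                res = ng86_kaks(codon_msa.row(a), codon_msa.row(b))
                rows.append(dict(
                    pair=f"{a}/{b}", S=res.S, N=res.N, sd=res.sd, nd=res.nd,
                    pS=res.ps, pN=res.pn,
                    Ka=res.ka if res.ka is not None else float("nan"),
                    Ks=res.ks if res.ks is not None else float("nan"),
                    ratio=res.ratio if res.ratio is not None else float("nan"),
                    na_reason=res.na_reason or "",
                ))
            table = pd.DataFrame(rows)
            write_table(table, stage_dir / "kaks.tsv")
            results["kaks"] = table
            log.info("kaks: %d pairs, %d N/A", len(table),
                     int((table["na_reason"] != "").sum()))

        if "dupes" in config.stages:
            stage_dir = out / "dupes"
            stage_dir.mkdir(exist_ok=True)
            loci = read_gene_loci(config.gff)
            pairs_df = read_table(config.pairs, {"gene_a": str, "gene_b": str})
            pairs = list(zip(pairs_df["gene_a"], pairs_df["gene_b"]))
            calls = classify_duplications(
                loci, pairs, config.match_size, config.max_gaps,
                config.tandem_window,
            )
            table = pd.DataFrame([dict(
                gene_a=c.pair[0], gene_b=c.pair[1], mode=c.mode,
                chain_id=c.chain_id if c.chain_id is not None else "",
                chain_length=c.chain_length if c.chain_length is not None else "",
            ) for c in calls])
            write_table(table, stage_dir / "duplications.tsv")
            results["dupes"] = table
            log.info("dupes: %s", table["mode"].value_counts().to_dict())

        if "promoters" in config.stages:
            stage_dir = out / "promoters"
            stage_dir.mkdir(exist_ok=True)
            genome = read_fasta_dict(config.genome)
            loci = read_gene_loci(config.gff)
            dictionary = (load_motif_dictionary(config.motifs)
                          if config.motifs else default_motif_dictionary())
            hits = []
            flagged = []
            for locus in loci:
                prom = extract_upstream(genome, locus, config.promoter_length)
                if prom.truncated:
                    flagged.append(locus.gene_id)
                if prom.sequence:
                    hits.extend(scan_motifs(prom, dictionary,
                                            strands=config.promoter_strands))
            table = count_by_category(hits, dictionary)
            write_table(table.counts.reset_index(names="gene_id"),
                        stage_dir / "element_counts.tsv")
            cat = pd.DataFrame({
                "category": list(table.category_totals),
                "total": list(table.category_totals.values()),
                "percent": [table.category_percent[c]
                            for c in table.category_totals],
            })
            write_table(cat, stage_dir / "category_percentages.tsv")
            results["promoters"] = cat
            log.info("promoters: %d hits; truncated=%s", table.grand_total,
                     flagged)

        if "expression" in config.stages:
            stage_dir = out / "expression"
            stage_dir.mkdir(exist_ok=True)
            if config.tpm:
                tpm = read_table(config.tpm).set_index("gene_id")
                clust = cluster_rows(tpm, transform=config.heatmap_transform)
                ordered = tpm.loc[clust.leaf_order]
                write_table(ordered.reset_index(), stage_dir / "tpm_ordered.tsv")
                with open(stage_dir / "merge_tree.nwk", "w") as fh:
                    fh.write(clust.merge_tree_newick() + "\n")
                results["expression_order"] = ordered
            if config.ct:
                ct = read_table(config.ct, {"gene": str, "sample": str,
                                            "ct": float})
                rq = relative_expression_ddct(ct, config.reference_gene,
                                              config.control_sample)
                write_table(rq, stage_dir / "relative_expression.tsv")
                results["expression_rq"] = rq
            log.info("expression stage done")

        summary = pd.DataFrame([
            dict(stage=k, rows=len(v)) for k, v in results.items()
        ])
        summary["timestamp"] = datetime.datetime.now().isoformat(timespec="seconds")
        write_table(summary, out / "summary.tsv")
    finally:
        log.removeHandler(handler)
        handler.close()
    return results
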