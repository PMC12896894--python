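"""Expression-matrix clustering and 2^-ddCt relative quantification.

The TPM matrix (genes x samples) is an input contract: quantification from
reads is upstream of this package.  Clustering for heatmap row ordering is
agglomerative average linkage on Euclidean distances (scipy), on
log2(TPM+1)-transformed rows by default.  qRT-PCR relative expression uses
the standard 2^-ddCt scheme against a designated reference gene and
control sample, reporting mean and SD of RQ over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree

__all__ = [
    "ClusterResult",
    "tpm_from_counts",
    "cluster_rows",
    "relative_expression_ddct",
]


@dataclass
class ClusterResult:
    leaf_order: list[str]
    linkage_matrix: np.ndarray
    genes: list[str]

    def merge_tree_newick(self) -> str:
        """The merge tree as a Newick string with merge-height branch lengths."""
        root = to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.genes[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return fmt(root, root.dist) + ";"


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from read counts and effective lengths.

    rate = count/length per gene; TPM = rate / sum(rate) * 1e6 per sample,
    so every non-degenerate column sums to one million.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing effective lengths for genes: {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum[colsum == 0].index.tolist()
    if zero_cols:
        warnings.warn(f"all-zero count columns: {zero_cols}; TPM set to 0")
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1) * 1e6
    return tpm.fillna(0.0)


def cluster_rows(matrix: pd.DataFrame, transform: str | None = "log2") -> ClusterResult:
    """Average-linkage/Euclidean row clustering for heatmap ordering.

    ``transform`` is ``"log2"`` (log2(x+1), the default for TPM heatmaps)
    or ``None`` for raw values.  Rows are pre-sorted by gene name so that
    distance ties resolve deterministically; the leaf order comes from the
    recursive subtree listing of the merge tree.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 genes to cluster")
    mat = matrix.sort_index()
    values = mat.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if transform == "log2":
        values = np.log2(values + 1.0)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    Z = linkage(values, method="average", metric="euclidean")
    order = leaves_list(Z)
    genes = list(mat.index)
    return ClusterResult(
        leaf_order=[genes[i] for i in order],
        linkage_matrix=Z,
        genes=genes,
    )


def relative_expression_ddct(ct: pd.DataFrame, reference_gene: str,
                             control_sample: str) -> pd.DataFrame:
    """2^-ddCt relative quantification of a long-format Ct table.

    ``ct`` columns: gene, sample, replicate, ct.  Per replicate,
    dCt = Ct_target - Ct_reference (same sample and replicate);
    ddCt = dCt - mean dCt of the control sample; RQ = 2^-ddCt.
    Returns one row per (gene, sample) with mean RQ, SD of RQ and the
    replicate count.
    """
    required = {"gene", "sample", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    if control_sample not in set(ct["sample"]):
        raise ValueError(f"control sample {control_sample!r} absent from Ct table")
    ref = ct[ct["gene"] == reference_gene].set_index(["sample", "replicate"])["ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    keys = list(zip(targets["sample"], targets["replicate"]))
    for key in keys:
        if key not in ref.index:
            raise ValueError(
                f"missing reference Ct for sample {key[0]!r} replicate {key[1]!r}"
            )
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[keys].to_numpy()
    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        control = sub[sub["sample"] == control_sample]
        if control.empty:
            raise ValueError(
                f"gene {gene!r}: no control-sample ({control_sample!r}) rows"
            )
        baseline = control["dct"].mean()
        for sample, ss in sub.groupby("sample", sort=True):
            rq = np.power(2.0, -(ss["dct"] - baseline))
            rows.append(dict(
                gene=gene, sample=sample,
                mean_rq=float(rq.mean()),
                sd_rq=float(rq.std(ddof=1)) if len(rq) > 1 else 0.0,
                n_replicates=int(len(rq)),
            ))
    return pd.DataFrame(rows, columns=["gene", "sample", "mean_rq", "sd_rq",
                                       "n_replicates"])
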