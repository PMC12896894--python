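"""Shared construction of cross-chromosome anchor chains for tests."""

from xylpscan.core_io import GeneLocus


def chain_layout(n_anchors, rank_step=1, chroms=("chr1", "chr2")):
    """n_anchors homolog pairs in collinear order with a given rank step."""
    loci, pairs = [], []
    for k in range(n_anchors):
        for name, chrom, rank in ((f"a{k}", chroms[0], 1 + k * rank_step),
                                  (f"b{k}", chroms[1], 11 + k * rank_step)):
            loci.append(GeneLocus(name, chrom, 1000 * rank, 1000 * rank + 500,
                                  "+", rank,
                                  ((1000 * rank, 1000 * rank + 500),)))
        pairs.append((f"a{k}", f"b{k}"))
    return loci, pairs
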