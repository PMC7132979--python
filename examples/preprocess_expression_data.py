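"""Preprocessing: probe collapse, RNA-seq zero handling, gene intersection.

Builds a toy probe-level microarray matrix and a toy FPKM matrix,
applies the preprocessing rules (drop multi-/un-mapped probes, average
probes per gene on the log2 scale; drop genes that are zero in more
than 75% of samples and fill remaining zeros with the smallest
positive value), then restricts both matrices to their common genes —
the cross-platform step that makes ordering-based discovery possible.
"""

import pandas as pd

from reograde import (
    ExpressionMatrix,
    collapse_probes,
    filter_rnaseq_zeros,
    intersect_genes,
)

probes = ExpressionMatrix(
    pd.DataFrame(
        {
            "arr_s1": [7.0, 9.0, 5.0, 6.0, 3.0],
            "arr_s2": [7.5, 8.5, 5.5, 6.5, 3.5],
        },
        index=["p1", "p2", "p3", "p4", "p5"],
    ),
    scale="log2",
)
probe_map = {
    "p1": {"1848"},          # DUSP6
    "p2": {"1848"},          # second DUSP6 probe -> averaged
    "p3": {"11065"},         # UBE2C
    "p4": {"1848", "11065"}, # multi-mapped -> dropped
    "p5": set(),             # unmapped -> dropped
}
array = collapse_probes(probes, probe_map)
print("collapsed microarray matrix (log2 means per gene):")
print(array.data, "\n")

fpkm = ExpressionMatrix(
    pd.DataFrame(
        {
            "rna_s1": [12.0, 0.0, 0.0],
            "rna_s2": [15.0, 0.4, 0.0],
            "rna_s3": [11.0, 2.0, 0.0],
            "rna_s4": [13.0, 0.0, 0.1],
        },
        index=["1848", "11065", "9319"],
    ),
    scale="linear",
)
rnaseq = filter_rnaseq_zeros(fpkm)  # gene 9319: zero in 3/4 = 75%, kept (rule is strict >)
print("zero-filtered FPKM matrix (zeros filled with the min positive value, 0.1):")
print(rnaseq.data, "\n")

array_common, rnaseq_common = intersect_genes([array, rnaseq])
print(f"common genes across platforms: {array_common.gene_ids}")
print(
    "\nDownstream discovery only compares within-sample orderings of these\n"
    "shared genes, so the two platforms' different scales never need to be\n"
    "normalized against each other."
)
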