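"""Small bundled datasets."""

from importlib import resources

import pandas as pd

from .genes import GeneResult

__all__ = ["load_top_shared_gene_pvalues"]


def load_top_shared_gene_pvalues() -> list[GeneResult]:
    """Published gene-based p-values for the top 20 shared osteoarthritis /
    major-depression risk genes (per-trait and cross-disorder meta-analysis),
    used as a worked input to the pleiotropic-gene prioritization filter."""
    path = resources.files("crosstrait.data").joinpath("shared_risk_genes_top20.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        GeneResult(gene_id=r.gene_id, n_snps=1, stat=float("nan"),
                   pval_meta=r.pval_meta, pval_a=r.pval_oa, pval_b=r.pval_md)
        for r in df.itertuples()
    ]
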