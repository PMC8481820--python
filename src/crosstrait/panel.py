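"""LD reference panel: variant orientation, allele frequencies, block LD.

The panel is the shared genomic scaffold every stage aligns to. It plays the
role usually played by a 1000-Genomes-derived European reference: it fixes
the canonical allele orientation (ref/alt), supplies allele frequencies for
strand resolution of palindromic SNPs, and carries block-diagonal LD
correlation matrices from which LD scores, clumping r-squared values and
gene-level LD submatrices are derived. Cross-block LD is exactly zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ReferencePanel", "read_panel", "write_panel"]

_VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "af", "block_id"]


@dataclass
class ReferencePanel:
    """Variant table plus per-block LD correlation matrices and LD scores.

    Parameters
    ----------
    variants
        One row per SNP with columns ``snp_id, chrom, pos, ref_allele,
        alt_allele, af, block_id``; ``af`` is the alt-allele frequency.
        Rows are in (chrom, pos) order and each SNP belongs to exactly one
        block.
    blocks
        Mapping ``block_id -> square LD correlation matrix`` over the block's
        member SNPs in position order.
    ld_scores
        Per-SNP LD score l_j = sum_k r^2_jk over the SNP's block, indexed by
        ``snp_id``. Always >= 1 (the self term).
    """

    variants: pd.DataFrame
    blocks: dict[int, np.ndarray]
    ld_scores: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"panel variants missing columns: {missing}")
        for bid, mat in self.blocks.items():
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError(f"block {bid}: LD matrix must be square")
            if not np.allclose(mat, mat.T, atol=1e-8):
                raise ValueError(f"block {bid}: LD matrix must be symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-6):
                raise ValueError(f"block {bid}: LD matrix must have unit diagonal")

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def block_members(self, block_id: int) -> pd.DataFrame:
        """Variant rows of one block, in position order."""
        sub = self.variants[self.variants["block_id"] == block_id]
        return sub.sort_values(["chrom", "pos"], kind="mergesort")

    def ld_r2(self, snp_a: str, snp_b: str) -> float:
        """Squared LD correlation between two panel SNPs (0 across blocks)."""
        if snp_a == snp_b:
            return 1.0
        idx = self.variants.set_index("snp_id")
        ra, rb = idx.loc[snp_a], idx.loc[snp_b]
        if ra["block_id"] != rb["block_id"]:
            return 0.0
        members = self.block_members(int(ra["block_id"]))["snp_id"].tolist()
        mat = self.blocks[int(ra["block_id"])]
        return float(mat[members.index(snp_a), members.index(snp_b)] ** 2)

    def ld_submatrix(self, snp_ids: list[str]) -> np.ndarray:
        """LD correlation matrix over an arbitrary SNP list (block-diagonal)."""
        idx = self.variants.set_index("snp_id")
        n = len(snp_ids)
        out = np.eye(n)
        bids = idx.loc[snp_ids, "block_id"].to_numpy()
        for bid in np.unique(bids):
            where = np.flatnonzero(bids == bid)
            if len(where) < 2:
                continue
            members = self.block_members(int(bid))["snp_id"].tolist()
            pos = [members.index(snp_ids[i]) for i in where]
            out[np.ix_(where, where)] = self.blocks[int(bid)][np.ix_(pos, pos)]
        return out


def compute_ld_scores(variants: pd.DataFrame, blocks: dict[int, np.ndarray]) -> pd.Series:
    """Within-block row sums of r^2, indexed by snp_id."""
    scores = {}
    for bid, mat in blocks.items():
        members = variants[variants["block_id"] == bid].sort_values(
            ["chrom", "pos"], kind="mergesort"
        )["snp_id"]
        l2 = (mat**2).sum(axis=1)
        for snp, val in zip(members, l2):
            scores[snp] = float(val)
    out = pd.Series(scores, name="l2")
    return out.reindex(variants["snp_id"])


def write_panel(panel: ReferencePanel, directory: str) -> None:
    """Write a panel as variants.tsv, ldscores.tsv and one matrix file per block."""
    os.makedirs(directory, exist_ok=True)
    panel.variants.to_csv(os.path.join(directory, "variants.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"snp_id": panel.ld_scores.index, "l2": panel.ld_scores.to_numpy()}
    ).to_csv(os.path.join(directory, "ldscores.tsv"), sep="\t", index=False)
    for bid, mat in panel.blocks.items():
        np.savetxt(os.path.join(directory, f"block_{bid}.ld"), mat, fmt="%.6g")


def read_panel(directory: str) -> ReferencePanel:
    """Read a panel written by :func:`write_panel`."""
    variants = pd.read_csv(os.path.join(directory, "variants.tsv"), sep="\t")
    ld = pd.read_csv(os.path.join(directory, "ldscores.tsv"), sep="\t")
    blocks = {}
    for bid in variants["block_id"].unique():
        mat = np.loadtxt(os.path.join(directory, f"block_{bid}.ld"))
        blocks[int(bid)] = np.atleast_2d(mat)
    scores = ld.set_index("snp_id")["l2"].reindex(variants["snp_id"])
    return ReferencePanel(variants=variants, blocks=blocks, ld_scores=scores)
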