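import numpy as np
import pandas as pd
import pytest

from crosstrait.panel import ReferencePanel
from crosstrait.simulate import PanelConfig, make_reference_panel
from crosstrait.sumstats import CANONICAL_COLUMNS, SumStats, to_zscores


def make_sumstats(rows: list[dict], label: str = "trait") -> SumStats:
    """Build a SumStats from partial row dicts, filling canonical defaults."""
    defaults = {
        "snp_id": "rs1", "chrom": 1, "pos": 100, "effect_allele": "G",
        "other_allele": "A", "eaf": 0.3, "beta": 0.1, "se": 0.01,
        "pval": np.nan, "z": np.nan, "n": 1e5, "n_cases": np.nan,
        "n_controls": np.nan,
    }
    table = pd.DataFrame([{**defaults, **row} for row in rows])[CANONICAL_COLUMNS]
    return to_zscores(SumStats(trait_label=label, table=table))


@pytest.fixture
def one_snp_panel() -> ReferencePanel:
    """A single-variant panel: ref=A, alt=G, alt frequency 0.3."""
    variants = pd.DataFrame({
        "snp_id": ["rs1"], "chrom": [1], "pos": [100],
        "ref_allele": ["A"], "alt_allele": ["G"], "af": [0.3], "block_id": [0],
    })
    return ReferencePanel(variants=variants, blocks={0: np.eye(1)},
                          ld_scores=pd.Series([1.0], index=["rs1"], name="l2"))


@pytest.fixture(scope="session")
def medium_panel() -> ReferencePanel:
    """20k-SNP panel with heterogeneous AR(1) LD blocks (shared across tests)."""
    return make_reference_panel(PanelConfig(m_snps=20_000, block_size=50, seed=11))


@pytest.fixture(scope="session")
def identity_panel() -> ReferencePanel:
    """20k-SNP panel with no LD (every LD score exactly 1)."""
    return make_reference_panel(
        PanelConfig(m_snps=20_000, block_size=50, ld_rho=0.0, ld_rho_range=None, seed=12)
    )
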