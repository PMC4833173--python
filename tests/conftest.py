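"""Shared fixtures: tiny synthetic panels and summary-statistic sets."""

import numpy as np
import pandas as pd
import pytest

from crosstrait.gwas_io import GenotypePanel, SummaryStatRecord
from crosstrait.synth import SimConfig


def make_panel(
    dosages,
    *,
    chrom="1",
    spacing_bp=1000,
    phenotypes=None,
    alleles=("A", "G"),
    positions=None,
    freqs=None,
) -> GenotypePanel:
    """Build a small GenotypePanel from a dosage matrix."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    var = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": positions if positions is not None else 1 + spacing_bp * np.arange(m),
            "allele1": alleles[0],
            "allele2": alleles[1],
        }
    )
    if freqs is not None:
        var["freq"] = freqs
    return GenotypePanel(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        phenotypes=np.full(n, -9) if phenotypes is None else np.asarray(phenotypes),
        variants=var,
        dosages=d,
    )


def make_record(snp_id="rs1", chrom="1", pos=1, a1="A", a2="G", odds_ratio=1.5,
                p_value=0.01, info=None) -> SummaryStatRecord:
    return SummaryStatRecord(snp_id, chrom, pos, a1, a2, odds_ratio, p_value, info)


@pytest.fixture
def small_config() -> SimConfig:
    """A quick-to-simulate paired-trait configuration."""
    return SimConfig(
        n_snps=300,
        block_size=10,
        rho=0.8,
        causal_fraction=0.05,
        h2_a=0.5,
        h2_b=0.5,
        effect_correlation=0.5,
        prevalence_a=0.2,
        prevalence_b=0.2,
        n_disc_cases=150,
        n_disc_controls=150,
        n_test_cases=150,
        n_test_controls=150,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
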