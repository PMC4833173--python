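"""Shared configuration for the numbered analysis drivers.

One modest paired-trait scenario is used throughout: 2,000 SNPs in
20-SNP AR(1) LD blocks, 600/600 case-control cohorts ascertained at 10%
prevalence, liability heritability 0.5 for both traits, causal effects
at 1% of SNPs with cross-trait correlation 0.5.
"""

from pathlib import Path

from crosstrait.synth import SimConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"

SIM_CONFIG = SimConfig(
    n_snps=2000,
    block_size=20,
    rho=0.9,
    causal_fraction=0.01,
    h2_a=0.5,
    h2_b=0.5,
    effect_correlation=0.5,
    prevalence_a=0.1,
    prevalence_b=0.1,
    n_disc_cases=600,
    n_disc_controls=600,
    n_test_cases=600,
    n_test_controls=600,
    seed=2026,
)


def banner(title: str) -> None:
    print(f"\n=== {title} ===")
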