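"""Generate the synthetic study data used by the downstream analyses.

Simulates a paired-trait dataset: a discovery case-control cohort for
trait A (run through a per-SNP logistic GWAS to give summary statistics)
and an independent test cohort for trait B whose causal effects share a
configurable correlation with trait A's.  Writes PLINK BED/BIM/FAM for
the test cohort and a tab-separated summary-statistics file under
results/sim/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import RESULTS, SIM_CONFIG, banner

from crosstrait import gwas_io, synth


def main() -> None:
    out = RESULTS / "sim"
    out.mkdir(parents=True, exist_ok=True)
    banner("simulating paired-trait cohorts")
    print(f"config: {SIM_CONFIG}")

    disc = synth.simulate_study(SIM_CONFIG, "discovery")
    records = synth.discovery_gwas(disc)
    gwas_io.write_summary_stats(records, out / "discovery_sumstats.tsv")
    print(
        f"discovery: {disc.n_samples} samples "
        f"({int(disc.phenotypes.sum())} cases), {len(records)} GWAS records"
    )

    test = synth.simulate_study(SIM_CONFIG, "test")
    gwas_io.write_genotype_panel(test, out / "test_panel")
    print(
        f"test: {test.n_samples} samples ({int(test.phenotypes.sum())} cases), "
        f"{test.n_variants} variants -> {out / 'test_panel'}.bed/.bim/.fam"
    )


if __name__ == "__main__":
    main()
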