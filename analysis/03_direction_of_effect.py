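"""Cross-GWAS direction-of-effect (sign test) analysis.

Runs a GWAS on both simulated cohorts, clumps each study to
near-independent SNPs, pairs the two studies' odds ratios on shared
alleles, and tests direction concordance at a ladder of p-value
thresholds — once thresholding/clumping by each study.  With a positive
cross-trait effect correlation the concordant share should exceed 1/2
at the stricter thresholds.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
import pandas as pd

from common import RESULTS, SIM_CONFIG, banner

from crosstrait import concordance, gwas_io, ld, synth


def main() -> None:
    banner("direction-of-effect sign test")
    disc = synth.simulate_study(SIM_CONFIG, "discovery")
    test = synth.simulate_study(SIM_CONFIG, "test")
    stats_a = synth.discovery_gwas(disc)
    stats_b = synth.discovery_gwas(test)
    pairs = concordance.pair_effects(stats_a, stats_b, drop_ambiguous=False)

    thresholds = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5)
    rows = []
    for source, panel, stats_src in (("a", disc, stats_a), ("b", test, stats_b)):
        harm = gwas_io.harmonize(stats_src, panel, drop_ambiguous=False)
        clumped = set(ld.clump(harm, panel, ld.ClumpSpec(tag=f"study-{source}")))
        for r in concordance.sign_test(pairs, thresholds, source, clumped):
            rows.append(
                {
                    "clumped_by": "trait A" if source == "a" else "trait B",
                    "threshold": r.threshold,
                    "n_snps": r.n_snps,
                    "chi2_p": r.p_value,
                    "proportion_same": r.proportion_same,
                }
            )
    table = pd.DataFrame(rows)
    out = RESULTS / "sign_test.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
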