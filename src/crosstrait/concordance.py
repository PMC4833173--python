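"""Cross-GWAS direction-of-effect analysis (the "sign test").

Two summary-statistic sets are merged on SNP id, study B's odds ratio is
re-oriented to study A's effect allele, and at each p-value threshold
the proportion of near-independent SNPs whose ORs point the same way is
tested against the null expectation of 1/2 with a Pearson chi-squared
statistic on 1 df: chi2 = (n_same - n_diff)^2 / n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gwas_io import COMPLEMENT, SummaryStatRecord

logger = logging.getLogger("crosstrait.concordance")


@dataclass(frozen=True)
class EffectPair:
    """One SNP's odds ratios from two studies, oriented to a shared allele."""

    snp_id: str
    effect_allele: str
    or_a: float
    or_b: float
    p_a: float
    p_b: float

    def __post_init__(self) -> None:
        if self.or_a <= 0 or self.or_b <= 0:
            raise ValueError("odds ratios must be positive")

    @property
    def same_direction(self) -> bool | None:
        """True/False for concordant/discordant; None when either OR is 1."""
        sa = np.sign(self.or_a - 1.0)
        sb = np.sign(self.or_b - 1.0)
        if sa == 0 or sb == 0:
            return None
        return bool(sa == sb)


@dataclass
class SignTestResult:
    clump_source: str
    threshold: float
    n_snps: int
    n_same: int
    chi2: float
    p_value: float
    n_directionless: int = 0

    @property
    def proportion_same(self) -> float:
        return self.n_same / self.n_snps if self.n_snps else float("nan")

    @property
    def empty(self) -> bool:
        return self.n_snps == 0


def pair_effects(
    stats_a: list[SummaryStatRecord],
    stats_b: list[SummaryStatRecord],
    drop_ambiguous: bool = True,
) -> list[EffectPair]:
    """Merge two GWAS on snp_id and orient study B to study A's allele.

    When B reports the swapped allele pair its OR is inverted; a strand
    complement is attempted before giving up.  A/T and C/G SNPs are
    dropped when ``drop_ambiguous``; irreconcilable allele sets are
    dropped and logged.
    """
    by_id_b = {r.snp_id: r for r in stats_b}
    pairs: list[EffectPair] = []
    n_dropped = 0
    for ra in stats_a:
        rb = by_id_b.get(ra.snp_id)
        if rb is None:
            continue
        if drop_ambiguous and (ra.is_ambiguous or rb.is_ambiguous):
            n_dropped += 1
            continue
        or_b = _orient_or(rb, ra.effect_allele, ra.other_allele)
        if or_b is None:
            n_dropped += 1
            continue
        pairs.append(
            EffectPair(
                snp_id=ra.snp_id,
                effect_allele=ra.effect_allele,
                or_a=ra.odds_ratio,
                or_b=or_b,
                p_a=ra.p_value,
                p_b=rb.p_value,
            )
        )
    if not pairs:
        raise ValueError("no SNPs shared between the two studies")
    logger.info("pair_effects: %d pairs (%d dropped)", len(pairs), n_dropped)
    return pairs


def _orient_or(rb: SummaryStatRecord, ea: str, oa: str) -> float | None:
    if (rb.effect_allele, rb.other_allele) == (ea, oa):
        return rb.odds_ratio
    if (rb.effect_allele, rb.other_allele) == (oa, ea):
        return 1.0 / rb.odds_ratio
    cea, coa = COMPLEMENT.get(ea), COMPLEMENT.get(oa)
    if (rb.effect_allele, rb.other_allele) == (cea, coa):
        return rb.odds_ratio
    if (rb.effect_allele, rb.other_allele) == (coa, cea):
        return 1.0 / rb.odds_ratio
    return None


def sign_test(
    pairs: list[EffectPair],
    thresholds: tuple[float, ...],
    threshold_on: str = "a",
    clumped_ids: set[str] | None = None,
) -> list[SignTestResult]:
    """Per-threshold Pearson chi-squared test of direction concordance.

    At each threshold, pairs with p (from the study named by
    ``threshold_on``) strictly below it — restricted to ``clumped_ids``
    when given — are classified by shared OR direction; ORs exactly 1
    carry no direction and are excluded (counted).  chi2 =
    (n_same - n_diff)^2 / n against chi2(1).  A threshold with no pairs
    yields an empty-flagged result, not an exception.
    """
    if threshold_on not in ("a", "b"):
        raise ValueError("threshold_on must be 'a' or 'b'")
    work = pairs if clumped_ids is None else [p for p in pairs if p.snp_id in clumped_ids]
    results = []
    for t in thresholds:
        sel = [p for p in work if (p.p_a if threshold_on == "a" else p.p_b) < t]
        directions = [p.same_direction for p in sel]
        n_less = sum(d is None for d in directions)
        n_same = sum(d is True for d in directions)
        n_diff = sum(d is False for d in directions)
        n = n_same + n_diff
        if n == 0:
            results.append(
                SignTestResult(threshold_on, t, 0, 0, float("nan"), float("nan"), n_less)
            )
            continue
        chi2 = (n_same - n_diff) ** 2 / n
        p = float(stats.chi2.sf(chi2, df=1))
        if n_less:
            logger.info("threshold %g: %d direction-less pairs excluded", t, n_less)
        results.append(SignTestResult(threshold_on, t, n, n_same, chi2, p, n_less))
    return results
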