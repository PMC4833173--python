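"""Monte-Carlo power estimation for cross-trait PRS association.

Each replicate replays the whole pipeline on fresh synthetic data:
simulate a discovery cohort, run the discovery GWAS, clump, score the
test cohort at one fixed p_T, and test the PRS-status association; a
replicate is "significant" when the Wald p falls below alpha.  Power is
the significant fraction with a Wilson 95% binomial interval.

A single fixed p_T is used per run (no best-threshold search), so the
estimate is free of the optimism a threshold sweep would inject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import association, ld, scoring
from .gwas_io import harmonize
from .synth import SimConfig, discovery_gwas, simulate_study

logger = logging.getLogger("crosstrait.power")


@dataclass
class PowerResult:
    config: SimConfig
    p_t: float
    alpha: float
    n_replicates: int
    n_significant: int
    power: float
    ci_low: float
    ci_high: float
    n_failed: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.power <= self.ci_high):
            raise ValueError("Wilson CI must contain the point estimate")


def run_replicate(
    config: SimConfig,
    p_t: float,
    *,
    clump_spec: ld.ClumpSpec = ld.ClumpSpec(),
    k_dims: int = 5,
) -> association.AssociationResult:
    """One end-to-end pipeline pass on a fresh simulation; returns the
    association result at ``p_t``."""
    disc = simulate_study(config, "discovery")
    stats_a = discovery_gwas(disc)
    test = simulate_study(config, "test")
    harm = harmonize(stats_a, test, drop_ambiguous=False)
    if clump_spec is not None:
        kept = set(ld.clump(harm, test, clump_spec))
        harm.table = harm.table[harm.table["snp_id"].isin(kept)].reset_index(drop=True)
    raw = scoring.polygenic_score(harm, test, thresholds=(p_t,))
    std = scoring.standardize(raw)
    covars = association.ancestry_dims(test, k=k_dims) if k_dims > 0 else None
    return association.prs_association(std, test.phenotypes, covars)[0]


def estimate_power(
    config: SimConfig,
    p_t: float = 0.1,
    alpha: float = 0.05,
    n_replicates: int = 100,
    seed: int | None = None,
    *,
    clump_spec: ld.ClumpSpec = ld.ClumpSpec(),
    k_dims: int = 5,
    max_redraws: int = 20,
) -> PowerResult:
    """Monte-Carlo power of the PRS association at significance ``alpha``.

    Replicate r uses the simulation config reseeded deterministically
    from ``seed`` (default: the config's own seed); a replicate whose
    pipeline fails (e.g. separation in a degenerate draw) is re-drawn
    with a fresh sub-seed and counted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    base = int(config.seed if seed is None else seed)
    rep_seeds = np.random.SeedSequence(base).generate_state(n_replicates + max_redraws)
    rep_seeds = (rep_seeds % (2**31 - 1)).astype(np.int64)

    n_sig = 0
    n_failed = 0
    done = 0
    i = 0
    while done < n_replicates:
        if i >= len(rep_seeds):
            raise RuntimeError("replicate redraw budget exhausted")
        cfg = replace(config, seed=int(rep_seeds[i]))
        i += 1
        try:
            res = run_replicate(cfg, p_t, clump_spec=clump_spec, k_dims=k_dims)
        except (ValueError, RuntimeError, association.SeparationError) as exc:
            n_failed += 1
            logger.warning("replicate failed (%s); redrawing", exc)
            continue
        done += 1
        if res.wald_p < alpha:
            n_sig += 1
    ci_low, ci_high = proportion_confint(n_sig, n_replicates, alpha=0.05, method="wilson")
    return PowerResult(
        config=config, p_t=p_t, alpha=alpha,
        n_replicates=n_replicates, n_significant=n_sig,
        power=n_sig / n_replicates,
        ci_low=float(ci_low), ci_high=float(ci_high),
        n_failed=n_failed,
    )


def power_curve(
    config: SimConfig,
    effect_correlations: list[float],
    p_t: float = 0.1,
    alpha: float = 0.05,
    n_replicates: int = 100,
    seed: int | None = None,
    **kwargs,
) -> list[PowerResult]:
    """Power over a grid of effect correlations, all else fixed."""
    return [
        estimate_power(
            replace(config, effect_correlation=r), p_t, alpha, n_replicates,
            seed=seed, **kwargs,
        )
        for r in effect_correlations
    ]
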